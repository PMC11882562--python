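"""Domain types, meteorological features, group sums and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teacat import (
    CATECHINS,
    CatechinProfile,
    Dataset,
    MeteoVector,
    SchemaError,
    ValidationError,
    compute_eat,
    compute_rainy_day_rainfall,
    group_sums,
    read_dataset,
    write_dataset,
)
from teacat.core import average_replicates

conc = st.floats(min_value=0, max_value=20, allow_nan=False)


class TestComputeEat:
    @pytest.mark.parametrize(
        "temps, zero, clip, expected",
        [
            ([20, 30], 10, True, 15.0),
            ([10, 10, 10], 10, True, 0.0),
            ([8, 12], 10, True, 1.0),   # only the day above the zero accumulates
            ([8, 12], 10, False, 0.0),  # literal signed excess averages out
        ],
    )
    def test_examples(self, temps, zero, clip, expected):
        assert compute_eat(temps, biological_zero=zero, clip_negative=clip) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            compute_eat([])

    @given(st.lists(st.floats(min_value=10, max_value=45), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_unclipped_equals_shifted_mean_when_all_above_zero(self, temps):
        expected = float(np.mean(temps)) - 10.0
        assert compute_eat(temps, clip_negative=False) == pytest.approx(expected, abs=1e-9)
        assert compute_eat(temps, clip_negative=True) == pytest.approx(expected, abs=1e-9)


class TestRainyDayRainfall:
    @pytest.mark.parametrize(
        "rain, expected",
        [([0, 5, 0, 3], 4.0), ([2.2], 2.2), ([0, 0, 0], 0.0)],
    )
    def test_examples(self, rain, expected):
        assert compute_rainy_day_rainfall(rain) == pytest.approx(expected)

    def test_no_rainy_days_warns(self, caplog):
        with caplog.at_level("WARNING", logger="teacat"):
            assert compute_rainy_day_rainfall([0.0, 0.0]) == 0.0
        assert "no rainy days" in caplog.text

    def test_measurable_threshold_excludes_trace(self):
        # with a 0.1 mm threshold the 0.05 mm trace day is a dry day
        assert compute_rainy_day_rainfall([0.05, 5.0], measurable_threshold=0.1) == pytest.approx(5.0)

    def test_negative_rain_rejected(self):
        with pytest.raises(ValidationError):
            compute_rainy_day_rainfall([1.0, -0.1])


class TestGroupSums:
    def test_unit_profile(self):
        profile = CatechinProfile(**{m: 1.0 for m in CATECHINS})
        assert group_sums(profile) == (4.0, 3.0, 7.0)
        assert (profile.tec, profile.tnec, profile.tc) == (4.0, 3.0, 7.0)

    def test_zero_profile(self):
        assert group_sums({m: 0.0 for m in CATECHINS}) == (0.0, 0.0, 0.0)

    def test_reported_spring_decomposition(self):
        # published site totals: TEC 16.49 with EGCG 11.79 and ECG 3.32
        gcg_cg = 16.49 - 11.79 - 3.32
        profile = CatechinProfile(egc=0, c=0, ec=0, egcg=11.79, gcg=gcg_cg, ecg=3.32, cg=0)
        tec, _, _ = group_sums(profile)
        assert tec == pytest.approx(16.49, abs=1e-9)

    def test_missing_monomer_named(self):
        partial = {m: 1.0 for m in CATECHINS if m != "egcg"}
        with pytest.raises(ValidationError, match="egcg"):
            group_sums(partial)

    @given(
        st.tuples(*[conc] * 7),
        st.tuples(*[conc] * 7),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, a, b):
        pa = dict(zip(CATECHINS, a))
        pb = dict(zip(CATECHINS, b))
        psum = {m: pa[m] + pb[m] for m in CATECHINS}
        left = np.array(group_sums(psum))
        right = np.array(group_sums(pa)) + np.array(group_sums(pb))
        assert np.allclose(left, right, atol=1e-9)


class TestMeteoVector:
    def test_round_trip_array(self):
        v = MeteoVector(5, 20, 300, 30, 10, 80, 22, 5000)
        assert MeteoVector.from_array(v.to_array()) == v

    @pytest.mark.parametrize(
        "overrides",
        [
            {"rainfall": -1.0},
            {"humidity": 120.0},
            {"irradiance": -5.0},
            {"eat": -1.0},
            {"temp_min": 25.0},  # breaks temp_min <= temp_avg
        ],
    )
    def test_invariants_enforced(self, overrides):
        base = dict(rainfall=5, temp_avg=20, eat=300, temp_max=30, temp_min=10,
                    humidity=80, ground_temp=22, irradiance=5000)
        base.update(overrides)
        with pytest.raises(ValidationError):
            MeteoVector(**base)


class TestCatechinProfileValidation:
    def test_observed_negative_flagged(self):
        profile = CatechinProfile(egc=0.5, c=-0.01, ec=0.2, egcg=10, gcg=1, ecg=3, cg=0.2)
        with pytest.raises(ValidationError, match="'c'"):
            profile.validate_observed()


class TestDatasetIO:
    def test_round_trip(self, small_frame, tmp_path):
        ds = Dataset(small_frame, provenance="built")
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        numeric = back.frame.select_dtypes("number")
        orig = ds.frame[numeric.columns]
        assert np.allclose(numeric.to_numpy(), orig.to_numpy(), rtol=1e-9)
        assert list(back.frame["site"]) == list(ds.frame["site"])

    def test_missing_column_named(self, small_frame, tmp_path):
        broken = small_frame.drop(columns=["egcg", "gcg", "ecg", "cg", "egc", "c", "ec"]).drop(columns=["eat"])
        path = tmp_path / "broken.csv"
        broken.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="eat"):
            read_dataset(path)

    def test_partial_catechin_block_rejected(self, small_frame):
        with pytest.raises(SchemaError, match="egcg"):
            Dataset(small_frame.drop(columns=["egcg"]))

    def test_duplicate_site_season_rejected(self, small_frame):
        dup = pd.concat([small_frame, small_frame.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match=r"\(GD, spring\)"):
            Dataset(dup)

    def test_non_numeric_cell_located(self, small_frame):
        bad = small_frame.copy()
        bad["egcg"] = bad["egcg"].astype(object)
        bad.loc[1, "egcg"] = "n/a"
        with pytest.raises(SchemaError, match="egcg.*row 1"):
            Dataset(bad)

    def test_empty_rejected(self, small_frame):
        with pytest.raises(ValidationError):
            Dataset(small_frame.iloc[0:0])

    def test_unknown_season_rejected(self, small_frame):
        bad = small_frame.copy()
        bad.loc[0, "season"] = "winter"
        with pytest.raises(ValidationError, match="winter"):
            Dataset(bad)

    def test_records_expose_typed_values(self, small_frame):
        recs = list(Dataset(small_frame).records())
        assert recs[0].site_id == "GD"
        assert isinstance(recs[0].meteo, MeteoVector)
        assert recs[0].catechins.tc == pytest.approx(sum(recs[0].catechins.to_dict().values()))


def test_average_replicates_collapses_rows(small_frame):
    rep = pd.concat([small_frame, small_frame], ignore_index=True)
    rep.loc[2, "egcg"] = rep.loc[0, "egcg"] + 2.0  # replicate disagreement
    out = average_replicates(rep)
    assert len(out) == 2
    assert out.loc[out["site"] == "GD", "egcg"].iloc[0] == pytest.approx(small_frame.loc[0, "egcg"] + 1.0)
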