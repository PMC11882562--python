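"""Synthetic generator: bounds, determinism, generative truth, qPCR structure."""

import numpy as np
import pandas as pd
import pytest

from teacat import CATECHINS, FACTORS, GeneratorConfig, ValidationError, fit_ols, load_table1
from teacat.core import SchemaError
from teacat.optimize import OPTIMAL_CONDITIONS
from teacat.synth import (
    DEFAULT_METEO_BOUNDS,
    generate_catechins,
    generate_dataset,
    generate_meteo,
    generate_qpcr,
)

ZERO_NOISE = {m: 0.0 for m in CATECHINS}


class TestGenerateMeteo:
    def test_layout_and_bounds(self):
        ds = generate_meteo(GeneratorConfig(seed=3))
        assert ds.n == 30  # 10 sites x 3 seasons
        for j, f in enumerate(FACTORS):
            lo, hi = DEFAULT_METEO_BOUNDS[f]
            col = ds.meteo_matrix()[:, j]
            assert col.min() >= lo and col.max() <= hi
        # temperature ordering holds record by record
        X = ds.frame
        assert (X["temp_min"] <= X["temp_avg"]).all()
        assert (X["temp_avg"] <= X["temp_max"]).all()

    def test_seed_determinism(self):
        a = generate_meteo(GeneratorConfig(seed=5)).frame
        b = generate_meteo(GeneratorConfig(seed=5)).frame
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_bounds_give_constant_column(self):
        bounds = dict(DEFAULT_METEO_BOUNDS)
        bounds["humidity"] = (80.0, 80.0)
        ds = generate_meteo(GeneratorConfig(seed=5, meteo_bounds=bounds))
        assert (ds.frame["humidity"] == 80.0).all()

    def test_correlation_knob_couples_eat_to_temperature(self):
        free = generate_meteo(GeneratorConfig(seed=6, n_sites=60))
        tied = generate_meteo(GeneratorConfig(seed=6, n_sites=60, factor_correlation=0.8))
        r_free = np.corrcoef(free.frame["temp_avg"], free.frame["eat"])[0, 1]
        r_tied = np.corrcoef(tied.frame["temp_avg"], tied.frame["eat"])[0, 1]
        assert r_tied > 0.5 > abs(r_free)
        for j, f in enumerate(FACTORS):  # blending must stay inside the box
            lo, hi = DEFAULT_METEO_BOUNDS[f]
            col = tied.meteo_matrix()[:, j]
            assert col.min() >= lo and col.max() <= hi

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(seed=1, n_sites=0)
        with pytest.raises(ValidationError):
            GeneratorConfig(seed=1, seasons=())
        bad = dict(DEFAULT_METEO_BOUNDS)
        bad["rainfall"] = (5.0, 1.0)
        with pytest.raises(ValidationError):
            GeneratorConfig(seed=1, meteo_bounds=bad)


class TestGenerateCatechins:
    def test_noise_free_reproduces_reported_egcg_optimum(self, dataset_at_vector):
        ds = dataset_at_vector(OPTIMAL_CONDITIONS["egcg"])
        out = generate_catechins(ds, noise_sd=ZERO_NOISE, seed=1)
        assert round(float(out.frame["egcg"].iloc[0]), 2) == 14.46

    def test_noise_free_at_zero_factors_gives_intercepts(self, dataset_at_vector):
        ds = dataset_at_vector(np.zeros(8))
        out = generate_catechins(ds, noise_sd=ZERO_NOISE, seed=1)
        table = load_table1()
        for m in CATECHINS:
            expected = table[m].intercept
            # negative intercepts are floored at zero by the generator
            assert float(out.frame[m].iloc[0]) == pytest.approx(max(expected, 0.0), abs=1e-12)

    def test_large_noise_floors_cg(self):
        ds = generate_meteo(GeneratorConfig(seed=9))
        noisy = {m: 0.0 for m in CATECHINS}
        noisy["cg"] = 1.0  # large against the small cg intercept
        out = generate_catechins(ds, noise_sd=noisy, seed=10)
        assert out.frame.attrs["floored_negative"] > 0
        assert (out.frame["cg"] >= 0).all()

    def test_missing_response_rejected(self, noise_free_dataset):
        table = load_table1()
        del table.models["cg"]
        with pytest.raises(SchemaError, match="cg"):
            generate_catechins(noise_free_dataset, coefficient_table=table, seed=1)

    def test_seed_required(self, noise_free_dataset):
        with pytest.raises(ValidationError):
            generate_catechins(noise_free_dataset)


class TestIdentifiability:
    def test_noise_free_ols_recovers_generating_table(self, noise_free_dataset, table1):
        for m in CATECHINS:
            fitted = fit_ols(noise_free_dataset, m)
            assert abs(fitted.intercept - table1[m].intercept) < 1e-6
            assert np.max(np.abs(fitted.coef_array() - table1[m].coef_array())) < 1e-6

    def test_coefficient_rmse_shrinks_with_n(self, table1):
        def coef_rmse(n_sites, seed):
            ds = generate_meteo(GeneratorConfig(seed=seed, n_sites=n_sites))
            ds = generate_catechins(ds, seed=seed + 1)
            errs = []
            for m in CATECHINS:
                fitted = fit_ols(ds, m)
                errs.extend(fitted.coef_array() - table1[m].coef_array())
            return float(np.sqrt(np.mean(np.square(errs))))

        assert coef_rmse(100, 31) < coef_rmse(10, 31)


class TestGenerateQpcr:
    links = {"CsCHS1": {"rainfall": 2.0}, "CsSCPL": {}}

    def test_zero_links_zero_noise_give_unit_expression(self):
        from teacat.expression import delta_delta_ct

        ds = generate_meteo(GeneratorConfig(seed=13))
        ct = generate_qpcr(ds, {"CsSCPL": {}}, seed=14)
        ref = f"{ds.frame.iloc[0]['site']}_{ds.frame.iloc[0]['season']}"
        rel = delta_delta_ct(ct, reference_sample=ref)
        assert np.allclose(rel.to_numpy(), 1.0, atol=1e-12)

    def test_positive_link_raises_expression_with_factor(self):
        from teacat.expression import delta_delta_ct

        ds = generate_meteo(GeneratorConfig(seed=15, n_sites=67))  # ~200 samples
        ct = generate_qpcr(ds, self.links, seed=16, ct_noise_sd=0.1)
        ref = f"{ds.frame.iloc[0]['site']}_{ds.frame.iloc[0]['season']}"
        rel = delta_delta_ct(ct, reference_sample=ref)
        samples = [f"{r.site}_{r.season}" for r in ds.frame.itertuples(index=False)]
        expr = np.array([rel.loc["CsCHS1", s] for s in samples])
        rain = ds.frame["rainfall"].to_numpy()
        high = expr[rain > np.median(rain)].mean()
        low = expr[rain <= np.median(rain)].mean()
        assert high > low

    def test_seed_determinism(self):
        ds = generate_meteo(GeneratorConfig(seed=17))
        a = generate_qpcr(ds, self.links, seed=18, ct_noise_sd=0.2)
        b = generate_qpcr(ds, self.links, seed=18, ct_noise_sd=0.2)
        pd.testing.assert_frame_equal(a, b)

    def test_reference_gene_among_targets_rejected(self):
        ds = generate_meteo(GeneratorConfig(seed=19))
        with pytest.raises(ValidationError, match="GAPDH"):
            generate_qpcr(ds, {"GAPDH": {}}, seed=20)


def test_generate_dataset_is_reproducible_end_to_end():
    cfg = GeneratorConfig(seed=23, expression_links={"CsANR": {"temp_avg": 1.0}}, ct_noise_sd=0.05)
    a = generate_dataset(cfg).frame
    b = generate_dataset(cfg).frame
    pd.testing.assert_frame_equal(a, b)
    assert "expr_CsANR" in a.columns
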