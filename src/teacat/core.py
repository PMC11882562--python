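"""Domain types and shared primitives for the tea-catechin / meteorology pipeline.

The study design is 10 tea-plantation sites sampled over three growing
seasons.  Each (site, season) record carries eight season-aggregate
meteorological factors and the concentrations of the seven catechin
monomers of *Camellia sinensis* leaves, expressed in percent dry mass:

====================  =========================================  ========
column                factor                                     unit
====================  =========================================  ========
rainfall              average daily rainfall on rainy days       mm/day
temp_avg              average air temperature                    deg C
eat                   effective accumulated temperature (EAT)    deg C
temp_max              maximum air temperature                    deg C
temp_min              minimum air temperature                    deg C
humidity              average relative humidity                  % RH
ground_temp           average 10-cm ground temperature           deg C
irradiance            average daily irradiance                   lux
====================  =========================================  ========

Catechin monomers: EGC, C, EC (non-esterified) and EGCG, GCG, ECG, CG
(esterified / galloylated).  Derived group sums: TEC (esterified),
TNEC (non-esterified) and TC (total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("teacat")

SEASONS: tuple[str, ...] = ("spring", "summer", "autumn")

#: canonical factor order; matches the symbol order x1..x8 used throughout
FACTORS: tuple[str, ...] = (
    "rainfall",
    "temp_avg",
    "eat",
    "temp_max",
    "temp_min",
    "humidity",
    "ground_temp",
    "irradiance",
)

FACTOR_UNITS: dict[str, str] = {
    "rainfall": "mm/day",
    "temp_avg": "degC",
    "eat": "degC",
    "temp_max": "degC",
    "temp_min": "degC",
    "humidity": "%RH",
    "ground_temp": "degC",
    "irradiance": "lux",
}

CATECHINS: tuple[str, ...] = ("egc", "c", "ec", "egcg", "gcg", "ecg", "cg")

#: esterified (galloylated) monomers -> TEC
TEC_GROUP: tuple[str, ...] = ("egcg", "gcg", "ecg", "cg")
#: non-esterified monomers -> TNEC
TNEC_GROUP: tuple[str, ...] = ("egc", "c", "ec")

GROUPS: dict[str, tuple[str, ...]] = {"TEC": TEC_GROUP, "TNEC": TNEC_GROUP}

#: canonical CSV column order (expression columns, prefixed ``expr_``, follow)
CSV_COLUMNS: tuple[str, ...] = ("site", "season") + FACTORS + CATECHINS


class TeacatError(Exception):
    """Base class for package errors."""


class SchemaError(TeacatError):
    """Malformed tabular input (missing column, bad cell, duplicate key)."""


class ValidationError(TeacatError):
    """A domain invariant is violated."""


# ---------------------------------------------------------------------------
# value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeteoVector:
    """One site-season's eight meteorological factors (x1..x8)."""

    rainfall: float
    temp_avg: float
    eat: float
    temp_max: float
    temp_min: float
    humidity: float
    ground_temp: float
    irradiance: float

    def __post_init__(self) -> None:
        if self.rainfall < 0:
            raise ValidationError(f"rainfall must be >= 0, got {self.rainfall}")
        if not 0 <= self.humidity <= 100:
            raise ValidationError(f"humidity must be in [0, 100], got {self.humidity}")
        if self.irradiance < 0:
            raise ValidationError(f"irradiance must be >= 0, got {self.irradiance}")
        if self.eat < 0:
            raise ValidationError(f"eat must be >= 0, got {self.eat}")
        if not self.temp_min <= self.temp_avg <= self.temp_max:
            raise ValidationError(
                "temperature ordering violated: need temp_min <= temp_avg <= "
                f"temp_max, got {self.temp_min}, {self.temp_avg}, {self.temp_max}"
            )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FACTORS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "MeteoVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FACTORS),):
            raise ValidationError(f"expected {len(FACTORS)} factor values, got shape {values.shape}")
        return cls(**dict(zip(FACTORS, values.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FACTORS}


@dataclass(frozen=True)
class CatechinProfile:
    """Seven catechin monomer concentrations in percent dry mass.

    Group sums (``tec``, ``tnec``, ``tc``) are derived, never stored, so they
    are exact by construction.  Observed profiles must be non-negative; model
    predictions may go negative and are handled (flagged) by the callers.
    """

    egc: float
    c: float
    ec: float
    egcg: float
    gcg: float
    ecg: float
    cg: float

    @property
    def tec(self) -> float:
        return self.egcg + self.gcg + self.ecg + self.cg

    @property
    def tnec(self) -> float:
        return self.egc + self.c + self.ec

    @property
    def tc(self) -> float:
        return self.tec + self.tnec

    def to_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in CATECHINS}

    def validate_observed(self) -> None:
        """Raise if any monomer is negative (observed data must be >= 0)."""
        for m in CATECHINS:
            if getattr(self, m) < 0:
                raise ValidationError(f"observed catechin {m!r} is negative: {getattr(self, m)}")


@dataclass(frozen=True)
class SampleRecord:
    """Per-(site, season) mean record: biological replicates are averaged upstream."""

    site_id: str
    season: str
    meteo: MeteoVector
    catechins: CatechinProfile | None = None
    expression: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(f"season must be one of {SEASONS}, got {self.season!r}")


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Ordered collection of site-season records, backed by a DataFrame.

    Column layout follows :data:`CSV_COLUMNS`; catechin columns are optional
    as a block (all seven or none), and relative-expression columns use the
    ``expr_<gene>`` prefix.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        f = self.frame
        if len(f) == 0:
            raise ValidationError("dataset is empty")
        missing = [c for c in ("site", "season") + FACTORS if c not in f.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        bad_season = sorted(set(f["season"]) - set(SEASONS))
        if bad_season:
            raise ValidationError(f"unknown season value(s): {bad_season}; expected one of {SEASONS}")
        dup = f.duplicated(subset=["site", "season"])
        if dup.any():
            pairs = f.loc[dup, ["site", "season"]].itertuples(index=False)
            raise ValidationError(
                "duplicate (site, season) record(s): " + ", ".join(f"({s}, {n})" for s, n in pairs)
            )
        present = [c for c in CATECHINS if c in f.columns]
        if present and len(present) != len(CATECHINS):
            raise SchemaError(
                f"catechin columns must be all-or-none; missing {sorted(set(CATECHINS) - set(present))}"
            )
        for col in ["expr_" + g for g in self.expression_genes()] + list(FACTORS) + present:
            vals = pd.to_numeric(f[col], errors="coerce")
            if vals.isna().any():
                row = int(f.index[vals.isna()][0])
                raise SchemaError(f"non-numeric cell in column {col!r}, row {row}")
            self.frame[col] = vals.astype(float)
        self.frame = self.frame.reset_index(drop=True)

    # -- accessors ----------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def has_catechins(self) -> bool:
        return all(c in self.frame.columns for c in CATECHINS)

    def expression_genes(self) -> list[str]:
        return [c[len("expr_"):] for c in self.frame.columns if c.startswith("expr_")]

    def meteo_matrix(self) -> np.ndarray:
        """n x 8 factor matrix in canonical x1..x8 order."""
        return self.frame[list(FACTORS)].to_numpy(dtype=float)

    def response(self, name: str) -> np.ndarray:
        """Response column (catechin monomer or ``expr_<gene>``)."""
        if name not in self.frame.columns:
            raise SchemaError(f"response column {name!r} not in dataset")
        return self.frame[name].to_numpy(dtype=float)

    def records(self) -> Iterator[SampleRecord]:
        genes = self.expression_genes()
        for _, row in self.frame.iterrows():
            meteo = MeteoVector(**{f: float(row[f]) for f in FACTORS})
            cat = CatechinProfile(**{m: float(row[m]) for m in CATECHINS}) if self.has_catechins else None
            expr = {g: float(row["expr_" + g]) for g in genes} or None
            yield SampleRecord(str(row["site"]), str(row["season"]), meteo, cat, expr)

    def with_frame(self, frame: pd.DataFrame, provenance: str | None = None) -> "Dataset":
        return Dataset(frame, self.provenance if provenance is None else provenance)


# ---------------------------------------------------------------------------
# meteorological feature construction
# ---------------------------------------------------------------------------


def compute_eat(
    daily_mean_temps: Sequence[float],
    biological_zero: float = 10.0,
    clip_negative: bool = True,
) -> float:
    """Effective accumulated temperature statistic from daily mean temperatures.

    The daily excess over the biological zero (10 degC for tea) is averaged
    over the observation period.  By the growing-degree convention, days
    below the biological zero contribute nothing (``clip_negative=True``,
    the default); with ``clip_negative=False`` the literal signed excess is
    averaged instead.
    """
    temps = np.asarray(daily_mean_temps, dtype=float)
    if temps.size == 0:
        raise ValidationError("compute_eat: empty temperature sequence")
    excess = temps - biological_zero
    if clip_negative:
        excess = np.maximum(excess, 0.0)
    return float(excess.mean())


def compute_rainy_day_rainfall(
    daily_rain: Sequence[float], measurable_threshold: float = 0.0
) -> float:
    """Average daily rainfall over days with measurable precipitation.

    Rainfall strictly above ``measurable_threshold`` (default 0 mm) counts as
    measurable; dry days are excluded from the denominator.  A period with no
    rainy days returns 0 with a warning rather than dividing by zero.
    """
    rain = np.asarray(daily_rain, dtype=float)
    if rain.size == 0:
        raise ValidationError("compute_rainy_day_rainfall: empty rainfall sequence")
    if (rain < 0).any():
        raise ValidationError("compute_rainy_day_rainfall: negative rainfall value")
    rainy = rain[rain > measurable_threshold]
    if rainy.size == 0:
        logger.warning("no rainy days in period; rainy-day rainfall set to 0")
        return 0.0
    return float(rainy.mean())


def group_sums(profile: CatechinProfile | Mapping[str, float]) -> tuple[float, float, float]:
    """(TEC, TNEC, TC) group sums from the seven monomer concentrations."""
    if isinstance(profile, CatechinProfile):
        values = profile.to_dict()
    else:
        values = dict(profile)
        missing = [m for m in CATECHINS if m not in values]
        if missing:
            raise ValidationError(f"missing catechin monomer(s): {', '.join(missing)}")
    tec = sum(values[m] for m in TEC_GROUP)
    tnec = sum(values[m] for m in TNEC_GROUP)
    return tec, tnec, tec + tnec


def average_replicates(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows to per-(site, season) means of numeric columns."""
    numeric = frame.select_dtypes(include=[np.number]).columns
    out = frame.groupby(["site", "season"], sort=False, as_index=False)[list(numeric)].mean()
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _ordered_columns(frame: pd.DataFrame) -> list[str]:
    head = [c for c in CSV_COLUMNS if c in frame.columns]
    expr = sorted(c for c in frame.columns if c.startswith("expr_"))
    rest = [c for c in frame.columns if c not in head and c not in expr]
    return head + rest + expr


def read_dataset(path: str | Path) -> Dataset:
    """Read a canonical site-season CSV into a :class:`Dataset`."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"site": str, "season": str})
    return Dataset(frame, provenance=str(path))


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a :class:`Dataset` back to CSV with a stable column order."""
    cols = _ordered_columns(dataset.frame)
    dataset.frame[cols].to_csv(path, index=False)
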