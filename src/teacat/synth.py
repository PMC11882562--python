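"""Synthetic site-season datasets with the statistical structure the pipeline assumes.

The generator emulates the study layout -- 10 plantation sites sampled in
spring, summer and autumn -- without any real download:

* meteorological factors are drawn uniformly inside a per-factor box
  (defaulting to the range spanned by the published optimal condition
  vectors), then repaired so temp_min <= temp_avg <= temp_max;
* catechin concentrations follow the published linear equations plus
  Gaussian noise, floored at zero (concentrations cannot be negative);
* optional qPCR threshold-cycle (Ct) tables in which the implied
  2^-ddCt relative expression follows a configured log-linear response
  to the factors, with cycle-scale Gaussian noise.

Everything is driven by one integer seed, so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    CATECHINS,
    FACTORS,
    SEASONS,
    Dataset,
    SchemaError,
    ValidationError,
)
from .regression import CoefficientTable, load_table1

logger = logging.getLogger("teacat")

__all__ = [
    "GeneratorConfig",
    "DEFAULT_METEO_BOUNDS",
    "DEFAULT_NOISE_SD",
    "generate_meteo",
    "generate_catechins",
    "generate_qpcr",
    "generate_dataset",
]

#: sampling box per factor.  Ranges are those spanned by the published
#: optimal condition vectors; temp_min gets a non-degenerate upper bound
#: (all published optima share temp_min = -3.6) chosen at the low end of
#: the temp_avg range so the temperature ordering holds without repair.
DEFAULT_METEO_BOUNDS: dict[str, tuple[float, float]] = {
    "rainfall": (1.13, 9.78),
    "temp_avg": (12.72, 25.53),
    "eat": (223.50, 553.74),
    "temp_max": (26.9, 35.30),
    "temp_min": (-3.60, 12.72),
    "humidity": (75.50, 96.34),
    "ground_temp": (14.36, 30.65),
    "irradiance": (1283.50, 8421.08),
}

#: per-response noise standard deviation (% dry mass): the published RMSEC
#: magnitudes scaled x10 -- the printed values (e.g. 0.0156 for EGCG against
#: concentrations above 10%) are implausibly small as generative noise.
DEFAULT_NOISE_SD: dict[str, float] = {
    "egc": 0.0044,
    "c": 0.0538,
    "ec": 0.0051,
    "egcg": 0.1559,
    "gcg": 0.0206,
    "ecg": 0.0847,
    "cg": 0.0038,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    The defaults reproduce the study conditions: 10 sites x 3 seasons,
    factors inside the observed box, catechins from the published
    equations.  ``seed`` has no default -- every draw must be reproducible.
    """

    seed: int
    n_sites: int = 10
    seasons: tuple[str, ...] = SEASONS
    meteo_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METEO_BOUNDS)
    )
    coefficient_table: CoefficientTable | None = None  # None -> published table
    noise_sd: Mapping[str, float] | None = None        # None -> DEFAULT_NOISE_SD
    expression_links: Mapping[str, Mapping[str, float]] | None = None
    reference_gene: str = "GAPDH"
    ct_noise_sd: float = 0.0
    #: 0 = independent factors; >0 couples eat (and ground_temp) to temp_avg,
    #: emulating the temperature/heat-sum collinearity of real seasons
    factor_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if not self.seasons:
            raise ValidationError("at least one season is required")
        bad = sorted(set(self.seasons) - set(SEASONS))
        if bad:
            raise ValidationError(f"unknown season(s) {bad}; expected subset of {SEASONS}")
        missing = [f for f in FACTORS if f not in self.meteo_bounds]
        if missing:
            raise ValidationError(f"meteo_bounds missing factor(s): {', '.join(missing)}")
        for f in FACTORS:
            lo, hi = self.meteo_bounds[f]
            if lo > hi:
                raise ValidationError(f"meteo_bounds low > high for {f!r}: ({lo}, {hi})")
        if self.noise_sd is not None:
            neg = [r for r, sd in self.noise_sd.items() if sd < 0]
            if neg:
                raise ValidationError(f"noise_sd must be >= 0; negative for {neg}")
        if not 0.0 <= self.factor_correlation < 1.0:
            raise ValidationError(
                f"factor_correlation must be in [0, 1), got {self.factor_correlation}"
            )

    def table(self) -> CoefficientTable:
        return self.coefficient_table if self.coefficient_table is not None else load_table1()

    def noise(self) -> dict[str, float]:
        return dict(self.noise_sd) if self.noise_sd is not None else dict(DEFAULT_NOISE_SD)


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------


def _repair_temperatures(frame: pd.DataFrame) -> int:
    """Enforce temp_min <= temp_avg <= temp_max by sorting each row's triple.

    Returns the number of repaired rows.  With the default bounds the three
    ranges barely overlap, so repairs are rare-to-absent.
    """
    triple = frame[["temp_min", "temp_avg", "temp_max"]].to_numpy()
    bad = ~((triple[:, 0] <= triple[:, 1]) & (triple[:, 1] <= triple[:, 2]))
    if bad.any():
        fixed = np.sort(triple[bad], axis=1)
        frame.loc[bad, ["temp_min", "temp_avg", "temp_max"]] = fixed
    return int(bad.sum())


def generate_meteo(config: GeneratorConfig) -> Dataset:
    """Draw the meteorological block: one record per (site, season)."""
    rng = np.random.default_rng(config.seed)
    sites = [f"S{i+1:02d}" for i in range(config.n_sites)]
    rows = []
    for season in config.seasons:
        for site in sites:
            rows.append({"site": site, "season": season})
    frame = pd.DataFrame(rows)
    n = len(frame)
    for f in FACTORS:
        lo, hi = config.meteo_bounds[f]
        frame[f] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    rho = config.factor_correlation
    if rho > 0:
        # blend heat-linked factors toward temp_avg rescaled into their own
        # range: convex combination of in-range values stays in range
        t_lo, t_hi = config.meteo_bounds["temp_avg"]
        t_unit = (frame["temp_avg"] - t_lo) / (t_hi - t_lo) if t_hi > t_lo else 0.5
        for f in ("eat", "ground_temp"):
            lo, hi = config.meteo_bounds[f]
            frame[f] = (1 - rho) * frame[f] + rho * (lo + t_unit * (hi - lo))
    repaired = _repair_temperatures(frame)
    if repaired:
        logger.info("repaired temperature ordering in %d record(s)", repaired)
    return Dataset(frame, provenance=f"synthetic meteo, seed={config.seed}")


# ---------------------------------------------------------------------------
# catechins
# ---------------------------------------------------------------------------


def generate_catechins(
    dataset: Dataset,
    coefficient_table: CoefficientTable | None = None,
    noise_sd: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> Dataset:
    """Fill the catechin block from the linear equations plus Gaussian noise.

    Each monomer is ``b0 + b.x + N(0, sd^2)``; negative draws are floored at
    0 and the count is logged (flooring should be rare at realistic noise).
    """
    if seed is None:
        raise ValidationError("generate_catechins requires an explicit seed")
    table = coefficient_table if coefficient_table is not None else load_table1()
    sds = dict(noise_sd) if noise_sd is not None else dict(DEFAULT_NOISE_SD)
    missing = [m for m in CATECHINS if m not in table]
    if missing:
        raise SchemaError(f"coefficient table missing response(s): {', '.join(missing)}")
    rng = np.random.default_rng(seed)
    X = dataset.meteo_matrix()
    frame = dataset.frame.copy()
    floored_total = 0
    for m in CATECHINS:
        model = table[m]
        sd = float(sds.get(m, 0.0))
        y = model.intercept + X @ model.coef_array()
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=len(y))
        floored = int((y < 0).sum())
        if floored:
            logger.info("floored %d negative draw(s) of %s at 0", floored, m)
            floored_total += floored
            y = np.maximum(y, 0.0)
        frame[m] = y
    frame.attrs["floored_negative"] = floored_total
    return Dataset(frame, provenance=dataset.provenance + f" + catechins(seed={seed})")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def generate_qpcr(
    dataset: Dataset,
    expression_links: Mapping[str, Mapping[str, float]],
    reference_gene: str = "GAPDH",
    seed: int | None = None,
    ct_noise_sd: float = 0.0,
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Emit a long-format Ct table (sample, gene, ct_target, ct_reference).

    For each gene the log2 relative expression is a linear function of the
    factors scaled to [0, 1] inside the generator box: log2(rel) = w . z(x),
    where ``w`` is the gene's sparse factor-weight vector.  Ct values are
    constructed so 2^-ddCt against any reference sample with z = z_ref
    recovers exactly that response; ``ct_noise_sd`` adds cycle-scale
    Gaussian noise to the target Ct (multiplicative noise on expression).
    """
    if seed is None:
        raise ValidationError("generate_qpcr requires an explicit seed")
    if reference_gene in expression_links:
        raise ValidationError(f"reference gene {reference_gene!r} listed among targets")
    rng = np.random.default_rng(seed)
    X = dataset.meteo_matrix()
    # scale factors to [0, 1] over their observed range (constant -> 0)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    Z = (X - lo) / span
    samples = [f"{r.site}_{r.season}" for r in dataset.frame.itertuples(index=False)]
    rows = []
    for gene, weights in expression_links.items():
        w = np.array([float(weights.get(f, 0.0)) for f in FACTORS])
        log2rel = Z @ w
        ct_target = base_ct - log2rel
        if ct_noise_sd > 0:
            ct_target = ct_target + rng.normal(0.0, ct_noise_sd, size=len(ct_target))
        for s, ct in zip(samples, ct_target):
            rows.append(
                {"sample": s, "gene": gene, "ct_target": float(ct), "ct_reference": reference_ct}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Meteorology plus catechins (plus expr_ columns if links are configured)."""
    ds = generate_meteo(config)
    ds = generate_catechins(ds, config.coefficient_table, config.noise_sd, seed=config.seed + 1)
    if config.expression_links:
        ct = generate_qpcr(
            ds, config.expression_links, config.reference_gene,
            seed=config.seed + 2, ct_noise_sd=config.ct_noise_sd,
        )
        from .expression import delta_delta_ct

        ref_sample = f"{ds.frame.iloc[0]['site']}_{ds.frame.iloc[0]['season']}"
        rel = delta_delta_ct(ct, reference_sample=ref_sample)
        frame = ds.frame.copy()
        sample_ids = [f"{r.site}_{r.season}" for r in frame.itertuples(index=False)]
        for gene in rel.index:
            frame["expr_" + gene] = [float(rel.loc[gene, s]) for s in sample_ids]
        ds = Dataset(frame, provenance=ds.provenance + " + expression")
    return ds
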