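"""qPCR expression processing: 2^-ddCt, amplification efficiency, clustering order.

Relative expression of each biosynthesis gene is computed against an
internal reference gene (GAPDH in the study) and a reference sample (the
BM plantation), by the standard threshold-cycle arithmetic:

    dCt  = Ct_target - Ct_reference          (per sample and gene)
    ddCt = dCt_sample - dCt_reference_sample
    rel  = 2^-ddCt

Amplification efficiency comes from a cDNA dilution series (5x, 25x, 125x
in the study): the slope of Ct against log10 relative concentration gives
E = 10^(-1/slope) - 1, with E = 1 for perfect per-cycle doubling.

For heatmap-style reporting the module computes a deterministic
hierarchical-clustering leaf order (Euclidean distance, average linkage by
default) of the log2-transformed matrix; rendering itself is left to any
plotting layer.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from .core import SchemaError, ValidationError

logger = logging.getLogger("teacat")

__all__ = [
    "delta_delta_ct",
    "log2_matrix",
    "amplification_efficiency",
    "hclust_leaf_order",
]

_CT_RANGE = (0.0, 60.0)


def _validate_ct_table(records: pd.DataFrame) -> pd.DataFrame:
    required = ["sample", "gene", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise SchemaError(f"Ct table missing column(s): {', '.join(missing)}")
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(records[col], errors="coerce")
        if vals.isna().any():
            raise SchemaError(f"non-numeric Ct in column {col!r}")
        if ((vals <= _CT_RANGE[0]) | (vals >= _CT_RANGE[1])).any():
            raise ValidationError(f"Ct values in {col!r} must lie in (0, 60)")
    return records


def delta_delta_ct(
    records: pd.DataFrame,
    reference_sample: str | None = None,
    reference_site: str | None = None,
) -> pd.DataFrame:
    """Genes x samples matrix of 2^-ddCt relative expression.

    Replicate rows (same sample and gene) are averaged on the Ct scale
    before the ddCt step.  With ``reference_sample``, every sample is
    normalized to that one sample (global reference); with
    ``reference_site`` and ``site_season`` sample ids, each sample is
    normalized to the reference site's sample of the *same season*
    (per-season reference).  Reference columns are exactly 1 for every
    gene by construction.
    """
    if (reference_sample is None) == (reference_site is None):
        raise ValidationError("give exactly one of reference_sample or reference_site")
    records = _validate_ct_table(records)
    mean_ct = records.groupby(["gene", "sample"], sort=False)[["ct_target", "ct_reference"]].mean()
    dct = (mean_ct["ct_target"] - mean_ct["ct_reference"]).unstack("sample")
    if dct.isna().any().any():
        gene, sample = next(
            (g, s) for g in dct.index for s in dct.columns if pd.isna(dct.loc[g, s])
        )
        raise SchemaError(f"missing Ct record for gene {gene!r}, sample {sample!r}")

    def _ref_column(name: str) -> pd.Series:
        if name not in dct.columns:
            raise SchemaError(f"reference sample {name!r} absent from Ct table")
        return dct[name]

    if reference_sample is not None:
        ddct = dct.sub(_ref_column(reference_sample), axis=0)
    else:
        ddct = dct.copy()
        for sample in dct.columns:
            try:
                _, season = str(sample).rsplit("_", 1)
            except ValueError:
                raise ValidationError(
                    f"per-season reference needs 'site_season' sample ids, got {sample!r}"
                ) from None
            ddct[sample] = dct[sample] - _ref_column(f"{reference_site}_{season}")
    return 2.0 ** (-ddct)


def log2_matrix(rel: pd.DataFrame) -> pd.DataFrame:
    """log2 view of a relative-expression matrix (values must be > 0)."""
    if (rel <= 0).any().any():
        raise ValidationError("relative expression must be > 0 for log2 transform")
    return np.log2(rel)


def amplification_efficiency(
    dilution_cts: Sequence[tuple[float, float]],
) -> float:
    """Amplification efficiency from a (dilution factor, Ct) series.

    The regression is Ct on log10 relative concentration (= -log10 of the
    dilution factor), so the slope is negative; E = 10^(-1/slope) - 1.
    A slope of exactly -log2(10)^-1... i.e. -3.3219 corresponds to perfect
    doubling and E = 1.  Slopes outside (-10, -1) trigger a warning for an
    implausible efficiency.
    """
    pairs = list(dilution_cts)
    if len(pairs) < 3:
        raise ValidationError("efficiency needs >= 3 dilution points")
    dilutions = np.array([d for d, _ in pairs], dtype=float)
    cts = np.array([ct for _, ct in pairs], dtype=float)
    if (dilutions <= 0).any():
        raise ValidationError("dilution factors must be > 0")
    if len(np.unique(dilutions)) != len(dilutions):
        raise ValidationError("dilution factors must be distinct")
    log_conc = -np.log10(dilutions)
    fit = linregress(log_conc, cts)
    slope = float(fit.slope)
    if not -10.0 < slope < -1.0:
        logger.warning("implausible efficiency: dilution-series slope %.4g", slope)
    if slope == 0:
        raise ValidationError("zero slope: dilution series carries no signal")
    return float(10.0 ** (-1.0 / slope) - 1.0)


def hclust_leaf_order(
    matrix: pd.DataFrame,
    axis: str = "rows",
    linkage_method: str = "average",
) -> list[str]:
    """Deterministic hierarchical-clustering leaf order (Euclidean distance).

    Labels are pre-sorted so distance ties resolve identically across runs;
    the default linkage is average (UPGMA), configurable to complete,
    single or ward.
    """
    if axis not in ("rows", "columns"):
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = matrix if axis == "rows" else matrix.T
    if len(data) < 2:
        raise ValidationError("clustering needs at least 2 items")
    if data.isna().any().any():
        raise ValidationError("clustering input contains NaN entries")
    data = data.sort_index()  # label-sorted input -> deterministic tie-breaks
    Z = linkage(pdist(data.to_numpy(dtype=float), metric="euclidean"), method=linkage_method)
    order = leaves_list(Z)
    return [str(label) for label in data.index[order]]
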