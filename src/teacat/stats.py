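"""Descriptive statistics: Pearson correlation with significance stars and PCA.

The correlation report follows the study's star convention:
``*`` for 0.01 < p <= 0.05, ``**`` for 0.001 < p <= 0.01 and ``***`` for
p <= 0.001 (two-sided t-test on r).

PCA of the seven-catechin profiles runs on the correlation matrix by
default (variables standardized to unit variance), so the squared
component standard deviations sum to the number of variables.  Loading
signs are fixed by making each loading vector's largest-magnitude entry
positive, removing the usual eigenvector sign arbitrariness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CATECHINS, Dataset, ValidationError

__all__ = ["CorrelationReport", "PcaResult", "pearson_with_stars", "pca_catechins", "star_code"]


def star_code(p: float) -> str:
    """Significance stars per the closed-interval convention."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """(var1, var2, r, p, stars) rows for the upper triangle."""
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(self.r.index):
            for b in cols:
                if a == b:
                    continue
                rows.append(
                    {"var1": a, "var2": b, "r": self.r.loc[a, b],
                     "p": self.p.loc[a, b], "stars": self.stars.loc[a, b]}
                )
        return pd.DataFrame(rows)


def pearson_with_stars(
    data: Dataset | pd.DataFrame,
    variables: Sequence[str] | None = None,
    columns: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> CorrelationReport:
    """Pearson r, two-sided p and star codes between two variable sets.

    With only ``variables`` given the report is the square symmetric matrix
    among them; ``columns`` selects a second set for a rectangular report
    (e.g. factors x catechins).  ``bh_correct=True`` applies
    Benjamini-Hochberg across the off-diagonal p-values before starring.
    """
    frame = data.frame if isinstance(data, Dataset) else data
    rows_vars = list(variables) if variables is not None else [c for c in CATECHINS if c in frame.columns]
    cols_vars = list(columns) if columns is not None else rows_vars
    n = len(frame)
    if n < 4:
        raise ValidationError(f"Pearson correlation needs n >= 4, got {n}")
    for v in set(rows_vars) | set(cols_vars):
        x = frame[v].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValidationError(f"r undefined: variable {v!r} has zero variance")
    r = pd.DataFrame(index=rows_vars, columns=cols_vars, dtype=float)
    p = pd.DataFrame(index=rows_vars, columns=cols_vars, dtype=float)
    for a in rows_vars:
        for b in cols_vars:
            if a == b:
                r.loc[a, b], p.loc[a, b] = 1.0, 0.0
                continue
            res = sps.pearsonr(frame[a].to_numpy(float), frame[b].to_numpy(float))
            r.loc[a, b], p.loc[a, b] = float(res.statistic), float(res.pvalue)
    if bh_correct:
        mask = ~np.eye(len(rows_vars), len(cols_vars), dtype=bool) if rows_vars == cols_vars else np.ones(p.shape, bool)
        flat = p.to_numpy()[mask]
        adj = sps.false_discovery_control(flat)
        out = p.to_numpy().copy()
        out[mask] = adj
        p = pd.DataFrame(out, index=p.index, columns=p.columns)
    stars = p.map(star_code)
    return CorrelationReport(r, p, stars)


@dataclass
class PcaResult:
    sdev: np.ndarray                 # component standard deviations
    proportion: np.ndarray           # variance share per component
    cumulative: np.ndarray
    loadings: pd.DataFrame           # variables x components
    scores: np.ndarray               # samples x components

    def summary(self) -> str:
        lines = ["PCA of standardized catechin profiles",
                 f"{'component':<12}{'sdev':>10}{'prop':>10}{'cum':>10}"]
        for k in range(len(self.sdev)):
            lines.append(
                f"{'PC' + str(k + 1):<12}{self.sdev[k]:>10.4f}"
                f"{self.proportion[k]:>10.4f}{self.cumulative[k]:>10.4f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        comp = [f"PC{k+1}" for k in range(len(self.sdev))]
        head = pd.DataFrame(
            {"component": comp, "sdev": self.sdev,
             "proportion": self.proportion, "cumulative": self.cumulative}
        )
        return head


def pca_catechins(
    data: Dataset | pd.DataFrame,
    variables: Sequence[str] | None = None,
    standardize: bool = True,
) -> PcaResult:
    """PCA of catechin profiles, correlation-matrix based by default.

    With ``standardize=True`` each variable is scaled to unit variance, so
    sum(sdev^2) equals the number of variables; ``standardize=False`` runs
    covariance-matrix PCA on centred data instead.
    """
    frame = data.frame if isinstance(data, Dataset) else data
    names = list(variables) if variables is not None else [c for c in CATECHINS if c in frame.columns]
    if len(names) < 2:
        raise ValidationError("PCA needs at least 2 variables")
    X = frame[names].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValidationError(f"PCA needs at least 3 samples, got {len(X)}")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dead = [names[j] for j in range(len(names)) if sd[j] == 0]
        if dead:
            raise ValidationError(f"constant variable(s) under standardization: {', '.join(dead)}")
        X = X / sd
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    # sign convention: largest-magnitude entry of each loading vector positive
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    sdev = np.sqrt(eigval)
    total = eigval.sum()
    prop = eigval / total if total > 0 else np.zeros_like(eigval)
    comp = [f"PC{k+1}" for k in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=names, columns=comp)
    scores = X @ eigvec
    return PcaResult(sdev, prop, np.cumsum(prop), loadings, scores)
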