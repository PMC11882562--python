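"""Single-response partial least squares (PLS1) and VIP variable screening.

Each catechin concentration or gene-expression level is regressed on the
eight standardized meteorological factors with sequential NIPALS
extraction; Variable Importance in Projection (VIP) scores then rank the
factors by the share of explained response variance their weights carry:

    VIP_j = sqrt( p * sum_a SS_a * w_aj^2 / sum_a SS_a ),

with p the number of predictors, w_a the unit-norm weight vector of
component a and SS_a the response variance that component explains.  The
scores satisfy sum_j VIP_j^2 = p, so VIP > 1 marks a factor carrying more
than an equal share of importance -- the screening rule used throughout
the pipeline.

Both X and y are autoscaled (mean 0, variance 1) before fitting, the
chemometrics default when predictors mix units as disparate as millimetres
of rainfall and lux of irradiance; VIP is computed in the scaled space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FACTORS, Dataset, ValidationError

__all__ = [
    "PLS1Model",
    "PLS1Results",
    "VipTable",
    "fit_pls1",
    "vip_scores",
    "screen_factors",
    "vip_table_for",
]

_EPS = 1e-12


class PLS1Model:
    """PLS1 of one response on a predictor matrix, NIPALS extraction.

    Parameters
    ----------
    X : (n, p) array
        Predictor matrix (the eight meteorological factors in pipeline use).
    y : (n,) array
        Response vector.
    n_components : int or "auto"
        Number of latent components A.  ``"auto"`` picks the A minimizing
        leave-one-out RMSECV, capped at min(n - 1, p), ties broken toward
        fewer components.  Extraction is deterministic (no random start).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        n_components: int | str = "auto",
        factor_names: Sequence[str] | None = None,
        response: str = "y",
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValidationError("X must be 2-D with one row per y value")
        n, p = self.X.shape
        if n < 3:
            raise ValidationError(f"PLS1 needs at least 3 samples, got {n}")
        if np.std(self.y) < _EPS:
            raise ValidationError("degenerate response: y is constant")
        col_sd = self.X.std(axis=0)
        if (col_sd < _EPS).all():
            raise ValidationError("all predictor columns are constant")
        self.n_components = n_components
        self.factor_names = list(factor_names) if factor_names is not None else list(FACTORS)[:p] if p == len(FACTORS) else [f"x{j+1}" for j in range(p)]
        self.response = response
        self.max_components = min(n - 1, p)

    def fit(self) -> "PLS1Results":
        if self.n_components == "auto":
            A, cv = self._select_components()
        else:
            A = int(self.n_components)
            if not 1 <= A <= self.max_components:
                raise ValidationError(
                    f"n_components must be in [1, {self.max_components}], got {A}"
                )
            cv = None
        return self._fit_fixed(self.X, self.y, A, rmsecv=cv)

    # -- internals ----------------------------------------------------------

    def _scale(self, X: np.ndarray, y: np.ndarray):
        x_mean, y_mean = X.mean(axis=0), y.mean()
        x_sd = X.std(axis=0, ddof=1)
        x_sd[x_sd < _EPS] = 1.0  # constant columns pass through unscaled
        y_sd = y.std(ddof=1)
        if y_sd < _EPS:
            y_sd = 1.0
        return (X - x_mean) / x_sd, (y - y_mean) / y_sd, x_mean, x_sd, y_mean, y_sd

    def _nipals(self, Xs: np.ndarray, ys: np.ndarray, A: int):
        """Sequential extraction on pre-scaled data; may stop early when the
        residual covariance vanishes (exact-fit or exhausted signal)."""
        n, p = Xs.shape
        Xr, yr = Xs.copy(), ys.copy()
        W, P, T, Q, SS = [], [], [], [], []
        for _ in range(A):
            w = Xr.T @ yr
            nw = np.linalg.norm(w)
            if nw < 1e-10:
                break
            w = w / nw
            t = Xr @ w
            tt = float(t @ t)
            if tt < _EPS:
                break
            pvec = Xr.T @ t / tt
            q = float(yr @ t / tt)
            Xr = Xr - np.outer(t, pvec)
            yr = yr - q * t
            W.append(w)
            P.append(pvec)
            T.append(t)
            Q.append(q)
            SS.append(q * q * tt)  # y-variance explained by this component
        if not W:
            raise ValidationError("zero explained variance: X carries no covariance with y")
        return (
            np.column_stack(W),
            np.column_stack(P),
            np.column_stack(T),
            np.array(Q),
            np.array(SS),
        )

    def _fit_fixed(self, X, y, A, rmsecv=None) -> "PLS1Results":
        Xs, ys, x_mean, x_sd, y_mean, y_sd = self._scale(X, y)
        W, P, T, Q, SS = self._nipals(Xs, ys, A)
        return PLS1Results(self, W, P, T, Q, SS, x_mean, x_sd, y_mean, y_sd, rmsecv)

    def _loo_rmsecv(self, A: int) -> float:
        n = len(self.y)
        errors = np.empty(n)
        for i in range(n):
            idx = np.arange(n) != i
            try:
                res = self._fit_fixed(self.X[idx], self.y[idx], A)
            except ValidationError:
                return np.inf
            errors[i] = self.y[i] - res.predict(self.X[i][None, :])[0]
        return float(np.sqrt(np.mean(errors**2)))

    def _select_components(self) -> tuple[int, float]:
        best_A, best_cv = 1, np.inf
        for A in range(1, self.max_components + 1):
            cv = self._loo_rmsecv(A)
            if cv < best_cv - _EPS:  # strict improvement: ties favour fewer components
                best_A, best_cv = A, cv
        return best_A, best_cv


class PLS1Results:
    """Fitted PLS1 model: weights, loadings, scores and VIP diagnostics."""

    def __init__(self, model, W, P, T, Q, SS, x_mean, x_sd, y_mean, y_sd, rmsecv=None):
        self.model = model
        self.weights = W          # p x A, unit-norm columns
        self.x_loadings = P       # p x A
        self.scores = T           # n x A, mutually orthogonal
        self.y_loadings = Q       # A,
        self.explained_ss = SS    # A, response variance explained per component
        self.x_mean, self.x_sd = x_mean, x_sd
        self.y_mean, self.y_sd = y_mean, y_sd
        self.rmsecv = rmsecv

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def coef_(self) -> np.ndarray:
        """Regression vector in original (unscaled) units."""
        W, P, Q = self.weights, self.x_loadings, self.y_loadings
        B_scaled = W @ np.linalg.solve(P.T @ W, Q)
        return B_scaled * self.y_sd / self.x_sd

    @property
    def intercept_(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef_)

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        return self.intercept_ + Xnew @ self.coef_

    def vip(self) -> np.ndarray:
        return vip_scores(self)

    def to_regression_model(self):
        """Export the PLS regression vector as a linear equation (for
        comparison with the OLS fit); requires the full 8-factor design."""
        from .core import FACTORS as _F
        from .regression import RegressionModel

        if self.weights.shape[0] != len(_F):
            raise ValidationError("export requires the full 8-factor design")
        return RegressionModel(
            response=self.model.response,
            intercept=self.intercept_,
            coefficients=tuple(self.coef_.tolist()),
        )

    def summary(self) -> str:
        lines = [
            f"PLS1 model for {self.model.response}: {self.n_components} component(s)",
            f"{'factor':<12}{'coef':>14}{'VIP':>10}",
        ]
        for name, b, v in zip(self.model.factor_names, self.coef_, self.vip()):
            lines.append(f"{name:<12}{b:>14.6g}{v:>10.4f}")
        if self.rmsecv is not None:
            lines.append(f"LOO RMSECV = {self.rmsecv:.6g}")
        return "\n".join(lines)


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | str = "auto",
    factor_names: Sequence[str] | None = None,
    response: str = "y",
) -> PLS1Results:
    """Fit a PLS1 model (see :class:`PLS1Model`)."""
    return PLS1Model(X, y, n_components, factor_names, response).fit()


def vip_scores(results: PLS1Results) -> np.ndarray:
    """Wold's VIP scores; satisfy sum(VIP^2) = number of predictors."""
    W, SS = results.weights, results.explained_ss
    total = SS.sum()
    if total < _EPS:
        raise ValidationError("zero explained variance: VIP undefined")
    p = W.shape[0]
    # columns of W are unit norm already; normalization kept for safety
    Wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (Wn2 @ SS) / total)


# ---------------------------------------------------------------------------
# VIP table across responses
# ---------------------------------------------------------------------------


@dataclass
class VipTable:
    """Factor x response VIP matrix with the screening threshold."""

    scores: pd.DataFrame  # index = factors, columns = responses
    threshold: float = 1.0

    @property
    def selected(self) -> pd.DataFrame:
        """Boolean mask, strict VIP > threshold."""
        return self.scores > self.threshold

    def links(self) -> pd.DataFrame:
        """Long-format (factor, response, vip) rows passing the threshold."""
        long = self.scores.stack().reset_index()
        long.columns = ["factor", "response", "vip"]
        return long[long["vip"] > self.threshold].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index_label="factor")


def screen_factors(vip_table: VipTable, threshold: float | None = None) -> dict[str, list[str]]:
    """Selected factor list per response (strict VIP > threshold)."""
    thr = vip_table.threshold if threshold is None else threshold
    mask = vip_table.scores > thr
    return {resp: list(mask.index[mask[resp]]) for resp in mask.columns}


def vip_table_for(
    dataset: Dataset,
    responses: Sequence[str],
    n_components: int | str = "auto",
    log_expression: bool = False,
) -> VipTable:
    """Fit one PLS1 model per response and collect the VIP matrix.

    ``log_expression=True`` log2-transforms ``expr_*`` responses before
    fitting (relative expressions are multiplicative); catechin responses
    are always fitted on the raw percent scale.
    """
    X = dataset.meteo_matrix()
    cols = {}
    for resp in responses:
        y = dataset.response(resp)
        if log_expression and resp.startswith("expr_"):
            if (y <= 0).any():
                raise ValidationError(f"cannot log-transform non-positive expression {resp!r}")
            y = np.log2(y)
        res = fit_pls1(X, y, n_components, factor_names=FACTORS, response=resp)
        cols[resp] = res.vip()
    return VipTable(pd.DataFrame(cols, index=list(FACTORS)))
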