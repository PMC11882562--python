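"""Per-catechin linear regression on the eight meteorological factors.

Each catechin concentration y (percent dry mass) is modelled as

    y = b0 + b1*x1 + ... + b8*x8

with x1..x8 the factors in canonical order (rainfall, temp_avg, eat,
temp_max, temp_min, humidity, ground_temp, irradiance).  Model quality is
reported as

* RMSEC  -- root mean squared residual on the calibration (training) set,
* RMSECV -- root mean squared out-of-fold error under cross-validation
  (leave-one-out by default),
* RMSEP  -- root mean squared error of the calibrated model on a held-out
  test set.

The module also ships, as a data fixture, a published seven-equation
coefficient table for Tieguanyin tea (one equation per monomer), used for
worked examples and as ground truth for the synthetic generator.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    CATECHINS,
    FACTORS,
    Dataset,
    MeteoVector,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("teacat")

__all__ = [
    "RegressionModel",
    "CoefficientTable",
    "CatechinLinearModel",
    "CatechinRegressionResults",
    "load_table1",
    "fit_ols",
    "predict",
    "rmsecv",
    "rmsep",
    "train_test_split",
]


# ---------------------------------------------------------------------------
# coefficient containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionModel:
    """One response's linear equation: intercept plus eight ordered slopes."""

    response: str
    intercept: float
    coefficients: tuple[float, ...]  # ordered x1..x8
    rmsec: float | None = None
    rmsecv: float | None = None
    rmsep: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(FACTORS):
            raise ValidationError(
                f"expected {len(FACTORS)} coefficients, got {len(self.coefficients)}"
            )
        for name, value in (("rmsec", self.rmsec), ("rmsecv", self.rmsecv), ("rmsep", self.rmsep)):
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")

    def predict(self, meteo: MeteoVector | Sequence[float] | np.ndarray) -> float | np.ndarray:
        """Evaluate the equation; predictions may be negative (flagged, not clipped)."""
        x = meteo.to_array() if isinstance(meteo, MeteoVector) else np.asarray(meteo, dtype=float)
        b = np.asarray(self.coefficients)
        if x.ndim == 1:
            value = float(self.intercept + x @ b)
            if value < 0:
                logger.warning("negative predicted %s concentration: %.4f", self.response, value)
            return value
        return self.intercept + x @ b

    def coef_array(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)


@dataclass
class CoefficientTable:
    """Map response -> :class:`RegressionModel`, with a provenance tag."""

    models: dict[str, RegressionModel]
    provenance: str = "fitted"

    def __getitem__(self, response: str) -> RegressionModel:
        try:
            return self.models[response]
        except KeyError:
            raise SchemaError(f"coefficient table has no response {response!r}") from None

    def __contains__(self, response: str) -> bool:
        return response in self.models

    def responses(self) -> list[str]:
        return list(self.models)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models.values():
            row: dict[str, object] = {"response": m.response, "intercept": m.intercept}
            row.update(dict(zip(FACTORS, m.coefficients)))
            row.update({"rmsep": m.rmsep, "rmsecv": m.rmsecv, "rmsec": m.rmsec})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "fitted") -> "CoefficientTable":
        required = ["response", "intercept", *FACTORS]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"coefficient table missing column(s): {', '.join(missing)}")
        models = {}
        for _, row in frame.iterrows():
            models[str(row["response"])] = RegressionModel(
                response=str(row["response"]),
                intercept=float(row["intercept"]),
                coefficients=tuple(float(row[f]) for f in FACTORS),
                rmsec=float(row["rmsec"]) if "rmsec" in frame.columns and pd.notna(row.get("rmsec")) else None,
                rmsecv=float(row["rmsecv"]) if "rmsecv" in frame.columns and pd.notna(row.get("rmsecv")) else None,
                rmsep=float(row["rmsep"]) if "rmsep" in frame.columns and pd.notna(row.get("rmsep")) else None,
            )
        return cls(models, provenance)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "CoefficientTable":
        return cls.from_frame(pd.read_csv(path), provenance or str(path))


def load_table1() -> CoefficientTable:
    """The published seven-equation coefficient table (percent dry mass scale)."""
    with importlib.resources.files("teacat.data").joinpath("table1.csv").open() as fh:
        return CoefficientTable.from_frame(pd.read_csv(fh), provenance="table1")


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming collinear columns when the design (with intercept) is rank-deficient."""
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank >= design.shape[1]:
        return
    suspects: list[str] = []
    centred = X - X.mean(axis=0)
    norms = np.linalg.norm(centred, axis=0)
    for j, name in enumerate(names):
        if norms[j] < 1e-12:
            suspects.append(f"{name} (constant)")
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if norms[i] > 1e-12 and norms[j] > 1e-12:
                r = centred[:, i] @ centred[:, j] / (norms[i] * norms[j])
                if abs(abs(r) - 1.0) < 1e-10:
                    suspects.append(f"{names[i]}~{names[j]}")
    detail = "; collinear: " + ", ".join(suspects) if suspects else ""
    raise ValidationError(f"design matrix is rank-deficient (rank {rank} < {design.shape[1]}){detail}")


class CatechinLinearModel:
    """OLS model of one response on the eight meteorological factors.

    Parameters
    ----------
    dataset : Dataset
        Site-season records; the design matrix is the eight-factor block.
    response : str
        Catechin monomer name (``egc`` .. ``cg``) or any numeric column
        such as ``expr_<gene>``.
    """

    def __init__(self, dataset: Dataset, response: str, factors: Sequence[str] | None = None):
        self.dataset = dataset
        self.response = response
        self.factors = list(factors) if factors is not None else list(FACTORS)
        unknown = sorted(set(self.factors) - set(FACTORS))
        if unknown:
            raise ValidationError(f"unknown factor(s): {', '.join(unknown)}")
        if not self.factors:
            raise ValidationError("at least one factor is required")
        self.y = dataset.response(response)
        cols = [FACTORS.index(f) for f in self.factors]
        self.X = dataset.meteo_matrix()[:, cols]
        min_records = len(self.factors) + 2  # slopes + intercept + 1
        if dataset.n < min_records:
            raise ValidationError(
                f"need at least {min_records} records to fit "
                f"{len(self.factors) + 1} parameters, got {dataset.n}"
            )
        _check_full_rank(self.X, self.factors)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: str,
                       factors: Sequence[str] | None = None) -> "CatechinLinearModel":
        return cls(Dataset(frame, provenance="dataframe"), response, factors)

    def fit(self) -> "CatechinRegressionResults":
        design = sm.add_constant(self.X, has_constant="add")
        res = sm.OLS(self.y, design).fit()
        return CatechinRegressionResults(self, res)


class CatechinRegressionResults:
    """Fitted per-catechin regression: estimates, errors and summary."""

    def __init__(self, model: CatechinLinearModel, sm_results):
        self.model = model
        self._sm = sm_results
        self.params = np.asarray(sm_results.params)  # [b0, b1..b8]
        self.bse = np.asarray(sm_results.bse)
        resid = np.asarray(sm_results.resid)
        self.rmsec = float(np.sqrt(np.mean(resid**2)))

    @property
    def response(self) -> str:
        return self.model.response

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> np.ndarray:
        return self.params[1:]

    def predict(self, meteo: MeteoVector | np.ndarray) -> float | np.ndarray:
        return self.to_model().predict(meteo)

    def rmsecv(self, folds: int | str = "loo", seed: int | None = None) -> float:
        return rmsecv(self.model.dataset, self.response, folds=folds, seed=seed,
                      factors=self.model.factors)

    def to_model(self, rmsecv_value: float | None = None, rmsep_value: float | None = None) -> RegressionModel:
        # excluded factors (VIP-restricted fits) carry zero coefficients
        full = dict.fromkeys(FACTORS, 0.0)
        full.update(dict(zip(self.model.factors, self.coefficients.tolist())))
        return RegressionModel(
            response=self.response,
            intercept=self.intercept,
            coefficients=tuple(full[f] for f in FACTORS),
            rmsec=self.rmsec,
            rmsecv=rmsecv_value,
            rmsep=rmsep_value,
        )

    def summary(self) -> str:
        lines = [
            f"Linear model for {self.response} on "
            f"{len(self.model.factors)} meteorological factor(s) "
            f"(n={self.model.dataset.n})",
            f"{'term':<12}{'coef':>14}{'std err':>14}",
            f"{'intercept':<12}{self.intercept:>14.6g}{self.bse[0]:>14.6g}",
        ]
        for name, b, se in zip(self.model.factors, self.coefficients, self.bse[1:]):
            lines.append(f"{name:<12}{b:>14.6g}{se:>14.6g}")
        lines.append(f"RMSEC = {self.rmsec:.6g} (% dry mass)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_ols(
    dataset: Dataset, response: str, factors: Sequence[str] | None = None
) -> RegressionModel:
    """Least-squares fit of one response; returns the equation with its RMSEC.

    ``factors`` restricts the design to a subset (the VIP-screened variant);
    excluded factors get zero coefficients so the equation stays 8-wide.
    """
    return CatechinLinearModel(dataset, response, factors).fit().to_model()


def predict(model: RegressionModel, meteo: MeteoVector | Sequence[float]) -> float:
    """Evaluate a regression equation at one meteorological vector."""
    return float(model.predict(meteo))


def _fold_indices(n: int, folds: int | str, seed: int | None) -> list[np.ndarray]:
    if folds == "loo" or folds == n:
        return [np.array([i]) for i in range(n)]
    k = int(folds)
    if not 2 <= k <= n:
        raise ValidationError(f"folds must be 'loo' or an int in [2, n={n}], got {folds}")
    if seed is None:
        raise ValidationError("k-fold RMSECV requires an explicit seed for fold assignment")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def rmsecv(
    dataset: Dataset, response: str, folds: int | str = "loo",
    seed: int | None = None, factors: Sequence[str] | None = None,
) -> float:
    """Cross-validated root mean squared prediction error (leave-one-out default).

    Each fold's model is refitted from scratch on the remaining records, so
    the metric honestly reflects out-of-sample error of the equation class.
    """
    names = list(factors) if factors is not None else list(FACTORS)
    y = dataset.response(response)
    X = dataset.meteo_matrix()[:, [FACTORS.index(f) for f in names]]
    n = len(y)
    errors = np.empty(n)
    for test_idx in _fold_indices(n, folds, seed):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr = X[train_idx]
        _check_full_rank(Xtr, names)
        design = np.column_stack([np.ones(len(train_idx)), Xtr])
        beta, *_ = np.linalg.lstsq(design, y[train_idx], rcond=None)
        pred = np.column_stack([np.ones(len(test_idx)), X[test_idx]]) @ beta
        errors[test_idx] = y[test_idx] - pred
    return float(np.sqrt(np.mean(errors**2)))


def rmsep(
    train: Dataset, test: Dataset, response: str, allow_overlap: bool = False
) -> float:
    """Root mean squared error on a held-out test set of the train-fitted model."""
    train_keys = set(map(tuple, train.frame[["site", "season"]].itertuples(index=False)))
    test_keys = set(map(tuple, test.frame[["site", "season"]].itertuples(index=False)))
    overlap = train_keys & test_keys
    if overlap and not allow_overlap:
        raise ValidationError(f"train and test sets overlap on {sorted(overlap)}")
    model = fit_ols(train, response)
    pred = model.predict(test.meteo_matrix())
    err = test.response(response) - pred
    return float(np.sqrt(np.mean(err**2)))


def train_test_split(
    dataset: Dataset, test_fraction: float = 0.3, seed: int | None = None
) -> tuple[Dataset, Dataset]:
    """Season-stratified random split; a seed is mandatory for reproducibility."""
    if seed is None:
        raise ValidationError("train_test_split requires an explicit seed")
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    test_rows: list[int] = []
    for _, idx in dataset.frame.groupby("season", sort=False).groups.items():
        idx = np.asarray(list(idx))
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_rows.extend(rng.choice(idx, size=n_test, replace=False).tolist())
    mask = dataset.frame.index.isin(test_rows)
    train = Dataset(dataset.frame[~mask].copy(), provenance=dataset.provenance + " [train]")
    test = Dataset(dataset.frame[mask].copy(), provenance=dataset.provenance + " [test]")
    return train, test
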