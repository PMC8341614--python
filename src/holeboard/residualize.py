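"""Confounder removal: mixed-model residual trajectories per dimension.

Each dimension's integrated z-scores are (optionally) transformed toward
residual normality (avoidance: log-shift; exploration: square-root shift;
locomotion: rank), then fit with a linear mixed model holding strain and
experimenter as fixed factors and mouse, test group and test order as
random intercepts, with CAR(1) within-mouse correlation over trials and a
separate residual-SD multiplier per strain.  Trial is deliberately not a
predictor: the across-trial habituation signal must survive into the
residuals, which are standardized Pearson residuals (conditional residual
divided by its stratum's model-implied SD) and form the 5 x 3 trajectory
clustered downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import DIMENSIONS, N_TRIALS
from .lmm import LMMResult, fit_marginal_lmm

__all__ = [
    "ResidualModelSpec",
    "transform_dimension",
    "fit_residual_model",
    "TrajectoryResidualizer",
    "residual_matrix",
]

_TRANSFORMS = ("log-shift", "sqrt-shift", "rank", "none")


def transform_dimension(values, kind: str) -> np.ndarray:
    """Normality-improving transforms for integrated z-scores.

    log-shift: log(x - min + 1) (the minimum maps to 0); sqrt-shift:
    sqrt(x - min); rank: ascending average ranks.  The shifts make the
    transforms well defined for scores <= 0 while preserving order.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if kind == "log-shift":
        return np.log(x - x.min() + 1.0)
    if kind == "sqrt-shift":
        return np.sqrt(x - x.min())
    if kind == "rank":
        return rankdata(x, method="average")
    if kind == "none":
        return x.copy()
    raise ValueError(f"unknown transformation {kind!r}; expected one of {_TRANSFORMS}")


@dataclass
class ResidualModelSpec:
    """Model layout for the residualization stage (trial never a predictor)."""

    transformations: dict = field(
        default_factory=lambda: {
            "avoidance": "log-shift",
            "exploration": "sqrt-shift",
            "locomotion": "rank",
        }
    )
    fixed: tuple = ("strain", "experimenter")
    random: tuple = ("mouse_id", "test_group", "test_order")
    car1: bool = True
    variance_stratum: str | None = "strain"
    #: REML optimizer budget (function evaluations per dimension).
    maxfev: int = 1000

    def __post_init__(self) -> None:
        for dim, kind in self.transformations.items():
            if kind not in _TRANSFORMS:
                raise ValueError(f"{dim}: unknown transformation {kind!r}")
        if "trial" in self.fixed or "trial" in self.random:
            raise ValueError("trial must not enter the residual model")


def _fixed_design(df: pd.DataFrame, factors: tuple) -> tuple[np.ndarray, list, dict]:
    """Intercept + treatment-coded dummies; returns (X, names, factor slices)."""
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    factor_cols: dict[str, list[int]] = {}
    for fac in factors:
        levels = sorted(df[fac].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"fixed factor {fac!r} has a single level (degenerate)")
        idx0 = len(names)
        for lvl in levels[1:]:
            cols.append((df[fac].astype(str) == lvl).to_numpy(dtype=float))
            names.append(f"{fac}[{lvl}]")
        factor_cols[fac] = list(range(idx0, len(names)))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for fac, jj in factor_cols.items():
            keep = [j for j in range(X.shape[1]) if j not in jj]
            if np.linalg.matrix_rank(X[:, keep]) + len(jj) > np.linalg.matrix_rank(X):
                raise ValueError(f"fixed factor {fac!r} is aliased with the others")
        raise ValueError("fixed-effects design matrix is rank deficient")
    return X, names, factor_cols


def _indicator(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype(str)).to_numpy(dtype=float)


def _fit_one_dimension(
    df: pd.DataFrame, response: np.ndarray, spec: ResidualModelSpec
) -> LMMResult:
    X, names, _ = _fixed_design(df, spec.fixed)
    vc = {fac: _indicator(df[fac]) for fac in spec.random}
    mouse_codes = pd.factorize(df["mouse_id"])[1], pd.factorize(df["mouse_id"])[0]
    codes = mouse_codes[1]
    times = df["trial"].to_numpy(dtype=float)
    strata = strata_levels = None
    if spec.variance_stratum is not None:
        levels = sorted(df[spec.variance_stratum].astype(str).unique())
        strata = df[spec.variance_stratum].astype(str).map(
            {lvl: i for i, lvl in enumerate(levels)}
        ).to_numpy()
        strata_levels = levels

    fallbacks: list[str] = []
    attempts = [
        dict(profile_phi=spec.car1, profile_weights=True),
        dict(profile_phi=False, profile_weights=True),
        dict(profile_phi=False, profile_weights=False),
    ]
    last_err: Exception | None = None
    for i, opts in enumerate(attempts):
        try:
            res = fit_marginal_lmm(
                response,
                X,
                vc=vc if i < 2 else {},
                car1_groups=codes if opts["profile_phi"] else None,
                car1_times=times,
                strata=strata,
                strata_levels=strata_levels,
                profile_phi=opts["profile_phi"],
                profile_weights=opts["profile_weights"],
                column_names=names,
                maxfev=spec.maxfev,
            )
            if res.converged or i == len(attempts) - 1:
                res.fallbacks = fallbacks
                return res
            fallbacks.append(
                "full covariance did not converge; retrying with phi = 0"
                if i == 0
                else "random effects dropped; fixed-effects-only fit"
            )
        except (RuntimeError, np.linalg.LinAlgError) as err:  # pragma: no cover
            last_err = err
            fallbacks.append(f"fit attempt {i} failed: {err}")
    raise RuntimeError(f"all residual-model fits failed: {last_err}")


def fit_residual_model(
    scores: pd.DataFrame, spec: ResidualModelSpec | None = None
) -> tuple[pd.DataFrame, dict]:
    """Residualize all dimensions of a wide dimension-score table.

    Returns a tidy frame (mouse_id, trial, dimension, residual) of
    standardized Pearson residuals plus a per-dimension metadata dict
    (transformation, variance components, phi, weights, convergence).
    """
    spec = spec or ResidualModelSpec()
    required = {"mouse_id", "trial", *spec.fixed, *spec.random} - {"mouse_id"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    counts = scores.groupby("mouse_id")["trial"].nunique()
    if (counts != N_TRIALS).any():
        bad = counts[counts != N_TRIALS].index.tolist()[:5]
        raise ValueError(f"every mouse needs {N_TRIALS} trials; incomplete: {bad}")

    df = scores.sort_values(["mouse_id", "trial"]).reset_index(drop=True)
    out_frames = []
    meta: dict[str, dict] = {}
    for dim in DIMENSIONS:
        col = f"{dim}_z"
        if col not in df.columns:
            raise ValueError(f"missing score column {col!r}")
        kind = spec.transformations.get(dim, "none")
        y = transform_dimension(df[col].to_numpy(dtype=float), kind)
        res = _fit_one_dimension(df, y, spec)
        if res.fallbacks:
            for msg in res.fallbacks:
                warnings.warn(f"{dim}: {msg}", stacklevel=2)
        out_frames.append(
            pd.DataFrame(
                {
                    "mouse_id": df["mouse_id"],
                    "trial": df["trial"],
                    "dimension": dim,
                    "residual": res.resid_pearson,
                }
            )
        )
        meta[dim] = {
            "transformation": kind,
            "sigma2": res.sigma2,
            "gammas": res.gammas,
            "phi": res.phi,
            "weights": res.weights,
            "converged": res.converged,
            "fallbacks": list(res.fallbacks),
            "fixed_effects": dict(zip(res.column_names, res.beta.tolist())),
            "residual_standardization": "conditional",
        }
    tidy = pd.concat(out_frames, ignore_index=True)
    return tidy, meta


def residual_matrix(tidy: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Tidy residuals -> (mouse_ids, n x 5 x 3 trajectory array)."""
    wide = tidy.pivot_table(
        index="mouse_id", columns=["trial", "dimension"], values="residual"
    )
    cols = [(t, d) for t in range(1, N_TRIALS + 1) for d in DIMENSIONS]
    wide = wide[cols]
    if wide.isna().any().any():
        raise ValueError("incomplete residual trajectories")
    ids = wide.index.to_numpy()
    arr = wide.to_numpy(dtype=float).reshape(len(ids), N_TRIALS, len(DIMENSIONS))
    return ids, arr


class TrajectoryResidualizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`fit_residual_model`.

    ``fit`` fits the per-dimension mixed models on a wide score table;
    ``transform`` returns the tidy standardized-residual frame for the same
    cohort.  Fitted attributes: ``metadata_`` (per-dimension fit summary),
    ``mouse_ids_`` and ``trajectories_`` (n x 5 x 3 residual array).
    """

    def __init__(self, spec: ResidualModelSpec | None = None):
        self.spec = spec

    def fit(self, X: pd.DataFrame, y=None):
        tidy, meta = fit_residual_model(X, self.spec)
        self.residuals_ = tidy
        self.metadata_ = meta
        self.mouse_ids_, self.trajectories_ = residual_matrix(tidy)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "residuals_"):
            raise RuntimeError("TrajectoryResidualizer is not fitted")
        return self.residuals_
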