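"""Integrated behavioral z-scores from raw mHB ethogram variables.

Each behavioral dimension (avoidance, exploration, locomotion) is measured
by several raw variables (counts, latencies, a percentage).  Every variable
is normalized to a z-score against the pooled cohort (all strains together
as the reference group), direction-aligned by a per-variable sign, and the
signed z-scores of a dimension's member variables are averaged into one
integrated score per mouse per trial.

The sign convention makes a higher integrated score mean *more* of the
named dimension: for avoidance, board entries and % time on board enter
with -1 and the latency to first board entry with +1; for exploration and
locomotion, counts enter with +1 and latencies with -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import DIMENSIONS
from .simulate import RAW_VARIABLES

__all__ = [
    "DimensionSpec",
    "DegenerateVariableError",
    "default_dimension_specs",
    "zscore_normalize",
    "integrate_dimension",
    "DimensionScorer",
    "compute_dimension_scores",
]


class DegenerateVariableError(ValueError):
    """Raised when a variable has zero spread in the reference cohort."""


@dataclass
class DimensionSpec:
    """Member variables of one behavioral dimension with direction signs."""

    dimension: str
    signs: dict = field(default_factory=dict)  # variable -> +1 | -1

    def __post_init__(self) -> None:
        if not self.signs:
            raise ValueError(f"dimension {self.dimension!r} has no member variables")
        for var, s in self.signs.items():
            if s not in (+1, -1):
                raise ValueError(f"sign for {var!r} must be +1 or -1, got {s!r}")

    @property
    def variables(self) -> tuple:
        return tuple(self.signs)


def default_dimension_specs() -> list[DimensionSpec]:
    """Default ethogram grouping with the standard direction signs.

    Latency-type variables carry the sign opposite to their dimension's
    count variables; for avoidance the board-approach variables are
    inverted instead, so that larger scores mean more avoidance.
    """
    signs: dict[str, dict] = {dim: {} for dim in DIMENSIONS}
    for name, dim, kind, _intercept, slope, _noise in RAW_VARIABLES:
        signs[dim][name] = +1 if slope > 0 else -1
    return [DimensionSpec(dimension=dim, signs=signs[dim]) for dim in DIMENSIONS]


def zscore_normalize(values, name: str = "variable") -> np.ndarray:
    """z-scores of ``values`` against their own pooled mean and SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"{name}: need at least 2 observations to normalize")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name}: non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateVariableError(
            f"variable {name!r} is constant in the reference cohort (SD = 0)"
        )
    return (x - x.mean()) / sd


def integrate_dimension(ztable: pd.DataFrame, spec: DimensionSpec) -> pd.DataFrame:
    """Average the signed member z-scores into one score per mouse x trial.

    ``ztable`` is long-format with columns mouse_id, trial, variable, z.
    Raises if any member variable is missing for any mouse x trial.
    """
    sub = ztable[ztable["variable"].isin(spec.variables)]
    wide = sub.pivot_table(
        index=["mouse_id", "trial"], columns="variable", values="z", aggfunc="first"
    )
    missing_cols = [v for v in spec.variables if v not in wide.columns]
    if missing_cols:
        raise ValueError(
            f"dimension {spec.dimension!r}: member variables entirely absent: "
            f"{missing_cols}"
        )
    wide = wide[list(spec.variables)]
    if wide.isna().any().any():
        holes = [
            (mouse, trial, var)
            for (mouse, trial), row in wide.iterrows()
            for var, val in row.items()
            if pd.isna(val)
        ]
        raise ValueError(
            f"dimension {spec.dimension!r}: missing member observations for "
            f"(mouse, trial, variable): {holes[:10]}"
            + ("..." if len(holes) > 10 else "")
        )
    signed = wide * pd.Series(spec.signs)
    out = signed.mean(axis=1).rename(f"{spec.dimension}_z").reset_index()
    return out


def _validate_raw(raw: pd.DataFrame) -> None:
    required = {"mouse_id", "trial", "variable", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw table missing columns: {sorted(missing)}")
    dup = raw.duplicated(subset=["mouse_id", "trial", "variable"])
    if dup.any():
        bad = raw.loc[dup, ["mouse_id", "trial", "variable"]].iloc[0].tolist()
        raise ValueError(f"duplicate (mouse, trial, variable) rows, e.g. {bad}")


class DimensionScorer(BaseEstimator, TransformerMixin):
    """Transformer from a raw long observation table to dimension scores.

    Parameters
    ----------
    specs : list of DimensionSpec, optional
        Member variables and signs per dimension; defaults to the standard
        ethogram grouping.

    ``fit`` learns the pooled per-variable reference mean and SD (across all
    strains, the normalization reference); ``transform`` emits one row per
    mouse x trial with the integrated z-score of each dimension.  Fitting
    and transforming the same cohort gives scores whose pooled mean is 0.
    """

    def __init__(self, specs: list | None = None):
        self.specs = specs

    def _specs(self) -> list[DimensionSpec]:
        return self.specs if self.specs is not None else default_dimension_specs()

    def fit(self, X: pd.DataFrame, y=None):
        _validate_raw(X)
        specs = self._specs()
        seen: dict[str, str] = {}
        for spec in specs:
            for var in spec.variables:
                if var in seen:
                    raise ValueError(
                        f"variable {var!r} appears in both {seen[var]!r} and "
                        f"{spec.dimension!r}"
                    )
                seen[var] = spec.dimension
        stats = {}
        for var in seen:
            vals = X.loc[X["variable"] == var, "value"].to_numpy(dtype=float)
            if vals.size < 2:
                raise ValueError(f"variable {var!r}: fewer than 2 observations")
            sd = vals.std(ddof=1)
            if sd == 0:
                raise DegenerateVariableError(
                    f"variable {var!r} is constant in the reference cohort (SD = 0)"
                )
            stats[var] = (vals.mean(), sd)
        self.reference_stats_ = stats
        self.n_features_in_ = len(stats)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_stats_"):
            raise RuntimeError("DimensionScorer is not fitted")
        _validate_raw(X)
        sub = X[X["variable"].isin(self.reference_stats_)].copy()
        mean = sub["variable"].map({v: m for v, (m, _) in self.reference_stats_.items()})
        sd = sub["variable"].map({v: s for v, (_, s) in self.reference_stats_.items()})
        sub["z"] = (sub["value"] - mean) / sd
        pieces = None
        for spec in self._specs():
            part = integrate_dimension(sub, spec)
            pieces = part if pieces is None else pieces.merge(
                part, on=["mouse_id", "trial"], how="outer"
            )
        covar_cols = [
            c
            for c in ("strain", "experimenter", "test_group", "test_order")
            if c in X.columns
        ]
        if covar_cols:
            covars = X[["mouse_id", *covar_cols]].drop_duplicates("mouse_id")
            pieces = pieces.merge(covars, on="mouse_id", how="left")
        return pieces.sort_values(["mouse_id", "trial"]).reset_index(drop=True)


def compute_dimension_scores(
    raw: pd.DataFrame, specs: list | None = None
) -> pd.DataFrame:
    """One-shot pooled-reference scoring of a raw observation table."""
    return DimensionScorer(specs=specs).fit(raw).transform(raw)
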