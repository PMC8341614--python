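"""Factorial analysis of the pharmacological phase, with effect sizes.

Fits the full-factorial fixed model (treatment x strain x pool x
experimenter, or any subset, all interactions) with a random block (test
day) intercept, as a linear mixed model; reports F-tests with partial eta
squared (noncentral-F confidence intervals and the neurobehavioral effect
bands), Dunn-Sidak-corrected estimated-marginal-mean contrasts with
Cohen's d, and a balanced-versus-unbalanced divergence report classifying
each term as significant in both pools, in neither, only in the unbalanced
pool ("augmented" by response-type variation) or only in the balanced pool
("unmasked" once that variation is controlled).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm import LMMResult, between_within_df, fit_marginal_lmm, wald_f_test
from .residualize import transform_dimension

__all__ = [
    "dunn_sidak",
    "eta_squared_band",
    "cohen_d_band",
    "partial_eta_squared",
    "FactorialResult",
    "fit_factorial_model",
    "emm_contrasts",
    "compare_pools",
]


def dunn_sidak(alpha: float, m: int) -> float:
    """Per-test alpha controlling the familywise level over m comparisons."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def eta_squared_band(value: float) -> str:
    """Effect bands for partial eta squared (0.03 / 0.10 / 0.20 cut points)."""
    if value <= 0.03:
        return "small"
    if value < 0.10:
        return "medium"
    if value < 0.20:
        return "large"
    return "very large"


def cohen_d_band(d: float) -> str:
    """Neurobehavioral bands for |d| (0.5 / 1.0 / 1.5 cut points)."""
    a = abs(d)
    if a < 0.5:
        return "small"
    if a < 1.0:
        return "medium"
    if a <= 1.5:
        return "large"
    return "very large"


def _eta_ci_from_f(
    F: float, df1: int, df2: int, level: float = 0.95
) -> tuple[float, float]:
    """CI for partial eta squared by inverting the noncentral-F distribution."""
    alpha = 1.0 - level

    def lam_solving(target: float) -> float:
        # find lambda with ncf.cdf(F; df1, df2, lambda) = target
        f0 = stats.ncf.cdf(F, df1, df2, 0.0)
        if f0 <= target:
            return 0.0
        hi = 1.0
        while stats.ncf.cdf(F, df1, df2, hi) > target:
            hi *= 2.0
            if hi > 1e7:  # pragma: no cover
                return hi
        return float(
            optimize.brentq(
                lambda lam: stats.ncf.cdf(F, df1, df2, lam) - target, 0.0, hi
            )
        )

    lam_lo = lam_solving(1.0 - alpha / 2.0)
    lam_hi = lam_solving(alpha / 2.0)
    denom = df1 + df2 + 1
    lo = lam_lo / (lam_lo + denom)
    hi = lam_hi / (lam_hi + denom)
    return float(max(0.0, lo)), float(min(1.0, hi))


def partial_eta_squared(
    ss_effect: float,
    ss_error: float,
    df_effect: int,
    df_error: int,
    level: float = 0.95,
) -> tuple[float, tuple[float, float], str]:
    """Partial eta squared with a noncentral-F CI and its effect band."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("both sums of squares are zero")
    value = ss_effect / (ss_effect + ss_error)
    if ss_error == 0:
        return 1.0, (1.0, 1.0), eta_squared_band(1.0)
    F = (ss_effect / df_effect) / (ss_error / df_error)
    ci = _eta_ci_from_f(F, df_effect, df_error, level)
    return float(value), ci, eta_squared_band(value)


def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    n = len(values)
    out = np.zeros((n, len(levels) - 1))
    arr = values.astype(str).to_numpy()
    for j, lvl in enumerate(levels[:-1]):
        out[arr == lvl, j] = 1.0
    out[arr == levels[-1], :] = -1.0
    return out


def _factorial_design(
    data: pd.DataFrame, factors: tuple
) -> tuple[np.ndarray, dict, dict]:
    """Sum-coded full-factorial design; returns (X, term columns, levels)."""
    levels = {f: sorted(data[f].astype(str).unique()) for f in factors}
    for f in factors:
        if len(levels[f]) < 2:
            raise ValueError(f"factor {f!r} has a single level")
    combos = data.groupby([*factors]).size()
    full = list(itertools.product(*[levels[f] for f in factors]))
    present = set(tuple(map(str, idx if isinstance(idx, tuple) else (idx,)))
                  for idx in combos.index)
    empty = [c for c in full if c not in present]
    if empty:
        raise ValueError(f"empty design cells: {empty[:10]}")

    main = {f: _sum_code(data[f], levels[f]) for f in factors}
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    term_cols: dict[str, np.ndarray] = {}
    for order in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, order):
            block = main[subset[0]]
            for f in subset[1:]:
                block = np.einsum("ni,nj->nij", block, main[f]).reshape(len(data), -1)
            start = sum(c.shape[1] if c.ndim == 2 else 1 for c in cols)
            cols.append(block)
            names.extend(
                [f"{':'.join(subset)}[{j}]" for j in range(block.shape[1])]
            )
            term_cols[":".join(subset)] = np.arange(start, start + block.shape[1])
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return X, term_cols, levels


@dataclass
class FactorialResult:
    """Fitted factorial mixed model plus its ANOVA-style summary."""

    anova: pd.DataFrame
    lmm: LMMResult
    X: np.ndarray
    term_cols: dict
    levels: dict
    factors: tuple
    data: pd.DataFrame
    response: str
    transformation: str
    groups: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def sigma(self) -> float:
        return self.lmm.sigma


def fit_factorial_model(
    data: pd.DataFrame,
    response: str,
    factors: tuple = ("treatment", "strain", "pool", "experimenter"),
    random: str = "block",
    transformation: str = "none",
) -> FactorialResult:
    """Fit  response ~ factors (all interactions) + (1 | random block).

    The response column is transformed first (phase-2 convention:
    exploration log-shift, locomotion rank, avoidance untransformed).
    Denominator df follow the between/within rule with the random block as
    the grouping level.
    """
    df = data.reset_index(drop=True)
    for col in (response, random, *factors):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    y = transform_dimension(df[response].to_numpy(dtype=float), transformation)
    X, term_cols, levels = _factorial_design(df, factors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("aliased terms in the factorial design")
    Z_block = pd.get_dummies(df[random].astype(str)).to_numpy(dtype=float)
    groups = pd.factorize(df[random])[0]
    res = fit_marginal_lmm(
        y, X, vc={"block": Z_block}, profile_phi=False, profile_weights=False
    )
    rows = []
    for term, cols in term_cols.items():
        _, df_den = between_within_df(X, groups, cols)
        F, df1, df2, p = wald_f_test(res, cols, df_den)
        eta = F * df1 / (F * df1 + df2)
        ci = _eta_ci_from_f(F, df1, df2)
        rows.append(
            {
                "term": term,
                "F": F,
                "df_num": df1,
                "df_den": df2,
                "p": p,
                "eta_p2": eta,
                "eta_ci_low": ci[0],
                "eta_ci_high": ci[1],
                "band": eta_squared_band(eta),
            }
        )
    anova = pd.DataFrame(rows)
    return FactorialResult(
        anova=anova,
        lmm=res,
        X=X,
        term_cols=term_cols,
        levels=levels,
        factors=factors,
        data=df,
        response=response,
        transformation=transformation,
        groups=groups,
    )


def _cell_design_row(result: FactorialResult, assignment: dict) -> np.ndarray:
    one = pd.DataFrame({f: [assignment[f]] for f in result.factors})
    X, _, _ = _factorial_design_for_row(one, result.factors, result.levels)
    return X[0]


def _factorial_design_for_row(
    data: pd.DataFrame, factors: tuple, levels: dict
) -> tuple[np.ndarray, dict, dict]:
    main = {f: _sum_code(data[f], levels[f]) for f in factors}
    cols = [np.ones(len(data))]
    for order in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, order):
            block = main[subset[0]]
            for f in subset[1:]:
                block = np.einsum("ni,nj->nij", block, main[f]).reshape(len(data), -1)
            cols.append(block)
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return X, {}, levels


def emm_contrasts(
    result: FactorialResult,
    factor: str,
    m: int | None = None,
    alpha: float = 0.05,
    by: str | None = None,
) -> pd.DataFrame:
    """Pairwise estimated-marginal-mean contrasts for ``factor``.

    Marginal means average the model's cell predictions with equal weight
    over the levels of every other factor (optionally conditioning on each
    level of ``by``).  p-values are judged against the Dunn-Sidak-adjusted
    alpha for ``m`` comparisons (default: the number of contrasts
    produced); Cohen's d standardizes the estimate by the model residual
    SD.
    """
    if factor not in result.factors:
        raise ValueError(f"factor {factor!r} is not in the fitted model")
    if by is not None and by not in result.factors:
        raise ValueError(f"conditioning factor {by!r} is not in the fitted model")
    others = [f for f in result.factors if f not in {factor, by}]
    by_levels = result.levels[by] if by else [None]

    def marginal_row(level: str, by_level) -> np.ndarray:
        rows = []
        for combo in itertools.product(*[result.levels[f] for f in others]):
            assignment = dict(zip(others, combo))
            assignment[factor] = level
            if by:
                assignment[by] = by_level
            rows.append(_cell_design_row(result, assignment))
        return np.mean(rows, axis=0)

    pairs = list(itertools.combinations(result.levels[factor], 2))
    n_comparisons = m if m is not None else len(pairs) * len(by_levels)
    alpha_adj = dunn_sidak(alpha, n_comparisons)
    _, df_den = between_within_df(
        result.X, result.groups, result.term_cols[factor]
    )
    sigma = result.sigma
    out = []
    for by_level in by_levels:
        for a, b in pairs:
            L = marginal_row(a, by_level) - marginal_row(b, by_level)
            est = float(L @ result.lmm.beta)
            se = float(np.sqrt(L @ result.lmm.cov_beta @ L))
            tstat = est / se
            p = 2.0 * float(stats.t.sf(abs(tstat), df_den))
            d = est / sigma
            tcrit = float(stats.t.ppf(1.0 - alpha_adj / 2.0, df_den))
            half = tcrit * se / sigma
            desc = f"{factor}: {a} - {b}" + (f" | {by} = {by_level}" if by else "")
            out.append(
                {
                    "contrast": desc,
                    "estimate": est,
                    "se": se,
                    "t": tstat,
                    "df": df_den,
                    "p": p,
                    "alpha_adjusted": alpha_adj,
                    "significant": p < alpha_adj,
                    "cohen_d": d,
                    "d_ci_low": d - half,
                    "d_ci_high": d + half,
                    "band": cohen_d_band(d),
                }
            )
    return pd.DataFrame(out)


def compare_pools(
    anova_balanced: pd.DataFrame,
    anova_unbalanced: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each model term by where it reaches significance.

    "augmented": significant only in the unbalanced pool (response-type
    variation inflates an apparent effect); "unmasked": significant only in
    the balanced pool (controlling type variation reveals an effect).
    """
    bal = anova_balanced.set_index("term")
    unbal = anova_unbalanced.set_index("term")
    if set(bal.index) != set(unbal.index):
        raise ValueError("the two analyses cover different terms")
    rows = []
    for term in bal.index:
        sig_b = bool(bal.loc[term, "p"] < alpha)
        sig_u = bool(unbal.loc[term, "p"] < alpha)
        if sig_b and sig_u:
            status = "both"
        elif sig_u:
            status = "augmented"
        elif sig_b:
            status = "unmasked"
        else:
            status = "neither"
        rows.append(
            {
                "term": term,
                "p_balanced": float(bal.loc[term, "p"]),
                "p_unbalanced": float(unbal.loc[term, "p"]),
                "classification": status,
            }
        )
    return pd.DataFrame(rows)
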