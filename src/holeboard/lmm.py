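"""Marginal linear mixed models by REML, with CAR(1) errors and variance
weights per stratum.

The covariance model is

    V = sigma^2 * [ sum_k gamma_k Z_k Z_k' + W^{1/2} C(phi) W^{1/2} ]

where each Z_k is the indicator matrix of a random-intercept factor (or a
per-group slope column), gamma_k is that component's variance ratio to the
residual variance, C(phi) is block-diagonal continuous-time AR(1)
correlation within repeated-measures groups (corr = phi^|t_i - t_j|), and W
holds squared per-stratum residual-SD multipliers (the first stratum level
is the reference with weight 1).  The variance ratios, phi and the weights
are profiled by restricted maximum likelihood with the residual variance
sigma^2 profiled out in closed form.

Likelihood evaluations exploit the structure: the error part S is block
diagonal over the repeated-measures groups (or diagonal without CAR(1)),
and the random effects add a low-rank term handled with the Woodbury
identity, so each evaluation costs small per-block solves plus one q x q
Cholesky (q = total number of random-effect levels) instead of an n x n
factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from scipy.special import expit, logit

__all__ = ["LMMResult", "fit_marginal_lmm", "wald_f_test", "between_within_df"]

_PHI_MAX = 0.995


@dataclass
class LMMResult:
    """Fitted marginal LMM: estimates, covariance pieces and residuals."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    gammas: dict
    phi: float
    weights: dict
    loglik: float
    converged: bool
    fallbacks: list = field(default_factory=list)
    n_obs: int = 0
    n_params_fixed: int = 0
    column_names: list = field(default_factory=list)
    #: conditional (BLUP-subtracted) residuals, one per observation
    resid_conditional: np.ndarray | None = None
    #: conditional residuals standardized by the model-implied residual SD
    #: of each observation's stratum (standardized Pearson residuals)
    resid_pearson: np.ndarray | None = None
    #: predicted random effects per component
    random_effects: dict = field(default_factory=dict)
    #: per-observation residual SD (sigma * stratum weight)
    resid_sd: np.ndarray | None = None

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    def fitted_fixed(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta


class _ErrorStructure:
    """Block-diagonal error covariance S = W^{1/2} C(phi) W^{1/2}.

    Groups must be contiguous in the observation order (callers sort by
    group); without CAR(1) groups, S is diagonal.
    """

    def __init__(self, n, car1_groups, car1_times, strata):
        self.n = n
        self.strata = strata
        self.slices: list[slice] | None = None
        self.times = None
        if car1_groups is not None:
            codes = np.asarray(car1_groups)
            change = np.flatnonzero(np.diff(codes)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [n]])
            for s, e in zip(starts, ends):
                if np.unique(codes[s:e]).size != 1:
                    raise ValueError("CAR(1) groups must be contiguous in the data")
            if len(np.unique(codes)) != len(starts):
                raise ValueError("CAR(1) groups must be contiguous in the data")
            self.slices = [slice(int(s), int(e)) for s, e in zip(starts, ends)]
            self.times = np.asarray(car1_times, dtype=float)

    def factor(self, phi: float, weights: np.ndarray):
        """Return (solve, logdet): solve applies S^{-1} to an n x m matrix."""
        w_obs = (
            weights[self.strata] if self.strata is not None else np.ones(self.n)
        )
        if self.slices is None or phi == 0.0:
            s_diag = w_obs**2
            logdet = float(np.sum(np.log(s_diag)))

            def solve(B: np.ndarray) -> np.ndarray:
                return B / s_diag[:, None]

            return solve, logdet

        # fast path: equal-length blocks, identical time pattern, constant
        # weight within each block (the usual 5-trials-per-mouse layout)
        lengths = {sl.stop - sl.start for sl in self.slices}
        if len(lengths) == 1:
            m = lengths.pop()
            tmat = self.times.reshape(-1, m)
            wmat = w_obs.reshape(-1, m)
            if np.allclose(tmat, tmat[0]) and np.allclose(wmat, wmat[:, :1]):
                t = tmat[0]
                C = phi ** np.abs(t[:, None] - t[None, :])
                Ci = np.linalg.inv(C)
                sign, logdet_C = np.linalg.slogdet(C)
                w2 = wmat[:, 0] ** 2
                logdet = float(
                    len(w2) * logdet_C + m * np.sum(np.log(w2))
                )

                def solve(B: np.ndarray) -> np.ndarray:
                    Bb = B.reshape(len(w2), m, -1)
                    out = np.einsum("ij,gjm->gim", Ci, Bb) / w2[:, None, None]
                    return out.reshape(B.shape)

                return solve, logdet

        chols = []
        logdet = 0.0
        for sl in self.slices:
            t = self.times[sl]
            C = phi ** np.abs(t[:, None] - t[None, :])
            w = w_obs[sl]
            block = C * np.outer(w, w)
            L = linalg.cholesky(block, lower=True)
            chols.append(L)
            logdet += 2.0 * float(np.sum(np.log(np.diag(L))))

        def solve(B: np.ndarray) -> np.ndarray:
            out = np.empty_like(B)
            for sl, L in zip(self.slices, chols):
                out[sl] = linalg.cho_solve((L, True), B[sl])
            return out

        return solve, logdet


def _neg2_reml(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    U: np.ndarray | None,
    comp_sizes: list[int],
    structure: _ErrorStructure,
    n_strata: int,
    profile_phi: bool,
    profile_weights: bool,
):
    """Profiled -2 REML log-likelihood (up to a constant) and fit pieces."""
    n, p = X.shape
    k = len(comp_sizes)
    gammas = np.exp(theta[:k])
    pos = k
    phi = 0.0
    if profile_phi:
        phi = float(expit(theta[pos]) * _PHI_MAX)
        pos += 1
    weights = np.ones(max(n_strata, 1))
    if profile_weights and n_strata > 1:
        weights[1:] = np.exp(theta[pos : pos + n_strata - 1])
        pos += n_strata - 1

    try:
        s_solve, logdet_S = structure.factor(phi, weights)
    except linalg.LinAlgError:
        return 1e12, None

    yX = np.column_stack([y, X])
    Si_yX = s_solve(yX)

    if U is not None and U.shape[1] > 0:
        g_obs = np.repeat(gammas, comp_sizes)
        Gh = np.sqrt(g_obs)
        Si_U = s_solve(U)
        A = U.T @ Si_U
        M = np.eye(U.shape[1]) + (Gh[:, None] * A) * Gh[None, :]
        try:
            LM = linalg.cholesky(M, lower=True)
        except linalg.LinAlgError:
            return 1e12, None
        logdet_V = logdet_S + 2.0 * float(np.sum(np.log(np.diag(LM))))
        # V^{-1} [y X] = S^{-1}[y X] - S^{-1} U Gh M^{-1} Gh U' S^{-1} [y X]
        UtSi_yX = U.T @ Si_yX
        corr = Gh[:, None] * linalg.cho_solve((LM, True), Gh[:, None] * UtSi_yX)
        Vi_yX = Si_yX - Si_U @ corr
        woodbury = (LM, Gh, Si_U)
    else:
        Vi_yX = Si_yX
        logdet_V = logdet_S
        woodbury = None

    Vi_y = Vi_yX[:, 0]
    Vi_X = Vi_yX[:, 1:]
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12, None
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = Vi_y - Vi_X @ beta
    q = float(r @ Vi_r)
    if q <= 0:
        return 1e12, None
    val = logdet_V + logdet_XtViX + (n - p) * np.log(q)
    aux = (gammas, phi, weights, beta, XtViX, r, Vi_r, q, woodbury)
    return val, aux


def fit_marginal_lmm(
    y: np.ndarray,
    X: np.ndarray,
    vc: dict | None = None,
    car1_groups: np.ndarray | None = None,
    car1_times: np.ndarray | None = None,
    strata: np.ndarray | None = None,
    strata_levels: list | None = None,
    profile_phi: bool = True,
    profile_weights: bool = True,
    column_names: list | None = None,
    maxfev: int = 2000,
) -> LMMResult:
    """REML fit of the marginal covariance model described in the module docstring.

    Parameters
    ----------
    vc : dict of name -> Z matrix
        Random-effect design matrices (indicator columns for intercepts, or
        e.g. centered trial values per mouse column for a random slope).
    car1_groups, car1_times : arrays, optional
        Repeated-measures group codes (contiguous in the row order) and
        time points for the CAR(1) correlation (typically mouse and trial).
    strata, strata_levels : optional
        Integer stratum codes (0-based) per observation and their labels;
        stratum 0 is the reference with residual-SD multiplier 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design matrix is rank deficient (aliased factor)")
    vc = vc or {}
    names = list(vc)
    Zs = [np.asarray(vc[name], dtype=float) for name in names]
    comp_sizes = [Z.shape[1] for Z in Zs]
    U = np.concatenate(Zs, axis=1) if Zs else None
    n_strata = len(strata_levels) if strata_levels else (
        int(strata.max()) + 1 if strata is not None else 1
    )
    use_phi = profile_phi and car1_groups is not None
    use_w = profile_weights and n_strata > 1 and strata is not None
    structure = _ErrorStructure(
        n, car1_groups if use_phi else None, car1_times, strata if use_w or strata is not None else None
    )

    k = len(Zs)
    x0 = [np.log(0.3)] * k
    if use_phi:
        x0.append(float(logit(0.2 / _PHI_MAX)))
    if use_w:
        x0.extend([0.0] * (n_strata - 1))
    x0 = np.asarray(x0, dtype=float)

    args = (y, X, U, comp_sizes, structure, n_strata, use_phi, use_w)

    if x0.size == 0:
        val, aux = _neg2_reml(x0, *args)
        converged = aux is not None
    else:
        res = optimize.minimize(
            lambda t: _neg2_reml(t, *args)[0],
            x0,
            method="Powell",
            options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-4},
        )
        val, aux = _neg2_reml(res.x, *args)
        converged = bool(res.success) and aux is not None
    if aux is None:
        raise RuntimeError("REML evaluation failed at the optimum (singular covariance)")

    gammas, phi, weights, beta, XtViX, r, Vi_r, q, _ = aux
    sigma2 = q / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtViX)

    random_effects = {}
    shrunk = np.zeros(n)
    offset = 0
    for name, g, Z in zip(names, gammas, Zs):
        u = g * (Z.T @ Vi_r)
        random_effects[name] = u
        shrunk += Z @ u
        offset += Z.shape[1]
    resid_cond = r - shrunk

    w_obs = weights[strata] if strata is not None else np.ones(n)
    resid_sd = np.sqrt(sigma2) * w_obs
    resid_pearson = resid_cond / resid_sd

    weight_map = (
        {lvl: float(weights[i]) for i, lvl in enumerate(strata_levels)}
        if strata_levels
        else {}
    )
    return LMMResult(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        gammas={name: float(g) for name, g in zip(names, gammas)},
        phi=float(phi),
        weights=weight_map,
        loglik=-0.5 * float(val),
        converged=converged,
        n_obs=n,
        n_params_fixed=p,
        column_names=list(column_names or []),
        resid_conditional=resid_cond,
        resid_pearson=resid_pearson,
        random_effects=random_effects,
        resid_sd=resid_sd,
    )


def between_within_df(
    X: np.ndarray, groups: np.ndarray, term_cols: np.ndarray
) -> tuple[bool, int]:
    """Denominator df for a fixed term under the between/within rule.

    A column is a *within* column when its value varies inside at least one
    repeated-measures group; a term containing any within column is tested
    against the observation-level df  N - g - p_within, otherwise against
    the group-level df  g - p_between - 1 (intercept excluded from both
    counts).  Returns ``(is_within_term, df_denominator)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    codes = np.unique(groups, return_inverse=True)[1]
    g = codes.max() + 1
    varies_within = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        for grp in range(g):
            v = col[codes == grp]
            if v.size > 1 and not np.allclose(v, v[0]):
                varies_within[j] = True
                break
    is_intercept = np.array(
        [np.allclose(X[:, j], X[0, j]) and X[0, j] != 0 for j in range(X.shape[1])]
    )
    p_within = int(np.sum(varies_within & ~is_intercept))
    p_between = int(np.sum(~varies_within & ~is_intercept))
    term_within = bool(np.any(varies_within[term_cols]))
    if term_within:
        return True, n - g - p_within
    return False, g - p_between - 1


def wald_f_test(
    result: LMMResult, term_cols: np.ndarray, df_den: int
) -> tuple[float, int, int, float]:
    """Wald F-test that the coefficients in ``term_cols`` are jointly zero."""
    L = np.zeros((len(term_cols), len(result.beta)))
    for i, c in enumerate(term_cols):
        L[i, c] = 1.0
    est = L @ result.beta
    cov = L @ result.cov_beta @ L.T
    stat = float(est @ np.linalg.solve(cov, est))
    df_num = len(term_cols)
    F = stat / df_num
    p = float(stats.f.sf(F, df_num, df_den))
    return F, df_num, df_den, p
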