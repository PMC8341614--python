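"""Multivariate longitudinal k-means over 5-trial x 3-dimension trajectories.

A mouse's datum is its joint residual trajectory, a 5 x 3 matrix; distance
between mice is the Frobenius norm of the trajectory difference (plain
Euclidean distance over the 15 entries, with no per-dimension rescaling:
the residualization stage already standardizes each dimension).  Clustering
is multi-restart Lloyd iteration; whether any partition beats one cluster
is decided by the gap statistic; the number of clusters is picked by a
majority vote of three cluster-validity indices (Calinski-Harabasz up,
Davies-Bouldin down, Ray-Turi down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .constants import DIMENSIONS, N_TRIALS
from .lmm import between_within_df, fit_marginal_lmm, wald_f_test
from .residualize import transform_dimension

__all__ = [
    "traj_distance",
    "TrajectoryKMeans",
    "ClusterSolution",
    "kmeans_longitudinal",
    "GapResult",
    "gap_statistic",
    "ray_turi_index",
    "compute_cvis",
    "select_k_cvi",
    "characterize_clusters",
]


def _flatten(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        return X.reshape(X.shape[0], -1)
    if X.ndim == 2:
        return X
    raise ValueError(f"expected (n, trials, dims) or (n, features), got shape {X.shape}")


def traj_distance(a, b) -> float:
    """Frobenius distance between two equally shaped trajectories."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite trajectory entries")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _exchange_pass(Xf: np.ndarray, labels: np.ndarray, centers: np.ndarray, k: int) -> None:
    """Hartigan-style single-point exchange refinement (in place).

    Lloyd iteration can stall at partitions that no batch reassignment
    improves; moving one point at a time with exact size-corrected SS deltas
    escapes those, and on tiny instances reaches the enumeration optimum.
    """
    n = Xf.shape[0]
    sizes = np.bincount(labels, minlength=k).astype(float)
    for _ in range(50):
        improved = False
        for i in range(n):
            a = labels[i]
            if sizes[a] <= 1:
                continue
            d2 = ((centers - Xf[i]) ** 2).sum(axis=1)
            loss_a = sizes[a] / (sizes[a] - 1.0) * d2[a]
            gains = sizes / (sizes + 1.0) * d2
            gains[a] = np.inf
            b = int(np.argmin(gains))
            if gains[b] - loss_a < -1e-12:
                centers[a] = (centers[a] * sizes[a] - Xf[i]) / (sizes[a] - 1.0)
                centers[b] = (centers[b] * sizes[b] + Xf[i]) / (sizes[b] + 1.0)
                sizes[a] -= 1.0
                sizes[b] += 1.0
                labels[i] = b
                improved = True
        if not improved:
            break


def _lloyd(
    Xf: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One Lloyd run from a k-distinct-points init; returns labels, centers, SS, iters."""
    n = Xf.shape[0]
    centers = Xf[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    ss_prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((Xf[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # empty-cluster repair: reseed from the point farthest from its center
        for j in range(k):
            if not np.any(new_labels == j):
                far = d2[np.arange(n), new_labels].argmax()
                centers[j] = Xf[far]
                new_labels[far] = j
                d2[:, j] = ((Xf - centers[j]) ** 2).sum(axis=1)
        for j in range(k):
            centers[j] = Xf[new_labels == j].mean(axis=0)
        ss = float(((Xf - centers[new_labels]) ** 2).sum())
        if ss > ss_prev + 1e-8 * max(1.0, ss_prev):
            raise AssertionError("within-cluster SS increased across a Lloyd iteration")
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        ss_prev = ss
    _exchange_pass(Xf, labels, centers, k)
    for j in range(k):
        centers[j] = Xf[labels == j].mean(axis=0)
    ss = float(((Xf - centers[labels]) ** 2).sum())
    return labels, centers, ss, it


class TrajectoryKMeans(BaseEstimator, ClusterMixin):
    """Best-of-restarts Lloyd k-means on flattened trajectories.

    Parameters
    ----------
    n_clusters : int
        Number of clusters (k >= 2).
    n_restarts : int
        Independent restarts; each initializes from ``n_clusters`` distinct
        trajectories sampled without replacement from a restart-specific RNG
        stream (seeded by ``(random_state, n_clusters, restart)``, so
        solutions are reproducible and independent of how many k values a
        caller sweeps).
    max_iter : int
        Iteration cap per restart.
    random_state : int or None
        Base seed; None draws fresh entropy.

    Attributes (after ``fit``): ``labels_``, ``cluster_centers_`` (k x 5 x 3
    when the input was 3-D), ``inertia_`` (best within-cluster sum of
    squares), ``n_iter_`` (iterations per restart).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_restarts: int = 100,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        Xf = _flatten(X)
        n = Xf.shape[0]
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if k > n:
            raise ValueError(f"n_clusters = {k} exceeds the number of trajectories {n}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        root = (
            self.random_state
            if self.random_state is not None
            else np.random.SeedSequence().entropy % (2**31)
        )
        best = None
        n_iter = []
        for r in range(self.n_restarts):
            rng = np.random.default_rng(np.random.SeedSequence((root, k, r)))
            labels, centers, ss, it = _lloyd(Xf, k, rng, self.max_iter)
            n_iter.append(it)
            if best is None or ss < best[2]:
                best = (labels, centers, ss)
        labels, centers, ss = best
        self.labels_ = labels
        self.inertia_ = ss
        self.n_iter_ = np.asarray(n_iter)
        orig = np.asarray(X, dtype=float)
        self.cluster_centers_ = (
            centers.reshape(k, *orig.shape[1:]) if orig.ndim == 3 else centers
        )
        self._centers_flat = centers
        return self

    def predict(self, X) -> np.ndarray:
        Xf = _flatten(X)
        d2 = ((Xf[:, None, :] - self._centers_flat[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


@dataclass
class ClusterSolution:
    """A fitted partition at one k, with bookkeeping for model selection."""

    k: int
    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    n_iter: np.ndarray
    n_restarts: int
    cvi: dict = field(default_factory=dict)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def ray_turi_index(Xf: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Mean squared distance to own center over min squared center gap (minimize)."""
    Xf = _flatten(Xf)
    centers = _flatten(centers)
    intra = float(((Xf - centers[labels]) ** 2).sum()) / Xf.shape[0]
    k = centers.shape[0]
    gaps = [
        float(((centers[i] - centers[j]) ** 2).sum())
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return intra / min(gaps)


def compute_cvis(X, labels: np.ndarray, centers: np.ndarray) -> dict:
    Xf = _flatten(X)
    k = len(np.unique(labels))
    if not 1 < k < Xf.shape[0]:  # indices undefined at k == n
        return {
            "calinski_harabasz": float("nan"),
            "davies_bouldin": float("nan"),
            "ray_turi": float(ray_turi_index(Xf, labels, centers)),
        }
    return {
        "calinski_harabasz": float(calinski_harabasz_score(Xf, labels)),
        "davies_bouldin": float(davies_bouldin_score(Xf, labels)),
        "ray_turi": float(ray_turi_index(Xf, labels, centers)),
    }


def kmeans_longitudinal(
    trajectories,
    k: int,
    n_restarts: int = 1000,
    seed: int | None = None,
    max_iter: int = 100,
) -> ClusterSolution:
    """Cluster trajectories at one k and attach the three validity indices."""
    est = TrajectoryKMeans(
        n_clusters=k, n_restarts=n_restarts, max_iter=max_iter, random_state=seed
    ).fit(trajectories)
    sol = ClusterSolution(
        k=k,
        labels=est.labels_,
        centers=est.cluster_centers_,
        inertia=est.inertia_,
        n_iter=est.n_iter_,
        n_restarts=n_restarts,
    )
    sol.cvi = compute_cvis(trajectories, est.labels_, est._centers_flat)
    return sol


@dataclass
class GapResult:
    """Gap curve with standard errors and the one-cluster verdict."""

    k_values: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w_obs: np.ndarray
    one_cluster: bool


def _within_ss_k1(Xf: np.ndarray) -> float:
    return float(((Xf - Xf.mean(axis=0)) ** 2).sum())


def gap_statistic(
    trajectories,
    k_max: int = 6,
    B: int = 50,
    seed: int | None = None,
    n_restarts: int = 20,
) -> GapResult:
    """Tibshirani-style gap statistic with a uniform-box reference.

    References are drawn uniformly over each feature's observed range.  The
    one-cluster verdict applies the one-standard-error rule at k = 1:
    the data are best left unpartitioned iff gap(1) >= gap(2) - SE(2).
    """
    if B < 10:
        raise ValueError("need B >= 10 reference sets")
    Xf = _flatten(trajectories)
    if np.allclose(Xf, Xf[0]):
        raise ValueError("degenerate data: all trajectories identical")
    n = Xf.shape[0]
    rng = np.random.default_rng(seed)
    lo, hi = Xf.min(axis=0), Xf.max(axis=0)

    def w_curve(Z: np.ndarray, seed_offset: int) -> np.ndarray:
        out = np.empty(k_max)
        out[0] = _within_ss_k1(Z)
        for k in range(2, k_max + 1):
            out[k - 1] = TrajectoryKMeans(
                n_clusters=k,
                n_restarts=n_restarts,
                random_state=seed_offset,
            ).fit(Z).inertia_
        return out

    log_w_obs = np.log(w_curve(Xf, seed_offset=0 if seed is None else seed))
    log_w_ref = np.empty((B, k_max))
    for b in range(B):
        Z = rng.uniform(lo, hi, size=Xf.shape)
        log_w_ref[b] = np.log(w_curve(Z, seed_offset=int(rng.integers(2**31))))
    gap = log_w_ref.mean(axis=0) - log_w_obs
    se = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    one_cluster = bool(gap[0] >= gap[1] - se[1]) if k_max >= 2 else True
    return GapResult(
        k_values=np.arange(1, k_max + 1),
        gap=gap,
        se=se,
        log_w_obs=log_w_obs,
        one_cluster=one_cluster,
    )


def select_k_cvi(solutions: dict) -> tuple[int, dict]:
    """Majority vote of the validity indices over candidate k values.

    Calinski-Harabasz votes for its maximum; Davies-Bouldin and Ray-Turi
    for their minima.  Ties break toward the smallest k.  Returns
    ``(k_selected, votes)``.
    """
    if len(solutions) < 2:
        raise ValueError("need solutions for at least 2 candidate k values")
    ks = sorted(solutions)
    votes = {
        "calinski_harabasz": max(
            ks, key=lambda k: (solutions[k].cvi["calinski_harabasz"], -k)
        ),
        "davies_bouldin": min(ks, key=lambda k: (solutions[k].cvi["davies_bouldin"], k)),
        "ray_turi": min(ks, key=lambda k: (solutions[k].cvi["ray_turi"], k)),
    }
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    k_selected = min(k for k, c in counts.items() if c == top)
    return k_selected, votes


def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    """Deviation (sum-to-zero) coding: L levels -> L-1 columns."""
    n = len(values)
    out = np.zeros((n, len(levels) - 1))
    arr = values.to_numpy()
    for j, lvl in enumerate(levels[:-1]):
        out[arr == lvl, j] = 1.0
    out[arr == levels[-1], :] = -1.0
    return out


def characterize_clusters(
    scores: pd.DataFrame,
    labels: dict | pd.Series,
    transformations: dict | None = None,
) -> dict:
    """Mixed-model contrast report of cluster trajectory differences.

    Per dimension, fits  score ~ cluster * trial  (both categorical,
    sum-coded) with a random intercept and a random trial slope per mouse,
    then reports F-tests for cluster, trial and their interaction plus
    estimated-marginal-mean contrasts: cluster differences at each trial
    and the trial 5 - trial 1 change within each cluster, each with
    estimate, SE, t, p and Cohen's d (estimate / residual SD).
    """
    transformations = (
        transformations if transformations is not None else {"locomotion": "rank"}
    )
    lab = pd.Series(labels) if isinstance(labels, dict) else pd.Series(labels)
    df = scores.copy()
    df["cluster"] = df["mouse_id"].map(lab)
    if df["cluster"].isna().any():
        raise ValueError("labels missing for some mice in the score table")
    clusters = sorted(df["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("need two or more clusters to characterize")
    trials = sorted(df["trial"].unique())
    if len(trials) != N_TRIALS:
        raise ValueError(f"expected {N_TRIALS} trials, found {len(trials)}")
    sizes = df.drop_duplicates("mouse_id")["cluster"].value_counts()
    singleton = [c for c in clusters if sizes.get(c, 0) < 2]

    df = df.sort_values(["mouse_id", "trial"]).reset_index(drop=True)
    Xc = _sum_code(df["cluster"], clusters)
    Xt = _sum_code(df["trial"], trials)
    inter = np.einsum("ni,nj->nij", Xc, Xt).reshape(len(df), -1)
    X = np.column_stack([np.ones(len(df)), Xc, Xt, inter])
    ncl, ntr = Xc.shape[1], Xt.shape[1]
    term_cols = {
        "cluster": np.arange(1, 1 + ncl),
        "trial": np.arange(1 + ncl, 1 + ncl + ntr),
        "cluster:trial": np.arange(1 + ncl + ntr, X.shape[1]),
    }

    mouse_ind = pd.get_dummies(df["mouse_id"]).to_numpy(dtype=float)
    trial_centered = df["trial"].to_numpy(dtype=float) - np.mean(trials)
    Z_slope = mouse_ind * trial_centered[:, None]
    groups = pd.factorize(df["mouse_id"])[0]

    def cell_row(cluster, trial) -> np.ndarray:
        one = pd.DataFrame({"cluster": [cluster], "trial": [trial]})
        xc = _sum_code(one["cluster"], clusters)
        xt = _sum_code(one["trial"], trials)
        xi = np.einsum("ni,nj->nij", xc, xt).reshape(1, -1)
        return np.concatenate([[1.0], xc[0], xt[0], xi[0]])

    report: dict[str, dict] = {}
    for dim in DIMENSIONS:
        y = df[f"{dim}_z"].to_numpy(dtype=float)
        kind = transformations.get(dim, "none")
        y = transform_dimension(y, kind)
        res = fit_marginal_lmm(
            y,
            X,
            vc={"mouse": mouse_ind, "mouse_slope": Z_slope},
            profile_phi=False,
            profile_weights=False,
        )
        anova_rows = []
        for term, cols in term_cols.items():
            _, df_den = between_within_df(X, groups, cols)
            F, df1, df2, p = wald_f_test(res, cols, df_den)
            anova_rows.append(
                {"term": term, "F": F, "df_num": df1, "df_den": df2, "p": p}
            )
        anova = pd.DataFrame(anova_rows)

        contrasts = []
        if not singleton:
            _, df_within = between_within_df(X, groups, term_cols["cluster:trial"])
            from scipy import stats as sps

            def add_contrast(desc: str, L: np.ndarray):
                est = float(L @ res.beta)
                se = float(np.sqrt(L @ res.cov_beta @ L))
                tstat = est / se
                p = 2.0 * float(sps.t.sf(abs(tstat), df_within))
                d = est / res.sigma
                tcrit = float(sps.t.ppf(0.975, df_within))
                half = tcrit * se / res.sigma
                contrasts.append(
                    {
                        "contrast": desc,
                        "estimate": est,
                        "se": se,
                        "t": tstat,
                        "df": df_within,
                        "p": p,
                        "cohen_d": d,
                        "d_ci_low": d - half,
                        "d_ci_high": d + half,
                    }
                )

            for t in trials:
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        L = cell_row(clusters[i], t) - cell_row(clusters[j], t)
                        add_contrast(
                            f"cluster {clusters[i]} - {clusters[j]} @ trial {t}", L
                        )
            for c in clusters:
                L = cell_row(c, trials[-1]) - cell_row(c, trials[0])
                add_contrast(
                    f"trial {trials[-1]} - {trials[0]} within cluster {c}", L
                )
        report[dim] = {
            "transformation": kind,
            "anova": anova,
            "contrasts": pd.DataFrame(contrasts),
            "sigma": res.sigma,
            "singleton_clusters": singleton,
        }
    return report
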