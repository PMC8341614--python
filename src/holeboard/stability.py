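"""Bootstrap Jaccard stability of a trajectory clustering.

Resamples mice with replacement, re-clusters each bootstrap sample at the
base k, aligns the candidate labels to the base solution by maximum-overlap
assignment, and records per mouse how often it lands back in its base
cluster.  Two Jaccard conventions are reported: the primary one divides by
the number of bootstrap samples that actually contain the mouse (about
63.2% of samples contain any given mouse, so dividing by the raw number of
samples would bound the index near 0.63); the raw-B convention is kept
alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import ClusterSolution, TrajectoryKMeans, _flatten

__all__ = ["align_cluster_labels", "StabilityReport", "bootstrap_stability"]


def align_cluster_labels(
    reference_labels: np.ndarray,
    candidate_labels: np.ndarray,
    shared: np.ndarray | None = None,
) -> dict:
    """Map candidate cluster labels onto reference labels by maximal overlap.

    ``shared`` optionally restricts the contingency table to a subset of
    individuals (positions valid in both label vectors).  Candidate
    clusters beyond the reference k map to -1 (unmatched).  Returns a dict
    candidate_label -> reference_label.
    """
    ref = np.asarray(reference_labels)
    cand = np.asarray(candidate_labels)
    if shared is not None:
        ref = ref[shared]
        cand = cand[shared]
    if ref.size == 0:
        raise ValueError("no shared individuals between the two solutions")
    ref_levels = np.unique(reference_labels)
    cand_levels = np.unique(candidate_labels)
    table = np.zeros((len(ref_levels), len(cand_levels)))
    for i, rl in enumerate(ref_levels):
        for j, cl in enumerate(cand_levels):
            table[i, j] = np.sum((ref == rl) & (cand == cl))
    row, col = linear_sum_assignment(-table)
    mapping = {int(cand_levels[j]): int(ref_levels[i]) for i, j in zip(row, col)}
    for cl in cand_levels:
        mapping.setdefault(int(cl), -1)
    return mapping


@dataclass
class StabilityReport:
    """Per-mouse and per-cluster bootstrap Jaccard indices."""

    per_mouse: pd.DataFrame
    per_cluster: pd.DataFrame
    B: int

    def mean_jaccard(self, cluster: int) -> float:
        row = self.per_cluster.loc[self.per_cluster["cluster"] == cluster]
        return float(row["jaccard"].iloc[0])


def bootstrap_stability(
    trajectories,
    base: ClusterSolution,
    B: int = 200,
    seed: int | None = None,
    n_restarts: int = 50,
    mouse_ids: np.ndarray | None = None,
) -> StabilityReport:
    """Bootstrap re-clustering stability of ``base`` on its own trajectories.

    For each of ``B`` samples of n mice drawn with replacement, the sample
    is re-clustered at ``base.k``, labels are aligned to the base solution
    over the mice present in the sample, and each present mouse scores a
    hit when its aligned label equals its base label.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    Xf = _flatten(trajectories)
    n = Xf.shape[0]
    if len(base.labels) != n:
        raise ValueError("base solution was not fitted on these trajectories")
    rng = np.random.default_rng(seed)
    same = np.zeros(n, dtype=int)
    included = np.zeros(n, dtype=int)
    occurrences = np.zeros(n, dtype=int)
    for b in range(B):
        sample = rng.integers(0, n, size=n)
        occurrences += np.bincount(sample, minlength=n)
        uniq = np.unique(sample)
        if uniq.size < base.k:
            raise ValueError(
                f"bootstrap sample {b} has {uniq.size} distinct individuals, "
                f"fewer than k = {base.k}"
            )
        est = TrajectoryKMeans(
            n_clusters=base.k,
            n_restarts=n_restarts,
            random_state=int(rng.integers(2**31)),
        ).fit(Xf[sample])
        # label of each unique mouse = label at its first occurrence
        first_pos = np.array([np.flatnonzero(sample == u)[0] for u in uniq])
        cand = est.labels_[first_pos]
        mapping = align_cluster_labels(base.labels[uniq], cand)
        aligned = np.array([mapping[int(c)] for c in cand])
        hits = aligned == base.labels[uniq]
        included[uniq] += 1
        same[uniq] += hits.astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        jac_incl = np.where(included > 0, same / np.maximum(included, 1), np.nan)
    per_mouse = pd.DataFrame(
        {
            "mouse_id": (
                mouse_ids if mouse_ids is not None else np.arange(n)
            ),
            "cluster": base.labels,
            "inclusion_count": included,
            "occurrence_count": occurrences,
            "same_cluster_count": same,
            "jaccard": jac_incl,
            "jaccard_raw_b": same / B,
        }
    )
    per_cluster = (
        per_mouse.groupby("cluster")
        .agg(
            n_mice=("mouse_id", "size"),
            jaccard=("jaccard", "mean"),
            jaccard_raw_b=("jaccard_raw_b", "mean"),
        )
        .reset_index()
    )
    return StabilityReport(per_mouse=per_mouse, per_cluster=per_cluster, B=B)
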