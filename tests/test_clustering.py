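"""Longitudinal k-means, gap statistic, CVI vote, cluster characterization."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import holeboard as hb
from holeboard.clustering import ClusterSolution, compute_cvis
from conftest import two_blob_trajectories


def partition_ss(Xf, labels):
    ss = 0.0
    for lab in np.unique(labels):
        pts = Xf[labels == lab]
        ss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return ss


def best_bipartition_ss(Xf):
    """Exhaustive minimum within-cluster SS over all 2-cluster partitions."""
    n = Xf.shape[0]
    best = np.inf
    best_labels = None
    for mask in range(1, 2 ** (n - 1)):  # point 0 fixed in cluster 0
        labels = np.array([0] + [(mask >> i) & 1 for i in range(n - 1)])
        if labels.sum() in (0, n):
            continue
        ss = partition_ss(Xf, labels)
        if ss < best:
            best, best_labels = ss, labels
    return best, best_labels


def test_traj_distance_examples(rng):
    a = rng.normal(size=(5, 3))
    assert hb.traj_distance(a, a) == 0.0
    b = rng.normal(size=(5, 3))
    assert hb.traj_distance(a, b) == pytest.approx(hb.traj_distance(b, a))
    np.testing.assert_allclose(hb.traj_distance(a, a + 2.0), np.sqrt(60.0))
    with pytest.raises(ValueError, match="shape"):
        hb.traj_distance(a, np.zeros((4, 3)))


def test_n_equals_k_each_point_its_own_cluster(rng):
    X = rng.normal(size=(4, 5, 3))
    sol = hb.kmeans_longitudinal(X, k=4, n_restarts=20, seed=0)
    assert sol.inertia == pytest.approx(0.0, abs=1e-12)
    assert len(np.unique(sol.labels)) == 4


def test_two_blob_assignment_matches_exhaustive_optimum(rng):
    X, truth = two_blob_trajectories(rng, n_per_blob=4)
    Xf = X.reshape(8, -1)
    best_ss, best_labels = best_bipartition_ss(Xf)
    sol = hb.kmeans_longitudinal(X, k=2, n_restarts=50, seed=1)
    assert sol.inertia == pytest.approx(best_ss, rel=1e-9)
    assert adjusted_rand_score(best_labels, sol.labels) == 1.0
    assert adjusted_rand_score(truth, sol.labels) == 1.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_tiny_instances_reach_enumeration_optimum(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(10, 5, 3))
    best_ss, _ = best_bipartition_ss(X.reshape(10, -1))
    sol = hb.kmeans_longitudinal(X, k=2, n_restarts=60, seed=seed)
    assert sol.inertia == pytest.approx(best_ss, rel=1e-9)


def test_best_ss_non_increasing_in_restarts(rng):
    X = rng.normal(size=(30, 5, 3))
    prev = np.inf
    for restarts in (1, 5, 20, 60):
        sol = hb.kmeans_longitudinal(X, k=3, n_restarts=restarts, seed=9)
        assert sol.inertia <= prev + 1e-12  # restart streams are nested
        prev = sol.inertia


def test_agrees_with_sklearn_kmeans(rng):
    X, _ = two_blob_trajectories(rng, n_per_blob=20, separation=6.0)
    ours = hb.kmeans_longitudinal(X, k=2, n_restarts=50, seed=3)
    ref = KMeans(n_clusters=2, n_init=20, random_state=0).fit(X.reshape(40, -1))
    assert ours.inertia <= ref.inertia_ + 1e-6
    assert adjusted_rand_score(ref.labels_, ours.labels) == 1.0


def test_kmeans_input_validation(rng):
    X = rng.normal(size=(5, 5, 3))
    with pytest.raises(ValueError, match="exceeds"):
        hb.kmeans_longitudinal(X, k=6)
    with pytest.raises(ValueError, match=">= 2"):
        hb.kmeans_longitudinal(X, k=1)
    with pytest.raises(ValueError, match="n_restarts"):
        hb.kmeans_longitudinal(X, k=2, n_restarts=0)


def test_gap_statistic_verdicts(rng):
    tight = rng.normal(0.0, 0.3, size=(60, 5, 3))
    gap_one = hb.gap_statistic(tight, k_max=3, B=15, seed=4, n_restarts=5)
    assert gap_one.one_cluster

    X, _ = two_blob_trajectories(rng, n_per_blob=30, separation=12.0, spread=0.4)
    gap_two = hb.gap_statistic(X, k_max=3, B=15, seed=4, n_restarts=5)
    assert not gap_two.one_cluster

    with pytest.raises(ValueError, match="B >= 10"):
        hb.gap_statistic(tight, B=5)
    with pytest.raises(ValueError, match="degenerate"):
        hb.gap_statistic(np.ones((10, 5, 3)), B=15)


def _stub_solution(k, cvi):
    return ClusterSolution(
        k=k,
        labels=np.zeros(4, dtype=int),
        centers=np.zeros((k, 5, 3)),
        inertia=1.0,
        n_iter=np.array([1]),
        n_restarts=1,
        cvi=cvi,
    )


def test_select_k_majority_and_tiebreak():
    # all three indices optimal at the same k
    sols = {
        2: _stub_solution(2, {"calinski_harabasz": 9, "davies_bouldin": 0.2, "ray_turi": 0.1}),
        3: _stub_solution(3, {"calinski_harabasz": 5, "davies_bouldin": 0.9, "ray_turi": 0.8}),
    }
    assert hb.select_k_cvi(sols)[0] == 2
    # two against one
    sols[3].cvi["calinski_harabasz"] = 20
    assert hb.select_k_cvi(sols)[0] == 2
    # full three-way split: tie resolves toward the smallest voted k
    sols[4] = _stub_solution(4, {"calinski_harabasz": 1, "davies_bouldin": 0.1, "ray_turi": 0.9})
    k, votes = hb.select_k_cvi(sols)
    assert len(set(votes.values())) == 3 and k == min(votes.values())
    with pytest.raises(ValueError, match="at least 2"):
        hb.select_k_cvi({2: sols[2]})


def test_cvis_match_reference_definitions(rng):
    X, _ = two_blob_trajectories(rng, n_per_blob=10)
    sol = hb.kmeans_longitudinal(X, k=2, n_restarts=20, seed=0)
    cvi = compute_cvis(X, sol.labels, sol.centers)
    assert cvi["calinski_harabasz"] > 50  # well separated
    assert cvi["davies_bouldin"] < 0.5
    assert cvi["ray_turi"] < 0.2


def _two_type_scores(seed=31, n=15):
    config = hb.SyntheticConfig(seed=seed, n_per_strain={"C": n, "B6N": n, "129S2": n})
    _, scores, truth = hb.simulate_phase1_cohort(config)
    return scores, truth


def test_characterization_detects_cluster_by_trial_interaction():
    scores, truth = _two_type_scores()
    labels = truth.set_index("mouse_id")["latent_type"].map({"A": 0, "B": 1})
    report = hb.characterize_clusters(scores, labels)
    for dim in ("avoidance", "exploration", "locomotion"):
        anova = report[dim]["anova"].set_index("term")
        assert anova.loc["cluster:trial", "p"] < 0.05
        contrasts = report[dim]["contrasts"]
        assert {"estimate", "se", "t", "p", "cohen_d"} <= set(contrasts.columns)
    # trial 5 - trial 1 within the avoidance-rising type is positive
    c = report["avoidance"]["contrasts"]
    rise = c[c["contrast"] == "trial 5 - 1 within cluster 0"]["estimate"].iloc[0]
    fall = c[c["contrast"] == "trial 5 - 1 within cluster 1"]["estimate"].iloc[0]
    assert rise > 0 > fall


def test_characterization_null_labels_are_calibrated():
    scores, truth = _two_type_scores(seed=8, n=12)
    rng = np.random.default_rng(17)
    mice = truth["mouse_id"].to_numpy()
    rejections = 0
    n_sims = 60
    for _ in range(n_sims):
        perm = dict(zip(mice, rng.permutation([0, 1] * (len(mice) // 2))))
        report = hb.characterize_clusters(
            scores, perm, transformations={}
        )
        p = report["exploration"]["anova"].set_index("term").loc["cluster:trial", "p"]
        rejections += p < 0.05
    assert rejections / n_sims <= 0.15  # no systematic anti-conservatism


def test_characterization_identical_cluster_means_give_zero_d(rng):
    # two "clusters" that are exact copies of each other
    config = hb.SyntheticConfig(seed=2, n_per_strain={"C": 6, "B6N": 6, "129S2": 6})
    _, scores, _ = hb.simulate_phase1_cohort(config)
    dup = scores.copy()
    dup["mouse_id"] = dup["mouse_id"] + "_copy"
    import pandas as pd

    combined = pd.concat([scores, dup], ignore_index=True)
    labels = {m: int(m.endswith("_copy")) for m in combined["mouse_id"].unique()}
    report = hb.characterize_clusters(combined, labels)
    for dim in ("avoidance",):
        c = report[dim]["contrasts"]
        per_trial = c[c["contrast"].str.startswith("cluster")]
        np.testing.assert_allclose(per_trial["estimate"], 0.0, atol=1e-8)
        np.testing.assert_allclose(per_trial["cohen_d"], 0.0, atol=1e-8)


def test_characterization_requires_two_clusters(small_cohort):
    scores = small_cohort["latent"]
    labels = {m: 0 for m in scores["mouse_id"].unique()}
    with pytest.raises(ValueError, match="two or more"):
        hb.characterize_clusters(scores, labels)
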