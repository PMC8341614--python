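"""Residualization: transforms, REML engine oracles, confounder removal."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import holeboard as hb
from holeboard.constants import DIMENSIONS
from holeboard.lmm import fit_marginal_lmm
from holeboard.residualize import _fixed_design, _indicator


@pytest.mark.parametrize(
    "values, kind, expected",
    [
        ([1, 5, 3], "rank", [1, 3, 2]),
        ([2, 2, 7], "rank", [1.5, 1.5, 3]),
        ([4, 9, 2.5], "log-shift", np.log([2.5, 7.5, 1.0]) - np.log(1.0) + 0.0),
        ([4, 9, 2.5], "sqrt-shift", np.sqrt([1.5, 6.5, 0.0])),
        ([1.0, -2.0], "none", [1.0, -2.0]),
    ],
)
def test_transform_examples(values, kind, expected):
    got = hb.transform_dimension(values, kind)
    if kind == "log-shift":
        # the minimum maps to log(1) = 0 by the shift definition
        assert got[np.argmin(values)] == 0.0
    np.testing.assert_allclose(got, np.asarray(expected, dtype=float))


def test_transform_errors():
    with pytest.raises(ValueError, match="empty"):
        hb.transform_dimension([], "rank")
    with pytest.raises(ValueError, match="unknown transformation"):
        hb.transform_dimension([1.0], "boxcox")


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=3, max_size=12, unique=True))
def test_rank_commutes_with_increasing_maps(values):
    from hypothesis import assume

    x = np.asarray(values)
    assume(len(np.unique(np.exp(x / 3))) == len(x))  # the map must stay injective in floats
    base = hb.transform_dimension(x, "rank")
    np.testing.assert_allclose(hb.transform_dimension(np.exp(x / 3), "rank"), base)
    np.testing.assert_allclose(hb.transform_dimension(3 * x + 10, "rank"), base)


def test_zero_variance_components_reduce_to_ols(rng):
    n, p = 60, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(0, 0.7, n)
    res = fit_marginal_lmm(y, X, vc={}, profile_phi=False, profile_weights=False)
    ols = sm.OLS(y, X).fit()
    np.testing.assert_allclose(res.beta, ols.params, rtol=1e-10)
    np.testing.assert_allclose(res.sigma2, ols.mse_resid, rtol=1e-10)
    np.testing.assert_allclose(
        res.resid_pearson, ols.resid / np.sqrt(ols.mse_resid), rtol=1e-9
    )


def test_orthogonal_response_yields_scaled_centered_response(rng):
    n = 40
    strain = np.repeat(["a", "b"], n // 2)
    X = np.column_stack([np.ones(n), (strain == "b").astype(float)])
    y0 = rng.normal(size=n)
    # project out the design, then shift: nothing for the model to remove
    y = y0 - X @ np.linalg.lstsq(X, y0, rcond=None)[0] + 2.0
    res = fit_marginal_lmm(y, X, vc={}, profile_phi=False, profile_weights=False)
    centered = y - y.mean()
    np.testing.assert_allclose(
        res.resid_pearson, centered / res.sigma, rtol=1e-8, atol=1e-10
    )


def test_rank_deficient_design_reported():
    n = 20
    X = np.column_stack([np.ones(n), np.arange(n), 2.0 * np.arange(n)])
    with pytest.raises(ValueError, match="rank deficient"):
        fit_marginal_lmm(np.random.default_rng(0).normal(size=n), X)


def _separation(traj, types):
    a = traj[types == "A"].mean(axis=0)
    b = traj[types == "B"].mean(axis=0)
    return float(np.sqrt(((a - b) ** 2).sum()))


def test_experimenter_offset_removed_and_type_separation_kept():
    config = hb.SyntheticConfig(
        seed=21,
        n_per_strain={"C": 20, "B6N": 20, "129S2": 20},
        experimenter_offsets={
            "E1": {"avoidance": 1.0, "exploration": 0.0, "locomotion": 0.0},
            "E2": {d: 0.0 for d in DIMENSIONS},
        },
    )
    raw, _, truth = hb.simulate_phase1_cohort(config)
    scores = hb.compute_dimension_scores(raw)
    tidy, _ = hb.fit_residual_model(scores)
    ids, traj = hb.residual_matrix(tidy)
    meta = truth.set_index("mouse_id").loc[ids]

    avoid_resid = traj[:, :, 0].mean(axis=1)
    diff = (
        avoid_resid[(meta["experimenter"] == "E1").to_numpy()].mean()
        - avoid_resid[(meta["experimenter"] == "E2").to_numpy()].mean()
    )
    assert abs(diff) < 0.15  # the injected +1 z offset is gone

    # type separation survives residualization (per-dimension standardized)
    pre = np.stack(
        [
            scores.pivot(index="mouse_id", columns="trial", values=f"{d}_z")
            .loc[ids]
            .to_numpy()
            / scores[f"{d}_z"].std()
            for d in DIMENSIONS
        ],
        axis=2,
    )
    types = meta["latent_type"].to_numpy()
    assert _separation(traj, types) >= 0.9 * _separation(pre, types)


def test_stratum_residual_sd_near_one(default_cohort, default_residuals):
    tidy = default_residuals["tidy"]
    strains = default_cohort["truth"].set_index("mouse_id")["strain"]
    merged = tidy.assign(strain=tidy["mouse_id"].map(strains))
    for (_, _), grp in merged.groupby(["dimension", "strain"]):
        assert abs(grp["residual"].std() - 1.0) < 0.1


def test_residuals_match_r_nlme_oracle(small_cohort, tmp_path):
    """Cross-check the REML engine against nlme::lme on the same model.

    Same layout the residualization stage uses, restricted to the single
    random factor nlme handles directly: mouse intercept, CAR(1) over
    trials, per-strain variance weights.
    """
    scores = (
        hb.compute_dimension_scores(small_cohort["raw"])
        .sort_values(["mouse_id", "trial"])
        .reset_index(drop=True)
    )
    scores["y"] = hb.transform_dimension(scores["avoidance_z"].to_numpy(), "log-shift")
    X, _, _ = _fixed_design(scores, ("strain", "experimenter"))
    levels = sorted(scores["strain"].unique())
    strata = scores["strain"].map({l: i for i, l in enumerate(levels)}).to_numpy()
    codes = pd.factorize(scores["mouse_id"])[0]
    res = fit_marginal_lmm(
        scores["y"].to_numpy(),
        X,
        vc={"mouse": _indicator(scores["mouse_id"])},
        car1_groups=codes,
        car1_times=scores["trial"].to_numpy(float),
        strata=strata,
        strata_levels=levels,
    )

    data_csv = tmp_path / "scores.csv"
    resid_csv = tmp_path / "resid.csv"
    scores.to_csv(data_csv, index=False)
    rcode = f"""
suppressMessages(library(nlme))
d <- read.csv("{data_csv}")
fit <- lme(y ~ strain + experimenter, random = ~1|mouse_id,
           correlation = corCAR1(form = ~trial|mouse_id),
           weights = varIdent(form = ~1|strain), data = d, method = "REML")
write.csv(data.frame(pr = as.numeric(resid(fit, type = "pearson")),
                     phi = coef(fit$modelStruct$corStruct, unconstrained = FALSE),
                     sigma = fit$sigma), "{resid_csv}", row.names = FALSE)
"""
    subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
    r_out = pd.read_csv(resid_csv)
    assert abs(res.phi - r_out["phi"].iloc[0]) < 0.05
    assert abs(res.sigma - r_out["sigma"].iloc[0]) < 0.05
    r_resid = r_out["pr"].to_numpy()
    assert np.corrcoef(r_resid, res.resid_pearson)[0, 1] > 0.999
    assert np.max(np.abs(r_resid - res.resid_pearson)) < 0.05


def test_trial_never_a_predictor():
    with pytest.raises(ValueError, match="trial"):
        hb.ResidualModelSpec(fixed=("strain", "trial"))


def test_incomplete_trials_rejected(small_cohort):
    scores = hb.compute_dimension_scores(small_cohort["raw"])
    broken = scores[~((scores["mouse_id"] == scores["mouse_id"].iloc[0]) & (scores["trial"] == 5))]
    with pytest.raises(ValueError, match="5 trials"):
        hb.fit_residual_model(broken)


def test_residualizer_estimator_surface(small_cohort):
    scores = hb.compute_dimension_scores(small_cohort["raw"])
    est = hb.TrajectoryResidualizer().fit(scores)
    assert est.trajectories_.shape == (24, 5, 3)
    assert set(est.metadata_) == set(DIMENSIONS)
    out = est.transform(scores)
    assert {"mouse_id", "trial", "dimension", "residual"} <= set(out.columns)
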