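"""Factorial models, effect sizes, corrected contrasts, pool comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import holeboard as hb
from holeboard.constants import DIMENSIONS


def test_dunn_sidak_reference_values():
    assert hb.dunn_sidak(0.05, 1) == pytest.approx(0.05)
    assert round(hb.dunn_sidak(0.05, 2), 6) == 0.025321
    assert round(hb.dunn_sidak(0.05, 3), 6) == 0.016952
    assert round(hb.dunn_sidak(0.05, 4), 5) == 0.01274


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(1, 50), st.floats(0.001, 0.2))
def test_dunn_sidak_bonferroni_sandwich(m, alpha):
    adj = hb.dunn_sidak(alpha, m)
    assert alpha / m - 1e-12 <= adj <= alpha + 1e-12


def test_dunn_sidak_input_validation():
    with pytest.raises(ValueError):
        hb.dunn_sidak(0.05, 0)
    with pytest.raises(ValueError):
        hb.dunn_sidak(1.5, 2)


def test_effect_size_bands():
    assert hb.eta_squared_band(0.01) == "small"
    assert hb.eta_squared_band(0.052) == "medium"
    assert hb.eta_squared_band(0.124) == "large"
    assert hb.eta_squared_band(0.25) == "very large"
    assert hb.cohen_d_band(0.3) == "small"
    assert hb.cohen_d_band(-0.7) == "medium"
    assert hb.cohen_d_band(1.2) == "large"
    assert hb.cohen_d_band(-2.0) == "very large"


def test_partial_eta_squared_degenerate_cases():
    value, ci, band = hb.partial_eta_squared(5.0, 0.0, 1, 10)
    assert value == 1.0 and band == "very large"
    value, ci, band = hb.partial_eta_squared(4.0, 4.0, 2, 20)
    assert value == pytest.approx(0.5)
    assert 0.0 <= ci[0] <= value <= ci[1] <= 1.0
    with pytest.raises(ValueError):
        hb.partial_eta_squared(0.0, 0.0, 1, 10)


def _phase2_frame(rng, n_per_cell=4, effects=None):
    effects = effects or {}
    rows = []
    for t in ("dexmedetomidine", "saline"):
        for s in ("C", "B6N", "129S2"):
            for e in ("E1", "E2"):
                for b in (1, 2, 3, 4):
                    for _ in range(n_per_cell):
                        y = rng.normal()
                        y += effects.get(("treatment", t), 0.0)
                        y += effects.get(("strain", s), 0.0)
                        rows.append(
                            {
                                "treatment": t,
                                "strain": s,
                                "experimenter": e,
                                "block": b,
                                "y": y,
                            }
                        )
    return pd.DataFrame(rows)


def test_eta_invariant_under_affine_response_rescaling(rng):
    data = _phase2_frame(rng, effects={("treatment", "dexmedetomidine"): 0.5})
    res1 = hb.fit_factorial_model(data, "y", factors=("treatment", "strain", "experimenter"))
    data2 = data.assign(y=3.0 * data["y"] + 7.0)
    res2 = hb.fit_factorial_model(data2, "y", factors=("treatment", "strain", "experimenter"))
    np.testing.assert_allclose(
        res1.anova["eta_p2"].to_numpy(), res2.anova["eta_p2"].to_numpy(), rtol=1e-6
    )
    np.testing.assert_allclose(
        res1.anova["F"].to_numpy(), res2.anova["F"].to_numpy(), rtol=1e-6
    )


def test_two_group_contrast_matches_closed_form(rng):
    # single factor, single block: the model collapses to a two-sample
    # pooled-variance t-test
    n_per = 12
    a = rng.normal(0.0, 1.0, n_per)
    b = rng.normal(0.8, 1.0, n_per)
    data = pd.DataFrame(
        {
            "treatment": ["dexmedetomidine"] * n_per + ["saline"] * n_per,
            "block": 1,
            "y": np.concatenate([a, b]),
        }
    )
    res = hb.fit_factorial_model(data, "y", factors=("treatment",))
    out = hb.emm_contrasts(res, "treatment").iloc[0]
    sp2 = ((n_per - 1) * a.var(ddof=1) + (n_per - 1) * b.var(ddof=1)) / (2 * n_per - 2)
    se = np.sqrt(sp2 * 2 / n_per)
    tstat = (a.mean() - b.mean()) / se
    assert out["estimate"] == pytest.approx(a.mean() - b.mean(), rel=1e-6)
    assert out["se"] == pytest.approx(se, rel=1e-6)
    assert out["t"] == pytest.approx(tstat, rel=1e-6)
    assert out["df"] == 2 * n_per - 2
    assert out["p"] == pytest.approx(
        2 * stats.t.sf(abs(tstat), 2 * n_per - 2), rel=1e-6
    )
    assert out["cohen_d"] == pytest.approx((a.mean() - b.mean()) / np.sqrt(sp2), rel=1e-4)


def test_identical_group_means_give_zero_contrast(rng):
    data = _phase2_frame(rng, n_per_cell=1)
    # force exact equality of treatment marginal means
    piv = data.groupby("treatment")["y"].transform("mean")
    data["y"] = data["y"] - piv
    res = hb.fit_factorial_model(data, "y", factors=("treatment", "strain", "experimenter"))
    out = hb.emm_contrasts(res, "treatment").iloc[0]
    assert abs(out["estimate"]) < 1e-10 and abs(out["cohen_d"]) < 1e-10


def test_exact_cell_means_zero_residual(rng):
    data = _phase2_frame(rng, n_per_cell=2)
    means = data.groupby(["treatment", "strain", "experimenter"])["y"].transform("mean")
    exact = data.assign(y=means)
    res = hb.fit_factorial_model(exact, "y", factors=("treatment", "strain", "experimenter"))
    anova = res.anova.set_index("term")
    # residual variation vanishes, so every non-null term explains ~everything
    assert res.sigma < 1e-6
    assert anova.loc["treatment", "eta_p2"] > 0.99


def test_empty_cells_listed(rng):
    data = _phase2_frame(rng)
    broken = data[~((data["treatment"] == "saline") & (data["strain"] == "C"))]
    with pytest.raises(ValueError, match="empty design cells"):
        hb.fit_factorial_model(broken, "y", factors=("treatment", "strain"))


def test_contrast_over_absent_factor_rejected(rng):
    data = _phase2_frame(rng)
    res = hb.fit_factorial_model(data, "y", factors=("treatment", "strain"))
    with pytest.raises(ValueError, match="not in the fitted model"):
        hb.emm_contrasts(res, "experimenter")


def test_compare_pools_classification():
    def tab(ps):
        return pd.DataFrame({"term": list(ps), "p": list(ps.values())})

    bal = tab({"treatment": 0.30, "strain": 0.01, "experimenter": 0.02, "x": 0.9})
    unb = tab({"treatment": 0.01, "strain": 0.02, "experimenter": 0.40, "x": 0.8})
    out = hb.compare_pools(bal, unb).set_index("term")["classification"]
    assert out["treatment"] == "augmented"
    assert out["strain"] == "both"
    assert out["experimenter"] == "unmasked"
    assert out["x"] == "neither"
    # identical tables diverge nowhere
    same = hb.compare_pools(bal, bal)
    assert set(same["classification"]) <= {"both", "neither"}
    with pytest.raises(ValueError, match="different terms"):
        hb.compare_pools(bal, unb.iloc[:-1])


def test_treatment_effect_recovery_via_factorial_fit(characterized_truth):
    """Mean recovered treatment contrast matches the injected -0.8 shift."""
    config = hb.SyntheticConfig(
        seed=0,
        treatment_effect={"avoidance": 0.0, "exploration": 0.0, "locomotion": -0.8},
    )
    design = hb.build_design_from_cohort(characterized_truth, seed=1)
    longd = hb.design_long(design)
    estimates = []
    for s in range(150):
        scores = hb.simulate_phase2_responses(longd, config, seed=5000 + s)
        merged = longd.merge(scores, on="mouse_id")
        res = hb.fit_factorial_model(
            merged,
            "locomotion_z",
            factors=("treatment", "strain", "pool", "experimenter"),
            transformation="none",
        )
        contrast = hb.emm_contrasts(res, "treatment").iloc[0]
        estimates.append(contrast["estimate"])  # dexmedetomidine - saline
    assert np.mean(estimates) == pytest.approx(-0.8, abs=0.04)
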