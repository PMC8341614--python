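"""Synthetic mHB cohorts with a latent two-response-type structure.

The generator emulates the study conditions the downstream stages assume:
three inbred strains (59/60/60 mice), five repeated trials, two latent
response types mixed within every strain (type A: avoidance rises across
trials while exploration stays low and locomotion falls; type B: avoidance
falls while exploration and locomotion rise), additive strain and
experimenter offsets, a per-mouse random intercept, CAR(1) trial-to-trial
noise, and a single-trial pharmacological phase in which treatment
suppresses activity.  Ground-truth type labels are always returned so that
label recovery can be tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    DIMENSIONS,
    EXPERIMENTERS,
    LATENCY_CEILING,
    N_TRIALS,
    RESPONSE_TYPES,
    STRAINS,
)

__all__ = [
    "SyntheticConfig",
    "simulate_phase1_cohort",
    "simulate_phase2_responses",
    "RAW_VARIABLES",
]


def _linear_ramp(start: float, stop: float) -> tuple[float, ...]:
    return tuple(float(v) for v in np.linspace(start, stop, N_TRIALS))


def _default_type_trajectories() -> dict:
    # Monotone ramps matching the qualitative cluster shapes: type A
    # sensitizes (avoidance up, activity down/flat), type B habituates.
    return {
        "A": {
            "avoidance": _linear_ramp(-0.5, 0.5),
            "exploration": tuple([-0.2] * N_TRIALS),
            "locomotion": _linear_ramp(0.2, -0.4),
        },
        "B": {
            "avoidance": _linear_ramp(0.5, -0.5),
            "exploration": _linear_ramp(-0.3, 0.6),
            "locomotion": _linear_ramp(-0.3, 0.6),
        },
    }


def _default_strain_offsets() -> dict:
    return {
        "C": {"avoidance": 0.2, "exploration": -0.1, "locomotion": 0.0},
        "B6N": {"avoidance": 0.0, "exploration": 0.3, "locomotion": 0.4},
        "129S2": {"avoidance": 0.1, "exploration": -0.2, "locomotion": -0.2},
    }


def _default_experimenter_offsets() -> dict:
    # Observer E1 scores more avoidance and less exploration than E2.
    return {
        "E1": {"avoidance": 0.15, "exploration": -0.15, "locomotion": 0.0},
        "E2": {"avoidance": 0.0, "exploration": 0.0, "locomotion": 0.0},
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    All behavioral quantities are in integrated z-score units; body weights
    are in grams.  ``strain_type_probs`` gives the probability that a mouse
    of each strain belongs to latent type A (the complement is type B).
    """

    n_per_strain: dict = field(
        default_factory=lambda: {"C": 59, "B6N": 60, "129S2": 60}
    )
    strain_type_probs: dict = field(
        default_factory=lambda: {"C": 0.119, "B6N": 0.70, "129S2": 0.90}
    )
    type_mean_trajectories: dict = field(default_factory=_default_type_trajectories)
    strain_offsets: dict = field(default_factory=_default_strain_offsets)
    experimenter_offsets: dict = field(default_factory=_default_experimenter_offsets)
    sd_individual: float = 0.25
    sd_noise: float = 0.30
    car1_phi: float = 0.4
    treatment_effect: dict = field(
        default_factory=lambda: {
            "avoidance": 0.3,
            "exploration": -0.6,
            "locomotion": -0.8,
        }
    )
    #: Per-type additive shift used in the single-trial phase-2 simulation;
    #: None derives it from each type's trial-5 trajectory value.
    phase2_type_offsets: dict | None = None
    weight_mean_sd: dict = field(
        default_factory=lambda: {
            "C": (20.4, 1.5),
            "B6N": (21.0, 1.6),
            "129S2": (24.1, 2.1),
        }
    )
    #: Between-test-day (block) SD of the phase-2 responses; the block
    #: factor of the randomized block design exists to absorb exactly this.
    sd_block: float = 0.2
    #: Multiplier on the raw Table-style variables' emission noise.
    raw_noise_scale: float = 1.0
    #: Mice tested per weekly batch (test group), split evenly over strains.
    batch_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for strain, n in self.n_per_strain.items():
            if n <= 0:
                raise ValueError(f"non-positive cohort size for strain {strain!r}")
        for strain, p in self.strain_type_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"type probability for {strain!r} not in [0, 1]")
        if self.sd_individual < 0 or self.sd_noise < 0 or self.sd_block < 0:
            raise ValueError("standard deviations must be non-negative")
        if not abs(self.car1_phi) < 1:
            raise ValueError("car1_phi must satisfy |phi| < 1")
        if self.raw_noise_scale < 0:
            raise ValueError("raw_noise_scale must be non-negative")
        for rtype in RESPONSE_TYPES:
            traj = self.type_mean_trajectories.get(rtype)
            if traj is None:
                raise ValueError(f"missing mean trajectories for type {rtype!r}")
            for dim in DIMENSIONS:
                if dim not in traj or len(traj[dim]) != N_TRIALS:
                    raise ValueError(
                        f"trajectory for type {rtype!r}, dimension {dim!r} must "
                        f"have exactly {N_TRIALS} trial entries"
                    )

    def type_offset_phase2(self, rtype: str, dim: str) -> float:
        if self.phase2_type_offsets is not None:
            return self.phase2_type_offsets[rtype][dim]
        return float(self.type_mean_trajectories[rtype][dim][-1])

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


# Raw ethogram variables emitted per dimension:
# (variable, dimension, kind, intercept, slope, noise_sd).  Each variable is
# an affine-plus-noise readout of its dimension's latent score; counts are
# rounded and floored at zero, latencies clipped to the 300 s ceiling,
# percentages clamped to [0, 100].
RAW_VARIABLES = (
    ("board_entries", "avoidance", "count", 12.0, -5.0, 1.5),
    ("latency_first_board_entry", "avoidance", "latency", 60.0, 60.0, 15.0),
    ("pct_time_on_board", "avoidance", "percent", 20.0, -10.0, 3.0),
    ("rearings_box", "exploration", "count", 25.0, 8.0, 2.5),
    ("latency_first_rearing_box", "exploration", "latency", 40.0, -25.0, 8.0),
    ("rearings_board", "exploration", "count", 8.0, 4.0, 1.5),
    ("latency_first_rearing_board", "exploration", "latency", 90.0, -50.0, 15.0),
    ("hole_explorations", "exploration", "count", 15.0, 6.0, 2.0),
    ("latency_first_hole_exploration", "exploration", "latency", 70.0, -40.0, 12.0),
    ("hole_visits", "exploration", "count", 6.0, 3.0, 1.2),
    ("latency_first_hole_visit", "exploration", "latency", 110.0, -55.0, 15.0),
    ("line_crossings", "locomotion", "count", 120.0, 35.0, 8.0),
    ("latency_first_line_crossing", "locomotion", "latency", 12.0, -8.0, 3.0),
)


def _car1_noise(rng: np.random.Generator, n_trials: int, sd: float, phi: float) -> np.ndarray:
    """Stationary CAR(1) series: lag-1 correlation phi, marginal SD ``sd``."""
    e = np.empty(n_trials)
    e[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    for t in range(1, n_trials):
        e[t] = phi * e[t - 1] + (rng.normal(0.0, innov_sd) if sd > 0 else 0.0)
    return e


def _assemble_cohort(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw mice with strain, type, experimenter, weight and batch structure."""
    rows = []
    for strain in config.n_per_strain:
        n = config.n_per_strain[strain]
        p_a = config.strain_type_probs.get(strain, 0.5)
        types = np.where(rng.random(n) < p_a, "A", "B")
        mean, sd = config.weight_mean_sd.get(strain, (22.0, 1.8))
        weights = rng.normal(mean, sd, size=n)
        # split each strain near-evenly over the two observers (housing rooms)
        exp_assign = np.array(
            [EXPERIMENTERS[i % 2] for i in range(n)], dtype=object
        )
        rng.shuffle(exp_assign)
        for i in range(n):
            rows.append(
                {
                    "mouse_id": f"{strain}_{i + 1:03d}",
                    "strain": strain,
                    "experimenter": exp_assign[i],
                    "latent_type": types[i],
                    "body_weight_g": round(float(weights[i]), 2),
                }
            )
    truth = pd.DataFrame(rows)

    # weekly batches: batch_size mice per test group, split evenly per strain
    per_strain_batch = max(1, config.batch_size // len(config.n_per_strain))
    order_pool = []
    for strain in config.n_per_strain:
        idx = truth.index[truth["strain"] == strain].to_numpy()
        rng.shuffle(idx)
        for j, row_i in enumerate(idx):
            order_pool.append((j // per_strain_batch, row_i))
    groups: dict[int, list[int]] = {}
    for week, row_i in order_pool:
        groups.setdefault(week, []).append(row_i)
    test_group = np.empty(len(truth), dtype=object)
    test_order = np.empty(len(truth), dtype=int)
    for week in sorted(groups):
        members = np.array(groups[week])
        rng.shuffle(members)
        for pos, row_i in enumerate(members, start=1):
            test_group[row_i] = f"W{week + 1}"
            test_order[row_i] = pos
    truth["test_group"] = test_group
    truth["test_order"] = test_order
    return truth


def _latent_scores(
    truth: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-mouse x trial x dimension latent integrated scores."""
    records = []
    for row in truth.itertuples(index=False):
        traj = config.type_mean_trajectories[row.latent_type]
        strain_off = config.strain_offsets.get(row.strain, {})
        exp_off = config.experimenter_offsets.get(row.experimenter, {})
        per_dim = {}
        for dim in DIMENSIONS:
            intercept = rng.normal(0.0, config.sd_individual) if config.sd_individual > 0 else 0.0
            noise = _car1_noise(rng, N_TRIALS, config.sd_noise, config.car1_phi)
            per_dim[dim] = (
                np.asarray(traj[dim], dtype=float)
                + strain_off.get(dim, 0.0)
                + exp_off.get(dim, 0.0)
                + intercept
                + noise
            )
        for t in range(N_TRIALS):
            records.append(
                {
                    "mouse_id": row.mouse_id,
                    "trial": t + 1,
                    **{f"{dim}_z": per_dim[dim][t] for dim in DIMENSIONS},
                }
            )
    return pd.DataFrame(records)


def _emit_raw(
    scores: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Table-style ethogram variables as affine-plus-noise readouts."""
    long_rows = []
    nscale = config.raw_noise_scale
    for row in scores.itertuples(index=False):
        for name, dim, kind, intercept, slope, noise_sd in RAW_VARIABLES:
            latent = getattr(row, f"{dim}_z")
            value = intercept + slope * latent
            if nscale > 0:
                value += rng.normal(0.0, noise_sd * nscale)
            if kind == "count":
                value = float(max(0, round(value)))
            elif kind == "latency":
                value = float(np.clip(value, 0.0, LATENCY_CEILING))
            elif kind == "percent":
                value = float(np.clip(value, 0.0, 100.0))
            long_rows.append(
                {
                    "mouse_id": row.mouse_id,
                    "trial": row.trial,
                    "variable": name,
                    "value": value,
                }
            )
    return pd.DataFrame(long_rows)


def simulate_phase1_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
):
    """Simulate the repeated-trial characterization cohort.

    Returns ``(raw, scores, truth)``: a long raw-observation table (one row
    per mouse x trial x ethogram variable, with covariates), the wide latent
    dimension-score table (one row per mouse x trial), and the per-mouse
    ground truth including the latent response type.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    truth = _assemble_cohort(config, rng)
    scores = _latent_scores(truth, config, rng)
    raw = _emit_raw(scores, config, rng)

    covars = truth[
        ["mouse_id", "strain", "experimenter", "test_group", "test_order"]
    ]
    raw = raw.merge(covars, on="mouse_id", how="left")
    raw = raw[
        [
            "mouse_id",
            "strain",
            "experimenter",
            "test_group",
            "test_order",
            "trial",
            "variable",
            "value",
        ]
    ]
    scores = scores.merge(covars, on="mouse_id", how="left")
    return raw, scores, truth


def simulate_phase2_responses(
    design_long: pd.DataFrame,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the single-trial pharmacological phase for a built design.

    ``design_long`` must carry one row per enrolled mouse with columns
    ``mouse_id, strain, experimenter, treatment, response_type`` (see
    :func:`holeboard.design.design_long`).  The response per dimension is
    strain offset + experimenter offset + type offset + treatment effect
    (treated mice only) + individual intercept + noise.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    required = {"mouse_id", "strain", "experimenter", "treatment", "response_type"}
    missing = required - set(design_long.columns)
    if missing:
        raise ValueError(f"design rows missing columns: {sorted(missing)}")
    if design_long["treatment"].isna().any():
        raise ValueError("design rows missing treatment labels")

    block_offsets: dict = {}
    if "block" in design_long.columns and config.sd_block > 0:
        for b in sorted(design_long["block"].unique()):
            block_offsets[b] = {
                dim: rng.normal(0.0, config.sd_block) for dim in DIMENSIONS
            }

    records = []
    for row in design_long.itertuples(index=False):
        treated = row.treatment == "dexmedetomidine"
        strain_off = config.strain_offsets.get(row.strain, {})
        exp_off = config.experimenter_offsets.get(row.experimenter, {})
        rec = {"mouse_id": row.mouse_id, "trial": 1}
        for dim in DIMENSIONS:
            value = (
                strain_off.get(dim, 0.0)
                + exp_off.get(dim, 0.0)
                + config.type_offset_phase2(row.response_type, dim)
            )
            if treated:
                value += config.treatment_effect.get(dim, 0.0)
            if block_offsets:
                value += block_offsets[row.block][dim]
            if config.sd_individual > 0:
                value += rng.normal(0.0, config.sd_individual)
            if config.sd_noise > 0:
                value += rng.normal(0.0, config.sd_noise)
            rec[f"{dim}_z"] = value
        records.append(rec)
    return pd.DataFrame(records)
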