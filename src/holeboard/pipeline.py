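"""End-to-end orchestration: simulate -> score -> residualize -> cluster ->
stability -> design -> phase-2 simulate -> analyze -> compare.

Every stage derives its own seed deterministically from the master seed and
the stage name, writes CSV outputs with recorded checksums, and reports
into a JSON run manifest, so a run is reproducible from its config alone
and any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import compare_pools, fit_factorial_model
from .clustering import gap_statistic, kmeans_longitudinal, select_k_cvi
from .constants import DIMENSIONS
from .design import build_design_from_cohort, design_long
from .residualize import ResidualModelSpec, fit_residual_model, residual_matrix
from .scores import DimensionScorer
from .simulate import SyntheticConfig, simulate_phase1_cohort, simulate_phase2_responses
from .stability import bootstrap_stability

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "PipelineError"]

STAGES = (
    "simulate",
    "score",
    "residualize",
    "cluster",
    "stability",
    "design",
    "phase2",
    "analyze",
    "compare",
)

_DEPENDENCIES = {
    "score": ("simulate",),
    "residualize": ("score",),
    "cluster": ("residualize",),
    "stability": ("cluster",),
    "design": ("simulate", "cluster"),
    "phase2": ("design",),
    "analyze": ("phase2",),
    "compare": ("analyze",),
}

#: Transformations of the phase-2 integrated z-scores before the factorial fit.
PHASE2_TRANSFORMS = {"avoidance": "none", "exploration": "log-shift", "locomotion": "rank"}


class PipelineError(RuntimeError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed; adding stages never perturbs earlier streams."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed and output directory."""

    outdir: str = "holeboard_run"
    master_seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    residual_spec: ResidualModelSpec = field(default_factory=ResidualModelSpec)
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 1000
    gap_b: int = 50
    gap_restarts: int = 20
    run_gap: bool = True
    stability_b: int = 200
    stability_restarts: int = 50
    n_blocks: int = 4
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
        if "residual_spec" in kwargs:
            spec = kwargs["residual_spec"]
            if "fixed" in spec:
                spec["fixed"] = tuple(spec["fixed"])
            if "random" in spec:
                spec["random"] = tuple(spec["random"])
            kwargs["residual_spec"] = ResidualModelSpec(**spec)
        stages = {s: True for s in STAGES}
        stages.update(kwargs.get("stages", {}))
        kwargs["stages"] = stages
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        data = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _check_dependencies(stages: dict) -> None:
    for stage, deps in _DEPENDENCIES.items():
        if stages.get(stage, False):
            for dep in deps:
                if not stages.get(dep, False):
                    raise PipelineError(
                        f"stage {stage!r} is enabled but its dependency "
                        f"{dep!r} is disabled"
                    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns (and writes) the run manifest."""
    _check_dependencies(config.stages)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": {},
        "outputs": {},
        "results": {},
        "warnings": [],
        "status": "RUNNING",
    }

    def write_csv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest["outputs"][name] = _sha256(path)

    state: dict = {}
    current = None
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for stage in STAGES:
                if not config.stages.get(stage, False):
                    continue
                current = stage
                seed = stage_seed(config.master_seed, stage)
                manifest["stage_seeds"][stage] = seed
                _run_stage(stage, config, seed, state, write_csv, manifest)
            manifest["warnings"] = [str(w.message) for w in caught]
        manifest["status"] = "OK"
    except Exception as err:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = current
        manifest["error"] = str(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(f"stage {current!r} failed: {err}") from err

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stage(stage, config, seed, state, write_csv, manifest) -> None:
    if stage == "simulate":
        raw, scores_latent, truth = simulate_phase1_cohort(config.synthetic, seed=seed)
        state.update(raw=raw, truth=truth)
        write_csv("raw_observations.csv", raw)
        write_csv("cohort_truth.csv", truth)
        manifest["results"]["n_mice"] = int(truth["mouse_id"].nunique())

    elif stage == "score":
        scorer = DimensionScorer().fit(state["raw"])
        scores = scorer.transform(state["raw"])
        state["scores"] = scores
        write_csv("dimension_scores.csv", scores)

    elif stage == "residualize":
        tidy, meta = fit_residual_model(state["scores"], config.residual_spec)
        ids, traj = residual_matrix(tidy)
        state.update(residuals=tidy, mouse_ids=ids, trajectories=traj)
        write_csv("residual_trajectories.csv", tidy)
        manifest["results"]["residual_models"] = meta

    elif stage == "cluster":
        traj = state["trajectories"]
        if config.run_gap:
            gap = gap_statistic(
                traj, k_max=config.k_max, B=config.gap_b,
                seed=seed, n_restarts=config.gap_restarts,
            )
            manifest["results"]["gap"] = {
                "gap": gap.gap.tolist(),
                "se": gap.se.tolist(),
                "one_cluster": gap.one_cluster,
            }
        solutions = {
            k: kmeans_longitudinal(traj, k, n_restarts=config.n_restarts, seed=seed)
            for k in range(config.k_min, config.k_max + 1)
        }
        k_sel, votes = select_k_cvi(solutions)
        best = solutions[k_sel]
        state.update(solutions=solutions, best_solution=best)
        manifest["results"]["k_selected"] = int(k_sel)
        manifest["results"]["cvi_votes"] = {n: int(v) for n, v in votes.items()}
        manifest["results"]["cluster_sizes"] = best.cluster_sizes().tolist()
        write_csv(
            "cluster_assignments.csv",
            pd.DataFrame({"mouse_id": state["mouse_ids"], "cluster": best.labels}),
        )
        centers = []
        for c in range(best.k):
            for t in range(best.centers.shape[1]):
                row = {"cluster": c, "trial": t + 1}
                row.update(
                    {dim: best.centers[c, t, i] for i, dim in enumerate(DIMENSIONS)}
                )
                centers.append(row)
        write_csv("cluster_centers.csv", pd.DataFrame(centers))
        write_csv(
            "cvi_table.csv",
            pd.DataFrame(
                [{"k": k, **sol.cvi, "within_ss": sol.inertia}
                 for k, sol in sorted(solutions.items())]
            ),
        )

    elif stage == "stability":
        report = bootstrap_stability(
            state["trajectories"],
            state["best_solution"],
            B=config.stability_b,
            seed=seed,
            n_restarts=config.stability_restarts,
            mouse_ids=state["mouse_ids"],
        )
        write_csv("stability_per_mouse.csv", report.per_mouse)
        write_csv("stability_per_cluster.csv", report.per_cluster)
        manifest["results"]["jaccard_per_cluster"] = {
            str(r["cluster"]): float(r["jaccard"])
            for _, r in report.per_cluster.iterrows()
        }

    elif stage == "design":
        truth = state["truth"].copy()
        labels = pd.Series(
            state["best_solution"].labels, index=state["mouse_ids"]
        ).map(lambda c: chr(ord("A") + int(c)))
        truth["response_type"] = truth["mouse_id"].map(labels)
        design = build_design_from_cohort(truth, seed=seed, n_blocks=config.n_blocks)
        state["design"] = design
        write_csv("design.csv", design)
        manifest["results"]["n_pairs"] = int(len(design))

    elif stage == "phase2":
        longd = design_long(state["design"])
        responses = simulate_phase2_responses(longd, config.synthetic, seed=seed)
        phase2 = longd.merge(responses, on="mouse_id")
        state["phase2"] = phase2
        write_csv("phase2_scores.csv", phase2)

    elif stage == "analyze":
        phase2 = state["phase2"]
        anovas = {}
        for dim in DIMENSIONS:
            kind = PHASE2_TRANSFORMS[dim]
            combined = fit_factorial_model(
                phase2, f"{dim}_z",
                factors=("treatment", "strain", "pool", "experimenter"),
                transformation=kind,
            )
            per_pool = {
                pool: fit_factorial_model(
                    phase2[phase2["pool"] == pool], f"{dim}_z",
                    factors=("treatment", "strain", "experimenter"),
                    transformation=kind,
                )
                for pool in ("balanced", "unbalanced")
            }
            anovas[dim] = {"combined": combined, **per_pool}
            write_csv(f"anova_{dim}_combined.csv", combined.anova)
            for pool in ("balanced", "unbalanced"):
                write_csv(f"anova_{dim}_{pool}.csv", per_pool[pool].anova)
        state["anovas"] = anovas

    elif stage == "compare":
        rows = []
        for dim in DIMENSIONS:
            cmp_df = compare_pools(
                state["anovas"][dim]["balanced"].anova,
                state["anovas"][dim]["unbalanced"].anova,
                alpha=config.alpha,
            )
            cmp_df.insert(0, "dimension", dim)
            rows.append(cmp_df)
        divergence = pd.concat(rows, ignore_index=True)
        write_csv("pool_divergence.csv", divergence)
        manifest["results"]["divergent_terms"] = int(
            (divergence["classification"].isin(["augmented", "unmasked"])).sum()
        )
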