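"""Phase-2 experimental design: weight-matched pairs in a complete
randomized block layout.

Half of the treatment-control pairs (the *balanced* pool) are matched on
body weight and on the individual response type recovered in phase 1; the
other half (the *unbalanced* pool, mimicking a conventional experiment) are
matched on body weight only.  Pairs are formed within strain and within
experimenter by adjacent pairing on the weight-sorted list, a deterministic
near-optimal rule for total within-pair weight difference.  The layout is a
complete randomized block design: one pair per (block x experimenter x
strain x pool) cell, 2 pools x 3 strains x 2 experimenters x 4 blocks = 48
pairs = 96 mice, with treatment assigned by fair coin within each pair and
balanced/unbalanced pairs alternating in the test order within a block.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .constants import EXPERIMENTERS, STRAINS

__all__ = [
    "DesignError",
    "match_pairs",
    "build_block_design",
    "build_design_from_cohort",
    "design_long",
    "validate_design",
]

TREATED_LABEL = "dexmedetomidine"
CONTROL_LABEL = "saline"


class DesignError(ValueError):
    """Raised when a feasible design cannot be constructed."""


def _adjacent_pairs(group: pd.DataFrame) -> list[tuple]:
    """Disjoint adjacent pairs over the weight-sorted rows of ``group``."""
    g = group.sort_values(["body_weight_g", "mouse_id"]).reset_index(drop=True)
    return [
        (g.iloc[2 * i], g.iloc[2 * i + 1]) for i in range(len(g) // 2)
    ]


def match_pairs(
    mice: pd.DataFrame,
    pool: str,
    strain: str,
    n_pairs: int,
    seed: int | None = None,
    experimenter: str | None = None,
) -> pd.DataFrame:
    """Form ``n_pairs`` weight-matched pairs from eligible mice.

    ``mice`` needs columns mouse_id, strain, body_weight_g, latent_type (or
    response_type) and experimenter.  ``pool`` is "balanced" (pairs share
    response type) or "unbalanced" (type ignored).  When more adjacent
    pairs are available than needed, the selection among them is seeded-
    random.  Raises :class:`DesignError` stating the shortfall when too few
    eligible mice exist.
    """
    if pool not in ("balanced", "unbalanced"):
        raise ValueError(f"unknown pool {pool!r}")
    rng = np.random.default_rng(seed)
    df = mice.copy()
    if "response_type" not in df.columns:
        df = df.rename(columns={"latent_type": "response_type"})
    df = df[df["strain"] == strain]
    if experimenter is not None:
        df = df[df["experimenter"] == experimenter]
    where = f"strain {strain!r}" + (
        f", experimenter {experimenter!r}" if experimenter else ""
    )
    if len(df) < 2 * n_pairs:
        raise DesignError(
            f"{pool} pool, {where}: need {2 * n_pairs} eligible mice, "
            f"have {len(df)} (short {2 * n_pairs - len(df)})"
        )

    candidates: list[tuple] = []
    if pool == "balanced":
        for _rtype, grp in df.groupby("response_type"):
            candidates.extend(_adjacent_pairs(grp))
    else:
        candidates.extend(_adjacent_pairs(df))
    if len(candidates) < n_pairs:
        raise DesignError(
            f"{pool} pool, {where}: only {len(candidates)} weight-adjacent "
            f"pairs available, need {n_pairs}"
        )
    chosen_idx = rng.choice(len(candidates), size=n_pairs, replace=False)
    rows = []
    for idx in sorted(chosen_idx):
        a, b = candidates[idx]
        rows.append(
            {
                "pool": pool,
                "strain": strain,
                "experimenter": experimenter if experimenter is not None
                else a["experimenter"],
                "mouse_id_1": a["mouse_id"],
                "mouse_id_2": b["mouse_id"],
                "weight_1": float(a["body_weight_g"]),
                "weight_2": float(b["body_weight_g"]),
                "type_1": a["response_type"],
                "type_2": b["response_type"],
                "weight_diff": abs(float(a["body_weight_g"]) - float(b["body_weight_g"])),
            }
        )
    return pd.DataFrame(rows)


def build_block_design(
    pairs: pd.DataFrame, seed: int | None = None, n_blocks: int = 4
) -> pd.DataFrame:
    """Allocate matched pairs to the complete randomized block layout.

    Requires exactly ``n_blocks`` pairs per (strain, experimenter, pool)
    cell group, so that every (block x experimenter x strain x pool) cell
    holds exactly one pair.  Randomizes (seeded) the block assignment
    within each group, the treated mouse within each pair, and the strain
    order within a block; balanced and unbalanced pairs alternate in the
    within-block test order.
    """
    rng = np.random.default_rng(seed)
    strains = sorted(pairs["strain"].unique())
    experimenters = sorted(pairs["experimenter"].unique())
    pools = sorted(pairs["pool"].unique())
    for strain, exp, pool in itertools.product(strains, experimenters, pools):
        grp = pairs[
            (pairs["strain"] == strain)
            & (pairs["experimenter"] == exp)
            & (pairs["pool"] == pool)
        ]
        if len(grp) != n_blocks:
            raise DesignError(
                f"cell-count infeasibility: (strain {strain!r}, experimenter "
                f"{exp!r}, pool {pool!r}) has {len(grp)} pairs, need {n_blocks}"
            )

    rows = []
    for strain, exp, pool in itertools.product(strains, experimenters, pools):
        grp = pairs[
            (pairs["strain"] == strain)
            & (pairs["experimenter"] == exp)
            & (pairs["pool"] == pool)
        ].reset_index(drop=True)
        block_order = rng.permutation(n_blocks) + 1
        for i, rec in grp.iterrows():
            d = rec.to_dict()
            d["block"] = int(block_order[i])
            rows.append(d)
    design = pd.DataFrame(rows)

    # fair coin inside each pair
    flip = rng.random(len(design)) < 0.5
    design["mouse_id_treated"] = np.where(
        flip, design["mouse_id_1"], design["mouse_id_2"]
    )
    design["mouse_id_control"] = np.where(
        flip, design["mouse_id_2"], design["mouse_id_1"]
    )
    design["weight_treated"] = np.where(flip, design["weight_1"], design["weight_2"])
    design["weight_control"] = np.where(flip, design["weight_2"], design["weight_1"])
    design["type_treated"] = np.where(flip, design["type_1"], design["type_2"])
    design["type_control"] = np.where(flip, design["type_2"], design["type_1"])

    # within-block test order: alternate balanced/unbalanced, strain order random
    order_rows = []
    for block in sorted(design["block"].unique()):
        for exp in experimenters:
            cell = design[(design["block"] == block) & (design["experimenter"] == exp)]
            strain_order = list(rng.permutation(strains))
            seq = []
            for s in strain_order:
                for pool in ("balanced", "unbalanced"):
                    sel = cell[(cell["strain"] == s) & (cell["pool"] == pool)]
                    seq.extend(sel.index.tolist())
            for pos, idx in enumerate(seq, start=1):
                order_rows.append((idx, pos))
    order = pd.Series(dict(order_rows))
    design["order_in_block"] = design.index.map(order)

    design = design.sort_values(
        ["block", "experimenter", "order_in_block"]
    ).reset_index(drop=True)
    design.insert(0, "pair_id", [f"P{i + 1:03d}" for i in range(len(design))])
    design = design.drop(
        columns=["mouse_id_1", "mouse_id_2", "weight_1", "weight_2", "type_1", "type_2"]
    )
    validate_design(design, n_blocks=n_blocks)
    return design


def build_design_from_cohort(
    truth: pd.DataFrame,
    seed: int | None = None,
    n_blocks: int = 4,
    pairs_per_cell: int = 1,
) -> pd.DataFrame:
    """Match pairs from a characterized cohort and lay out the full design.

    Balanced cells are filled first (they are the constrained ones: pairs
    must share a response type), then unbalanced cells from the remaining
    mice.  ``truth`` needs mouse_id, strain, experimenter, body_weight_g
    and a response_type (or latent_type) column.
    """
    rng = np.random.default_rng(seed)
    df = truth.copy()
    if "response_type" not in df.columns:
        df = df.rename(columns={"latent_type": "response_type"})
    n_pairs = n_blocks * pairs_per_cell
    pieces = []
    used: set = set()
    strains = sorted(df["strain"].unique())
    experimenters = sorted(df["experimenter"].unique())
    for pool in ("balanced", "unbalanced"):
        for strain in strains:
            for exp in experimenters:
                avail = df[~df["mouse_id"].isin(used)]
                got = match_pairs(
                    avail,
                    pool,
                    strain,
                    n_pairs,
                    seed=int(rng.integers(2**31)),
                    experimenter=exp,
                )
                used.update(got["mouse_id_1"])
                used.update(got["mouse_id_2"])
                pieces.append(got)
    pairs = pd.concat(pieces, ignore_index=True)
    return build_block_design(pairs, seed=int(rng.integers(2**31)), n_blocks=n_blocks)


def validate_design(design: pd.DataFrame, n_blocks: int = 4) -> None:
    """Check the design invariants; raise :class:`DesignError` on violation."""
    mice = pd.concat([design["mouse_id_treated"], design["mouse_id_control"]])
    if mice.duplicated().any():
        raise DesignError("a mouse appears in more than one pair")
    balanced = design[design["pool"] == "balanced"]
    if not (balanced["type_treated"] == balanced["type_control"]).all():
        raise DesignError("balanced pairs must share a response type")
    counts = design.groupby(["block", "experimenter", "strain", "pool"]).size()
    if counts.nunique() != 1:
        raise DesignError("unequal (block x experimenter x strain x pool) cell counts")
    n_cells = (
        n_blocks
        * design["experimenter"].nunique()
        * design["strain"].nunique()
        * design["pool"].nunique()
    )
    if len(counts) != n_cells or len(design) != n_cells * int(counts.iloc[0]):
        raise DesignError("pair count inconsistent with the factorial layout")


def design_long(design: pd.DataFrame) -> pd.DataFrame:
    """One row per enrolled mouse with its treatment and design factors."""
    rows = []
    for rec in design.itertuples(index=False):
        for role, treatment in (
            ("treated", TREATED_LABEL),
            ("control", CONTROL_LABEL),
        ):
            rows.append(
                {
                    "mouse_id": getattr(rec, f"mouse_id_{role}"),
                    "pair_id": rec.pair_id,
                    "pool": rec.pool,
                    "strain": rec.strain,
                    "experimenter": rec.experimenter,
                    "block": rec.block,
                    "treatment": treatment,
                    "body_weight_g": getattr(rec, f"weight_{role}"),
                    "response_type": getattr(rec, f"type_{role}"),
                }
            )
    return pd.DataFrame(rows)
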