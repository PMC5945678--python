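"""Fold-change differential expression calling.

The study's rule is a pure fold-change gate: a gene is differentially
expressed when its expression changes two-fold or more between treated
and control libraries (boundary inclusive). Group summaries are
arithmetic means of linear-scale FPKM with a pseudocount guarding
zero denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

DIRECTIONS = ("up", "down", "unchanged")


def fold_change(
    expr: ExpressionMatrix,
    treated_samples,
    control_samples,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean treated + c) / (mean control + c)) on FPKM."""
    if expr.log_transformed:
        raise ValueError("fold_change expects a linear-scale FPKM matrix")
    treated = list(treated_samples)
    control = list(control_samples)
    if not treated or not control:
        raise ValueError("treated and control groups must be non-empty")
    overlap = set(treated) & set(control)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    missing = (set(treated) | set(control)) - set(expr.sample_ids)
    if missing:
        raise KeyError(f"samples absent from matrix: {sorted(missing)[:5]}")
    mt = expr.data[treated].mean(axis=1)
    mc = expr.data[control].mean(axis=1)
    # difference of logs, so swapping the groups negates the result exactly
    fc = np.log2(mt + pseudocount) - np.log2(mc + pseudocount)
    return fc.rename("log2_fc")


def call_degs(
    log2_fc: pd.Series,
    fc_threshold: float = 2.0,
    condition_label: str = "",
) -> pd.DataFrame:
    """Classify genes as up / down / unchanged at a fold-change gate.

    ``up`` iff log2_fc >= log2(threshold), ``down`` iff
    log2_fc <= -log2(threshold) — the two-fold boundary itself counts as
    differentially expressed.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    # tiny tolerance so an exact 2-fold ratio lands inside the inclusive
    # boundary despite log-space rounding (log2(3)-log2(1.5) < 1 by 1 ulp)
    cut = np.log2(fc_threshold) - 1e-9
    direction = pd.Series("unchanged", index=log2_fc.index, dtype=object)
    direction[log2_fc >= cut] = "up"
    direction[log2_fc <= -cut] = "down"
    return pd.DataFrame(
        {
            "gene_id": log2_fc.index,
            "condition_label": condition_label,
            "log2_fc": log2_fc.values,
            "direction": direction.values,
        }
    )


def deg_counts(degs: pd.DataFrame) -> dict[str, int]:
    counts = degs["direction"].value_counts()
    return {d: int(counts.get(d, 0)) for d in DIRECTIONS}
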