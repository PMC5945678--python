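"""Module-trait association, gene significance, and hub ranking.

The external trait is a numeric encoding of the nitrate treatment
(default: z-scored log(1 + mM KNO3)). A module is significant when its
eigengene correlates with the trait at |r| >= r_min and p <= p_max
(study gates: 0.4 and 0.05; significant modules may have either sign,
as the reported modules include down-regulated ones). Gene significance
GS is |cor(gene, trait)| and scaled intramodular connectivity K is the
within-module connectivity divided by the module maximum, so the top
hub of every module sits at exactly K = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GREY, AnnotationMap, ExpressionMatrix, warn
from .modules import EigengeneSet, ModulePartition
from .network import _cor_test

TRAIT_SCHEMES = ("dose_log", "dose_linear", "binary")


@dataclass
class ModuleTraitResult:
    module: str
    r: float
    p: float
    significant: bool
    direction: int


def encode_trait(design: pd.DataFrame, scheme: str = "dose_log") -> pd.Series:
    """Numeric per-sample trait from the design table's nitrate dose."""
    if scheme not in TRAIT_SCHEMES:
        raise ValueError(f"unknown trait scheme {scheme!r}; choose from {TRAIT_SCHEMES}")
    dose = design["kno3_mM"].astype(float)
    if scheme == "binary":
        return (dose > 0).astype(float).rename("trait")
    raw = np.log1p(dose) if scheme == "dose_log" else dose
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance trait: all samples share one dose")
    return ((raw - raw.mean()) / sd).rename("trait")


def module_trait_correlation(
    eigengenes: EigengeneSet,
    trait: pd.Series,
    r_min: float = 0.4,
    p_max: float = 0.05,
) -> list[ModuleTraitResult]:
    """Eigengene-trait Pearson correlations with the significance gate."""
    samples = eigengenes.sample_ids
    missing = set(samples) - set(trait.index)
    if missing:
        raise KeyError(f"trait missing samples: {sorted(missing)[:5]}")
    t = trait.loc[samples].to_numpy(dtype=float)
    if len(samples) <= 2:
        raise ValueError("module-trait correlation needs > 2 samples")
    results = []
    for module in eigengenes.module_names:
        e = eigengenes.eigengenes.loc[module].to_numpy(dtype=float)
        r, p = _cor_test(e, t)
        results.append(
            ModuleTraitResult(
                module=module,
                r=r,
                p=p,
                significant=bool(abs(r) >= r_min and p <= p_max),
                direction=int(np.sign(r)) if r != 0 else 0,
            )
        )
    return results


def gene_significance(expr: ExpressionMatrix, trait: pd.Series) -> pd.Series:
    """GS_g = |cor(x_g, trait)|; zero-variance genes get GS = 0."""
    missing = set(expr.sample_ids) - set(trait.index)
    if missing:
        raise KeyError(f"trait missing samples: {sorted(missing)[:5]}")
    t = trait.loc[expr.sample_ids].to_numpy(dtype=float)
    x = expr.values
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    st = np.sqrt((tc**2).sum())
    denom = sx * st
    zero = denom == 0
    if zero.any():
        warn(f"{int(zero.sum())} zero-variance genes: GS set to 0")
    denom[zero] = 1.0
    gs = np.abs(xc @ tc) / denom
    gs[zero] = 0.0
    return pd.Series(np.clip(gs, 0.0, 1.0), index=expr.gene_ids, name="GS")


def scaled_connectivity(
    adjacency: np.ndarray, gene_ids, partition: ModulePartition
) -> pd.Series:
    """Scaled intramodular connectivity K per assigned gene.

    kIM_g sums adjacency from g to the other members of its module; K is
    kIM divided by the module maximum. Grey genes are absent from the
    result; a singleton module's gene has K = 1 by convention.
    """
    gene_ids = list(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = set(partition.gene_ids) - set(pos)
    if missing:
        raise KeyError(f"partition genes absent from adjacency: {sorted(missing)[:5]}")
    adjacency = np.asarray(adjacency, dtype=float)
    out = {}
    for module in partition.module_names:
        members = partition.members(module)
        idx = [pos[g] for g in members]
        sub = adjacency[np.ix_(idx, idx)]
        kim = sub.sum(axis=1)  # zero diagonal excludes self
        top = kim.max()
        k = kim / top if top > 0 else np.ones_like(kim)
        if len(members) == 1:
            k = np.ones(1)
        for g, val in zip(members, k):
            out[g] = float(val)
    return pd.Series(out, name="K")


def top_hub_tfs(
    k: pd.Series,
    gs: pd.Series,
    tf_map: AnnotationMap,
    partition: ModulePartition,
    n_top: int = 5,
    modules=None,
) -> pd.DataFrame:
    """Top-n TF-annotated hubs per module, ranked by K then GS.

    ``modules`` restricts the table (e.g. to significant modules); by
    default every non-grey module is reported. Modules without any
    TF-annotated gene simply contribute no rows. The TF family shown is
    the lexicographically first of the gene's annotated families.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    chosen = list(modules) if modules is not None else partition.module_names
    rows = []
    for module in chosen:
        if module == GREY:
            continue
        tf_genes = [g for g in partition.members(module) if tf_map.terms_of(g)]
        ranked = sorted(
            tf_genes,
            key=lambda g: (-k.get(g, 0.0), -gs.get(g, 0.0), g),
        )
        for rank, g in enumerate(ranked[:n_top], start=1):
            rows.append(
                {
                    "module": module,
                    "rank": rank,
                    "gene_id": g,
                    "tf_family": sorted(tf_map.terms_of(g))[0],
                    "K": float(k.get(g, 0.0)),
                    "GS": float(gs.get(g, 0.0)),
                }
            )
    return pd.DataFrame(rows, columns=["module", "rank", "gene_id", "tf_family", "K", "GS"])
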