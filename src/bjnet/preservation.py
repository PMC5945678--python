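"""Cross-network module matching and permutation preservation Z-scores.

Module definitions from a reference network (the high-NUE cultivar) are
matched to the test network by an overlap contingency table with
hypergeometric cell p-values, and evaluated in the test network by two
permutation Z statistics:

* Zdensity     — mean off-diagonal adjacency among the module's genes in
                 the test network, standardized against random gene sets
                 of the same size;
* Zconnectivity — Pearson correlation of the module genes' intramodular
                 connectivity between reference and test, standardized
                 the same way.

Zsummary is their mean. Conventional interpretation: > 10 strong
preservation, 2-10 weak to moderate, < 2 none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import warn
from .modules import ModulePartition

ZSUMMARY_STRONG = 10.0
ZSUMMARY_WEAK = 2.0


@dataclass
class OverlapTable:
    counts: pd.DataFrame  # reference modules x test modules
    p_values: pd.DataFrame
    best_match: dict[str, str]


@dataclass
class PreservationResult:
    module: str
    z_density: float
    z_connectivity: float
    z_summary: float
    observed_density: float
    observed_connectivity_cor: float
    n_permutations: int


def module_overlap(
    partition_ref: ModulePartition,
    partition_test: ModulePartition,
    include_grey: bool = False,
) -> OverlapTable:
    """Contingency table of shared genes with hypergeometric cell p-values.

    Both partitions must cover the same (common) gene set. The cell
    p-value is the upper tail P(X >= n_AB) for drawing |A| genes from a
    population of N with |B| successes. Each reference module's best
    match minimizes p, ties broken by larger overlap.
    """
    genes_ref = set(partition_ref.gene_ids)
    genes_test = set(partition_test.gene_ids)
    if genes_ref != genes_test:
        raise ValueError("partitions are defined on different gene sets")
    if not genes_ref:
        raise ValueError("empty common gene set")
    n_pop = len(genes_ref)
    mods_ref = partition_ref.module_names
    mods_test = partition_test.module_names
    if include_grey:
        mods_ref = mods_ref + ["grey"]
        mods_test = mods_test + ["grey"]
    counts = pd.DataFrame(0, index=mods_ref, columns=mods_test, dtype=int)
    pvals = pd.DataFrame(1.0, index=mods_ref, columns=mods_test, dtype=float)
    members_test = {
        b: set(partition_test.labels.index[partition_test.labels == b])
        for b in mods_test
    }
    best: dict[str, str] = {}
    for a in mods_ref:
        set_a = set(partition_ref.labels.index[partition_ref.labels == a])
        for b in mods_test:
            k = len(set_a & members_test[b])
            counts.loc[a, b] = k
            pvals.loc[a, b] = float(
                hypergeom.sf(k - 1, n_pop, len(members_test[b]), len(set_a))
            )
        if mods_test:
            ranked = sorted(
                mods_test, key=lambda b: (pvals.loc[a, b], -counts.loc[a, b], b)
            )
            best[a] = ranked[0]
    return OverlapTable(counts=counts, p_values=pvals, best_match=best)


def zsummary(
    adj_ref: np.ndarray,
    adj_test: np.ndarray,
    gene_ids,
    module_genes,
    n_permutations: int = 200,
    seed: int = 0,
) -> PreservationResult:
    """Permutation preservation Z-scores for one reference module.

    Null gene sets are sampled without replacement from the common genes
    excluding the module itself; both observed statistics are
    standardized by the null mean and sd. A zero null sd yields an
    infinite Z with a warning.
    """
    gene_ids = list(gene_ids)
    module_genes = list(module_genes)
    if len(module_genes) < 3:
        raise ValueError("module must contain at least 3 genes")
    if n_permutations < 50:
        raise ValueError("use at least 50 permutations")
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = set(module_genes) - set(pos)
    if missing:
        raise KeyError(f"module genes absent from network: {sorted(missing)[:5]}")
    adj_ref = np.asarray(adj_ref, dtype=float)
    adj_test = np.asarray(adj_test, dtype=float)
    idx = np.array([pos[g] for g in module_genes])

    obs_density = _density(adj_test, idx)
    obs_cor = _kim_pattern_cor(adj_ref, adj_test, idx)

    rng = np.random.default_rng(seed)
    # pool ordered by gene id so results are invariant to input gene order
    in_module = set(module_genes)
    pool = np.array([pos[g] for g in sorted(pos) if g not in in_module])
    if len(pool) < len(idx):
        raise ValueError("too few genes outside the module for null draws")
    null_density = np.empty(n_permutations)
    null_cor = np.empty(n_permutations)
    for b in range(n_permutations):
        draw = rng.choice(pool, size=len(idx), replace=False)
        null_density[b] = _density(adj_test, draw)
        null_cor[b] = _kim_pattern_cor(adj_ref, adj_test, draw)

    z_density = _standardize(obs_density, null_density, "density")
    z_cor = _standardize(obs_cor, null_cor, "connectivity")
    return PreservationResult(
        module="",
        z_density=z_density,
        z_connectivity=z_cor,
        z_summary=(z_density + z_cor) / 2.0,
        observed_density=obs_density,
        observed_connectivity_cor=obs_cor,
        n_permutations=n_permutations,
    )


def _density(adj: np.ndarray, idx: np.ndarray) -> float:
    sub = adj[np.ix_(idx, idx)]
    m = len(idx)
    return float(sub.sum() / (m * (m - 1)))


def _kim_pattern_cor(adj_ref: np.ndarray, adj_test: np.ndarray, idx: np.ndarray) -> float:
    k_ref = adj_ref[np.ix_(idx, idx)].sum(axis=1)
    k_test = adj_test[np.ix_(idx, idx)].sum(axis=1)
    if k_ref.std() == 0 or k_test.std() == 0:
        return 0.0
    return float(np.corrcoef(k_ref, k_test)[0, 1])


def _standardize(obs: float, null: np.ndarray, what: str) -> float:
    sd = null.std(ddof=1)
    if sd == 0:
        warn(f"zero null sd for {what}; Z reported as +/-inf")
        diff = obs - null.mean()
        return float(np.inf) if diff >= 0 else float(-np.inf)
    return float((obs - null.mean()) / sd)
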