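"""Module detection: average-linkage clustering on DistTOM and a tree cut.

The cut is a static-height variant of dynamic tree cut: the dendrogram
is cut at a fraction of its maximum merge height chosen by ``deep_split``
(0..4 -> 0.95, 0.90, 0.85, 0.80, 0.75 of the max), clusters below the
minimum size become "grey" (unassigned), and an optional PAM-like stage
re-attaches grey genes to the nearest module by average DistTOM when
that average falls below the cut height. Surviving modules are relabeled
by decreasing size with the conventional WGCNA color palette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import GREY, ExpressionMatrix, warn

#: Conventional module color palette, assigned by decreasing module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta",
)

#: deep_split -> cut height as a fraction of the maximum merge height.
DEEP_SPLIT_FRACTION = {0: 0.95, 1: 0.90, 2: 0.85, 3: 0.80, 4: 0.75}


@dataclass
class Dendrogram:
    """UPGMA merge tree over genes (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    gene_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.gene_ids[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass
class ModulePartition:
    """Gene -> module label; "grey" marks unassigned genes."""

    labels: pd.Series  # index gene_id, values module label

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.labels.index, "module": self.labels.values}
        )


@dataclass
class EigengeneSet:
    """Module -> unit-norm eigengene over samples, plus explained variance."""

    eigengenes: pd.DataFrame  # modules x samples
    explained_variance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def module_names(self) -> list[str]:
        return list(self.eigengenes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.eigengenes.columns)


def average_linkage(dist: np.ndarray, gene_ids=None) -> Dendrogram:
    """UPGMA merge tree of a symmetric dissimilarity with zero diagonal."""
    dist = np.asarray(dist, dtype=float)
    if np.isnan(dist).any():
        raise ValueError("NaN in dissimilarity matrix")
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dissimilarity must be square")
    if np.abs(dist - dist.T).max(initial=0.0) > 1e-8:
        raise ValueError("dissimilarity is not symmetric")
    if np.abs(np.diag(dist)).max(initial=0.0) > 1e-8:
        raise ValueError("dissimilarity diagonal must be zero")
    n = dist.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n:
        raise ValueError("gene_ids length does not match matrix")
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=z, gene_ids=gene_ids)


def cut_height(dendrogram: Dendrogram, deep_split: int) -> float:
    if deep_split not in DEEP_SPLIT_FRACTION:
        raise ValueError("deep_split must be an integer in 0..4")
    return DEEP_SPLIT_FRACTION[deep_split] * float(dendrogram.heights.max())


def dynamic_tree_cut(
    dendrogram: Dendrogram,
    dist_tom: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    pam_stage: bool = True,
) -> ModulePartition:
    """Cut the merge tree into modules; undersized clusters become grey.

    With ``pam_stage``, each grey gene is re-assigned to the module whose
    average DistTOM to it is smallest, provided that average lies below
    the cut height.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    genes = dendrogram.gene_ids
    n = len(genes)
    if min_module_size > n:
        warn("min_module_size exceeds gene count; all genes are grey")
        return ModulePartition(pd.Series(GREY, index=genes))
    h = cut_height(dendrogram, deep_split)
    raw = hierarchy.fcluster(dendrogram.linkage, t=h, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_module_size]
    labels = labels.where(labels.isin(keep), other=-1)

    if pam_stage and (labels == -1).any() and len(keep):
        dist_tom = np.asarray(dist_tom, dtype=float)
        pos = {g: i for i, g in enumerate(genes)}
        module_rows = {
            m: [pos[g] for g in labels.index[labels == m]] for m in keep
        }
        grey_idx = [pos[g] for g in labels.index[labels == -1]]
        mods = list(module_rows)
        avg = np.column_stack(
            [dist_tom[np.ix_(grey_idx, module_rows[m])].mean(axis=1) for m in mods]
        )
        best = avg.argmin(axis=1)
        best_d = avg[np.arange(len(grey_idx)), best]
        for gi, b, d in zip(grey_idx, best, best_d):
            if d < h:
                labels.iloc[gi] = mods[b]

    final_sizes = labels[labels != -1].value_counts()
    order = sorted(
        final_sizes.index, key=lambda m: (-final_sizes[m], int(m))
    )
    names = {}
    for rank, m in enumerate(order):
        names[m] = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module_{rank + 1}"
        )
    out = labels.map(lambda m: GREY if m == -1 else names[m])
    return ModulePartition(out.astype(str))


def module_eigengenes(expr: ExpressionMatrix, partition: ModulePartition) -> EigengeneSet:
    """First principal component per module over samples.

    Each gene is z-scored across samples; the eigengene is the unit-norm
    first right singular vector of the module's standardized submatrix,
    sign-oriented so it correlates non-negatively with the module's mean
    expression profile.
    """
    missing = set(partition.gene_ids) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"partition genes absent from expression: {sorted(missing)[:5]}")
    samples = expr.sample_ids
    rows, ev = {}, {}
    for module in partition.module_names:
        sub = expr.data.loc[partition.members(module)].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        rows[module] = eig
        total = float((s**2).sum())
        ev[module] = float(s[0] ** 2 / total) if total > 0 else 0.0
    frame = pd.DataFrame(rows, index=samples).T
    order = sorted(rows, key=lambda m: -partition.sizes[m])
    return EigengeneSet(
        eigengenes=frame.loc[order],
        explained_variance=pd.Series(ev).loc[order] if rows else pd.Series(dtype=float),
    )
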