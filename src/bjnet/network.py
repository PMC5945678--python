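"""Weighted co-expression network construction.

One network per cultivar: Pearson correlation of (log-scale) expression
profiles, unsigned soft-thresholded adjacency a_ij = |cor_ij|^beta, the
topological overlap similarity

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_u a_iu * a_uj,   k_i = sum_u a_iu,

and DistTOM = 1 - TOM as the clustering dissimilarity. The diagonal of
the adjacency is defined as 0 for all sums (so l_ij automatically
excludes u in {i, j}), and TOM_ii = 1.

The soft-threshold power is chosen by a scale-free topology fit: bin the
connectivity distribution, regress log10(frequency) on log10(k), and
take the smallest candidate power whose signed R^2 = -sign(slope) * R^2
reaches the configured threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, warn

_SYM_TOL = 1e-8


@dataclass
class TomNetwork:
    """Soft-thresholded adjacency plus TOM for one cultivar dataset."""

    gene_ids: list[str]
    power: float
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def dist_tom(self) -> np.ndarray:
        d = 1.0 - self.tom
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class SoftThresholdScan:
    """Scale-free fit diagnostics per candidate power."""

    table: pd.DataFrame  # power, scale_free_r2, mean_k, median_k, max_k
    chosen_power: int


def correlation_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Gene-gene Pearson correlation; zero-variance genes correlate 0."""
    x = expr.values
    if np.isnan(x).any():
        raise ValueError("expression contains NA; run filtering first")
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    if (sd == 0).any():
        warn(f"{int((sd == 0).sum())} zero-variance genes correlate 0 by convention")
    return np.clip(c, -1.0, 1.0)


def adjacency(cor_matrix: np.ndarray, power: float) -> np.ndarray:
    """Unsigned adjacency |cor|^power with a zero diagonal."""
    if power <= 0:
        raise ValueError("soft-threshold power must be > 0")
    cor_matrix = np.asarray(cor_matrix, dtype=float)
    if np.abs(cor_matrix).max(initial=0.0) > 1 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    a = np.abs(cor_matrix) ** power
    np.fill_diagonal(a, 0.0)
    return a


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_u a_iu (zero diagonal)."""
    adj = _check_adjacency(adj)
    return adj.sum(axis=1)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    Because the diagonal is zero, the matrix product A @ A equals
    l_ij = sum_{u != i,j} a_iu a_uj. The denominator uses whole-network
    connectivity including the direct i-j edge, per the printed formula.
    """
    adj = _check_adjacency(adj)
    k = adj.sum(axis=1)
    l = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + adj) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(adj - adj.T).max(initial=0.0) > _SYM_TOL:
        raise ValueError("adjacency is not symmetric")
    if adj.min(initial=0.0) < -_SYM_TOL or adj.max(initial=0.0) > 1 + _SYM_TOL:
        raise ValueError("adjacency entries must lie in [0, 1]")
    adj = np.clip((adj + adj.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(adj, 0.0)
    return adj


def filter_genes_and_samples(
    expr: ExpressionMatrix,
    max_missing_frac: float = 0.1,
    min_variance: float = 1e-12,
    sample_outlier_z: float = 2.5,
):
    """Drop low-quality genes and outlying samples.

    Genes with a missing fraction above ``max_missing_frac`` or variance
    at or below ``min_variance`` are removed. Samples whose standardized
    connectivity in the sample-sample correlation network falls below
    -``sample_outlier_z`` are removed. Residual NAs in the surviving
    matrix are mean-imputed per gene, so the result is NA-free.

    Returns (filtered matrix, removed gene ids, removed sample ids).
    """
    df = expr.data
    miss = df.isna().mean(axis=1)
    var = df.var(axis=1, ddof=0)
    gene_bad = (miss > max_missing_frac) | (var <= min_variance) | var.isna()
    removed_genes = df.index[gene_bad].tolist()
    df = df.loc[~gene_bad]
    if df.shape[0] == 0:
        raise ValueError("all genes removed by filtering")

    removed_samples: list[str] = []
    if df.shape[1] >= 3:
        c = df.corr(method="pearson").to_numpy()
        np.fill_diagonal(c, 0.0)
        k = ((1.0 + c) / 2.0).sum(axis=1)  # sample network adjacency
        sd = k.std()
        if sd > 0:
            z = (k - k.mean()) / sd
            out = z < -sample_outlier_z
            removed_samples = [s for s, o in zip(df.columns, out) if o]
            df = df.loc[:, ~out]
    if df.shape[1] == 0:
        raise ValueError("all samples removed by filtering")

    if df.isna().any().any():
        df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
    return (
        ExpressionMatrix(df, expr.log_transformed),
        removed_genes,
        removed_samples,
    )


def intersect_common_genes(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix):
    """Restrict both matrices to their sorted common gene set."""
    common = sorted(set(expr_a.gene_ids) & set(expr_b.gene_ids))
    if not common:
        raise ValueError("no common genes between datasets")
    return expr_a.subset_genes(common), expr_b.subset_genes(common)


def _cor_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from t = r*sqrt((n-2)/(1-r^2))."""
    n = len(x)
    if n < 3:
        raise ValueError("correlation test needs at least 3 observations")
    r = float(np.corrcoef(x, y)[0, 1])
    if np.isnan(r):
        return 0.0, 1.0
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def comparability(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    power_a: float = 6.0,
    power_b: float = 6.0,
):
    """Cross-dataset agreement of per-gene mean expression and connectivity.

    Both matrices must share gene order. Returns two (r, p) pairs: the
    Pearson correlation across genes of (i) mean expression and (ii)
    whole-network connectivity at each dataset's chosen power.
    """
    if expr_a.gene_ids != expr_b.gene_ids:
        raise ValueError("gene order differs between datasets")
    if expr_a.n_genes < 3:
        raise ValueError("comparability needs at least 3 genes")
    mean_a = expr_a.values.mean(axis=1)
    mean_b = expr_b.values.mean(axis=1)
    cor_mean = _cor_test(mean_a, mean_b)
    k_a = connectivity(adjacency(correlation_matrix(expr_a), power_a))
    k_b = connectivity(adjacency(correlation_matrix(expr_b), power_b))
    cor_k = _cor_test(k_a, k_b)
    return cor_mean, cor_k


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology R^2 of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10(mean bin
    frequency) on log10(mean bin k) over non-empty bins, and returns
    (signed R^2, slope) with signed R^2 = -sign(slope) * R^2.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: all k identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(freq))
    if len(log_k) < 3:
        raise ValueError("too few non-empty bins for the scale-free fit")
    slope, _, r, _, _ = stats.linregress(log_k, log_f)
    return float(-np.sign(slope) * r * r), float(slope)


def soft_threshold_scan(
    expr: ExpressionMatrix,
    powers=None,
    r2_threshold: float = 0.80,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers for approximate scale-free topology.

    The chosen power is the smallest candidate whose signed R^2 reaches
    ``r2_threshold``; if none does, the candidate maximizing signed R^2
    is taken with a warning.
    """
    if expr.n_genes < 20:
        raise ValueError("soft-threshold scan needs at least 20 genes")
    powers = list(powers) if powers is not None else list(range(1, 21))
    abs_cor = np.abs(correlation_matrix(expr))
    np.fill_diagonal(abs_cor, 0.0)
    rows = []
    for beta in powers:
        k = (abs_cor**beta).sum(axis=1)
        r2, _ = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": beta,
                "scale_free_r2": r2,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    passing = table.loc[table["scale_free_r2"] >= r2_threshold, "power"]
    if len(passing):
        chosen = int(passing.iloc[0])
    else:
        chosen = int(table.loc[table["scale_free_r2"].idxmax(), "power"])
        warn(
            f"no candidate power reached signed R^2 >= {r2_threshold}; "
            f"using best fit power {chosen}"
        )
    return SoftThresholdScan(table=table, chosen_power=chosen)


def default_unsigned_power(n_samples: int) -> int:
    """Standard unsigned soft-threshold power by sample count.

    The usual fallback when the scale-free fit is ambiguous or the data
    are known not to follow a scale-free degree distribution: 9 below 20
    samples, 8 for 20-29, 7 for 30-39, 6 from 40 up.
    """
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


def build_network(expr: ExpressionMatrix, power: float) -> TomNetwork:
    """Adjacency + TOM at a given power for a filtered, NA-free matrix."""
    adj = adjacency(correlation_matrix(expr), power)
    return TomNetwork(
        gene_ids=expr.gene_ids,
        power=float(power),
        adjacency=adj,
        tom=tom_similarity(adj),
    )
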