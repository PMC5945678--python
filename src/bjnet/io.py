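"""Tabular I/O and shared domain types.

Every artifact the pipeline touches is plain TSV (tab-separated, header
row, UTF-8, '.' decimal): the expression matrix (genes x samples, FPKM),
the sample design table, gene->term annotation tables, module assignment
tables, a VisANT-compatible edge list, and a JSON run configuration.
Missing expression values are encoded as ``NA`` and are tolerated only
upstream of filtering; everywhere else they are an error.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Nitrate doses applied in the study design, in mM KNO3.
VALID_DOSES = (0.0, 0.25, 2.0, 4.0)

#: Ordered sampling timepoints after nitrate supply.
TIMEPOINTS = ("20min", "2h", "12h", "24h", "3d", "7d")

GREY = "grey"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with row/column identity.

    ``data`` is a DataFrame indexed by gene id with sample-id columns.
    Values are linear-scale FPKM unless ``log_transformed`` is set, in
    which case they are log2(FPKM + offset).
    """

    data: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not self.log_transformed:
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative FPKM values in linear-scale matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.log_transformed)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.log_transformed)

    def to_log2(self, offset: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(FPKM + offset) view of a linear-scale matrix."""
        if self.log_transformed:
            return self
        if offset <= 0:
            raise ValueError("log2 offset must be > 0")
        return ExpressionMatrix(np.log2(self.data + offset), log_transformed=True)


@dataclass
class AnnotationMap:
    """Gene -> set of term/family identifiers, flat labels.

    ``kind`` is ``"GO"`` or ``"TF"``. Genes without any annotation are
    absent from ``entries`` rather than mapped to empty sets.
    """

    kind: str
    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        if self.kind not in ("GO", "TF"):
            raise ValueError(f"annotation kind must be GO or TF, got {self.kind!r}")
        empties = [g for g, terms in self.entries.items() if not terms]
        if empties:
            raise ValueError(f"genes mapped to empty term sets: {empties[:5]}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def terms_of(self, gene_id: str) -> set[str]:
        return self.entries.get(gene_id, set())

    def genes_with(self, term: str) -> set[str]:
        return {g for g, terms in self.entries.items() if term in terms}


@dataclass
class RunConfig:
    """Pipeline-wide analysis parameters.

    Defaults reproduce the study's stated gates: module-trait |r| >= 0.4
    at p <= 0.05, and a boundary-inclusive 2-fold differential-expression
    rule.
    """

    power_candidates: list[int] = field(default_factory=lambda: list(range(1, 21)))
    scale_free_r2_threshold: float = 0.80
    min_module_size: int = 30
    deep_split: int = 2
    module_trait_r_min: float = 0.4
    module_trait_p_max: float = 0.05
    fc_threshold: float = 2.0
    pseudocount: float = 1.0
    n_permutations: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.scale_free_r2_threshold < 1:
            raise ValueError("scale_free_r2_threshold must lie in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be an integer in 0..4")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_expression_matrix(path, log2_offset: float = 0.0) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV; optionally log2-transform.

    The first column carries gene ids, the header row sample ids. With
    ``log2_offset`` c > 0, values become log2(FPKM + c) and the returned
    matrix is flagged ``log_transformed``. Input row order is preserved.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dup_cols = [s for s in header if s in seen or seen.add(s)]
    if dup_cols:
        raise ValueError(f"duplicate sample ids in {path}: {dup_cols[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value in column {col!r}, row {bad[0]!r}"
                )
            df[col] = coerced
    df = df.astype(float)
    if np.nanmin(df.to_numpy(), initial=0.0) < 0:
        locs = np.argwhere(df.to_numpy() < 0)
        g, s = locs[0]
        raise ValueError(
            f"negative FPKM at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if log2_offset > 0:
        return ExpressionMatrix(np.log2(df + log2_offset), log_transformed=True)
    return ExpressionMatrix(df, log_transformed=False)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_sample_design(path, strict_doses: bool = True) -> pd.DataFrame:
    """Read the sample design TSV (sample_id, cultivar, kno3_mM, timepoint).

    Derives the ``treated`` flag (dose > 0). Doses outside the study grid
    {0, 0.25, 2, 4} mM are rejected unless ``strict_doses`` is False.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cultivar": str, "timepoint": str})
    required = {"sample_id", "cultivar", "kno3_mM", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in design: {dups[:5]}")
    df["kno3_mM"] = df["kno3_mM"].astype(float)
    if (df["kno3_mM"] < 0).any():
        bad = df.loc[df["kno3_mM"] < 0, "sample_id"].iloc[0]
        raise ValueError(f"negative KNO3 dose for sample {bad!r}")
    if strict_doses:
        bad = ~df["kno3_mM"].isin(VALID_DOSES)
        if bad.any():
            raise ValueError(
                f"doses outside {VALID_DOSES} mM: samples "
                f"{df.loc[bad, 'sample_id'].tolist()[:5]}"
            )
    df["treated"] = df["kno3_mM"] > 0
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINTS, ordered=True)
    return df.set_index("sample_id", drop=False)


def write_sample_design(design: pd.DataFrame, path) -> None:
    design[["sample_id", "cultivar", "kno3_mM", "timepoint"]].to_csv(
        path, sep="\t", index=False
    )


def read_annotation_map(path, kind: str) -> AnnotationMap:
    """Read a two-column (gene_id, term_id) TSV into an AnnotationMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation table needs columns gene_id, term_id")
    entries: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        entries.setdefault(gene, set()).add(term)
    return AnnotationMap(kind=kind, entries=entries)


def write_annotation_map(annot: AnnotationMap, path) -> None:
    rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(annot.entries)
        for t in sorted(annot.entries[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def write_module_assignments(assignments: pd.DataFrame, path) -> None:
    """Write a gene_id / module / K / GS table (missing stats allowed)."""
    assignments.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_edge_list(gene_ids, matrix: np.ndarray, threshold: float, path) -> int:
    """Write a VisANT-style plain edge list; return the edge count.

    Emits one ``gene_a gene_b weight`` line per unordered pair whose
    matrix entry exceeds ``threshold``; no self-edges, each pair once.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("edge threshold must lie in [0, 1]")
    matrix = np.asarray(matrix, dtype=float)
    n = len(gene_ids)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match gene_ids")
    iu, ju = np.triu_indices(n, k=1)
    keep = matrix[iu, ju] > threshold
    count = 0
    with open(path, "w") as fh:
        for i, j in zip(iu[keep], ju[keep]):
            fh.write(f"{gene_ids[i]}\t{gene_ids[j]}\t{matrix[i, j]:.6g}\n")
            count += 1
    return count


def check_design_covers(expr: ExpressionMatrix, design: pd.DataFrame) -> None:
    """Raise if any expression sample lacks a design row."""
    missing = set(expr.sample_ids) - set(design["sample_id"])
    if missing:
        raise KeyError(f"samples without design rows: {sorted(missing)[:5]}")


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
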