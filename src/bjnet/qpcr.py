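"""2^-ddCT relative quantification and RNA-seq concordance.

CT tables are long-format (gene_id, sample_id, replicate, ct), with the
internal reference gene (BjUbq9-style) present as ordinary rows.
Replicate CTs are averaged on the cycle scale before differencing
(Livak convention); the amplification efficiency is fixed at 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import _cor_test

CT_COLUMNS = ("gene_id", "sample_id", "replicate", "ct")


def _mean_ct(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if not np.isfinite(records["ct"]).all() or (records["ct"] <= 0).any():
        raise ValueError("CT values must be finite and > 0")
    return records.groupby(["gene_id", "sample_id"], as_index=False)["ct"].mean()


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str,
    treated_samples,
    control_samples,
    condition_label: str = "treated vs control",
) -> pd.DataFrame:
    """Relative expression ratio 2^-ddCT per target gene.

    dCT is the replicate-averaged target CT minus reference CT, averaged
    over the samples of each group; ddCT = dCT_treated - dCT_control and
    ratio = 2^-ddCT, so log2(ratio) = -ddCT exactly.
    """
    treated = list(treated_samples)
    control = list(control_samples)
    if not treated or not control:
        raise ValueError("treated and control groups must be non-empty")
    mean_ct = _mean_ct(records)
    ref = mean_ct[mean_ct["gene_id"] == reference_gene].set_index("sample_id")["ct"]
    for s in treated + control:
        if s not in ref.index:
            raise ValueError(f"missing reference CT for sample {s!r}")
    targets = sorted(set(mean_ct["gene_id"]) - {reference_gene})
    wide = mean_ct.pivot(index="gene_id", columns="sample_id", values="ct")
    rows = []
    for gene in targets:
        cts = wide.loc[gene]
        if cts[treated + control].isna().any():
            raise ValueError(f"missing CT for gene {gene!r} in requested samples")
        d_treated = float((cts[treated] - ref[treated]).mean())
        d_control = float((cts[control] - ref[control]).mean())
        ddct = d_treated - d_control
        rows.append(
            {
                "gene_id": gene,
                "condition_label": condition_label,
                "delta_ct_treated": d_treated,
                "delta_ct_control": d_control,
                "delta_delta_ct": ddct,
                "ratio": float(2.0 ** (-ddct)),
            }
        )
    return pd.DataFrame(rows)


def concordance(relative: pd.DataFrame, rnaseq_log2fc: pd.Series) -> tuple[float, float]:
    """Pearson r (and p) of qPCR log2 ratios against RNA-seq log2 FC."""
    shared = [g for g in relative["gene_id"] if g in rnaseq_log2fc.index]
    if len(shared) < 3:
        raise ValueError("concordance needs at least 3 shared genes")
    qpcr_log2 = (
        np.log2(relative.set_index("gene_id").loc[shared, "ratio"]).to_numpy(dtype=float)
    )
    seq_log2 = rnaseq_log2fc.loc[shared].to_numpy(dtype=float)
    return _cor_test(qpcr_log2, seq_log2)
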