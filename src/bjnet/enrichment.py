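"""Singular enrichment analysis (SEA-style) of a gene set.

Hypergeometric upper-tail test of each annotation term represented in
the study set against the annotated background, with Bonferroni
correction over the terms actually tested. Annotations are flat labels;
no ontology-graph propagation is performed.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .io import AnnotationMap, warn


def enrich(study_genes, background: AnnotationMap, alpha: float = 0.05) -> pd.DataFrame:
    """Test every term present in the study set for over-representation.

    The background universe N is the set of annotated genes; study genes
    without any annotation are dropped (with a warning). For a term
    carried by K background and k of the n annotated study genes,
    p = P(X >= k) under Hypergeom(N, K, n); p_bonferroni = min(1, p * m)
    with m the number of terms tested. Rows are sorted by p ascending
    with a stable term-id tie-break.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    universe = background.genes
    study = set(study_genes)
    dropped = study - universe
    study &= universe
    if dropped:
        warn(f"{len(dropped)} study genes lack annotation and were dropped")
    if not study:
        warn("no annotated study genes; empty enrichment result")
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p", "p_bonferroni", "significant"]
        )
    n_universe = len(universe)
    n_study = len(study)
    study_terms: dict[str, int] = {}
    for g in study:
        for t in background.terms_of(g):
            study_terms[t] = study_terms.get(t, 0) + 1
    bg_counts: dict[str, int] = {}
    for terms in background.entries.values():
        for t in terms:
            bg_counts[t] = bg_counts.get(t, 0) + 1
    m = len(study_terms)
    rows = []
    for term, k in study_terms.items():
        big_k = bg_counts[term]
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_study))
        p = min(max(p, 0.0), 1.0)
        p_bonf = min(1.0, p * m)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n_study,
                "K": big_k,
                "N": n_universe,
                "p": p,
                "p_bonferroni": p_bonf,
                "significant": p_bonf <= alpha,
            }
        )
    out = pd.DataFrame(rows).sort_values(["p", "term"], kind="mergesort")
    return out.reset_index(drop=True)
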