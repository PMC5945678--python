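"""End-to-end orchestration of the two-cultivar network analysis.

Stage order: simulate (or load) -> log2 transform -> gene/sample
filtering -> common-gene intersection -> soft-threshold scan ->
comparability -> network (adjacency + TOM) -> clustering + tree cut ->
eigengenes -> module-trait gating, GS, K, hub-TF tables -> cross-network
overlap + preservation Zsummary -> per-module GO enrichment -> DEG
calling -> qPCR concordance. Every stage's parameters, seeds and output
files are recorded in a JSON manifest; the same config and seed
reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, modules, network, preservation, qpcr, stats
from .io import (
    GREY,
    RunConfig,
    write_annotation_map,
    write_edge_list,
    write_expression_matrix,
    write_module_assignments,
    write_sample_design,
)
from .simulate import REFERENCE_GENE, SyntheticConfig, generate_dataset, generate_qpcr

DEG_TIMEPOINT = "2h"
EDGE_THRESHOLD = 0.5
QPCR_GENES_PER_MODULE = 3
QPCR_CT_NOISE_SD = 0.2


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, float) and math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return value


class PipelineReport:
    """Machine-readable run manifest, one record per stage."""

    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.seed = seed
        self.stages: list[dict] = []
        self._t0 = time.monotonic()

    def record(self, stage: str, **info) -> None:
        entry = {"stage": stage, "elapsed_s": round(time.monotonic() - self._t0, 3)}
        entry.update({k: _jsonable(v) for k, v in info.items()})
        self.stages.append(entry)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "stages": self.stages}

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        payload = {
            "seed": self.seed,
            # wall times are dropped so identical runs give identical bytes
            "stages": [
                {k: v for k, v in entry.items() if k != "elapsed_s"}
                for entry in self.stages
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    def stage_names(self) -> list[str]:
        return [s["stage"] for s in self.stages]


def run_pipeline(
    outdir,
    run_config: RunConfig | None = None,
    sim_config: SyntheticConfig | None = None,
) -> PipelineReport:
    """Run the full synthetic-data-driven analysis into ``outdir``."""
    run_config = run_config or RunConfig()
    sim_config = sim_config or SyntheticConfig(rng_seed=run_config.rng_seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(outdir, seed=run_config.rng_seed)

    # --- simulate -----------------------------------------------------
    expr_raw, design, go_map, tf_map, truth = generate_dataset(sim_config)
    cultivars = list(sim_config.cultivars)
    for cv in cultivars:
        write_expression_matrix(expr_raw[cv], outdir / f"expression_{cv}.tsv")
    write_sample_design(design, outdir / "design.tsv")
    write_annotation_map(go_map, outdir / "annotations_go.tsv")
    write_annotation_map(tf_map, outdir / "annotations_tf.tsv")
    report.record(
        "simulate",
        seed=sim_config.rng_seed,
        n_genes=sim_config.n_genes,
        modules=sim_config.module_names,
        responsive_modules=sorted(truth.responsive_modules),
        preserved_modules=sorted(truth.preserved_modules),
        outputs=[f"expression_{cv}.tsv" for cv in cultivars]
        + ["design.tsv", "annotations_go.tsv", "annotations_tf.tsv"],
    )

    # --- filtering on the log2 scale ---------------------------------
    expr_log, removed = {}, {}
    for cv in cultivars:
        filtered, bad_genes, bad_samples = network.filter_genes_and_samples(
            expr_raw[cv].to_log2(1.0)
        )
        expr_log[cv] = filtered
        removed[cv] = (bad_genes, bad_samples)
    report.record(
        "filter",
        removed_genes={cv: len(removed[cv][0]) for cv in cultivars},
        removed_samples={cv: removed[cv][1] for cv in cultivars},
        genes_retained={cv: expr_log[cv].n_genes for cv in cultivars},
    )

    a, b = cultivars
    expr_log[a], expr_log[b] = network.intersect_common_genes(expr_log[a], expr_log[b])
    common_genes = expr_log[a].gene_ids
    report.record("intersect", common_genes=len(common_genes))

    # --- soft threshold + comparability ------------------------------
    # The scan is recorded as a diagnostic; planted-block synthetic data
    # is not scale-free by construction, so the network power is the
    # standard unsigned sample-size default (8 for 21-sample datasets).
    scans, powers = {}, {}
    for cv in cultivars:
        scan = network.soft_threshold_scan(
            expr_log[cv],
            powers=run_config.power_candidates,
            r2_threshold=run_config.scale_free_r2_threshold,
        )
        scan.table.to_csv(outdir / f"soft_threshold_{cv}.tsv", sep="\t", index=False)
        scans[cv] = scan
        powers[cv] = network.default_unsigned_power(expr_log[cv].n_samples)
    (mean_r, mean_p), (k_r, k_p) = network.comparability(
        expr_log[a], expr_log[b], powers[a], powers[b]
    )
    report.record(
        "soft_threshold",
        scan_power={cv: scans[cv].chosen_power for cv in cultivars},
        chosen_power={cv: powers[cv] for cv in cultivars},
        comparability_mean_expression={"r": mean_r, "p": mean_p},
        comparability_connectivity={"r": k_r, "p": k_p},
    )

    # --- networks + modules ------------------------------------------
    nets, partitions, eigensets = {}, {}, {}
    for cv in cultivars:
        net = network.build_network(expr_log[cv], powers[cv])
        nets[cv] = net
        dend = modules.average_linkage(net.dist_tom, net.gene_ids)
        part = modules.dynamic_tree_cut(
            dend,
            net.dist_tom,
            min_module_size=run_config.min_module_size,
            deep_split=run_config.deep_split,
        )
        partitions[cv] = part
        eigensets[cv] = modules.module_eigengenes(expr_log[cv], part)
        eigensets[cv].eigengenes.to_csv(
            outdir / f"eigengenes_{cv}.tsv", sep="\t", index_label="module"
        )
        n_edges = write_edge_list(
            net.gene_ids, net.adjacency, EDGE_THRESHOLD, outdir / f"edges_{cv}.txt"
        )
        report.record(
            f"network_{cv}",
            power=net.power,
            modules_found=len(part.module_names),
            grey=int((part.labels == GREY).sum()),
            edges_written=n_edges,
        )

    # --- module-trait, GS, K, hubs -----------------------------------
    sig_modules, hub_tables = {}, {}
    for cv in cultivars:
        sub_design = design[design["cultivar"] == cv].loc[expr_log[cv].sample_ids]
        trait = stats.encode_trait(sub_design, "dose_log")
        mt = stats.module_trait_correlation(
            eigensets[cv],
            trait,
            r_min=run_config.module_trait_r_min,
            p_max=run_config.module_trait_p_max,
        )
        mt_frame = pd.DataFrame([dataclasses.asdict(r) for r in mt])
        mt_frame.to_csv(outdir / f"module_trait_{cv}.tsv", sep="\t", index=False)
        sig_modules[cv] = [r.module for r in mt if r.significant]
        gs = stats.gene_significance(expr_log[cv], trait)
        k = stats.scaled_connectivity(
            nets[cv].adjacency, nets[cv].gene_ids, partitions[cv]
        )
        assignments = partitions[cv].to_frame()
        assignments["K"] = assignments["gene_id"].map(k)
        assignments["GS"] = assignments["gene_id"].map(gs)
        write_module_assignments(assignments, outdir / f"modules_{cv}.tsv")
        hubs = stats.top_hub_tfs(
            k, gs, tf_map, partitions[cv], n_top=5, modules=sig_modules[cv]
        )
        hubs.to_csv(outdir / f"hubs_{cv}.tsv", sep="\t", index=False)
        hub_tables[cv] = hubs
        report.record(
            f"module_trait_{cv}",
            significant_modules=sig_modules[cv],
            hub_rows=len(hubs),
        )

    # --- cross-network preservation ----------------------------------
    overlap = preservation.module_overlap(partitions[a], partitions[b])
    overlap.counts.to_csv(outdir / "overlap_counts.tsv", sep="\t", index_label="module")
    overlap.p_values.to_csv(outdir / "overlap_p.tsv", sep="\t", index_label="module")
    pres_rows = []
    for i, module in enumerate(partitions[a].module_names):
        members = partitions[a].members(module)
        res = preservation.zsummary(
            nets[a].adjacency,
            nets[b].adjacency,
            common_genes,
            members,
            n_permutations=run_config.n_permutations,
            seed=run_config.rng_seed + 1000 + i,
        )
        pres_rows.append(
            {
                "module": module,
                "size": len(members),
                "best_match": overlap.best_match[module],
                "overlap_p": float(
                    overlap.p_values.loc[module, overlap.best_match[module]]
                ),
                "z_density": res.z_density,
                "z_connectivity": res.z_connectivity,
                "z_summary": res.z_summary,
            }
        )
    pres_frame = pd.DataFrame(pres_rows)
    pres_frame.to_csv(outdir / "preservation.tsv", sep="\t", index=False)
    report.record(
        "preservation",
        n_permutations=run_config.n_permutations,
        strongly_preserved=[
            r["module"] for r in pres_rows if r["z_summary"] > preservation.ZSUMMARY_STRONG
        ],
    )

    # --- GO enrichment of significant modules ------------------------
    enr_frames = []
    for cv in cultivars:
        for module in sig_modules[cv]:
            res = enrichment.enrich(partitions[cv].members(module), go_map)
            res.insert(0, "module", module)
            res.insert(0, "cultivar", cv)
            enr_frames.append(res)
    enr = (
        pd.concat(enr_frames, ignore_index=True)
        if enr_frames
        else pd.DataFrame(
            columns=["cultivar", "module", "term", "k", "n", "K", "N", "p",
                     "p_bonferroni", "significant"]
        )
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    report.record(
        "enrichment",
        enriched_terms=int(enr["significant"].sum()) if len(enr) else 0,
    )

    # --- DEG calling --------------------------------------------------
    deg_frames = []
    for cv in cultivars:
        sub = design[design["cultivar"] == cv]
        controls = list(
            sub.loc[(sub["kno3_mM"] == 0) & (sub["timepoint"] == DEG_TIMEPOINT),
                    "sample_id"]
        )
        for dose in sorted({d for d in sub["kno3_mM"] if d > 0}):
            treated = list(
                sub.loc[(sub["kno3_mM"] == dose) & (sub["timepoint"] == DEG_TIMEPOINT),
                        "sample_id"]
            )
            fc = diffexpr.fold_change(
                expr_raw[cv], treated, controls, run_config.pseudocount
            )
            label = f"{cv} {dose:g} mM vs 0 mM, {DEG_TIMEPOINT}"
            deg_frames.append(diffexpr.call_degs(fc, run_config.fc_threshold, label))
    degs = pd.concat(deg_frames, ignore_index=True)
    degs[degs["direction"] != "unchanged"].to_csv(
        outdir / "degs.tsv", sep="\t", index=False
    )
    report.record(
        "diffexpr",
        deg_counts={
            label: diffexpr.deg_counts(grp)
            for label, grp in degs.groupby("condition_label")
        },
    )

    # --- qPCR concordance --------------------------------------------
    qpcr_genes = []
    for m in sorted(truth.responsive_modules):
        qpcr_genes.extend(truth.members(a, m)[:QPCR_GENES_PER_MODULE])
    background = [g for g, m in truth.module_of[a].items() if m == "background"]
    qpcr_genes.extend(background[:QPCR_GENES_PER_MODULE])
    ct = generate_qpcr(
        truth,
        expr_raw[a],
        qpcr_genes,
        reference_gene=REFERENCE_GENE,
        ct_noise_sd=QPCR_CT_NOISE_SD,
        seed=run_config.rng_seed + 2000,
    )
    ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    sub = design[design["cultivar"] == a]
    treated = list(
        sub.loc[(sub["kno3_mM"] == 4.0) & (sub["timepoint"] == DEG_TIMEPOINT),
                "sample_id"]
    )
    controls = list(
        sub.loc[(sub["kno3_mM"] == 0) & (sub["timepoint"] == DEG_TIMEPOINT),
                "sample_id"]
    )
    rel = qpcr.delta_delta_ct(ct, REFERENCE_GENE, treated, controls)
    rel.to_csv(outdir / "qpcr_relative.tsv", sep="\t", index=False)
    fc = diffexpr.fold_change(expr_raw[a], treated, controls, run_config.pseudocount)
    r, p = qpcr.concordance(rel, fc)
    report.record("qpcr", seed=run_config.rng_seed + 2000, concordance_r=r, p=p)

    report.write()
    return report
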