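"""Synthetic two-cultivar nitrate-response expression data.

Generates paired expression datasets with planted ground truth so every
downstream stage (networks, modules, hubs, preservation, enrichment,
qPCR) is testable without any sequencing data. The model is a single
latent factor per module:

* each module m has a latent eigengene e_m(s) over samples, unit
  population variance; nitrate-responsive modules build it as
  (dose_effect * z(log(1 + mM)) + noise) / sqrt(1 + dose_effect^2),
  others are pure standard noise;
* a member gene's log2 expression is
  x_gs = baseline_g + u_g * e_m(s) + sd_g * eps_gs with
  u_g = membership_strength; planted hubs get loading
  min(0.99, membership_strength * (1 + hub_boost)) and residual noise
  shrunk by ``hub_noise_frac`` — a hub is a gene that tracks its module
  eigengene almost perfectly, which is what makes its scaled
  connectivity approach 1;
* background genes are i.i.d. noise around their baseline;
* linear-scale FPKM = 2^x - 1, clipped at 0 (log-normal-like marginals).

The second cultivar shares eigengene structure for preserved modules
(fresh noise, fresh eigengene realizations, same memberships); for
non-preserved modules the membership is re-randomized, so the reference
module's genes are plain background in the test network.

GO terms are assigned at a base rate everywhere and at
``enrichment_odds``-times the odds inside each module for its planted
term. TF-family labels cover ``tf_fraction`` of genes plus all planted
hubs. Everything is reproducible from ``rng_seed``.

The 21-sample default design mirrors the study: three nitrate doses
(0.25, 2, 4 mM KNO3) at six timepoints plus three control (0 mM)
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationMap, ExpressionMatrix, TIMEPOINTS

REFERENCE_GENE = "BjUbq9"
REFERENCE_FPKM = 50.0

TF_FAMILIES = (
    "MYB", "WRKY", "bZIP", "AP2-EREBP", "NAC", "C2H2", "mTERF", "FHA",
    "G2-like", "RWP-RK", "bHLH", "FAR1", "C3H", "Orphans", "SET",
)

CONTROL_TIMEPOINTS = ("2h", "24h", "7d")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the study-scale conditions."""

    n_genes: int = 2000
    module_sizes: list[int] = field(default_factory=lambda: [80] * 5)
    n_responsive: int = 2
    n_hubs_per_module: int = 2
    cultivars: tuple[str, str] = ("PB", "PJK")
    doses: tuple[float, ...] = (0.0, 0.25, 2.0, 4.0)
    timepoints: tuple[str, ...] = TIMEPOINTS
    membership_strength: float = 0.8
    hub_boost: float = 0.25
    hub_noise_frac: float = 0.25
    dose_effect: float = 1.0
    noise_sd: float = 0.4
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    frac_preserved: float = 0.6
    tf_fraction: float = 0.10
    go_terms: int = 20
    go_base_rate: float = 0.05
    enrichment_odds: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed gene count")
        if not 0 <= self.membership_strength < 1:
            raise ValueError("membership_strength must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.frac_preserved <= 1:
            raise ValueError("frac_preserved must lie in [0, 1]")
        if self.enrichment_odds <= 1:
            raise ValueError("enrichment_odds must exceed 1")
        if self.n_responsive > len(self.module_sizes):
            raise ValueError("more responsive modules than modules")
        if any(s < self.n_hubs_per_module for s in self.module_sizes):
            raise ValueError("module smaller than its planted hub count")

    @property
    def module_names(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset pair."""

    module_of: dict[str, dict[str, str]]  # cultivar -> gene -> module/"background"
    responsive_modules: set[str]
    hub_genes: dict[str, list[str]]
    enriched_terms: dict[str, str]
    preserved_modules: set[str]
    eigengene_matrix: dict[str, pd.DataFrame]  # cultivar -> modules x samples

    def members(self, cultivar: str, module: str) -> list[str]:
        return [g for g, m in self.module_of[cultivar].items() if m == module]


def make_design(config: SyntheticConfig) -> pd.DataFrame:
    """Per-cultivar sample design: treated doses at every timepoint plus
    a reduced set of control libraries (21 samples per cultivar)."""
    rows = []
    for cultivar in config.cultivars:
        i = 0
        for dose in config.doses:
            tps = config.timepoints if dose > 0 else CONTROL_TIMEPOINTS
            for tp in tps:
                i += 1
                rows.append(
                    {
                        "sample_id": f"{cultivar}_{i:02d}",
                        "cultivar": cultivar,
                        "kno3_mM": dose,
                        "timepoint": tp,
                    }
                )
    df = pd.DataFrame(rows)
    df["treated"] = df["kno3_mM"] > 0
    return df.set_index("sample_id", drop=False)


def _dose_z(doses: np.ndarray) -> np.ndarray:
    raw = np.log1p(doses)
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)


def generate_dataset(config: SyntheticConfig):
    """Generate the paired datasets, annotations and planted truth.

    Returns ``(expr_by_cultivar, design, go_map, tf_map, truth)`` where
    ``expr_by_cultivar`` maps cultivar name to a linear-scale FPKM
    ExpressionMatrix (including the constant reference gene BjUbq9).
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    modules = config.module_names
    design = make_design(config)

    # membership in the reference cultivar: a random permutation of genes
    perm = rng.permutation(config.n_genes)
    module_of_ref: dict[str, str] = {g: "background" for g in genes}
    members_ref: dict[str, list[str]] = {}
    start = 0
    for m, size in zip(modules, config.module_sizes):
        idx = perm[start : start + size]
        members_ref[m] = [genes[i] for i in idx]
        for i in idx:
            module_of_ref[genes[i]] = m
        start += size

    hub_genes = {m: members_ref[m][: config.n_hubs_per_module] for m in modules}
    responsive = set(modules[: config.n_responsive])
    n_preserved = int(round(config.frac_preserved * len(modules)))
    preserved = set(modules[:n_preserved])

    # test-cultivar membership: preserved modules keep their genes,
    # non-preserved ones are re-drawn from the reference background
    module_of_test = {g: "background" for g in genes}
    members_test: dict[str, list[str]] = {}
    bg_pool = [g for g in genes if module_of_ref[g] == "background"]
    bg_pool = list(rng.permutation(bg_pool))
    for m in modules:
        if m in preserved:
            members_test[m] = members_ref[m]
        else:
            size = len(members_ref[m])
            members_test[m], bg_pool = bg_pool[:size], bg_pool[size:]
        for g in members_test[m]:
            module_of_test[g] = m

    baselines = (
        config.baseline_log2_mean
        + config.baseline_log2_sd * rng.standard_normal(config.n_genes)
    )
    baseline_of = dict(zip(genes, baselines))
    u_member = config.membership_strength
    u_hub = min(0.99, config.membership_strength * (1.0 + config.hub_boost))
    sd_hub = config.noise_sd * config.hub_noise_frac
    scale = np.sqrt(1.0 + config.dose_effect**2)

    expr: dict[str, ExpressionMatrix] = {}
    eigen: dict[str, pd.DataFrame] = {}
    module_of = {}
    hubs_all = {h for hs in hub_genes.values() for h in hs}
    for cultivar, membership in zip(
        config.cultivars, (members_ref, members_test)
    ):
        sub = design[design["cultivar"] == cultivar]
        samples = list(sub["sample_id"])
        n_s = len(samples)
        z = _dose_z(sub["kno3_mM"].to_numpy(dtype=float))
        e_mat = np.empty((len(modules), n_s))
        for j, m in enumerate(modules):
            noise = rng.standard_normal(n_s)
            if m in responsive:
                e_mat[j] = (config.dose_effect * z + noise) / scale
            else:
                e_mat[j] = noise
            # standardize the realization so every module is equally tight
            e_mat[j] = (e_mat[j] - e_mat[j].mean()) / e_mat[j].std()
        x = np.tile(baselines[:, None], (1, n_s)).astype(float)
        x += config.noise_sd * rng.standard_normal((config.n_genes, n_s))
        gene_pos = {g: i for i, g in enumerate(genes)}
        for j, m in enumerate(modules):
            for g in membership[m]:
                i = gene_pos[g]
                if g in hubs_all and module_of_ref[g] == m:
                    u, sd = u_hub, sd_hub
                else:
                    u, sd = u_member, config.noise_sd
                x[i] = (
                    baseline_of[g]
                    + u * e_mat[j]
                    + sd * rng.standard_normal(n_s)
                )
        fpkm = np.clip(2.0**x - 1.0, 0.0, None)
        frame = pd.DataFrame(fpkm, index=genes, columns=samples)
        frame.loc[REFERENCE_GENE] = REFERENCE_FPKM
        expr[cultivar] = ExpressionMatrix(frame, log_transformed=False)
        eigen[cultivar] = pd.DataFrame(e_mat, index=modules, columns=samples)
        module_of[cultivar] = (
            dict(module_of_ref) if membership is members_ref else dict(module_of_test)
        )

    go_map, enriched_terms = _plant_go(config, genes, members_ref, rng)
    tf_map = _plant_tf(config, genes, hubs_all, rng)
    truth = SyntheticTruth(
        module_of=module_of,
        responsive_modules=responsive,
        hub_genes=hub_genes,
        enriched_terms=enriched_terms,
        preserved_modules=preserved,
        eigengene_matrix=eigen,
    )
    return expr, design, go_map, tf_map, truth


def _plant_go(config, genes, members_ref, rng):
    terms = [f"GO:{i + 1:07d}" for i in range(config.go_terms)]
    p0 = config.go_base_rate
    odds0 = p0 / (1.0 - p0)
    p_enriched = (config.enrichment_odds * odds0) / (1.0 + config.enrichment_odds * odds0)
    enriched_terms = {
        m: terms[j % len(terms)] for j, m in enumerate(members_ref)
    }
    entries: dict[str, set[str]] = {}
    module_term_of = {}
    for m, term in enriched_terms.items():
        for g in members_ref[m]:
            module_term_of[g] = term
    for g in genes:
        hot = module_term_of.get(g)
        for t in terms:
            p = p_enriched if t == hot else p0
            if rng.random() < p:
                entries.setdefault(g, set()).add(t)
    return AnnotationMap(kind="GO", entries=entries), enriched_terms


def _plant_tf(config, genes, hubs, rng):
    entries: dict[str, set[str]] = {}
    for g in genes:
        if g in hubs or rng.random() < config.tf_fraction:
            entries[g] = {TF_FAMILIES[int(rng.integers(len(TF_FAMILIES)))]}
    return AnnotationMap(kind="TF", entries=entries)


def generate_qpcr(
    truth: SyntheticTruth,
    expr: ExpressionMatrix,
    genes,
    reference_gene: str = REFERENCE_GENE,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 3,
    ct0: float = 35.0,
) -> pd.DataFrame:
    """Long-format CT table consistent with the expression matrix.

    CT_gs = ct0 - log2(FPKM_gs + 1) + noise per technical replicate; the
    reference gene (constant FPKM) therefore has constant CT up to
    noise, and noiseless 2^-ddCT exactly recovers (FPKM_t+1)/(FPKM_c+1).
    """
    if expr.log_transformed:
        raise ValueError("generate_qpcr expects a linear-scale matrix")
    genes = list(genes)
    for g in genes + [reference_gene]:
        if g not in expr.data.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    rng = np.random.default_rng(seed)
    rows = []
    for g in [reference_gene] + [g for g in genes if g != reference_gene]:
        base = ct0 - np.log2(expr.data.loc[g].to_numpy(dtype=float) + 1.0)
        for rep in range(1, n_replicates + 1):
            noisy = base + ct_noise_sd * rng.standard_normal(len(base))
            for s, ct in zip(expr.sample_ids, noisy):
                rows.append(
                    {"gene_id": g, "sample_id": s, "replicate": rep, "ct": float(ct)}
                )
    return pd.DataFrame(rows)
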