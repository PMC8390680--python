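"""Synthetic ICB trial cohort with known ground truth.

Generates every input the analysis pipeline consumes — clinical table,
longitudinal ctDNA (MTM/mL) and target-lesion measurements, MAF-like
mutations with per-sample covered megabases, allele-specific copy-number
segments on a 22-autosome toy genome, and paired baseline/on-treatment
expression mixed from a cell-type reference — so that every downstream stage
is testable without access-restricted trial data.

Construction guarantees: each patient's (ΔctDNA, ΔTM) signs match their true
sensitivity group (values drawn from truncated normals restricted to the
group's quadrant); survival times are exponential with group-specific
hazards and independent uniform censoring, so hazard ratios have a closed
form; B2M LOH and planted gene enrichments occur at exactly the configured
Bernoulli rates; expression mixtures are reference x true proportions with
multiplicative log-normal noise.

All randomness flows from one root seed fanned out to named substreams, so
each generator is individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("LS", "HS", "MSPP", "MSER")

#: quadrant sign of (ΔctDNA, ΔTM) per group: +1 increase, -1 decrease
GROUP_SIGNS = {"LS": (1, 1), "HS": (-1, -1), "MSPP": (-1, 1), "MSER": (1, -1)}

# ---------------------------------------------------------------------------
# toy genome: 22 autosomes, lengths in bp summing to exactly 3,000 Mb
_CHROM_MB = [248, 242, 198, 190, 181, 171, 159, 145, 138, 134,
             135, 133, 114, 107, 102, 90, 83, 80, 64, 59, 47, 42]
_CHROM_MB[-1] += 3000 - sum(_CHROM_MB)  # exact total
CHROM_LENGTHS = {f"chr{i+1}": mb * 1_000_000 for i, mb in enumerate(_CHROM_MB)}
GENOME_LENGTH = sum(CHROM_LENGTHS.values())

#: toy coordinates (1-based inclusive) for genes with copy-number readouts
TOY_GENES = {
    "B2M": ("chr15", 45_000_001, 45_010_000),
    "MYC": ("chr8", 127_700_001, 127_710_000),
    "PTEN": ("chr10", 87_800_001, 87_900_000),
    "STAT1": ("chr2", 190_900_001, 191_000_000),
    "JAK1": ("chr1", 64_800_001, 65_000_000),
    "JAK2": ("chr9", 4_900_001, 5_100_000),
    "CD274": ("chr9", 5_400_001, 5_500_000),
    "HLA-A": ("chr6", 29_900_001, 29_950_000),
    "HLA-B": ("chr6", 31_200_001, 31_250_000),
    "HLA-C": ("chr6", 31_260_001, 31_300_000),
    "TP53": ("chr17", 7_600_001, 7_700_000),
    "BRCA1": ("chr17", 43_000_001, 43_100_000),
    "BRCA2": ("chr13", 32_300_001, 32_400_000),
}

CANCER_COHORTS = ("HNSCC", "TNBC", "HGSC", "MM", "MST")

#: immune-evasion / antigen-presentation catalog used for frequency reporting
DEFAULT_CATALOG = [
    "TP53", "PTEN", "B2M", "HLA-A", "HLA-B", "HLA-C", "TAP1", "TAP2",
    "STAT1", "STAT3", "JAK1", "JAK2", "IFNGR1", "IFNGR2", "BRCA1", "BRCA2",
    "MYC", "PREX2", "BIRC6", "CNTNAP2", "PTPRB", "GRM3", "ANKRD11", "TET3",
]


@dataclass
class CohortConfig:
    """Study conditions for the generator (defaults mirror the trial design:

    71 evaluable patients over five cancer cohorts; sensitivity mix
    45/22.5/22.5/10% for LS/HS/MSPP/MSER; high-sensitivity tumors carry high
    TMB and immune-signature-shifted expression; low-sensitivity tumors carry
    high PGA and frequent B2M LOH; survival is exponential with lower hazard
    in sensitive groups)."""

    n_patients: int = 71
    seed: int = 0
    cohort_mix: dict = field(default_factory=lambda: {
        "HNSCC": 0.19, "TNBC": 0.21, "HGSC": 0.21, "MM": 0.12, "MST": 0.27})
    group_mix: dict = field(default_factory=lambda: {
        "LS": 0.45, "HS": 0.225, "MSPP": 0.225, "MSER": 0.10})
    # per-month exponential hazards
    os_hazard: dict = field(default_factory=lambda: {
        "LS": 0.12, "MSER": 0.10, "MSPP": 0.05, "HS": 0.025})
    pfs_hazard: dict = field(default_factory=lambda: {
        "LS": 0.35, "MSER": 0.20, "MSPP": 0.30, "HS": 0.04})
    censor_max_months: float = 36.0
    # (location, scale) of truncated normals for the percent changes
    ctdna_params: dict = field(default_factory=lambda: {
        "LS": (150.0, 100.0), "HS": (-85.0, 20.0),
        "MSPP": (-60.0, 30.0), "MSER": (80.0, 60.0)})
    tm_params: dict = field(default_factory=lambda: {
        "LS": (35.0, 20.0), "HS": (-45.0, 20.0),
        "MSPP": (25.0, 15.0), "MSER": (-35.0, 15.0)})
    # mutations
    enrichment_spec: list = field(default_factory=lambda: [
        ("BRCA2", "HS", 0.30, 0.02)])
    tmb_mut_per_mb: dict = field(default_factory=lambda: {
        "LS": 1.0, "MSER": 1.5, "MSPP": 1.5, "HS": 7.7})
    silent_mut_per_mb: float = 0.3
    covered_mb_mean: float = 40.0
    covered_mb_sd: float = 5.0
    # copy number
    pga_params: dict = field(default_factory=lambda: {
        "LS": 0.45, "MSER": 0.35, "MSPP": 0.20, "HS": 0.10})
    pga_concentration: float = 20.0
    b2m_loh_prob: dict = field(default_factory=lambda: {
        "LS": 0.50, "MSER": 0.20, "MSPP": 0.10, "HS": 0.0})
    segments_per_chrom: int = 3
    # expression
    n_genes: int = 300
    n_celltypes: int = 5
    noise_sd: float = 0.1
    paired_fraction: float = 0.6
    immune_shift_log2: float = 1.0
    n_treatment_genes: int = 20
    treatment_log2fc: float = 2.0
    treatment_groups: tuple = ("HS", "LS")

    def __post_init__(self) -> None:
        for name, mix in (("cohort_mix", self.cohort_mix),
                          ("group_mix", self.group_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(not 0 <= v <= 1 for v in mix.values()):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
        if set(self.group_mix) != set(GROUPS):
            raise ValueError(f"group_mix must cover exactly {GROUPS}")
        for name, d in (("os_hazard", self.os_hazard),
                        ("pfs_hazard", self.pfs_hazard)):
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"{name} entries must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


@dataclass
class GroundTruth:
    """Construction-time truth for recovery tests."""

    groups: dict = field(default_factory=dict)  # patient_id -> group
    enriched_genes: dict = field(default_factory=dict)  # gene -> group
    b2m_loh: dict = field(default_factory=dict)  # sample_id -> bool
    pga_fraction: dict = field(default_factory=dict)  # sample_id -> target
    proportions: pd.DataFrame | None = None  # cell types x samples
    treatment_log2fc: pd.DataFrame | None = None  # genes x groups


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the root seed (module-level reproducibility)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _truncated_normal(rng, loc, scale, low, high, size=None):
    a, b = (low - loc) / scale, (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                               random_state=rng)


def _assign_counts(n: int, mix: dict, rng) -> list[str]:
    """Deterministic largest-remainder allocation of n items to categories."""
    keys = sorted(mix)
    exact = np.array([mix[k] * n for k in keys])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    labels = [k for k, c in zip(keys, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# clinical / ctDNA / imaging / survival


def generate_clinical(config: CohortConfig):
    """Clinical, ctDNA, lesion, and survival tables plus ground truth.

    Percent changes are sampled inside each group's quadrant, then baseline
    levels are drawn and on-treatment values back-computed, so the generated
    deltas reproduce the group label exactly.
    """
    rng = _substream(config.seed, "clinical")
    n = config.n_patients
    pids = [f"PT{i+1:04d}" for i in range(n)]
    groups = _assign_counts(n, config.group_mix, rng)
    cohorts = _assign_counts(n, config.cohort_mix, rng)

    clinical_rows, ctdna_rows, lesion_rows, surv_rows = [], [], [], []
    truth = GroundTruth()
    for pid, group, cohort in zip(pids, groups, cohorts):
        truth.groups[pid] = group
        ct_sign, tm_sign = GROUP_SIGNS[group]
        loc, scale = config.ctdna_params[group]
        d_ct = float(_truncated_normal(
            rng, loc, scale,
            low=-100.0 if ct_sign < 0 else 1e-6,
            high=-1e-6 if ct_sign < 0 else np.inf))
        loc, scale = config.tm_params[group]
        d_tm = float(_truncated_normal(
            rng, loc, scale,
            low=-100.0 if tm_sign < 0 else 1e-6,
            high=-1e-6 if tm_sign < 0 else np.inf))

        base_mtm = float(rng.lognormal(mean=1.5, sigma=1.2))
        on_mtm = base_mtm * (1 + d_ct / 100.0)
        base_tm = float(rng.lognormal(mean=np.log(60.0), sigma=0.4))
        on_tm = base_tm * (1 + d_tm / 100.0)
        ctdna_rows += [(pid, "baseline", base_mtm), (pid, "C3", max(on_mtm, 0.0))]
        lesion_rows += [(pid, 0, base_tm), (pid, 9, max(on_tm, 0.0))]

        os_t = float(rng.exponential(1.0 / config.os_hazard[group]))
        pfs_t = float(rng.exponential(1.0 / config.pfs_hazard[group]))
        for endpoint, t in (("OS", os_t), ("PFS", pfs_t)):
            c = float(rng.uniform(0, config.censor_max_months))
            surv_rows.append((pid, endpoint, max(min(t, c), 1e-3),
                              int(t <= c)))

        pfs_months = min(pfs_t, config.censor_max_months)
        if d_tm <= -30:
            response = "CR" if rng.random() < 0.15 else "PR"
        elif d_tm >= 20:
            response = "PD"
        else:
            response = "SD"
        sd_weeks = pfs_months * (52.0 / 12.0) if response == "SD" else 0.0
        pd_l1 = int(rng.integers(0, 101)) if rng.random() < 0.8 else -1
        clinical_rows.append((pid, cohort, response, round(sd_weeks, 1), pd_l1))

    clinical = pd.DataFrame(
        clinical_rows,
        columns=["patient_id", "cancer_cohort", "best_overall_response",
                 "sd_duration_weeks", "pd_l1_mps"])
    ctdna = pd.DataFrame(ctdna_rows, columns=["patient_id", "cycle", "mtm_per_ml"])
    lesions = pd.DataFrame(
        lesion_rows, columns=["patient_id", "week", "target_lesion_sum_mm"])
    survival = pd.DataFrame(
        surv_rows, columns=["patient_id", "endpoint", "time_months", "event"])
    return clinical, ctdna, lesions, survival, truth


# ---------------------------------------------------------------------------
# mutations


def default_background_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic TCGA-style cancer_type x gene background mutation-rate table."""
    rng = _substream(seed, "background")
    genes = DEFAULT_CATALOG
    rows = []
    for cancer in CANCER_COHORTS:
        for gene in genes:
            if gene == "TP53":
                rate = float(rng.uniform(0.3, 0.5))
            elif gene in ("BRCA1", "BRCA2", "PTEN"):
                rate = float(rng.uniform(0.02, 0.08))
            else:
                rate = float(rng.uniform(0.005, 0.05))
            rows.append((cancer, gene, rate, 500))
    return pd.DataFrame(rows, columns=["cancer_type", "gene", "rate", "n"])


def generate_mutations(
    config: CohortConfig,
    clinical: pd.DataFrame,
    truth: GroundTruth,
    background: pd.DataFrame | None = None,
):
    """MAF-like mutation table plus per-sample covered megabases.

    Catalog genes mutate per patient as Bernoulli draws at the patient's
    cancer-type background rate, overridden by ``enrichment_spec`` entries
    (rate_in_group inside the spec's group, rate_elsewhere outside).
    Passenger burden is Poisson at the group's TMB rate times covered Mb.
    """
    if background is None:
        background = default_background_table(config.seed)
    rng = _substream(config.seed, "mutations")
    gene_universe = set(background["gene"])
    for gene, group, *_ in config.enrichment_spec:
        if gene not in gene_universe:
            raise ValueError(f"enrichment gene {gene!r} not in the gene universe")
    rates = {(r.cancer_type, r.gene): r.rate for r in background.itertuples()}
    overrides = {g: (grp, rin, rout) for g, grp, rin, rout in config.enrichment_spec}

    rows = []
    coverage = []
    genes_sorted = sorted(gene_universe)
    classes = ["missense", "nonsense", "frameshift_indel", "splice_site",
               "in_frame_indel"]
    class_p = [0.7, 0.1, 0.1, 0.05, 0.05]
    for rec in clinical.itertuples():
        pid = rec.patient_id
        group = truth.groups[pid]
        cov = float(np.clip(rng.normal(config.covered_mb_mean,
                                       config.covered_mb_sd), 10.0, None))
        coverage.append((pid, cov))
        for gene in genes_sorted:
            if gene in overrides:
                grp, rin, rout = overrides[gene]
                rate = rin if group == grp else rout
            else:
                rate = rates[(rec.cancer_cohort, gene)]
            if rng.random() < rate:
                origin = ("germline_pathogenic"
                          if gene in ("BRCA1", "BRCA2") and rng.random() < 0.3
                          else "somatic")
                vc = classes[rng.choice(len(classes), p=class_p)]
                rows.append((pid, gene, vc, origin))
        n_passenger = int(rng.poisson(config.tmb_mut_per_mb[group] * cov))
        for _ in range(n_passenger):
            rows.append((pid, f"PSG{int(rng.integers(0, 99999)):05d}",
                         "missense", "somatic"))
        for _ in range(int(rng.poisson(config.silent_mut_per_mb * cov))):
            rows.append((pid, f"PSG{int(rng.integers(0, 99999)):05d}",
                         "silent", "somatic"))
    muts = pd.DataFrame(
        rows, columns=["sample_id", "gene", "variant_classification", "origin"])
    covered = pd.DataFrame(coverage, columns=["sample_id", "covered_mb"])
    for gene, grp, rin, rout in config.enrichment_spec:
        truth.enriched_genes[gene] = grp
    return muts, covered


# ---------------------------------------------------------------------------
# copy number


def generate_copy_number(config: CohortConfig, clinical: pd.DataFrame,
                         truth: GroundTruth):
    """Allele-specific segments tiling the toy genome, plus purity/ploidy.

    Each chromosome is split into ``segments_per_chrom`` segments at random
    breakpoints; every segment is independently set non-diploid (total CN 1
    or 3) with the group's target PGA fraction, so expected PGA equals the
    configured parameter.  The segment containing B2M is forced to total CN 1
    with probability ``b2m_loh_prob`` of the group (and forced diploid
    otherwise, making the flag exact).
    """
    rng = _substream(config.seed, "copy_number")
    b2m_chrom, b2m_start, b2m_end = TOY_GENES["B2M"]
    seg_rows, purity_rows = [], []
    for rec in clinical.itertuples():
        pid = rec.patient_id
        group = truth.groups[pid]
        mean = config.pga_params[group]
        conc = config.pga_concentration
        target = float(rng.beta(mean * conc, (1 - mean) * conc)) if 0 < mean < 1 \
            else float(mean)
        truth.pga_fraction[pid] = target
        has_b2m_loh = bool(rng.random() < config.b2m_loh_prob[group])
        truth.b2m_loh[pid] = has_b2m_loh
        for chrom, length in CHROM_LENGTHS.items():
            cuts = np.sort(rng.integers(1, length,
                                        size=config.segments_per_chrom - 1))
            bounds = [1, *[int(c) for c in cuts], length]
            start = bounds[0]
            for end in bounds[1:]:
                if end < start:
                    continue
                if rng.random() < target:
                    cn_total = 1 if rng.random() < 0.5 else 3
                else:
                    cn_total = 2
                cn_minor = 0 if cn_total == 1 else 1
                covers_b2m = (chrom == b2m_chrom and start <= b2m_end
                              and end >= b2m_start)
                if covers_b2m:
                    cn_total, cn_minor = (1, 0) if has_b2m_loh else (2, 1)
                seg_rows.append((pid, chrom, start, end, cn_total, cn_minor))
                start = end + 1
        purity_rows.append((pid, float(rng.uniform(0.3, 0.95)), 2.0))
    segments = pd.DataFrame(
        seg_rows,
        columns=["sample_id", "chromosome", "start", "end",
                 "cn_total", "cn_minor"])
    purity = pd.DataFrame(
        purity_rows, columns=["sample_id", "cellularity", "ploidy"])
    return segments, purity


# ---------------------------------------------------------------------------
# expression


def default_reference(n_genes: int = 300, n_celltypes: int = 5,
                      seed: int = 0) -> pd.DataFrame:
    """Cell-type signature matrix with exclusive marker blocks per type.

    Genes are IMM0001..; GZMA and PRF1 are appended as cytotoxic markers so
    the CYT score is computable on mixtures.
    """
    rng = _substream(seed, "reference")
    genes = [f"IMM{i+1:04d}" for i in range(n_genes)]
    types = [f"celltype_{chr(65+i)}" for i in range(n_celltypes)]
    base = rng.uniform(0.5, 2.0, size=(n_genes, n_celltypes))
    block = n_genes // (n_celltypes + 1)
    for j in range(n_celltypes):
        rows = slice(j * block, (j + 1) * block)
        base[rows, j] += rng.uniform(30.0, 80.0, size=block)
    ref = pd.DataFrame(base, index=genes, columns=types)
    cyto = rng.uniform(0.5, 2.0, size=(2, n_celltypes))
    cyto[:, -1] += 40.0  # last type carries the cytotoxic markers
    ref = pd.concat([ref, pd.DataFrame(cyto, index=["GZMA", "PRF1"],
                                       columns=types)])
    return ref


def immune_gene_sets(reference: pd.DataFrame,
                     n_celltypes: int = 5) -> dict[str, list[str]]:
    """IM and IFNG signature sets over the reference gene universe.

    Both signatures mark the first cell type (the designated immune lineage
    block), split into disjoint halves, so they track the same underlying
    immune content — mirroring the strong IM/IFNG concordance seen in tumor
    expression data.
    """
    genes = [g for g in reference.index if g.startswith("IMM")]
    block = len(genes) // (n_celltypes + 1)
    return {"IM": genes[: block // 2], "IFNG": genes[block // 2: block]}


def generate_expression(
    config: CohortConfig,
    clinical: pd.DataFrame,
    truth: GroundTruth,
    reference: pd.DataFrame | None = None,
):
    """Baseline + on-treatment expression with known mixing proportions.

    Bulk TPM = reference x true cell-type proportions, times multiplicative
    log-normal noise ``exp(N(0, noise_sd))``.  HS baselines draw
    immune-skewed proportions and get IM/IFNG marker genes shifted up by
    ``immune_shift_log2``.  The last ``n_treatment_genes`` genes are planted
    treatment-induced: on-treatment samples of ``treatment_groups`` are
    multiplied by ``2**treatment_log2fc`` (HS/CB gets the full effect, other
    listed groups half), recorded in the ground truth.
    """
    if reference is None:
        reference = default_reference(config.n_genes, config.n_celltypes,
                                      config.seed)
    if reference.shape[1] < 2:
        raise ValueError("reference needs at least 2 cell types")
    if (reference.to_numpy() < 0).any():
        raise ValueError("reference must be non-negative")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _substream(config.seed, "expression")
    n_types = reference.shape[1]
    R = reference.to_numpy(dtype=float)
    genes = reference.index
    sets = immune_gene_sets(reference, config.n_celltypes)
    im_mask = genes.isin(sets["IM"]) | genes.isin(sets["IFNG"])
    trt_genes = [g for g in genes if g.startswith("IMM")][-config.n_treatment_genes:]
    trt_mask = genes.isin(trt_genes)

    cols, col_meta, props = [], [], []
    for rec in clinical.itertuples():
        pid = rec.patient_id
        group = truth.groups[pid]
        alpha = np.ones(n_types)
        if group == "HS":
            alpha[0] = 4.0  # immune-rich baseline composition
        p = rng.dirichlet(alpha)
        paired = rng.random() < config.paired_fraction
        for timepoint in (("baseline", "on_treatment") if paired
                          else ("baseline",)):
            suffix = "B" if timepoint == "baseline" else "C3"
            sid = f"{pid}_{suffix}"
            x = R @ p
            if group == "HS" and timepoint == "baseline":
                x = np.where(im_mask, x * 2 ** config.immune_shift_log2, x)
            if timepoint == "on_treatment" and group in config.treatment_groups:
                lfc = config.treatment_log2fc
                if group != config.treatment_groups[0]:
                    lfc = lfc / 2.0
                x = np.where(trt_mask, x * 2 ** lfc, x)
            if config.noise_sd > 0:
                x = x * np.exp(rng.normal(0.0, config.noise_sd, size=x.shape))
            cols.append(x)
            col_meta.append((sid, pid, timepoint))
            props.append(p)
    tpm = pd.DataFrame(np.column_stack(cols), index=genes,
                       columns=[m[0] for m in col_meta])
    meta = pd.DataFrame(col_meta, columns=["sample_id", "patient_id", "timepoint"])
    counts = pd.DataFrame(rng.poisson(tpm.to_numpy() * 30.0),
                          index=tpm.index, columns=tpm.columns)
    truth.proportions = pd.DataFrame(
        np.column_stack(props), index=reference.columns,
        columns=tpm.columns)
    lfc_rows = {}
    for grp in GROUPS:
        if grp in config.treatment_groups:
            lfc = config.treatment_log2fc
            if grp != config.treatment_groups[0]:
                lfc = lfc / 2.0
        else:
            lfc = 0.0
        lfc_rows[grp] = np.where(trt_mask, lfc, 0.0)
    truth.treatment_log2fc = pd.DataFrame(lfc_rows, index=genes)
    return tpm, counts, meta, reference


# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus construction-time truth."""

    config: CohortConfig
    clinical: pd.DataFrame
    ctdna: pd.DataFrame
    lesions: pd.DataFrame
    survival: pd.DataFrame
    mutations: pd.DataFrame
    coverage: pd.DataFrame
    segments: pd.DataFrame
    purity: pd.DataFrame
    expression_tpm: pd.DataFrame
    expression_counts: pd.DataFrame
    sample_meta: pd.DataFrame
    reference: pd.DataFrame
    background: pd.DataFrame
    truth: GroundTruth


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """One-call generation of the full synthetic cohort."""
    if config is None:
        config = CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    clinical, ctdna, lesions, survival, truth = generate_clinical(config)
    background = default_background_table(config.seed)
    muts, coverage = generate_mutations(config, clinical, truth, background)
    segments, purity = generate_copy_number(config, clinical, truth)
    tpm, counts, meta, reference = generate_expression(config, clinical, truth)
    return SyntheticCohort(config, clinical, ctdna, lesions, survival,
                           muts, coverage, segments, purity,
                           tpm, counts, meta, reference, background, truth)
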