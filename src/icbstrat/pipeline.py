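"""End-to-end driver: synthetic cohort -> all analysis stages -> result bundle.

Stage order mirrors the study design: (1) sensitivity stratification from
ctDNA/lesion dynamics, (2) per-sample genomic features (TMB, PGA, B2M LOH),
(3) mutation enrichment of HS/CB vs LS against the weighted background,
(4) immune scores and deconvolution, (5) longitudinal DRG analysis with
preranked GSEA, (6) survival comparisons across every stratification.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dynamics, enrichment, genomics, immune
from . import stratify as strat
from . import survival as surv
from .synthetic import (DEFAULT_CATALOG, TOY_GENES, CohortConfig,
                        SyntheticCohort, generate_cohort, immune_gene_sets)

#: months from treatment start to cycle 3 (two 3-week cycles)
CYCLE3_MONTHS = 6 * 7 / 30.44


@dataclass
class PipelineThresholds:
    tmb_high: float = 10.0
    drg_fdr: float = 0.10
    enrich_min_frac: float = 0.25
    enrich_max_frac: float = 0.05
    significance: float = 0.10
    background_n: int = 1000
    gsea_n_perm: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.enrich_max_frac < self.enrich_min_frac < 1:
            raise ValueError("enrichment fractions out of range")
        for v in (self.drg_fdr, self.significance):
            if not 0 < v < 1:
                raise ValueError("FDR/significance thresholds must be in (0,1)")


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    features: pd.DataFrame
    enrichment: pd.DataFrame
    immune_scores: pd.DataFrame
    cell_fractions: pd.DataFrame
    cell_log2fc: pd.DataFrame
    de_tables: dict
    drg_classification: pd.DataFrame
    gsea: pd.DataFrame
    survival_summaries: dict
    manifest: dict = field(default_factory=dict)


def sensitivity_calls(cohort: SyntheticCohort) -> pd.DataFrame:
    calls = strat.call_cohort(cohort.ctdna, cohort.lesions)
    cb = cohort.clinical.apply(
        lambda r: strat.classify_clinical_benefit(
            r["best_overall_response"], r["sd_duration_weeks"]),
        axis=1,
    )
    clin = cohort.clinical.assign(clinical_benefit=cb)
    return calls.merge(clin, on="patient_id")


def genomic_features(cohort: SyntheticCohort,
                     thresholds: PipelineThresholds) -> pd.DataFrame:
    """Per-sample TMB (with class), PGA, and B2M LOH flag."""
    rows = []
    coverage = dict(zip(cohort.coverage["sample_id"],
                        cohort.coverage["covered_mb"]))
    kept = set(genomics.filter_by_cellularity(cohort.purity)["sample_id"])
    ploidies = dict(zip(cohort.purity["sample_id"], cohort.purity["ploidy"]))
    b2m_chrom, b2m_start, b2m_end = TOY_GENES["B2M"]
    for sid, segs_df in cohort.segments.groupby("sample_id"):
        if sid not in kept:
            continue
        segs = [genomics.CopyNumberSegment(sid, r.chromosome, r.start, r.end,
                                           r.cn_total, r.cn_minor)
                for r in segs_df.itertuples()]
        muts = cohort.mutations[cohort.mutations["sample_id"] == sid]
        tmb = genomics.compute_tmb(muts, coverage[sid])
        pga = genomics.compute_pga(segs)
        status = genomics.gene_copy_status(b2m_chrom, b2m_start, b2m_end,
                                           segs, ploidies[sid])
        rows.append({
            "sample_id": sid,
            "tmb": tmb,
            "tmb_class": genomics.classify_tmb(tmb, thresholds.tmb_high),
            "pga": pga,
            "b2m_loh": status is not None and "LOH" in status,
        })
    feats = pd.DataFrame(rows)
    feats["pga_class"] = genomics.classify_pga(feats["pga"])
    return feats


def _hscb_ls_groups(calls: pd.DataFrame) -> tuple[list[str], list[str]]:
    """HS-or-clinical-benefit versus LS patient id lists (disjoint)."""
    hscb = calls[(calls["group"] == "HS") | calls["clinical_benefit"]]
    ls = calls[(calls["group"] == "LS") & ~calls["clinical_benefit"]]
    return hscb["patient_id"].tolist(), ls["patient_id"].tolist()


def mutation_enrichment(cohort: SyntheticCohort, calls: pd.DataFrame,
                        thresholds: PipelineThresholds) -> pd.DataFrame:
    hscb, ls = _hscb_ls_groups(calls)
    candidates = enrichment.select_candidates(
        cohort.mutations, hscb, ls,
        min_frac=thresholds.enrich_min_frac,
        max_frac=thresholds.enrich_max_frac,
        label_a="HS/CB", label_b="LS")
    # restrict to genes with background rates (passengers have none)
    known = set(cohort.background["gene"])
    candidates = candidates[candidates["gene"].isin(known)].reset_index(drop=True)
    weights = (cohort.clinical["cancer_cohort"].value_counts(normalize=True)
               .to_dict())
    results = enrichment.test_enrichment(
        candidates, cohort.background, weights,
        background_n=thresholds.background_n)
    return enrichment.results_to_frame(results)


def immune_profiles(cohort: SyntheticCohort):
    log_tpm = np.log2(cohort.expression_tpm + 1)
    sets = immune_gene_sets(cohort.reference, cohort.config.n_celltypes)
    scores = pd.DataFrame({
        "IM": immune.ssgsea_score(log_tpm, sets["IM"]),
        "IFNG": immune.ssgsea_score(log_tpm, sets["IFNG"]),
        "CYT": immune.cytolytic_score(cohort.expression_tpm),
    })
    fractions, absolute = immune.deconvolve(cohort.expression_tpm,
                                            cohort.reference)
    log2fc = immune.cell_score_log2fc(absolute, cohort.sample_meta)
    return scores, fractions, log2fc


def expression_dynamics(cohort: SyntheticCohort, calls: pd.DataFrame,
                        thresholds: PipelineThresholds, seed: int = 0):
    hscb, ls = _hscb_ls_groups(calls)
    meta = cohort.sample_meta
    log_tpm = np.log2(cohort.expression_tpm + 1)

    def pairs_for(patients):
        out = []
        for pid in patients:
            rows = meta[meta["patient_id"] == pid]
            b = rows[rows["timepoint"] == "baseline"]["sample_id"]
            o = rows[rows["timepoint"] == "on_treatment"]["sample_id"]
            if len(b) and len(o):
                out.append((b.iloc[0], o.iloc[0]))
        return out

    de_tables, drgs, changes = {}, {}, {}
    for label, patients in (("HS/CB", hscb), ("LS", ls)):
        pairs = pairs_for(patients)
        if len(pairs) < 3:
            raise ValueError(f"group {label} has <3 expression pairs")
        de = dynamics.paired_de(log_tpm, pairs, counts=cohort.expression_counts)
        de_tables[label] = de
        drgs[label] = dynamics.select_drgs(de, thresholds.drg_fdr)
        diff = (log_tpm[[o for _, o in pairs]].to_numpy()
                - log_tpm[[b for b, _ in pairs]].to_numpy())
        changes[label] = pd.DataFrame(diff, index=log_tpm.index)
    classification = dynamics.overlap_and_classify(
        drgs["HS/CB"], drgs["LS"], changes["HS/CB"], changes["LS"],
        label_a="HS/CB", label_b="LS")
    ranking = dynamics.ranked_list(de_tables["HS/CB"])
    sets = immune_gene_sets(cohort.reference, cohort.config.n_celltypes)
    trt_genes = cohort.truth.treatment_log2fc.index[
        cohort.truth.treatment_log2fc["HS"] != 0].tolist()
    gene_sets = {**sets, "TREATMENT_INDUCED": trt_genes}
    gsea = dynamics.preranked_gsea(
        ranking, gene_sets,
        min_size=min(dynamics.GSEA_MIN_SIZE,
                     min(len(v) for v in gene_sets.values())),
        n_perm=thresholds.gsea_n_perm, seed=seed)
    return de_tables, classification, gsea


def survival_analysis(cohort: SyntheticCohort, calls: pd.DataFrame,
                      features: pd.DataFrame,
                      landmark_months: float = CYCLE3_MONTHS) -> dict:
    """KM/log-rank/Cox across the main stratifications, landmarked at cycle 3."""
    out: dict = {}
    merged = calls.merge(features, left_on="patient_id", right_on="sample_id",
                         how="left")
    for endpoint in ("OS", "PFS"):
        rec = cohort.survival[cohort.survival["endpoint"] == endpoint]
        rec = rec.merge(merged, on="patient_id")
        rec = surv.landmark_filter(rec, landmark_months)
        ep: dict = {}
        by_group = rec[rec["group"].isin(("LS", "HS", "MSPP", "MSER"))]
        stat, p = surv.logrank_test(by_group, "group")
        ep["sensitivity_logrank"] = {"statistic": stat, "p": p}
        hs_ls = by_group[by_group["group"].isin(("HS", "LS"))]
        cox = surv.cox_univariate(hs_ls, "group", reference="LS")
        ep["hs_vs_ls_cox"] = {"hr": cox.hazard_ratio, "p": cox.p_value,
                              "ci": [cox.ci_low, cox.ci_high]}
        strata = rec.dropna(subset=["tmb_class", "delta_ctdna_pct"]).copy()
        strata["stratum"] = [
            strat.combine_strata(t, "ΔctDNA<0" if d <= 0 else "ΔctDNA>0")
            for t, d in zip(strata["tmb_class"], strata["delta_ctdna_pct"])]
        if strata["stratum"].nunique() >= 2:
            stat, p = surv.logrank_test(strata, "stratum")
            ep["tmb_ctdna_logrank"] = {"statistic": stat, "p": p}
        pga = rec.dropna(subset=["pga_class"])
        if pga["pga_class"].nunique() == 2:
            cox = surv.cox_univariate(pga, "pga_class", reference="PGA-low")
            ep["pga_high_cox"] = {"hr": cox.hazard_ratio, "p": cox.p_value}
        out[endpoint] = ep
    return out


def run_pipeline(config: CohortConfig | None = None,
                 thresholds: PipelineThresholds | None = None,
                 seed: int = 0,
                 outdir=None) -> PipelineResult:
    """Full analysis on a synthetic cohort; deterministic given the seed."""
    thresholds = thresholds or PipelineThresholds()
    cohort = generate_cohort(config, seed=seed)
    calls = sensitivity_calls(cohort)
    features = genomic_features(cohort, thresholds)
    enrich_df = mutation_enrichment(cohort, calls, thresholds)
    scores, fractions, cell_fc = immune_profiles(cohort)
    de_tables, classification, gsea = expression_dynamics(
        cohort, calls, thresholds, seed=seed)
    survival_summaries = survival_analysis(cohort, calls, features)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "n_patients": cohort.config.n_patients,
        "thresholds": asdict(thresholds),
        "landmark_months": CYCLE3_MONTHS,
        "catalog": DEFAULT_CATALOG,
    }
    result = PipelineResult(calls, features, enrich_df, scores, fractions,
                            cell_fc, de_tables, classification, gsea,
                            survival_summaries, manifest)
    if outdir is not None:
        _write_results(result, outdir)
    return result


def _write_results(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.calls.to_csv(outdir / "sensitivity_calls.csv", index=False)
    result.features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    result.immune_scores.rename_axis("sample_id").to_csv(
        outdir / "immune_scores.tsv", sep="\t")
    result.cell_fractions.rename_axis("cell_type").to_csv(
        outdir / "cell_fractions.tsv", sep="\t")
    result.cell_log2fc.rename_axis("patient_id").to_csv(
        outdir / "cell_log2fc.tsv", sep="\t")
    for label, de in result.de_tables.items():
        safe = label.replace("/", "_")
        de.to_csv(outdir / f"de_{safe}.tsv", sep="\t", index=False)
    result.drg_classification.to_csv(outdir / "drg_classification.tsv",
                                     sep="\t", index=False)
    result.gsea.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
    (outdir / "survival.json").write_text(
        json.dumps(result.survival_summaries, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
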