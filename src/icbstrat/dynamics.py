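"""Longitudinal differential expression and preranked gene-set enrichment.

Identifies differentially regulated genes (DRGs) between paired baseline and
on-treatment tumor samples separately within each sensitivity group (FDR <=
0.10), overlaps the per-group DRG lists, classifies shared genes into four
categories by direction and by which group changed more, ranks genes by the
signed metric ``-log10(p) * sign(log2FC)``, and runs preranked GSEA with
gene-label permutations (sets of 15-500 genes, 1000 permutations).

The paired test is a nonparametric stand-in for a count-model engine: per
gene, Wilcoxon signed-rank on paired log2(TPM+1) differences (exact for
n <= 25), log2FC = mean paired difference, BH correction within group.
Externally produced per-gene (p, log2FC) tables are accepted everywhere
downstream of :func:`paired_de`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

DRG_FDR = 0.10
GSEA_MIN_SIZE = 15
GSEA_MAX_SIZE = 500
GSEA_N_PERM = 1000
GSEA_FDR = 0.10
MIN_MEAN_COUNT = 10.0

DRG_CATEGORIES = (
    "up_both_higher_in_A",
    "up_both_higher_in_B",
    "down_both_more_in_B",
    "down_both_more_in_A",
)


def paired_de(
    log_tpm: pd.DataFrame,
    pairs: list[tuple[str, str]],
    counts: pd.DataFrame | None = None,
    min_mean_count: float = MIN_MEAN_COUNT,
) -> pd.DataFrame:
    """Paired baseline vs on-treatment differential expression for one group.

    ``log_tpm`` is genes x samples on the log2(TPM+1) scale; *pairs* lists
    (baseline_sample, on_treatment_sample) per patient.  Genes whose mean raw
    count across the paired samples (from *counts*, same layout) is below
    *min_mean_count* are excluded before testing.  Returns a frame with gene,
    log2_fold_change, p_value, q_value.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete sample pairs")
    base_cols = [b for b, _ in pairs]
    on_cols = [o for _, o in pairs]
    genes = log_tpm.index
    if counts is not None:
        mean_counts = counts[base_cols + on_cols].mean(axis=1)
        genes = genes[mean_counts.reindex(genes).to_numpy() >= min_mean_count]
    diffs = (
        log_tpm.loc[genes, on_cols].to_numpy()
        - log_tpm.loc[genes, base_cols].to_numpy()
    )
    n_pairs = diffs.shape[1]
    mode = "exact" if n_pairs <= 25 else "approx"
    rows = []
    for gene, d in zip(genes, diffs):
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(
                stats.wilcoxon(d, zero_method="wilcox", mode=mode).pvalue
            )
        rows.append((gene, float(d.mean()), p))
    out = pd.DataFrame(rows, columns=["gene", "log2_fold_change", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out


def select_drgs(results: pd.DataFrame, fdr: float = DRG_FDR) -> pd.DataFrame:
    """Treatment-responsive genes at FDR <= *fdr*, with direction recorded."""
    hits = results[results["q_value"] <= fdr].copy()
    hits["direction"] = np.where(hits["log2_fold_change"] > 0, "up", "down")
    return hits.reset_index(drop=True)


def overlap_and_classify(
    drgs_a: pd.DataFrame,
    drgs_b: pd.DataFrame,
    changes_a: pd.DataFrame,
    changes_b: pd.DataFrame,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Shared DRGs classified into four direction/magnitude categories.

    *changes_a/b* are genes x patients matrices of paired log2 changes per
    group.  A shared gene with concordant direction in both groups falls in
    one of four categories from the sign of its median change and the sign of
    (median change in A - median change in B); discordant genes are labelled
    ``discordant`` and excluded from the four categories.
    """
    shared = sorted(set(drgs_a["gene"]) & set(drgs_b["gene"]))
    rows = []
    for gene in shared:
        med_a = float(np.median(changes_a.loc[gene]))
        med_b = float(np.median(changes_b.loc[gene]))
        delta = med_a - med_b
        if med_a > 0 and med_b > 0:
            cat = (
                f"up_both_higher_in_{label_a}"
                if delta > 0
                else f"up_both_higher_in_{label_b}"
            )
        elif med_a < 0 and med_b < 0:
            # "more" down = more negative median change
            cat = (
                f"down_both_more_in_{label_b}"
                if delta > 0
                else f"down_both_more_in_{label_a}"
            )
        else:
            cat = "discordant"
        rows.append((gene, med_a, med_b, delta, cat))
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            f"median_change_{label_a}",
            f"median_change_{label_b}",
            "delta_median_change",
            "category",
        ],
    )


def rank_metric(p_value: float, log2fc: float) -> float:
    """Signed ranking score ``-log10(p) * sign(log2FC)``; 0 when log2FC is 0."""
    p = max(float(p_value), np.finfo(float).tiny)
    if not 0 < p <= 1:
        raise ValueError(f"p-value out of (0, 1]: {p_value}")
    if log2fc == 0:
        return 0.0
    return -np.log10(p) * (1.0 if log2fc > 0 else -1.0)


def ranked_list(de_table: pd.DataFrame) -> pd.Series:
    """Gene ranking from a DE table (gene, p_value, log2_fold_change).

    Sorted by decreasing metric; zero-metric genes sort after all non-zero
    entries, tie-broken by gene identifier for determinism.
    """
    metrics = de_table.apply(
        lambda r: rank_metric(r["p_value"], r["log2_fold_change"]), axis=1
    )
    s = pd.Series(metrics.to_numpy(), index=de_table["gene"].to_numpy())
    if s.index.has_duplicates:
        raise ValueError("duplicate genes in the ranking")
    order = sorted(
        s.index, key=lambda g: (s[g] == 0, -abs(s[g]) if s[g] == 0 else -s[g], g)
    )
    return s.loc[order]


def enrichment_score(metric: np.ndarray, hit_mask: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    *metric* must already be sorted in ranking order.  Hits advance the sum by
    ``|metric|`` (normalized over in-set total); misses retreat by
    ``1/(N - k)``.  ES is the running sum's maximum deviation from zero.
    """
    n = metric.shape[0]
    k = int(hit_mask.sum())
    if k == 0 or k == n:
        raise ValueError("degenerate gene set for ES")
    w = np.abs(metric) * hit_mask
    total = w.sum()
    if total == 0:  # all-hit metrics are 0: fall back to unweighted steps
        w = hit_mask.astype(float)
        total = w.sum()
    steps = w / total - (~hit_mask) / (n - k)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    min_size: int = GSEA_MIN_SIZE,
    max_size: int = GSEA_MAX_SIZE,
    n_perm: int = GSEA_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutations.

    *ranking* maps gene -> metric, sorted by decreasing metric.  Sets are
    filtered to [min_size, max_size] members after intersecting with the
    ranking.  The permutation p-value uses the add-one estimator over random
    same-size gene sets, one-sided on the side of the observed ES's sign;
    q-values are BH across the tested sets.
    """
    if ranking.index.has_duplicates:
        raise ValueError("duplicate genes in the ranking")
    rng = np.random.default_rng(seed)
    metric = ranking.to_numpy(dtype=float)
    index = pd.Index(ranking.index)
    n = len(index)
    rows = []
    skipped = []
    for name in sorted(gene_sets):
        positions = index.get_indexer_for(
            [g for g in gene_sets[name] if g in index]
        )
        k = len(positions)
        if not (min_size <= k <= max_size):
            skipped.append(name)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[positions] = True
        es = enrichment_score(metric, mask)
        null = np.empty(n_perm)
        for b in range(n_perm):
            pm = np.zeros(n, dtype=bool)
            pm[rng.choice(n, size=k, replace=False)] = True
            null[b] = enrichment_score(metric, pm)
        # add-one estimator over permutations on the observed ES's side
        if es >= 0:
            same_side = null[null >= 0]
            p = (1 + np.sum(same_side >= es)) / (1 + same_side.size)
        else:
            same_side = null[null < 0]
            p = (1 + np.sum(same_side <= es)) / (1 + same_side.size)
        rows.append((name, k, es, float(p), "up" if es >= 0 else "down"))
    out = pd.DataFrame(rows, columns=["gene_set", "size", "es", "p_value", "direction"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out.attrs["skipped"] = skipped
    return out
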