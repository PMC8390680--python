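"""Differential mutation-frequency analysis against a weighted background.

Candidate genes are those recurrently mutated in at least ``min_frac`` (default
25%) of one sensitivity group and at most ``max_frac`` (default 5%) of the
other, counting non-synonymous somatic events and pathogenic germline
mutations.  Each candidate is then tested for occurrence above a
cancer-type-weighted background mutation rate (TCGA-style table) with a
Fisher exact test and Benjamini-Hochberg FDR control over the candidate list.

The background contingency is built as a pseudo-cohort: the enriched group's
(mutated, unmutated) counts against ``(round(rate * N), N - round(rate * N))``
for an effective background size N (default 1000); an exact one-sample
binomial test is available as an alternative construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomics import NONSYNONYMOUS_CLASSES

DEFAULT_MIN_FRAC = 0.25
DEFAULT_MAX_FRAC = 0.05
DEFAULT_BACKGROUND_N = 1000
SIGNIFICANCE_Q = 0.05


@dataclass
class EnrichmentResult:
    gene: str
    enriched_in: str
    count_in: int
    n_in: int
    count_out: int
    n_out: int
    freq_in: float
    freq_out: float
    background_rate: float
    p_value: float
    q_value: float = math.nan

    @property
    def significant(self) -> bool:
        return self.q_value < SIGNIFICANCE_Q


def qualifying_mutations(muts: pd.DataFrame) -> pd.DataFrame:
    """Non-synonymous somatic events plus pathogenic germline mutations."""
    keep = muts["variant_classification"].isin(NONSYNONYMOUS_CLASSES) & muts[
        "origin"
    ].isin(["somatic", "germline_pathogenic"])
    return muts[keep]


def mutated_sample_counts(
    muts: pd.DataFrame, samples: list[str]
) -> dict[str, int]:
    """Per-gene number of samples (within *samples*) carrying >=1 qualifying record."""
    m = qualifying_mutations(muts)
    m = m[muts_sample_mask(m, samples)]
    return m.groupby("gene")["sample_id"].nunique().to_dict()


def muts_sample_mask(muts: pd.DataFrame, samples: list[str]) -> pd.Series:
    return muts["sample_id"].isin(set(samples))


def select_candidates(
    muts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    min_frac: float = DEFAULT_MIN_FRAC,
    max_frac: float = DEFAULT_MAX_FRAC,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Genes at >= min_frac in one group and <= max_frac in the other.

    The fractional thresholds act on counts: recurrent means
    ``count >= ceil(min_frac * n)``, rare means ``count <= floor(max_frac * n)``
    (so with n=19 and 25%/5%, >=5 carriers versus <=0).  Returns a frame with
    gene, enriched_in, count_in/n_in, count_out/n_out, freq_in, freq_out.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    counts_a = mutated_sample_counts(muts, group_a)
    counts_b = mutated_sample_counts(muts, group_b)
    na, nb = len(group_a), len(group_b)
    min_a, max_a = math.ceil(min_frac * na), math.floor(max_frac * na)
    min_b, max_b = math.ceil(min_frac * nb), math.floor(max_frac * nb)
    rows = []
    for gene in sorted(set(counts_a) | set(counts_b)):
        ca = counts_a.get(gene, 0)
        cb = counts_b.get(gene, 0)
        if ca >= min_a and cb <= max_b:
            rows.append((gene, label_a, ca, na, cb, nb))
        elif cb >= min_b and ca <= max_a:
            rows.append((gene, label_b, cb, nb, ca, na))
    df = pd.DataFrame(
        rows,
        columns=["gene", "enriched_in", "count_in", "n_in", "count_out", "n_out"],
    )
    df["freq_in"] = df["count_in"] / df["n_in"]
    df["freq_out"] = df["count_out"] / df["n_out"]
    return df


def weighted_background_rate(
    gene: str,
    background: pd.DataFrame,
    cohort_weights: dict[str, float],
) -> float:
    """Cohort-composition-weighted background mutation rate for one gene.

    ``background`` has columns cancer_type, gene, rate; *cohort_weights* maps
    each cancer type in the study cohort to its share (must sum to 1).
    """
    total = sum(cohort_weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"cohort weights must sum to 1, got {total}")
    sub = background[background["gene"] == gene]
    rates = dict(zip(sub["cancer_type"], sub["rate"]))
    missing = [c for c in cohort_weights if c not in rates]
    if missing:
        raise KeyError(
            f"gene {gene!r} has no background rate for cancer types {missing}"
        )
    return sum(w * rates[c] for c, w in cohort_weights.items())


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> float:
    """Fisher exact p for the table ``[[a, b], [c, d]]``.

    Two-sided p sums hypergeometric probabilities (margins fixed) of tables no
    more probable than the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_enrichment(
    candidates: pd.DataFrame,
    background: pd.DataFrame,
    cohort_weights: dict[str, float],
    background_n: int = DEFAULT_BACKGROUND_N,
    test: str = "fisher",
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Test each candidate gene's frequency against its weighted background rate.

    ``test='fisher'`` builds the pseudo-cohort 2x2 described in the module
    docstring; ``test='binomial'`` uses an exact one-sample binomial test of
    the in-group count against the background rate.  q-values are BH-adjusted
    across the candidate list only.
    """
    if background_n <= 0:
        raise ValueError("effective background N must be positive")
    results: list[EnrichmentResult] = []
    for row in candidates.itertuples(index=False):
        rate = weighted_background_rate(row.gene, background, cohort_weights)
        if test == "fisher":
            bg_mut = round(rate * background_n)
            p = fisher_exact_2x2(
                row.count_in,
                row.n_in - row.count_in,
                bg_mut,
                background_n - bg_mut,
                alternative=alternative,
            )
        elif test == "binomial":
            p = float(
                stats.binomtest(
                    row.count_in, row.n_in, rate, alternative="greater"
                ).pvalue
            )
        else:
            raise ValueError(f"unknown test: {test}")
        results.append(
            EnrichmentResult(
                gene=row.gene,
                enriched_in=row.enriched_in,
                count_in=row.count_in,
                n_in=row.n_in,
                count_out=row.count_out,
                n_out=row.n_out,
                freq_in=row.freq_in,
                freq_out=row.freq_out,
                background_rate=rate,
                p_value=p,
            )
        )
    if results:
        qs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = [
        "gene", "enriched_in", "count_in", "n_in", "count_out", "n_out",
        "freq_in", "freq_out", "background_rate", "p_value", "q_value",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)
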