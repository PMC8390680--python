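"""Per-sample genomic biomarkers from mutation tables and copy-number segments.

Covers tumor mutation burden (TMB, non-synonymous somatic mutations per Mb of
covered sequence), percent genome altered (PGA, percent of segmented genome
with non-diploid total copy number), segment- and gene-level copy-number
status (LOH = total CN 1; gain = total CN > ploidy + 2), alteration-catalog
frequencies, and COSMIC-style mutational-signature exposures by non-negative
least squares over the 96 trinucleotide contexts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

#: variant classes counted as non-synonymous for TMB and enrichment analyses
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "nonstop",
        "translation_start_site",
        "splice_site",
        "in_frame_indel",
        "frameshift_indel",
    }
)

VARIANT_CLASSES = NONSYNONYMOUS_CLASSES | {"silent", "other"}

TMB_HIGH_THRESHOLD = 10.0  # mut/Mb
MIN_CELLULARITY = 0.20  # samples below this are excluded from CN analyses


@dataclass(frozen=True)
class CopyNumberSegment:
    """One allele-specific copy-number segment (1-based inclusive bp)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    cn_total: int
    cn_minor: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end < start: {self}")
        if self.cn_minor > self.cn_total or self.cn_total < 0 or self.cn_minor < 0:
            raise ValueError(f"invalid copy numbers: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def is_nonsynonymous(variant_classification: str) -> bool:
    return variant_classification in NONSYNONYMOUS_CLASSES


def compute_tmb(muts: pd.DataFrame, covered_mb: float) -> float:
    """TMB for one sample: non-synonymous somatic mutations per covered Mb.

    ``muts`` has columns variant_classification and origin; silent variants and
    germline records are excluded before counting.
    """
    if covered_mb <= 0:
        raise ValueError(f"covered_mb must be > 0, got {covered_mb}")
    if len(muts) == 0:
        return 0.0
    bad = set(muts["variant_classification"]) - VARIANT_CLASSES
    if bad:
        raise ValueError(f"unknown variant classifications: {sorted(bad)}")
    keep = muts["variant_classification"].isin(NONSYNONYMOUS_CLASSES) & (
        muts["origin"] == "somatic"
    )
    return float(keep.sum()) / covered_mb


def classify_tmb(tmb: float, threshold: float = TMB_HIGH_THRESHOLD) -> str:
    """``TMB-high`` iff tmb >= 10 mut/Mb (FDA pan-cancer criterion)."""
    if tmb < 0:
        raise ValueError("TMB cannot be negative")
    return "TMB-high" if tmb >= threshold else "TMB-low"


def compute_pga(segments: list[CopyNumberSegment]) -> float:
    """Percent of covered genome with non-diploid total copy number.

    Denominator is the summed length of the sample's segments (exome
    segmentation never tiles the whole genome); returns NaN for no segments.
    """
    if not segments:
        return float("nan")
    _check_non_overlapping(segments)
    total = sum(s.length for s in segments)
    altered = sum(s.length for s in segments if s.cn_total != 2)
    return 100.0 * altered / total


def _check_non_overlapping(segments: list[CopyNumberSegment]) -> None:
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def call_segment_status(segment: CopyNumberSegment, ploidy: float) -> list[str]:
    """Status flags for one segment given tumor ploidy.

    LOH is total CN = 1 (co-labelled single_copy_loss); gain is total
    CN strictly greater than ploidy + 2; total CN 0 is homozygous_loss.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    cn = segment.cn_total
    if cn == 0:
        return ["homozygous_loss"]
    if cn == 1:
        return ["LOH", "single_copy_loss"]
    if cn > ploidy + 2:
        return ["gain"]
    return ["neutral"]


def gene_copy_status(
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    segments: list[CopyNumberSegment],
    ploidy: float,
    rule: str = "any_overlap",
) -> list[str] | None:
    """Gene-level status from the segment(s) overlapping the gene interval.

    With the default ``any_overlap`` rule the gene carries every non-neutral
    flag of any overlapping segment (conservative, deterministic); with
    ``majority_base`` it inherits the status of the segment covering the most
    gene bases.  Returns None when no segment covers the gene (missing, not
    negative).
    """
    hits = [
        s
        for s in segments
        if s.chromosome == gene_chrom and s.start <= gene_end and s.end >= gene_start
    ]
    if not hits:
        return None
    if rule == "any_overlap":
        flags: list[str] = []
        for s in hits:
            for f in call_segment_status(s, ploidy):
                if f != "neutral" and f not in flags:
                    flags.append(f)
        return flags if flags else ["neutral"]
    if rule == "majority_base":
        best = max(
            hits,
            key=lambda s: min(s.end, gene_end) - max(s.start, gene_start) + 1,
        )
        return call_segment_status(best, ploidy)
    raise ValueError(f"unknown rule: {rule}")


def filter_by_cellularity(
    purity: pd.DataFrame, min_cellularity: float = MIN_CELLULARITY
) -> pd.DataFrame:
    """Drop samples below the cellularity floor from copy-number analyses.

    ``purity`` has columns sample_id, cellularity, ploidy.
    """
    return purity[purity["cellularity"] >= min_cellularity].reset_index(drop=True)


def catalog_alteration_frequencies(
    muts: pd.DataFrame,
    catalog: list[str],
    samples: list[str],
    nonsynonymous_only: bool = True,
    include_germline_pathogenic: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Per-gene and any-gene alteration frequencies over a sample set.

    Returns ``(per_gene, any_gene_fraction)`` where ``per_gene`` has columns
    gene, n_altered, n_samples, frequency (sorted by descending frequency) and
    the fraction is the share of samples with at least one altered catalog
    gene.  A record qualifies if it is a non-synonymous somatic event or (by
    default) a pathogenic germline mutation.
    """
    n = len(samples)
    if n == 0:
        raise ValueError("empty sample set")
    sample_set = set(samples)
    m = muts[muts["sample_id"].isin(sample_set)]
    if nonsynonymous_only:
        qualifying = m["variant_classification"].isin(NONSYNONYMOUS_CLASSES)
        if include_germline_pathogenic:
            qualifying &= m["origin"].isin(["somatic", "germline_pathogenic"])
        else:
            qualifying &= m["origin"] == "somatic"
        m = m[qualifying]
    rows = []
    hit_samples: set[str] = set()
    for gene in catalog:
        carriers = set(m.loc[m["gene"] == gene, "sample_id"])
        hit_samples |= carriers
        rows.append(
            {
                "gene": gene,
                "n_altered": len(carriers),
                "n_samples": n,
                "frequency": len(carriers) / n,
            }
        )
    per_gene = (
        pd.DataFrame(rows, columns=["gene", "n_altered", "n_samples", "frequency"])
        .sort_values(["frequency", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return per_gene, len(hit_samples) / n


@dataclass
class SignatureExposure:
    sample_id: str
    weights: np.ndarray  # raw NNLS weights, >= 0
    normalized: np.ndarray  # weights / sum (zeros if all-zero)
    residual: float


def fit_signatures(
    context_counts: np.ndarray,
    signature_matrix: np.ndarray,
    sample_id: str = "",
) -> SignatureExposure:
    """Mutational-signature exposures by non-negative least squares.

    Solves ``argmin_w ||counts - M w||_2, w >= 0`` over the 96 trinucleotide
    context counts; exposures are reported raw and normalized to sum 1.
    """
    counts = np.asarray(context_counts, dtype=float)
    M = np.asarray(signature_matrix, dtype=float)
    if counts.ndim != 1 or M.ndim != 2 or M.shape[0] != counts.shape[0]:
        raise ValueError("counts must be a vector matching the matrix rows")
    if (counts < 0).any():
        raise ValueError("context counts must be non-negative")
    if (M < 0).any():
        raise ValueError("signature matrix must be non-negative")
    if not counts.any():
        warnings.warn(f"all-zero context counts for sample {sample_id!r}")
        z = np.zeros(M.shape[1])
        return SignatureExposure(sample_id, z, z.copy(), 0.0)
    w, resid = nnls(M, counts)
    total = w.sum()
    norm = w / total if total > 0 else np.zeros_like(w)
    return SignatureExposure(sample_id, w, norm, float(resid))


def tertile_threshold(values: np.ndarray) -> float:
    """Upper-tertile cutoff (66.67th percentile, linear interpolation)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least 3 finite values for a tertile split")
    return float(np.percentile(v, 100 * 2 / 3, method="linear"))


def classify_pga(pga_values: pd.Series) -> pd.Series:
    """``PGA-high`` iff strictly above the cohort upper tertile."""
    cut = tertile_threshold(pga_values.to_numpy())
    return pga_values.gt(cut).map({True: "PGA-high", False: "PGA-low"})
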