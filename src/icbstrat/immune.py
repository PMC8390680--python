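"""Gene-expression immune scores and reference-based cell-type deconvolution.

Implements single-sample gene-set enrichment (ssGSEA) for immune-infiltration
(IM) and interferon-gamma (IFNG) signatures, the cytolytic activity score
(CYT, geometric mean of GZMA and PRF1 in TPM), constrained-regression
deconvolution of bulk expression onto an LM22-style cell-type reference with
absolute scaling, and on-treatment log2 fold changes of cell scores with a
median-baseline fallback for patients lacking a baseline sample.

The ssGSEA score for one sample ranks all genes by expression and accumulates
the difference between a weighted in-set empirical CDF (weights
``|rank|^alpha``, alpha = 0.25) and the unweighted out-of-set ECDF over the
ranked positions; normalization divides all sample scores by the cross-sample
(max - min) range.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SSGSEA_ALPHA = 0.25
CYT_OFFSET = 0.01  # TPM pseudo-offset for the geometric mean
CELL_SCORE_EPS = 1e-3  # log2 pseudocount for absolute cell scores


def ssgsea_sample(values: np.ndarray, in_set: np.ndarray, alpha: float = SSGSEA_ALPHA) -> float:
    """Unnormalized ssGSEA score for one sample.

    *values* are the sample's expression values over the gene universe;
    *in_set* is a boolean membership mask.  Genes are ranked by decreasing
    expression; the rank statistic is the gene's rank position counted from
    the bottom (lowest expression = 1), so the score depends on expression
    only through the ordering.
    """
    n = values.shape[0]
    k = int(in_set.sum())
    if k < 1:
        raise ValueError("gene set does not intersect the universe")
    if k == n:
        raise ValueError("gene set equals the whole universe")
    order = np.argsort(-values, kind="stable")  # descending expression
    mask = in_set[order]
    # rank value: n for the top gene down to 1 for the bottom gene
    rank_values = np.arange(n, 0, -1, dtype=float)
    w = np.abs(rank_values) ** alpha
    w_in = np.where(mask, w, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    cdf_out = np.cumsum(~mask) / (n - k)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    alpha: float = SSGSEA_ALPHA,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample ssGSEA scores for one gene set.

    ``expr`` is genes x samples.  Genes absent from the matrix are dropped;
    an empty intersection yields all-NaN scores with a warning.  With
    *normalize* the scores are divided by the cross-sample (max - min) range.
    """
    members = [g for g in gene_set if g in expr.index]
    if not members:
        warnings.warn("gene set has no genes in the expression matrix")
        return pd.Series(np.nan, index=expr.columns)
    in_set = expr.index.isin(members)
    values = expr.to_numpy(dtype=float)
    scores = np.array(
        [ssgsea_sample(values[:, j], in_set, alpha) for j in range(values.shape[1])]
    )
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return pd.Series(scores, index=expr.columns)


def cytolytic_score(expr: pd.DataFrame, offset: float = CYT_OFFSET) -> pd.Series:
    """CYT per sample: geometric mean of (GZMA + offset) and (PRF1 + offset), TPM."""
    for g in ("GZMA", "PRF1"):
        if g not in expr.index:
            warnings.warn(f"{g} absent; CYT score undefined")
            return pd.Series(np.nan, index=expr.columns)
    gzma = expr.loc["GZMA"].astype(float) + offset
    prf1 = expr.loc["PRF1"].astype(float) + offset
    return np.sqrt(gzma * prf1)


def deconvolve(
    expr: pd.DataFrame,
    reference: pd.DataFrame,
    min_gene_overlap: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type composition of bulk samples by non-negative least squares.

    ``reference`` is genes x cell types (non-negative signature matrix).
    Returns ``(fractions, absolute)``: relative fractions per sample summing
    to 1, and absolute scores = fraction x (median expression of reference
    genes in the sample / median of the reference matrix), an overall
    immune-content scaling.
    """
    shared = reference.index.intersection(expr.index)
    if len(shared) < min_gene_overlap * reference.shape[0]:
        raise ValueError(
            f"only {len(shared)}/{reference.shape[0]} reference genes present "
            "in the expression matrix"
        )
    R = reference.loc[shared].to_numpy(dtype=float)
    X = expr.loc[shared].to_numpy(dtype=float)
    ref_median = np.median(R[R > 0]) if (R > 0).any() else 1.0
    fracs = np.zeros((reference.shape[1], expr.shape[1]))
    absolute = np.zeros_like(fracs)
    for j in range(X.shape[1]):
        try:
            w, _ = nnls(R, X[:, j])
        except RuntimeError:  # degenerate reference
            warnings.warn("NNLS failed; falling back to clipped pseudo-inverse")
            w = np.clip(np.linalg.pinv(R) @ X[:, j], 0, None)
        total = w.sum()
        f = w / total if total > 0 else np.full(w.shape, 1.0 / w.size)
        fracs[:, j] = f
        sample_median = np.median(X[:, j])
        absolute[:, j] = f * (sample_median / ref_median)
    cols = expr.columns
    types = reference.columns
    return (
        pd.DataFrame(fracs, index=types, columns=cols),
        pd.DataFrame(absolute, index=types, columns=cols),
    )


def cell_score_log2fc(
    scores: pd.DataFrame,
    sample_meta: pd.DataFrame,
    eps: float = CELL_SCORE_EPS,
) -> pd.DataFrame:
    """Per-patient, per-cell-type on-treatment change in absolute cell score.

    ``scores`` is cell types x samples; ``sample_meta`` has columns sample_id,
    patient_id, timepoint ('baseline' or 'on_treatment').  Paired patients use
    ``log2(on + eps) - log2(base + eps)``; patients without a baseline sample
    fall back to the median of all baseline samples per cell type.  Returns
    patients x cell types.
    """
    meta = sample_meta.set_index("sample_id")
    base_cols = meta.index[meta["timepoint"] == "baseline"].intersection(scores.columns)
    on_cols = meta.index[meta["timepoint"] == "on_treatment"].intersection(scores.columns)
    if len(base_cols) == 0:
        raise ValueError("no baseline samples in the cohort")
    base_median = scores[base_cols].median(axis=1)
    rows = {}
    for s in on_cols:
        pid = meta.loc[s, "patient_id"]
        patient_base = [c for c in base_cols if meta.loc[c, "patient_id"] == pid]
        ref = scores[patient_base[0]] if patient_base else base_median
        rows[pid] = np.log2(scores[s] + eps) - np.log2(ref + eps)
    return pd.DataFrame(rows).T


def tertile_high_split(values: pd.Series) -> pd.Series:
    """Boolean high/low labels: high iff strictly above the 66.67th percentile."""
    v = values.to_numpy(dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 3:
        raise ValueError("need at least 3 finite values")
    cut = np.percentile(finite, 100 * 2 / 3, method="linear")
    return values > cut


def aggregate_cell_types(
    scores: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Sum member cell-type scores into coarser groups (e.g. all T-cell subsets)."""
    rows = {}
    for name, members in groups.items():
        present = [m for m in members if m in scores.index]
        if present:
            rows[name] = scores.loc[present].sum(axis=0)
    return pd.DataFrame(rows).T
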