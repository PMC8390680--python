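# Methods

## Sensitivity classification

ΔctDNA is the percent change in mean tumor molecules per mL plasma between
baseline and the on-treatment draw (cycle 3 preferred, cycle 2 otherwise —
the 6–7-week window); ΔTM is the percent change in the target-lesion sum
between baseline and week 9. An *increase* is strictly greater than zero;
an exact zero change is grouped with decrease, because a quantity that did
not move has not increased. The four sign combinations map to LS/HS/MSPP/
MSER; a missing component yields UNCLASSIFIED rather than a silent drop.

Two degenerate cases are resolved explicitly. A baseline ctDNA of exactly
0 leaves the percent change undefined, but the increase/no-increase rule
still applies: any on-treatment signal is an increase (classified, with the
magnitude flagged undefined); 0 → 0 stays unclassified. ΔTM requires a
positive baseline lesion sum by construction.

Clinical benefit is CR, PR, or SD sustained for more than 18 weeks (six
3-week cycles). The HS/CB comparison group used by the enrichment and
expression analyses is "HS or clinical benefit"; its complement in those
analyses is LS without benefit, keeping the two groups disjoint.

## Genomic features

**TMB** counts somatic records in the non-synonymous classes (missense,
nonsense, nonstop, translation start site, splice site, in-frame and
frameshift indels) divided by covered megabases; silent and germline
records are excluded. High is ≥ 10 mut/Mb (the pan-cancer companion-
diagnostic cutoff), inclusive at the boundary.

**PGA** is the percent of *segmented* bases with total copy number ≠ 2.
The denominator is the summed segment length, not the nominal genome,
because exome segmentation never tiles the full genome; with the synthetic
generator's toy genome (22 autosomes, exactly 3,000 Mb) the two coincide.
PGA is invariant to splitting a segment into adjacent halves. PGA-high is
the upper cohort tertile (strictly above the 66.67th percentile, linear
interpolation).

**Copy-number status** per segment: LOH iff total CN = 1 (co-labelled
single-copy loss), homozygous loss iff 0, gain iff CN > ploidy + 2, else
neutral. The LOH rule is total-CN-based by default; an allele-aware variant
(minor CN = 0) would flag copy-neutral LOH as well and is deliberately not
the default, keeping the call conservative. Gene-level status uses the
*any-overlap* rule — a gene inherits every non-neutral flag of any
overlapping segment — which is deterministic and conservative for loss
calls; a majority-base rule is available. A gene covered by no segment is
*missing*, not negative. Samples with cellularity < 20% are excluded from
all copy-number outputs.

**Signature exposures** solve min‖c − Mw‖₂ s.t. w ≥ 0 over the 96
trinucleotide-context counts (scipy NNLS); exposures are reported raw and
sum-normalized. All-zero counts yield a zero exposure with a warning rather
than an error.

## Mutation enrichment

Candidates are genes altered (non-synonymous somatic or pathogenic
germline) in at least 25% of one group and at most 5% of the other, with
the fractions applied to counts as ceil/floor respectively — so 5 of 19
qualifies (26%) while the other group may carry at most ⌊0.05·n⌋ carriers.
This count arithmetic matches the worked frequencies the procedure is
designed around.

Each candidate is tested against a cancer-type-weighted background rate
Σ_c w_c·rate(c, g), with cohort-composition weights. The test's
contingency construction is not uniquely determined by "Fisher exact test
against a background rate"; the default builds a pseudo-cohort of effective
size N = 1000 with round(rate·N) background carriers and runs the standard
two-sided Fisher test; an exact one-sample binomial test (greater) is
available behind a flag, and both report their construction in the result
metadata. Benjamini–Hochberg correction is applied within the candidate
list only, since only selected genes are tested.

## Immune profiling

**ssGSEA** ranks each sample's genes by expression; walking down the
ranking, the score accumulates (weighted in-set ECDF − out-of-set ECDF) per
position, with in-set weights |rank|^α, α = 0.25, where the rank statistic
is the position counted from the bottom. The score therefore depends on
expression only through the ordering (invariant to per-sample monotone
transforms). Normalization divides all sample scores by the cross-sample
max − min range (GSVA-compatible convention). A set equal to the whole
universe is rejected (the out-of-set ECDF is undefined).

**CYT** is the geometric mean of GZMA and PRF1 in TPM with a 0.01 offset
(the score's original convention), configurable.

**Deconvolution** replaces ν-SVR with NNLS of each bulk sample onto the
reference columns: deterministic, dependency-light, and recoverable on
synthetic mixtures. Relative fractions are the normalized weights (simplex
by construction); the absolute score scales fractions by (median expression
of reference genes in the sample) / (median of the reference matrix) as an
overall immune-content factor. Cell-score changes are
log₂(on + ε) − log₂(base + ε) with ε = 10⁻³ (absolute scores can be 0);
patients without a baseline sample use the cohort-wide per-cell-type
baseline median. Cell-type aggregation (when coarser groups are wanted)
sums member scores under a configurable map.

## Expression dynamics

The per-group differential test is a deliberate nonparametric stand-in for
a count-model engine: genes with mean raw count < 10 are dropped, then each
gene's paired log₂(TPM+1) differences get an exact (n ≤ 25) Wilcoxon
signed-rank test, log₂FC = mean paired difference, BH within group. The
module equally accepts externally produced per-gene (p, log₂FC) tables, so
a negative-binomial GLM engine can be plugged in unchanged. A
between-group interaction test is not implemented; between-group
differences of paired changes stand in for it, and are labelled as such.

DRGs are genes at FDR ≤ 0.10 within a group. Shared DRGs (the
intersection across groups) are classified by the sign of their median
paired change per group and the sign of the between-group difference of
medians into four categories (up in both/higher in A, up in both/higher in
B, down in both/more in B, down in both/more in A); genes with discordant
directions are reported separately rather than forced into a category.

The ranking metric is −log₁₀(p)·sign(log₂FC); p = 0 is clamped to the
smallest positive double, log₂FC = 0 maps to metric 0 and sorts after all
non-zero entries, tie-broken by gene identifier for determinism.

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (weight
exponent 1, |ES| ≤ 1 under the normalization used) on sets of 15–500 genes
after intersection. Significance comes from seeded gene-label permutations
(1000 by default): the add-one estimator over permutations on the observed
ES's side of zero, which is calibrated (approximately uniform under a null
ranking) where a both-sides count would be anti-conservative by half. BH is
applied across tested sets; FDR < 0.10 is reported significant.

## Survival

Kaplan–Meier, log-rank, and univariate Cox go through lifelines. Ties use
Efron's method in Cox and the standard hypergeometric variance in the
log-rank statistic — common defaults, documented rather than inferred.
Landmark analyses re-origin time at cycle 3 (42 days ≈ 1.38 months) and
exclude patients without follow-up beyond it. Complete separation in Cox is
reported as an effectively unbounded hazard ratio with a warning, not an
error. The default reporting threshold for significance is p ≤ 0.10,
configurable; all tests are two-sided by default with sidedness an explicit
argument.

## Synthetic cohort generator

The generator's defaults encode the study conditions the pipeline targets:
71 evaluable patients over five cancer cohorts; sensitivity mix
45/22.5/22.5/10% (LS/HS/MSPP/MSER, allocated by largest remainder so a
trial-sized run reproduces 32:16:16:7 exactly); exponential survival with
per-month OS hazards 0.12/0.10/0.05/0.025 (LS/MSER/MSPP/HS) and PFS hazards
ordered so MSPP has longer OS but shorter PFS than MSER; uniform censoring
on [0, 36] months; HS mean TMB ≈ 7.7 vs ≈ 1.0–1.5 mut/Mb elsewhere; B2M
LOH probability 0.5 (LS) to 0.0 (HS); group-mean PGA 0.45 (LS) down to 0.10
(HS).

Per-patient (ΔctDNA, ΔTM) pairs are drawn from truncated normals restricted
to the group's quadrant — magnitudes are a modelling choice (the source
trial publishes quadrant proportions, not per-patient values) — which
makes label recovery a construction guarantee, not a statistical event.
Baseline MTM and lesion sums are log-normal; on-treatment values are
back-computed from the drawn deltas.

Mutations: catalog genes are Bernoulli draws at a synthetic TCGA-style
cancer-type × gene background table (TP53 high, others low), with
enrichment-spec overrides (rate inside the named group, rate elsewhere);
passenger burden is Poisson at the group TMB rate × covered Mb, plus silent
passengers at 0.3/Mb. Copy number: each of the 22 toy autosomes (3,000 Mb
total, exact) splits into 3 segments at random breakpoints; each segment
goes non-diploid (CN 1 or 3) with the group's target PGA fraction, so
expected PGA equals the parameter; the B2M segment is forced to CN 1 or
diploid by an exact Bernoulli flag. Expression: bulk TPM = reference ×
Dirichlet proportions with multiplicative log-normal noise exp(N(0, σ));
the reference has exclusive marker blocks per cell type plus GZMA/PRF1; IM
and IFNG signatures are disjoint halves of the first (immune) cell type's
marker block, so both track the same immune content and correlate
positively, as the real scores do; HS baselines are immune-skewed
(Dirichlet α boosted on the immune type) with signature genes shifted up
one log₂ unit; the last 20 genes are planted treatment-induced (log₂FC 2 in
HS on-treatment, half elsewhere when configured). Raw counts are Poisson at
TPM × 30 so the mean-count filter is exercised.

All randomness flows from one root seed through named substreams (CRC-32 of
the stream name), so each generator is reproducible in isolation and runs
are bit-identical per seed.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: realistic trinucleotide spectra, subclonality and
purity-driven signal attenuation, batch effects, RECIST measurement error,
informative censoring, correlated gene-gene backgrounds, and reference
mismatch in deconvolution. Recovery results here demonstrate correctness
of the machinery under the stated model, not clinical performance.

## Problem sizes and numerical choices

Simulation-backed checks run at desk scale chosen for stable statistics:
quadrant recovery at n = 400; Cox recovery at n = 500 (±3 SE criterion);
deconvolution at 50 samples, σ = 0.1; enrichment power/null calibration at
200 replicates (group n = 20, planted rate 0.5 vs background 0.02); GSEA
null calibration at 100 replicates × 199 permutations on a 200-gene
universe. Percentiles use linear interpolation; tertile splits are strict
(>). Ties in rankings break on gene identifier. BED input is 0-based
half-open and converted once, at the reader, to the 1-based inclusive
coordinates used internally and in SEG tables.

## Known limitations

- The paired Wilcoxon stand-in is less powerful than a count-model GLM at
  small n and ignores dispersion sharing across genes.
- The enrichment test's pseudo-cohort construction treats the background
  rate as known; uncertainty in the background is not propagated.
- Gene-level copy-number calls ignore intra-gene breakpoint structure
  beyond the any-overlap/majority-base choice.
- Absolute deconvolution scores are a median-ratio heuristic, not a
  calibrated cell count.
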