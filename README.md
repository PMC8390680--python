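# icbstrat

Early-dynamics stratification and immunogenomic biomarker analysis for
immune-checkpoint-blockade (ICB) cohorts.

Patients on anti-PD-1 therapy respond heterogeneously, and neither tumor
mutation burden nor PD-L1 staining predicts benefit reliably across cancer
types. A practical alternative is to classify patients early on treatment by
the *joint* direction of two dynamic measurements: the percent change from
baseline in circulating tumor DNA (ΔctDNA, quantified as mean tumor
molecules per mL plasma at treatment cycle 2–3) and the percent change in
the sum of RECIST target-lesion diameters (ΔTM, at week 9). The four sign
quadrants define molecular-sensitivity groups:

| ΔctDNA | ΔTM | group | reading |
|---|---|---|---|
| > 0 | > 0 | LS   | low sensitivity |
| ≤ 0 | ≤ 0 | HS   | high sensitivity |
| ≤ 0 | > 0 | MSPP | mixed — potential pseudoprogression |
| > 0 | ≤ 0 | MSER | mixed — emerging resistance |

`icbstrat` implements this classifier and the analysis battery built around
it, for statisticians and computational biologists working with
longitudinal ICB trial data:

- **Genomic features** — tumor mutation burden
  (TMB = non-synonymous somatic mutations / covered Mb, high iff ≥ 10),
  percent genome altered (PGA = % of segmented genome with total copy
  number ≠ 2), segment and gene-level copy-number status
  (LOH: CN<sub>t</sub> = 1; gain: CN<sub>t</sub> > ploidy + 2), alteration-catalog
  frequencies, and COSMIC-style signature exposures by NNLS over the 96
  trinucleotide contexts.
- **Mutation enrichment** — candidate genes mutated in ≥ 25% of one
  sensitivity group and ≤ 5% of the other, tested by Fisher's exact test
  against a cancer-type-weighted background rate with Benjamini–Hochberg
  FDR control.
- **Immune profiling** — ssGSEA immune-infiltration (IM) and
  interferon-gamma (IFNG) signature scores, the cytolytic score
  CYT = √((GZMA + 0.01)(PRF1 + 0.01)) in TPM, NNLS cell-type deconvolution
  against an LM22-style reference, and on-treatment log₂ cell-score changes
  with a median-baseline fallback for unpaired patients.
- **Expression dynamics** — paired differential expression per group,
  differentially regulated gene (DRG) selection at FDR ≤ 0.10, cross-group
  overlap with four-way direction/magnitude classification, the signed
  ranking metric −log₁₀(p)·sign(log₂FC), and preranked GSEA
  (sets of 15–500 genes, permutation p-values).
- **Survival** — Kaplan–Meier, log-rank, univariate Cox (Efron ties), and
  landmark analyses from treatment cycle 3, applied to every
  stratification (sensitivity groups, TMB × ΔctDNA, PGA tertiles,
  immune-score splits).
- **Synthetic cohorts** — a generator producing every input table
  (clinical, ctDNA, lesions, MAF, SEG, expression) with known ground truth,
  so the full pipeline is testable without access-restricted patient data.

## Worked example

```python
from icbstrat.pipeline import run_pipeline

r = run_pipeline(seed=1)          # 71-patient synthetic cohort
print(r.calls["group"].value_counts().to_dict())
os = r.survival_summaries["OS"]
print("OS log-rank p:", round(os["sensitivity_logrank"]["p"], 6))
print("OS HR (HS vs LS):", round(os["hs_vs_ls_cox"]["hr"], 3))
```

prints

```
{'LS': 32, 'HS': 16, 'MSPP': 16, 'MSER': 7}
OS log-rank p: 3e-06
OS HR (HS vs LS): 0.152
```

i.e. the classifier reproduces the configured 45/22.5/22.5/10% group mix
exactly (its quadrant construction guarantees label recovery), the four
groups separate in landmarked overall survival, and the high-sensitivity
group's hazard is a fraction of the low-sensitivity group's, as planted by
the generator's exponential hazards. `r.enrichment`, `r.immune_scores`,
`r.drg_classification` and `r.gsea` hold the remaining stage outputs; the
planted treatment-induced gene set, for instance, is recovered by preranked
GSEA with a strongly positive enrichment score:

```
         gene_set  size        es  p_value  q_value
TREATMENT_INDUCED    20  0.996454 0.004149 0.004149
```

The same stages are available from the shell:

```
icbstrat simulate --seed 1 --out cohort/
icbstrat stratify --cohort cohort/ --out calls.csv
icbstrat run-all --seed 1 --out results/
```

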