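"""Readers and writers for the on-disk formats.

Tabular inputs are plain TSV/CSV with documented headers; mutations travel as
MAF-style TSV (Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification,
Mutation_Status), copy number as SEG-style TSV plus a purity/ploidy table,
gene sets as GMT, gene coordinates as BED (0-based half-open on disk,
converted to 1-based inclusive here and nowhere else).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

# internal variant class <-> canonical MAF Variant_Classification
_MAF_CLASS = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "nonstop": "Nonstop_Mutation",
    "translation_start_site": "Translation_Start_Site",
    "splice_site": "Splice_Site",
    "in_frame_indel": "In_Frame_Del",
    "frameshift_indel": "Frame_Shift_Del",
    "silent": "Silent",
    "other": "Other",
}
_FROM_MAF_CLASS = {v: k for k, v in _MAF_CLASS.items()}
_FROM_MAF_CLASS.update({"In_Frame_Ins": "in_frame_indel",
                        "Frame_Shift_Ins": "frameshift_indel"})

_MAF_STATUS = {"somatic": "Somatic", "germline_pathogenic": "Germline"}
_FROM_MAF_STATUS = {v: k for k, v in _MAF_STATUS.items()}

MAF_REQUIRED = ["Hugo_Symbol", "Tumor_Sample_Barcode",
                "Variant_Classification", "Mutation_Status"]


class ParseError(ValueError):
    """Malformed input line; message names file, line, and field."""


def write_maf(muts: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": muts["gene"],
            "Tumor_Sample_Barcode": muts["sample_id"],
            "Variant_Classification": muts["variant_classification"].map(_MAF_CLASS),
            "Mutation_Status": muts["origin"].map(_MAF_STATUS),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing MAF columns {missing}")
    for i, vc in enumerate(df["Variant_Classification"]):
        if vc not in _FROM_MAF_CLASS:
            raise ParseError(
                f"{path}: line {i + 2}: unknown Variant_Classification {vc!r}")
    for i, st in enumerate(df["Mutation_Status"]):
        if st not in _FROM_MAF_STATUS:
            raise ParseError(
                f"{path}: line {i + 2}: unknown Mutation_Status {st!r}")
    return pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "gene": df["Hugo_Symbol"],
            "variant_classification": df["Variant_Classification"].map(
                _FROM_MAF_CLASS),
            "origin": df["Mutation_Status"].map(_FROM_MAF_STATUS),
        }
    )


SEG_COLUMNS = ["sample_id", "chromosome", "start", "end", "cn_total", "cn_minor"]


def write_seg(segments: pd.DataFrame, path) -> None:
    segments[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing SEG columns {missing}")
    for col in ("start", "end", "cn_total", "cn_minor"):
        df[col] = df[col].astype(int)
    bad = df[df["end"] < df["start"]]
    if len(bad):
        raise ParseError(
            f"{path}: line {bad.index[0] + 2}: segment end < start")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            tokens = line.split("\t")
            if len(tokens) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description, "
                    "and at least one gene")
            sets[tokens[0]] = tokens[2:]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive gene coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tokens = line.split("\t")
            if len(tokens) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: BED needs chrom, start, end, name")
            chrom, start, end, name = tokens[:4]
            rows.append((name, chrom, int(start) + 1, int(end)))
    return pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression values")
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene identifiers")
    return df


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write every table of a synthetic cohort; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _csv(name, df):
        p = outdir / name
        df.to_csv(p, index=False)
        paths[name.split(".")[0]] = str(p)

    _csv("clinical.csv", cohort.clinical)
    _csv("ctdna.csv", cohort.ctdna)
    _csv("lesions.csv", cohort.lesions)
    _csv("survival.csv", cohort.survival)
    write_maf(cohort.mutations, outdir / "mutations.maf.tsv")
    paths["mutations"] = str(outdir / "mutations.maf.tsv")
    cohort.coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    paths["coverage"] = str(outdir / "coverage.tsv")
    write_seg(cohort.segments, outdir / "segments.seg.tsv")
    paths["segments"] = str(outdir / "segments.seg.tsv")
    cohort.purity.to_csv(outdir / "purity.tsv", sep="\t", index=False)
    paths["purity"] = str(outdir / "purity.tsv")
    write_expression(cohort.expression_tpm, outdir / "expression_tpm.tsv")
    paths["expression_tpm"] = str(outdir / "expression_tpm.tsv")
    write_expression(cohort.expression_counts, outdir / "expression_counts.tsv")
    paths["expression_counts"] = str(outdir / "expression_counts.tsv")
    cohort.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
    paths["sample_meta"] = str(outdir / "sample_meta.tsv")
    write_expression(cohort.reference, outdir / "reference.tsv")
    paths["reference"] = str(outdir / "reference.tsv")
    cohort.background.to_csv(outdir / "background_rates.tsv", sep="\t",
                             index=False)
    paths["background_rates"] = str(outdir / "background_rates.tsv")
    truth = {
        "groups": cohort.truth.groups,
        "enriched_genes": cohort.truth.enriched_genes,
        "b2m_loh": cohort.truth.b2m_loh,
        "pga_fraction": cohort.truth.pga_fraction,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths


def read_cohort_tables(indir) -> dict:
    """Read back the tables written by :func:`write_cohort`, with
    cross-file sample/patient consistency checks."""
    indir = Path(indir)
    tables = {
        "clinical": pd.read_csv(indir / "clinical.csv"),
        "ctdna": pd.read_csv(indir / "ctdna.csv"),
        "lesions": pd.read_csv(indir / "lesions.csv"),
        "survival": pd.read_csv(indir / "survival.csv"),
        "mutations": read_maf(indir / "mutations.maf.tsv"),
        "coverage": pd.read_csv(indir / "coverage.tsv", sep="\t"),
        "segments": read_seg(indir / "segments.seg.tsv"),
        "purity": pd.read_csv(indir / "purity.tsv", sep="\t"),
        "expression_tpm": read_expression(indir / "expression_tpm.tsv"),
        "expression_counts": read_expression(indir / "expression_counts.tsv"),
        "sample_meta": pd.read_csv(indir / "sample_meta.tsv", sep="\t"),
        "reference": pd.read_csv(indir / "reference.tsv", sep="\t", index_col=0),
        "background": pd.read_csv(indir / "background_rates.tsv", sep="\t"),
    }
    gt = indir / "ground_truth.json"
    if gt.exists():
        tables["ground_truth"] = json.loads(gt.read_text())
    patients = set(tables["clinical"]["patient_id"])
    for name, col in (("ctdna", "patient_id"), ("lesions", "patient_id"),
                      ("survival", "patient_id"), ("mutations", "sample_id"),
                      ("segments", "sample_id")):
        unknown = set(tables[name][col]) - patients
        if unknown:
            raise ParseError(
                f"{name}: unknown sample/patient ids {sorted(unknown)[:5]}")
    meta = tables["sample_meta"]
    unknown = set(meta["patient_id"]) - patients
    if unknown:
        raise ParseError(f"sample_meta: unknown patients {sorted(unknown)[:5]}")
    expr_unknown = set(tables["expression_tpm"].columns) - set(meta["sample_id"])
    if expr_unknown:
        raise ParseError(
            f"expression: samples without metadata {sorted(expr_unknown)[:5]}")
    return tables


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
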