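"""Readers and writers for the plain-text formats the pipeline exchanges.

VCF 4.2 is handled through pysam (uncompressed for diff-ability); tables
are tab-separated pandas frames.  Copy-number ratio files follow the
Control-FREEC ``ratio.txt`` dialect (columns Chromosome, Start, Ratio,
MedianRatio, CopyNumber; a MedianRatio of -1 encodes missing).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .germline import GERMLINE_COLUMNS
from .presence import SomaticVariant, VariantKey
from .signatures import CHANNELS

_CONTIG_LENGTH = 250_000_000


def _header(contigs: Iterable[str], lines: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig, length=_CONTIG_LENGTH)
    for line in lines:
        header.add_line(line)
    return header


def _sorted_contigs(names: Iterable[str]) -> list[str]:
    def key(name: str):
        return (0, int(name)) if name.isdigit() else (1, name)

    return sorted(set(names), key=key)


# ---------------------------------------------------------------------------
# somatic calls

_SOMATIC_INFO = (
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">',
    '##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Reference trinucleotide context">',
)


def write_somatic_vcf(variants: Sequence[SomaticVariant], path) -> None:
    header = _header(_sorted_contigs(v.chrom for v in variants), _SOMATIC_INFO)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.key[0], v.key[1], v.key[2], v.key[3])):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.effect:
                rec.info["EFFECT"] = v.effect
            if v.context:
                rec.info["CONTEXT"] = v.context
            out.write(rec)


def read_somatic_vcf(path) -> list[SomaticVariant]:
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            variants.append(
                SomaticVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=rec.info.get("GENE", ""),
                    effect=rec.info.get("EFFECT", "other"),
                    context=rec.info.get("CONTEXT", ""),
                )
            )
    return variants


# ---------------------------------------------------------------------------
# candidate sites and pileups

def write_candidates_tsv(keys: Iterable[VariantKey], path) -> None:
    frame = pd.DataFrame(sorted(keys), columns=["chrom", "pos", "ref", "alt"])
    frame.to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> set[VariantKey]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (row.chrom, int(row.pos), row.ref, row.alt)
        for row in frame.itertuples(index=False)
    }


def write_pileups_tsv(pileups: pd.DataFrame, path) -> None:
    cols = ["sample", "chrom", "pos", "ref", "alt", "depth", "alt_count"]
    pileups[cols].to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


# ---------------------------------------------------------------------------
# germline replicates

_GERMLINE_LINES = (
    '##FILTER=<ID=LowConf,Description="Low-confidence call">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=EXONIC,Number=0,Type=Flag,Description="Variant falls in an exon">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted impact">',
    '##INFO=<ID=AF_WES,Number=1,Type=Float,Description="Population AF from exomes">',
    '##INFO=<ID=AF_GENOME,Number=1,Type=Float,Description="Population AF from genomes">',
    '##INFO=<ID=CLINVAR,Number=1,Type=String,Description="ClinVar annotation passthrough">',
)


def write_germline_vcf(records: pd.DataFrame, path) -> None:
    """Write a germline record table (``GERMLINE_COLUMNS`` schema) as VCF 4.2."""
    header = _header(_sorted_contigs(records["chrom"].astype(str)), _GERMLINE_LINES)
    ordered = records.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in ordered.itertuples(index=False):
            alts = tuple(str(row.alt).split(","))
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                alleles=(str(row.ref),) + alts,
            )
            rec.qual = float(row.qual)
            rec.filter.add(str(row.filter))
            rec.info["DP"] = int(row.depth)
            if bool(row.exonic):
                rec.info["EXONIC"] = True
            if isinstance(row.gene, str) and row.gene:
                rec.info["GENE"] = row.gene
            if isinstance(row.impact, str) and row.impact:
                rec.info["IMPACT"] = row.impact
            if pd.notna(row.af_wes):
                rec.info["AF_WES"] = float(row.af_wes)
            if pd.notna(row.af_genome):
                rec.info["AF_GENOME"] = float(row.af_genome)
            if isinstance(row.clinvar, str) and row.clinvar:
                rec.info["CLINVAR"] = row.clinvar
            out.write(rec)


def read_germline_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter)
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": ",".join(rec.alts or ()),
                    "filter": filters[0] if filters else ".",
                    "qual": float(rec.qual) if rec.qual is not None else 0.0,
                    "depth": int(rec.info.get("DP", 0)),
                    "exonic": bool(rec.info.get("EXONIC", False)),
                    "gene": rec.info.get("GENE", ""),
                    "impact": rec.info.get("IMPACT", ""),
                    "af_wes": float(rec.info["AF_WES"]) if "AF_WES" in rec.info else np.nan,
                    "af_genome": float(rec.info["AF_GENOME"]) if "AF_GENOME" in rec.info else np.nan,
                    "clinvar": rec.info.get("CLINVAR", ""),
                }
            )
    return pd.DataFrame(rows, columns=GERMLINE_COLUMNS)


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# signature matrices (COSMIC v2 tab-separated layout)

def write_signature_matrix(signatures: pd.DataFrame, path) -> None:
    out = signatures.copy()
    out.index.name = "Somatic Mutation Type"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_signature_matrix(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    label_col = None
    for cand in ("Somatic Mutation Type", frame.columns[0]):
        if cand in frame.columns and frame[cand].astype(str).str.contains(r"\[").all():
            label_col = cand
            break
    if label_col is None:
        raise ValueError("no channel-label column (e.g. 'A[C>A]A') found")
    frame = frame.set_index(label_col)
    frame = frame.drop(columns=[c for c in ("Substitution Type", "Trinucleotide") if c in frame.columns])
    missing = set(CHANNELS) - set(frame.index)
    if missing:
        raise ValueError(f"signature matrix lacks {len(missing)} channels")
    return frame.loc[list(CHANNELS)].astype(float)


# ---------------------------------------------------------------------------
# expression, fractions, copy-number ratios

def write_matrix_tsv(matrix: pd.DataFrame, path, index_name: str = "gene") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_series_tsv(series: pd.Series, path, index_name: str, value_name: str) -> None:
    frame = series.rename(value_name).to_frame()
    frame.index.name = index_name
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_series_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0]


def write_ratio_profile(profile: pd.Series, path) -> None:
    """Write a (chrom, start)-indexed median-ratio profile as ratio.txt.

    Missing values are encoded as MedianRatio -1; Ratio repeats the median
    and CopyNumber is the rounded ``2 * ratio`` diploid equivalent.
    """
    frame = profile.rename("MedianRatio").reset_index()
    frame.columns = ["Chromosome", "Start", "MedianRatio"]
    filled = frame["MedianRatio"].fillna(-1.0)
    frame["Ratio"] = filled
    frame["MedianRatio"] = filled
    copy_number = np.rint(2.0 * filled).astype(int).clip(lower=0)
    copy_number[filled < 0] = -1
    frame["CopyNumber"] = copy_number
    frame = frame[["Chromosome", "Start", "Ratio", "MedianRatio", "CopyNumber"]]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ratio_profile(path) -> pd.Series:
    """Read a Control-FREEC-style ratio file into a (chrom, start) series."""
    frame = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    values = frame["MedianRatio"].astype(float).where(frame["MedianRatio"] >= 0, np.nan)
    index = pd.MultiIndex.from_arrays(
        [frame["Chromosome"], frame["Start"].astype(int)], names=["chrom", "start"]
    )
    return pd.Series(values.to_numpy(), index=index, name="MedianRatio")
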