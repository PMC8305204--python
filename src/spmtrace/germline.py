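"""Replicate-aware germline predisposition filter cascade.

Germline variants are called independently from two replicate libraries of
the matched normal sample.  Each replicate's call table is filtered on its
own (exonic, FILTER=PASS, depth >= 8, depth <= 99% quantile of the depth
distribution, QUAL >= 20), the replicates are merged by union (a variant
seen in only one replicate is kept), multi-allelic sites are removed, and
the survivors are restricted to cancer-list genes with moderate/high
predicted impact and a Non-Finnish European population allele frequency
below 0.05 (WES frequency preferred, genome frequency as fallback, records
with neither retained).  Every stage's in/out record counts are traced.

Tables are plain pandas DataFrames with the columns of
:data:`GERMLINE_COLUMNS`; ``alt`` holds comma-joined alternate alleles so a
multi-allelic record is any row whose ``alt`` contains a comma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GERMLINE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "filter", "qual", "depth",
    "exonic", "gene", "impact", "af_wes", "af_genome", "clinvar",
]

IMPACT_LEVELS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})
DAMAGING_IMPACTS = frozenset({"HIGH", "MODERATE"})

MIN_DEPTH = 8
MIN_QUAL = 20.0
DEPTH_QUANTILE = 0.99
AF_THRESHOLD = 0.05


def empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=GERMLINE_COLUMNS)


def normalize_impact(value: object) -> str:
    """Map an annotation impact string onto the four canonical categories.

    Unknown or missing strings become ``"unknown"`` (which fails the impact
    filter).
    """
    if not isinstance(value, str):
        return "unknown"
    up = value.strip().upper()
    return up if up in IMPACT_LEVELS else "unknown"


@dataclass(frozen=True)
class FilterStage:
    name: str
    n_in: int
    n_out: int
    detail: str = ""


@dataclass
class FilterTrace:
    """Ordered per-stage audit of the cascade (records in/out, fitted cutoffs)."""

    stages: list[FilterStage]
    #: depth caps actually applied at the quantile stages, keyed by stage name
    depth_caps: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out, s.detail) for s in self.stages],
            columns=["stage", "n_in", "n_out", "detail"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def concat(cls, *traces: "FilterTrace") -> "FilterTrace":
        stages: list[FilterStage] = []
        caps: dict[str, float] = {}
        for t in traces:
            stages.extend(t.stages)
            caps.update(t.depth_caps)
        return cls(stages=stages, depth_caps=caps)


def filter_replicate(
    records: pd.DataFrame,
    *,
    min_depth: int = MIN_DEPTH,
    min_qual: float = MIN_QUAL,
    depth_quantile: float = DEPTH_QUANTILE,
    quantile_method: str = "linear",
    quantile_on_raw: bool = False,
    depth_cap: float | None = None,
    name: str = "rep",
) -> tuple[pd.DataFrame, FilterTrace]:
    """Per-replicate quality filters, applied in the canonical order.

    Stages: exonic, FILTER=PASS, depth >= ``min_depth``, depth <= the
    ``depth_quantile`` quantile of the depth distribution (records strictly
    above are removed, flagging likely paralogous pile-ups), QUAL >=
    ``min_qual``.

    The quantile is computed on the records entering that stage (i.e. after
    the preceding filters) unless ``quantile_on_raw`` is set, and uses
    ``numpy.quantile`` with the given interpolation ``method`` ("linear" or
    "nearest" for nearest-rank).  Passing an explicit ``depth_cap`` re-applies
    a previously fitted cutoff instead of re-estimating it, which makes the
    stage idempotent.
    """
    df = records
    stages: list[FilterStage] = []

    n_in = len(df)
    df = df[df["exonic"].astype(bool)]
    stages.append(FilterStage(f"{name}:exonic", n_in, len(df)))

    n_in = len(df)
    df = df[df["filter"] == "PASS"]
    stages.append(FilterStage(f"{name}:pass", n_in, len(df)))

    n_in = len(df)
    df = df[df["depth"] >= min_depth]
    stages.append(FilterStage(f"{name}:min_depth", n_in, len(df)))

    n_in = len(df)
    cap_stage = f"{name}:depth_quantile"
    if depth_cap is None:
        basis = records if quantile_on_raw else df
        if len(basis):
            depth_cap = float(
                np.quantile(basis["depth"].to_numpy(float), depth_quantile,
                            method=quantile_method)
            )
        else:
            depth_cap = float("inf")
    df = df[df["depth"] <= depth_cap]
    stages.append(FilterStage(cap_stage, n_in, len(df), detail=f"cap={depth_cap:g}"))

    n_in = len(df)
    df = df[df["qual"] >= min_qual]
    stages.append(FilterStage(f"{name}:qual", n_in, len(df)))

    return df.reset_index(drop=True), FilterTrace(stages=stages, depth_caps={cap_stage: depth_cap})


def merge_replicates(
    rep1: pd.DataFrame, rep2: pd.DataFrame
) -> tuple[pd.DataFrame, FilterTrace]:
    """Union-merge two filtered replicate tables and drop multi-allelic sites.

    Records are keyed on (chrom, pos, ref, alt); a key present in both
    replicates keeps rep1's annotation (a differing rep2 annotation is
    logged).  Multi-allelic removal drops records carrying more than one
    alternate allele and, after the union, every record at a position where
    more than one distinct alternate allele is observed.  A ``provenance``
    column records rep1/rep2/both.
    """
    a = rep1.copy()
    a["provenance"] = "rep1"
    b = rep2.copy()
    b["provenance"] = "rep2"
    frames = [f for f in (a, b) if not f.empty]  # avoid all-NA concat dtype churn
    both = pd.concat(frames, ignore_index=True) if frames else a.iloc[0:0]
    n_in = len(both)

    key_cols = ["chrom", "pos", "ref", "alt"]
    dup_keys = both.duplicated(subset=key_cols, keep=False)
    annot_cols = ["gene", "impact", "exonic"]
    if dup_keys.any():
        for _, grp in both[dup_keys].groupby(key_cols, sort=False):
            if len(grp) > 1 and not (grp[annot_cols].nunique(dropna=False) <= 1).all():
                first = grp.iloc[0]
                logger.warning(
                    "conflicting annotations at %s:%s %s>%s; keeping rep1's",
                    first["chrom"], first["pos"], first["ref"], first["alt"],
                )
    merged = both.drop_duplicates(subset=key_cols, keep="first").copy()
    in_both = both[both["provenance"] == "rep2"].set_index(key_cols).index
    merged.loc[
        merged.set_index(key_cols).index.isin(in_both)
        & (merged["provenance"] == "rep1"),
        "provenance",
    ] = "both"
    union_stage = FilterStage("merge:union", n_in, len(merged))

    n_in = len(merged)
    multi_record = merged["alt"].astype(str).str.contains(",")
    merged = merged[~multi_record]
    alleles_per_site = merged.groupby(["chrom", "pos"])["alt"].transform("nunique")
    merged = merged[alleles_per_site <= 1].reset_index(drop=True)
    multi_stage = FilterStage("merge:multiallelic", n_in, len(merged))

    return merged, FilterTrace(stages=[union_stage, multi_stage], depth_caps={})


def annotate_and_restrict(
    records: pd.DataFrame, cancer_genes: Sequence[str]
) -> pd.DataFrame:
    """Keep records in cancer-list genes with MODERATE or HIGH impact.

    Gene matching is exact on upper-cased symbols.
    """
    genes = {g.strip().upper() for g in cancer_genes if g.strip()}
    if not genes:
        logger.warning("empty cancer-gene list: all records removed")
        return records.iloc[0:0].reset_index(drop=True)
    impact = records["impact"].map(normalize_impact)
    keep = (
        records["gene"].astype(str).str.upper().isin(genes)
        & impact.isin(DAMAGING_IMPACTS)
    )
    return records[keep].reset_index(drop=True)


def population_af_filter(
    records: pd.DataFrame, threshold: float = AF_THRESHOLD
) -> pd.DataFrame:
    """Remove records common in the reference population (effective AF >= threshold).

    The effective allele frequency is the WES-based value when present and
    the genome-based value otherwise; records with neither are retained
    (absence of evidence of commonness) and logged.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    eff = records["af_wes"].astype(float)
    eff = eff.where(eff.notna(), records["af_genome"].astype(float))
    n_missing = int(eff.isna().sum())
    if n_missing:
        logger.info("%d records with no population AF retained", n_missing)
    keep = eff.isna() | (eff < threshold)
    return records[keep].reset_index(drop=True)


def run_cascade(
    rep1_raw: pd.DataFrame,
    rep2_raw: pd.DataFrame,
    cancer_genes: Sequence[str],
    *,
    af_threshold: float = AF_THRESHOLD,
    min_depth: int = MIN_DEPTH,
    min_qual: float = MIN_QUAL,
    depth_quantile: float = DEPTH_QUANTILE,
    quantile_method: str = "linear",
    quantile_on_raw: bool = False,
    depth_caps: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, FilterTrace]:
    """Full cascade: per-replicate filters, union merge, gene/impact, population AF.

    ``depth_caps`` (keyed ``rep1:depth_quantile`` / ``rep2:depth_quantile``)
    re-applies quantile cutoffs recorded in a previous trace; without it the
    cutoffs are estimated from the input replicates.
    """
    depth_caps = depth_caps or {}
    kwargs = dict(
        min_depth=min_depth, min_qual=min_qual, depth_quantile=depth_quantile,
        quantile_method=quantile_method, quantile_on_raw=quantile_on_raw,
    )
    f1, t1 = filter_replicate(
        rep1_raw, name="rep1", depth_cap=depth_caps.get("rep1:depth_quantile"), **kwargs
    )
    f2, t2 = filter_replicate(
        rep2_raw, name="rep2", depth_cap=depth_caps.get("rep2:depth_quantile"), **kwargs
    )
    merged, tm = merge_replicates(f1, f2)

    n_in = len(merged)
    restricted = annotate_and_restrict(merged, cancer_genes)
    tg = FilterTrace(
        stages=[FilterStage("cancer_gene_impact", n_in, len(restricted))], depth_caps={}
    )

    n_in = len(restricted)
    final = population_af_filter(restricted, threshold=af_threshold)
    ta = FilterTrace(
        stages=[FilterStage("population_af", n_in, len(final))], depth_caps={}
    )

    return final, FilterTrace.concat(t1, t2, tm, tg, ta)
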