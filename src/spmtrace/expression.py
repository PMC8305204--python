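"""RPKM normalisation, tumour-overexpression calling, clustering, immune summaries.

Expression is normalised within-sample to RPKM (reads per kilobase of
transcript per million mapped reads).  A gene counts as overexpressed in a
tumour sample when its RPKM is above ``min_rpkm`` (strictly) and at least
``fold`` times the median RPKM of an unrelated normal-tissue cohort.  For
visualisation-style clustering, rows are standardised to Z-scores and both
genes and samples are agglomerated by complete linkage on Euclidean
distance.  Immune-deconvolution fraction tables are summarised per sample
into the total immune fraction, the M1/M2 macrophage ratio, and the
immunosuppressive percentage 100 * (Treg + M2) / total immune.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

MIN_RPKM = 10.0
FOLD = 10.0

#: canonical deconvolution cell-type columns (quanTIseq naming); "Other"
#: is the uncharacterised, non-immune remainder.
CELL_TYPES = (
    "B.cells",
    "Macrophages.M1",
    "Macrophages.M2",
    "Monocytes",
    "Neutrophils",
    "NK.cells",
    "T.cells.CD4",
    "T.cells.CD8",
    "Tregs",
    "Dendritic.cells",
    "Other",
)
IMMUNE_TYPES = tuple(t for t in CELL_TYPES if t != "Other")


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    mapped_totals: pd.Series,
) -> pd.DataFrame:
    """RPKM = count / (length/1000) / (mapped_total/1e6), per gene and sample.

    ``counts`` is genes x samples; ``lengths`` is per-gene transcript length
    in bases; ``mapped_totals`` is per-sample mapped-read totals.
    """
    lengths = lengths.reindex(counts.index)
    mapped_totals = mapped_totals.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if mapped_totals.isna().any() or (mapped_totals <= 0).any():
        raise ValueError("every sample needs a positive mapped-read total")
    kb = lengths.to_numpy(float) / 1e3
    millions = mapped_totals.to_numpy(float) / 1e6
    values = counts.to_numpy(float) / kb[:, None] / millions[None, :]
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def call_overexpressed(
    tumour: pd.DataFrame,
    normals: pd.DataFrame,
    *,
    min_rpkm: float = MIN_RPKM,
    fold: float = FOLD,
) -> dict[str, set[str]]:
    """Per-sample overexpressed gene sets against a normal cohort.

    Gene ``g`` is overexpressed in tumour sample ``s`` iff
    ``tumour[g, s] > min_rpkm`` and ``tumour[g, s] >= fold * median over
    normals of g``.  The comparison runs on the intersection of gene
    universes; an empty intersection or an empty normal cohort is rejected.
    A normal median of 0 makes any tumour value above ``min_rpkm`` qualify
    (any fold over zero); such genes are logged.
    """
    if normals.shape[1] < 1:
        raise ValueError("need at least one normal sample")
    genes = tumour.index.intersection(normals.index)
    if len(genes) == 0:
        raise ValueError("tumour and normal matrices share no genes")
    t = tumour.loc[genes]
    med = normals.loc[genes].median(axis=1)
    zero_med = med == 0
    if zero_med.any():
        logger.info("%d genes have zero normal-cohort median", int(zero_med.sum()))
    over = t.gt(min_rpkm) & t.ge(fold * med, axis=0)
    return {s: set(genes[over[s].to_numpy(bool)]) for s in tumour.columns}


def overexpressed_union(calls: Mapping[str, set[str]]) -> set[str]:
    """Genes overexpressed in at least one tumour sample."""
    out: set[str] = set()
    for genes in calls.values():
        out |= genes
    return out


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardise each row to mean 0, sd 1 (population sd).

    Zero-variance rows become all-zero and are logged.
    """
    values = expr.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d zero-variance rows Z-scored to 0", int(flat.sum()))
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


@dataclass
class BiClustering:
    """Row (gene) and column (sample) complete-linkage trees over Z-scores."""

    zscores: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    @property
    def row_order(self) -> list:
        return [self.zscores.index[i] for i in hierarchy.leaves_list(self.row_linkage)]

    @property
    def col_order(self) -> list:
        return [self.zscores.columns[i] for i in hierarchy.leaves_list(self.col_linkage)]

    def first_col_merge(self) -> tuple[str, str]:
        i, j = int(self.col_linkage[0, 0]), int(self.col_linkage[0, 1])
        return str(self.zscores.columns[i]), str(self.zscores.columns[j])

    def cut_columns(self, height: float) -> dict[str, int]:
        labels = hierarchy.fcluster(self.col_linkage, t=height, criterion="distance")
        return {str(s): int(l) for s, l in zip(self.zscores.columns, labels)}


def zscore_cluster(expr: pd.DataFrame) -> BiClustering:
    """Cluster genes and samples of an expression matrix.

    Rows are Z-scored, then genes (rows) and samples (columns) are each
    agglomerated with complete linkage on Euclidean distances.  SciPy's
    deterministic tie-breaking (merge-order by index) makes the leaf order
    reproducible for identical input order.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    z = zscore_rows(expr)
    row_linkage = hierarchy.linkage(pdist(z.to_numpy(float)), method="complete")
    col_linkage = hierarchy.linkage(pdist(z.to_numpy(float).T), method="complete")
    return BiClustering(zscores=z, row_linkage=row_linkage, col_linkage=col_linkage)


@dataclass
class ImmuneSummary:
    """Per-sample immune-infiltrate summary; NaN marks undefined quantities."""

    sample: str
    total_immune: float
    m1_m2_ratio: float
    immunosuppressive_pct: float


def immune_summary(fractions: pd.DataFrame) -> pd.DataFrame:
    """Summarise a deconvolution fraction table (samples x cell types).

    For each sample: ``total_immune`` sums every immune cell type (the
    "Other" remainder is not immune); ``m1_m2_ratio`` = M1 / M2 (NaN when
    M2 = 0); ``immunosuppressive_pct`` = 100 * (Tregs + M2) / total_immune
    (NaN when total immune = 0).
    """
    missing = [c for c in IMMUNE_TYPES if c not in fractions.columns]
    if missing:
        raise ValueError(f"fraction table lacks cell types: {missing}")
    vals = fractions[list(IMMUNE_TYPES)].astype(float)
    if (vals.to_numpy() < 0).any():
        raise ValueError("cell fractions must be non-negative")
    total = vals.sum(axis=1)
    m1 = vals["Macrophages.M1"]
    m2 = vals["Macrophages.M2"]
    treg = vals["Tregs"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m2 > 0, m1 / m2, np.nan)
        supp = np.where(total > 0, 100.0 * (treg + m2) / total, np.nan)
    out = pd.DataFrame(
        {
            "total_immune": total,
            "m1_m2_ratio": ratio,
            "immunosuppressive_pct": supp,
        },
        index=fractions.index,
    )
    return out
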