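"""Sample-sharing partition, recurrence-origin inference, CN-profile similarity.

Once every variant has a presence status in every sample, the distinct
non-excluded variants partition into disjoint classes by the exact subset
of samples carrying them (the Venn-diagram counts).  The recurrence's
primary tumour of origin is inferred as the primary sharing the most
variants with the recurrence; copy-number median-ratio profiles give an
orthogonal line of evidence via rank correlation and complete-linkage
clustering on 1 - rho.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .presence import PresenceMatrix, VariantKey

logger = logging.getLogger(__name__)

#: sentinel origin call when the top two primaries tie
AMBIGUOUS = "AMBIGUOUS"

#: distance assigned to profile pairs whose correlation is undefined
MAX_DISTANCE = 2.0


@dataclass
class OverlapPartition:
    """Disjoint classes of non-excluded variants keyed by carrying-sample subset."""

    classes: dict[frozenset[str], list[VariantKey]]
    n_excluded: int
    samples: tuple[str, ...]

    @property
    def counts(self) -> dict[frozenset[str], int]:
        return {subset: len(keys) for subset, keys in self.classes.items()}

    @property
    def n_variants(self) -> int:
        """Number of non-excluded distinct variants."""
        return sum(len(keys) for keys in self.classes.values())

    def count(self, *samples: str) -> int:
        """Count of variants present in exactly the given subset."""
        return len(self.classes.get(frozenset(samples), ()))

    def shared(self, a: str, b: str) -> int:
        """Variants jointly present in ``a`` and ``b`` (other samples allowed)."""
        return sum(
            len(keys)
            for subset, keys in self.classes.items()
            if a in subset and b in subset
        )

    def total_in(self, sample: str) -> int:
        """Total non-excluded variants present in ``sample``."""
        return sum(len(keys) for subset, keys in self.classes.items() if sample in subset)

    def to_records(self) -> pd.DataFrame:
        rows = [
            {"subset": "&".join(sorted(subset)), "count": len(keys)}
            for subset, keys in sorted(
                self.classes.items(), key=lambda kv: sorted(kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["subset", "count"])


def partition_overlaps(matrix: PresenceMatrix) -> OverlapPartition:
    """Partition non-excluded variants by the exact subset of carrying samples.

    Variants flagged excluded (any EXCLUDED cell) are dropped from all
    classes and only counted in ``n_excluded``.
    """
    if matrix.statuses.empty:
        raise ValueError("presence matrix is empty")
    present = matrix.present_mask()
    excluded = matrix.excluded
    classes: dict[frozenset[str], list[VariantKey]] = {}
    for key, row in present[~excluded].iterrows():
        subset = frozenset(present.columns[row.to_numpy(dtype=bool)])
        if not subset:
            # cannot happen for matrices built from call sets (every variant
            # is CALLED somewhere) but guard for hand-built matrices
            logger.warning("variant %s present in no sample; skipped", key)
            continue
        classes.setdefault(subset, []).append(key)
    return OverlapPartition(
        classes=classes,
        n_excluded=int(excluded.sum()),
        samples=tuple(matrix.samples),
    )


@dataclass
class OriginCall:
    """Ranked shared-variant evidence for the recurrence's lesion of origin."""

    recurrence: str
    shared: dict[str, int]
    best: str
    margin: int

    @property
    def is_ambiguous(self) -> bool:
        return self.best == AMBIGUOUS

    def ranked(self) -> list[tuple[str, int]]:
        return sorted(self.shared.items(), key=lambda kv: (-kv[1], kv[0]))


def infer_origin(
    partition: OverlapPartition,
    recurrence: str,
    primaries: Sequence[str],
) -> OriginCall:
    """Infer the primary of origin as the argmax of shared-variant counts.

    ``shared(p)`` counts non-excluded variants jointly present in primary
    ``p`` and the recurrence regardless of other samples.  A tie between
    the top two primaries yields :data:`AMBIGUOUS`.
    """
    if not primaries:
        raise ValueError("primary list must be non-empty")
    universe = set(partition.samples)
    missing = ({recurrence} | set(primaries)) - universe
    if missing:
        raise ValueError(f"samples not in partition universe: {sorted(missing)}")
    shared = {p: partition.shared(p, recurrence) for p in primaries}
    ranked = sorted(shared.items(), key=lambda kv: (-kv[1], kv[0]))
    top_name, top = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else 0
    margin = top - second
    best = top_name if (margin > 0 or len(ranked) == 1) else AMBIGUOUS
    return OriginCall(recurrence=recurrence, shared=shared, best=best, margin=margin)


# ---------------------------------------------------------------------------
# copy-number median-ratio profiles


def align_profiles(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Inner-join two bin-indexed profiles and drop bins missing in either."""
    joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").dropna()
    return joined["a"].to_numpy(float), joined["b"].to_numpy(float)


def profile_spearman(
    a: pd.Series, b: pd.Series, *, min_bins: int = 3
) -> float:
    """Spearman rank correlation between two median-ratio profiles.

    Bins are matched on the (chrom, start) index; bins with a missing value
    in either profile are deleted pairwise.  Returns NaN when fewer than
    ``min_bins`` shared bins remain or either side is constant.
    """
    x, y = align_profiles(a, b)
    if x.size < min_bins:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_pvalue(a: pd.Series, b: pd.Series, *, min_bins: int = 3) -> tuple[float, float]:
    """(rho, p) using the t-approximation; informational only."""
    x, y = align_profiles(a, b)
    if x.size < min_bins:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ProfileClustering:
    """Complete-linkage agglomeration of ratio profiles on distance 1 - rho."""

    labels: list[str]
    linkage: np.ndarray
    distances: pd.DataFrame = field(repr=False)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def first_merge(self) -> tuple[str, str]:
        """The two leaves joined at the lowest merge height."""
        i, j = int(self.linkage[0, 0]), int(self.linkage[0, 1])
        return self.labels[i], self.labels[j]


def cluster_profiles(
    profiles: Mapping[str, pd.Series], *, min_bins: int = 3
) -> ProfileClustering:
    """Cluster ratio profiles by complete linkage on 1 - Spearman rho.

    Pairs whose correlation is undefined (too few shared bins or constant
    input) get the maximal distance 2 and a logged warning.
    """
    labels = list(profiles)
    if len(labels) < 2:
        raise ValueError("need at least two profiles to cluster")
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rho = profile_spearman(profiles[labels[i]], profiles[labels[j]], min_bins=min_bins)
            if math.isnan(rho):
                logger.warning(
                    "undefined correlation between %s and %s; distance set to %.1f",
                    labels[i], labels[j], MAX_DISTANCE,
                )
                d = MAX_DISTANCE
            else:
                d = 1.0 - rho
            dist[i, j] = dist[j, i] = max(d, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return ProfileClustering(
        labels=labels,
        linkage=linkage,
        distances=pd.DataFrame(dist, index=labels, columns=labels),
    )
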