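"""Cross-sample presence adjudication of somatic SNVs.

A somatic SNV called in one tumour sample of a patient may be a false
negative in another sample rather than truly absent.  The adjudication
procedure therefore checks, for every variant detected in any sample and
for every other sample: (1) was it called there, (2) does it appear in
that sample's candidate-mutation-site list, and (3) failing both, what do
the aligned reads at the position say.  The read-level rescue rule is a
pure depth/VAF threshold:

* depth < 50                        -> EXCLUDED (site not assessable)
* depth >= 50 and VAF < 0.01        -> ABSENT
* depth >= 50 and VAF > 0.02        -> RESCUED_PRESENT
* depth >= 50 and 0.01 <= VAF <= 0.02 -> EXCLUDED (ambiguous band)

Both VAF inequalities are strict.  A variant with any EXCLUDED cell is
flagged and dropped from downstream overlap counting (global exclusion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Collection, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: thresholds of the read-inspection rescue rule
MIN_DEPTH = 50
VAF_ABSENT = 0.01
VAF_PRESENT = 0.02

VariantKey = tuple[str, int, str, str]


class PresenceStatus(str, Enum):
    """Adjudicated status of one variant in one sample."""

    CALLED = "CALLED"
    CANDIDATE_PRESENT = "CANDIDATE_PRESENT"
    RESCUED_PRESENT = "RESCUED_PRESENT"
    ABSENT = "ABSENT"
    EXCLUDED = "EXCLUDED"


#: statuses that count as "the variant is present in this sample"
PRESENT_STATUSES = frozenset(
    {
        PresenceStatus.CALLED,
        PresenceStatus.CANDIDATE_PRESENT,
        PresenceStatus.RESCUED_PRESENT,
    }
)


@dataclass(frozen=True, order=True)
class SomaticVariant:
    """A somatic single-nucleotide variant with optional annotation.

    ``context`` is the reference trinucleotide centred on the variant
    position (bases pos-1..pos+1); when given, its middle base must equal
    ``ref``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect: str = "other"
    context: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single bases ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.context:
            if len(self.context) != 3 or self.context[1] != self.ref:
                raise ValueError(
                    f"context {self.context!r} inconsistent with ref {self.ref!r}"
                )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def adjudicate_site(
    depth: int,
    alt_count: int,
    *,
    min_depth: int = MIN_DEPTH,
    vaf_absent: float = VAF_ABSENT,
    vaf_present: float = VAF_PRESENT,
) -> PresenceStatus:
    """Apply the depth/VAF rescue rule to one pileup observation.

    Parameters
    ----------
    depth, alt_count
        Total read depth and alternate-allele read count at the site.

    Returns
    -------
    PresenceStatus
        ABSENT, RESCUED_PRESENT, or EXCLUDED (never CALLED/CANDIDATE).
    """
    if depth < 0 or alt_count < 0:
        raise ValueError("depth and alt_count must be non-negative")
    if alt_count > depth:
        raise ValueError(f"alt_count {alt_count} exceeds depth {depth}")
    if depth < min_depth:
        return PresenceStatus.EXCLUDED
    vaf = alt_count / depth
    if vaf < vaf_absent:
        return PresenceStatus.ABSENT
    if vaf > vaf_present:
        return PresenceStatus.RESCUED_PRESENT
    return PresenceStatus.EXCLUDED


@dataclass
class PresenceMatrix:
    """Adjudicated presence of every distinct variant in every sample.

    Attributes
    ----------
    statuses
        DataFrame indexed by variant key ``(chrom, pos, ref, alt)`` with one
        column per sample holding :class:`PresenceStatus` values.
    variants
        Annotation lookup for each row key.
    """

    statuses: pd.DataFrame
    variants: dict[VariantKey, SomaticVariant] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.statuses.columns)

    @property
    def excluded(self) -> pd.Series:
        """Boolean per-variant flag: any cell EXCLUDED."""
        return (self.statuses == PresenceStatus.EXCLUDED).any(axis=1)

    def present_mask(self) -> pd.DataFrame:
        """Boolean matrix of 'present in sample' statuses."""
        return self.statuses.isin(list(PRESENT_STATUSES))

    def to_frame(self) -> pd.DataFrame:
        out = self.statuses.apply(lambda c: c.map(lambda s: PresenceStatus(s).value))
        out = out.copy()
        out["excluded"] = self.excluded
        return out

    def write_tsv(self, path) -> None:
        frame = self.to_frame().reset_index()
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        frame = frame.set_index(["chrom", "pos", "ref", "alt"])
        frame = frame.drop(columns=["excluded"], errors="ignore")
        statuses = frame.apply(lambda c: c.map(PresenceStatus))
        return cls(statuses=statuses)


def _pileup_lookup(
    pileups: pd.DataFrame | Mapping[tuple[str, VariantKey], tuple[int, int]],
) -> Mapping[tuple[str, VariantKey], tuple[int, int]]:
    if isinstance(pileups, pd.DataFrame):
        lookup: dict[tuple[str, VariantKey], tuple[int, int]] = {}
        for row in pileups.itertuples(index=False):
            key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
            lookup[(str(row.sample), key)] = (int(row.depth), int(row.alt_count))
        return lookup
    return pileups


def build_presence_matrix(
    callsets: Mapping[str, Iterable[SomaticVariant]],
    candidates: Mapping[str, Collection[VariantKey]] | None = None,
    pileups: pd.DataFrame | Mapping[tuple[str, VariantKey], tuple[int, int]] | None = None,
    *,
    min_depth: int = MIN_DEPTH,
    vaf_absent: float = VAF_ABSENT,
    vaf_present: float = VAF_PRESENT,
) -> PresenceMatrix:
    """Adjudicate every variant detected in any sample across all samples.

    For each distinct variant and each sample, the status is CALLED if the
    variant is in that sample's call set, else CANDIDATE_PRESENT if its key
    is in the sample's candidate-site list, else the outcome of
    :func:`adjudicate_site` on the sample's pileup at the site.  A missing
    pileup record yields EXCLUDED with a warning.

    The result is invariant to the order of variants within call sets;
    rows are sorted by variant key.
    """
    candidates = candidates or {}
    lookup = _pileup_lookup(pileups if pileups is not None else {})

    samples = list(callsets)
    if len(set(samples)) != len(samples):
        raise ValueError("sample identifiers must be unique")

    variants: dict[VariantKey, SomaticVariant] = {}
    called: dict[str, set[VariantKey]] = {}
    for sample, calls in callsets.items():
        keys: set[VariantKey] = set()
        for v in calls:
            keys.add(v.key)
            # keep the first annotated instance seen for a key
            variants.setdefault(v.key, v)
        called[sample] = keys

    candidate_keys = {s: set(candidates.get(s, ())) for s in samples}

    rows: dict[VariantKey, dict[str, PresenceStatus]] = {}
    for key in sorted(variants):
        row: dict[str, PresenceStatus] = {}
        for sample in samples:
            if key in called[sample]:
                row[sample] = PresenceStatus.CALLED
            elif key in candidate_keys[sample]:
                row[sample] = PresenceStatus.CANDIDATE_PRESENT
            else:
                stat = lookup.get((sample, key))
                if stat is None:
                    logger.warning(
                        "no pileup for sample %s at %s:%d %s>%s; cell EXCLUDED",
                        sample, key[0], key[1], key[2], key[3],
                    )
                    row[sample] = PresenceStatus.EXCLUDED
                else:
                    depth, alt_count = stat
                    row[sample] = adjudicate_site(
                        depth,
                        alt_count,
                        min_depth=min_depth,
                        vaf_absent=vaf_absent,
                        vaf_present=vaf_present,
                    )
        rows[key] = row

    index = pd.MultiIndex.from_tuples(sorted(rows), names=["chrom", "pos", "ref", "alt"])
    statuses = pd.DataFrame(
        [[rows[key][s] for s in samples] for key in index],
        index=index,
        columns=samples,
        dtype=object,
    )
    return PresenceMatrix(statuses=statuses, variants=variants)
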