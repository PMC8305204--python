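"""96-channel mutation catalogues and NNLS signature-exposure decomposition.

Single-base substitutions are classified into 96 channels: the six
pyrimidine-strand substitutions (C>A, C>G, C>T, T>A, T>C, T>G) times the
16 combinations of 5' and 3' flanking bases.  Variants whose reference
base is a purine are mapped onto the pyrimidine strand by reverse
complement.  A sample's catalogue (channel counts) is decomposed into
non-negative absolute exposures over a fixed column-stochastic signature
matrix by non-negative least squares, the linear-combination model behind
reference-signature fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .presence import SomaticVariant

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical channel order: substitution class major, then 5' and 3' flank
#: alphabetically — the layout of the COSMIC v2 signature tables.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
)
CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_label(ref: str, alt: str, context: str) -> str:
    """Map a substitution with trinucleotide context onto its canonical channel.

    Purine-reference substitutions are reverse-complemented first; applying
    the map to an already-pyrimidine variant is the identity.

    Raises ``ValueError`` if the context is not 3 valid bases centred on
    ``ref`` or if ``ref == alt``.
    """
    if len(context) != 3 or any(b not in COMPLEMENT for b in context):
        raise ValueError(f"invalid trinucleotide context {context!r}")
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise ValueError(f"invalid substitution {ref!r}>{alt!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} middle base != ref {ref!r}")
    if ref not in PYRIMIDINES:
        context = reverse_complement(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class CatalogVector:
    """Per-channel mutation counts for one sample."""

    sample: str
    counts: pd.Series  # indexed by CHANNELS, non-negative integers
    n_rejected: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_array(self) -> np.ndarray:
        return self.counts.to_numpy(float)


def build_catalog(
    variants: Iterable[SomaticVariant], sample: str
) -> CatalogVector:
    """Accumulate SNVs with trinucleotide contexts into a 96-channel catalogue.

    Variants without a context, or whose context middle base disagrees with
    the reference allele, are skipped with a warning and counted in
    ``n_rejected``; the catalogue total equals the number of accepted SNVs.
    """
    counts = np.zeros(96, dtype=int)
    n_rejected = 0
    for v in variants:
        try:
            label = channel_label(v.ref, v.alt, v.context)
        except ValueError as exc:
            logger.warning("variant %s:%d %s>%s skipped: %s", v.chrom, v.pos, v.ref, v.alt, exc)
            n_rejected += 1
            continue
        counts[CHANNEL_INDEX[label]] += 1
    return CatalogVector(
        sample=sample,
        counts=pd.Series(counts, index=list(CHANNELS), name=sample),
        n_rejected=n_rejected,
    )


def validate_signature_matrix(signatures: pd.DataFrame, *, tol: float = 1e-6) -> None:
    """Check COSMIC-style layout: 96 canonical rows, column-stochastic, >= 0."""
    if list(signatures.index) != list(CHANNELS):
        raise ValueError("signature matrix rows must be the 96 canonical channels in order")
    if signatures.shape[1] == 0:
        raise ValueError("signature matrix has no columns")
    vals = signatures.to_numpy(float)
    if (vals < 0).any():
        raise ValueError("signature matrix entries must be non-negative")
    colsums = vals.sum(axis=0)
    if np.max(np.abs(colsums - 1.0)) > tol:
        raise ValueError("signature columns must each sum to 1")


@dataclass
class ExposureVector:
    """Non-negative absolute exposures (mutation-count units) and fit residual."""

    sample: str
    exposures: pd.Series  # indexed by signature name
    residual: float

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    def proportions(self) -> pd.Series:
        total = self.total
        if total == 0:
            return self.exposures * 0.0
        return self.exposures / total

    def support(self) -> list[str]:
        return [name for name, e in self.exposures.items() if e > 0]


def decompose_nnls(
    catalog: CatalogVector, signatures: pd.DataFrame
) -> ExposureVector:
    """Fit ``min ||S e - c||_2 s.t. e >= 0`` by active-set NNLS.

    Deterministic (Lawson-Hanson active set, no random initialisation);
    exposures come back in absolute mutation-count units on the catalogue
    scale, with the Euclidean residual of the fit.
    """
    validate_signature_matrix(signatures)
    S = signatures.to_numpy(float)
    c = catalog.to_array()
    e, rnorm = nnls(S, c)
    return ExposureVector(
        sample=catalog.sample,
        exposures=pd.Series(e, index=list(signatures.columns), name=catalog.sample),
        residual=float(rnorm),
    )


def apply_exposure_cutoff(
    exposure: ExposureVector,
    rel_cutoff: float,
    *,
    signatures: pd.DataFrame | None = None,
    catalog: CatalogVector | None = None,
    refit: bool = False,
) -> ExposureVector:
    """Zero signatures whose exposure share is below ``rel_cutoff``.

    Without ``refit`` the surviving exposures are left unchanged; with
    ``refit`` (requires ``signatures`` and ``catalog``) NNLS is re-run on
    the surviving support, whose residual can only be >= the unrestricted
    one.
    """
    if not (0 <= rel_cutoff < 1):
        raise ValueError(f"rel_cutoff must be in [0, 1), got {rel_cutoff}")
    total = exposure.total
    keep = (
        exposure.exposures / total >= rel_cutoff
        if total > 0
        else exposure.exposures >= 0
    )
    if rel_cutoff == 0:
        keep = pd.Series(True, index=exposure.exposures.index)
    trimmed = exposure.exposures.where(keep, 0.0)
    if not refit:
        return ExposureVector(exposure.sample, trimmed, exposure.residual)
    if signatures is None or catalog is None:
        raise ValueError("refit requires the signature matrix and catalogue")
    support = [name for name, k in keep.items() if k]
    out = pd.Series(0.0, index=exposure.exposures.index, name=exposure.sample)
    if support:
        sub = decompose_nnls(catalog, signatures[support])
        out.loc[support] = sub.exposures
        residual = sub.residual
    else:
        residual = float(np.linalg.norm(catalog.to_array()))
    return ExposureVector(exposure.sample, out, residual)


def kkt_violation(
    exposure: ExposureVector, signatures: pd.DataFrame, catalog: CatalogVector
) -> float:
    """Worst violation of the NNLS optimality (KKT) conditions.

    The gradient of the objective is ``g = S^T (S e - c)``; at the optimum
    the components on the active support vanish and the rest are
    non-negative.  Returns ``max(max |g_active|, max(-g_inactive, 0))``.
    """
    S = signatures.to_numpy(float)
    e = exposure.exposures.to_numpy(float)
    g = S.T @ (S @ e - catalog.to_array())
    active = e > 0
    worst = 0.0
    if active.any():
        worst = float(np.max(np.abs(g[active])))
    if (~active).any():
        worst = max(worst, float(np.max(-g[~active], initial=0.0)))
    return worst


def block_signature_matrix(
    n_signatures: int = 5, seed: int = 0, *, jitter: tuple[float, float] = (0.5, 1.5)
) -> pd.DataFrame:
    """Generate a well-conditioned signature matrix with disjoint supports.

    The 96 channels are split into ``n_signatures`` contiguous blocks and
    each signature is a mildly jittered uniform profile over its own block,
    making the columns orthogonal (Gram-matrix condition number close to 1).
    Useful wherever decomposition accuracy should not be confounded by
    signature collinearity.
    """
    if not (1 <= n_signatures <= 96):
        raise ValueError("n_signatures must be in [1, 96]")
    rng = np.random.default_rng(seed)
    mat = np.zeros((96, n_signatures))
    for j, block in enumerate(np.array_split(np.arange(96), n_signatures)):
        profile = rng.uniform(*jitter, size=len(block))
        mat[block, j] = profile / profile.sum()
    names = [f"Signature {i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(mat, index=list(CHANNELS), columns=names)


def synthetic_signature_matrix(
    n_signatures: int = 30, seed: int = 0, *, concentration: float = 0.25
) -> pd.DataFrame:
    """Generate a COSMIC-v2-shaped synthetic signature matrix.

    Columns are independent sparse Dirichlet draws over the 96 channels
    (small ``concentration`` gives the peaked, process-like profiles real
    signatures have).  Deterministic given ``seed``; for test and
    simulation use, not a stand-in for the real reference profiles.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = np.random.default_rng(seed)
    cols = rng.gamma(concentration, 1.0, size=(96, n_signatures))
    cols = cols / cols.sum(axis=0, keepdims=True)
    names = [f"Signature {i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(cols, index=list(CHANNELS), columns=names)
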