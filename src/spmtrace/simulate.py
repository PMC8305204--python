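"""Ground-truthed synthetic patient generator.

Emulates the data shapes of a multi-omic tumour case study: a germline
background with two replicate libraries of the matched normal, three
synchronous primary tumours with disjoint or pairwise-shared somatic SNV
sets, and a recurrence inheriting a subset of one primary's mutations plus
private ones.  Observed allele counts follow a diploid heterozygous model
(expected VAF = purity / 2) with Poisson depths and a small independent
per-site error rate in non-carrying lesions; a configurable fraction of
truly carried calls is withheld from the call tables (still visible in
pileups) to exercise the cross-sample rescue path.  Expression, immune
cell-fraction, and copy-number ratio tables are generated with planted
truth so every downstream stage can be scored against known answers.

All randomness derives from a single master seed through per-component
``numpy.random.SeedSequence`` spawns, so adding or re-running one
component does not perturb the draws of the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .expression import CELL_TYPES
from .presence import SomaticVariant, VariantKey
from .signatures import (
    CHANNELS,
    COMPLEMENT,
    CatalogVector,
    reverse_complement,
    synthetic_signature_matrix,
    validate_signature_matrix,
)

_CHROMS = tuple(str(c) for c in range(1, 23))

_EFFECTS = ("non-synonymous", "synonymous", "other")
_EFFECT_PROBS = (0.6, 0.3, 0.1)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GermlineParams:
    """Germline-replicate generator settings.

    ``n_records`` is the base cohort of distinct germline variants; each is
    carried into each replicate library independently with probability
    ``1 - replicate_dropout``.  Depth is Poisson around ``mean_depth`` with
    a ``low_depth_fraction`` subpopulation of poorly covered sites, QUAL is
    gamma-distributed, population allele frequencies are Beta-distributed
    with independent missingness for the exome- and genome-derived values.
    """

    n_records: int = 20_000
    exonic_fraction: float = 0.35
    pass_fraction: float = 0.9
    multiallelic_fraction: float = 0.02
    replicate_dropout: float = 0.15
    mean_depth: float = 277.81
    low_depth_fraction: float = 0.05
    low_depth_mean: float = 4.0
    qual_shape: float = 2.0
    qual_scale: float = 30.0
    cancer_gene_fraction: float = 0.05
    n_cancer_genes: int = 300
    impact_probs: dict[str, float] = field(
        default_factory=lambda: {
            "HIGH": 0.03, "MODERATE": 0.22, "LOW": 0.35, "MODIFIER": 0.40,
        }
    )
    af_beta: tuple[float, float] = (0.2, 1.8)
    af_missing_wes: float = 0.2
    af_missing_genome: float = 0.1


@dataclass
class ExpressionParams:
    """Expression generator: planted overexpressed genes over a normal cohort."""

    n_genes: int = 2000
    n_normals: int = 42
    mapped_total_mean: float = 35.1e6
    mapped_total_sd: float = 4.06e6
    gene_length_range: tuple[int, int] = (500, 5000)
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.2
    noise_sd: float = 0.35
    uplift_range: tuple[float, float] = (1.5, 3.0)
    n_overexpressed: dict[str, int] = field(
        default_factory=lambda: {"T1": 150, "T2": 80, "T3": 150, "R1": 100}
    )
    n_overexpressed_shared_pairs: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("T2", "R1"): 120, ("T1", "T2"): 31}
    )


@dataclass
class ImmuneParams:
    """Target immune composition per sample; observed tables add Dirichlet noise."""

    total_immune: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.324, "T2": 0.352, "T3": 0.125, "R1": 0.178}
    )
    suppressive_pct: dict[str, float] = field(
        default_factory=lambda: {"T1": 53.5, "T2": 37.3, "T3": 16.4, "R1": 27.0}
    )
    m1_m2_ratio: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.66, "T2": 0.96, "T3": 2.22, "R1": 2.0}
    )
    noise_concentration: float = 5000.0


@dataclass
class CopyNumberParams:
    """Segment-wise median-ratio profiles with replicate noise."""

    n_chromosomes: int = 22
    bins_per_chrom: int = 100
    segment_switch_prob: float = 0.05
    ratio_levels: tuple[float, ...] = (0.5, 1.0, 1.0, 1.5, 2.0)
    noise_sd: float = 0.10
    missing_fraction: float = 0.02
    n_replicates: int = 2
    recurrence_divergence: float = 0.1


def _default_mixtures() -> dict[str, dict[str, float]]:
    return {
        "T1": {"Signature 16": 0.5, "Signature 1": 0.2, "Signature 13": 0.2,
               "Signature 20": 0.1},
        "T2": {"Signature 16": 0.45, "Signature 1": 0.2, "Signature 24": 0.15,
               "Signature 7": 0.1, "Signature 22": 0.1},
        "T3": {"Signature 16": 0.5, "Signature 24": 0.3, "Signature 6": 0.2},
        "R1": {"Signature 16": 0.45, "Signature 1": 0.2, "Signature 11": 0.15,
               "Signature 13": 0.1, "Signature 24": 0.1},
    }


@dataclass
class ClonalScenarioConfig:
    """Full scenario: lesion-membership classes, sequencing model, side channels.

    The defaults template the studied case: three primaries T1/T2/T3 with
    141/5/120 private somatic SNVs, two variants shared between T1 and T3,
    a recurrence R1 inheriting 120 of T2's mutations plus 97 private ones,
    purities 0.18/0.16/0.68/0.64 and ~296x mean depth.
    """

    primaries: tuple[str, ...] = ("T1", "T2", "T3")
    recurrence: str = "R1"
    origin_primary: str = "T2"
    n_private_per_primary: dict[str, int] = field(
        default_factory=lambda: {"T1": 141, "T2": 5, "T3": 120}
    )
    n_inherited: int = 120
    n_recurrence_private: int = 97
    n_shared_pairs: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("T1", "T3"): 2}
    )
    purity_per_sample: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.18, "T2": 0.16, "T3": 0.68, "R1": 0.64}
    )
    mean_depth_per_sample: dict[str, float] = field(
        default_factory=lambda: {"T1": 295.72, "T2": 295.72, "T3": 295.72, "R1": 295.72}
    )
    error_rate: float = 2e-4
    call_dropout: float = 0.10
    candidate_fraction: float = 0.5
    signature_mixture_per_sample: dict[str, dict[str, float]] = field(
        default_factory=_default_mixtures
    )
    n_signatures: int = 30
    germline: GermlineParams = field(default_factory=GermlineParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    immune: ImmuneParams = field(default_factory=ImmuneParams)
    copy_number: CopyNumberParams = field(default_factory=CopyNumberParams)
    seed: int = 0

    @property
    def samples(self) -> tuple[str, ...]:
        return self.primaries + (self.recurrence,)

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        if self.origin_primary not in self.primaries:
            raise ValueError(
                f"origin_primary {self.origin_primary!r} is not one of {self.primaries}"
            )
        counts = dict(self.n_private_per_primary)
        if set(counts) != set(self.primaries):
            raise ValueError("n_private_per_primary must cover exactly the primaries")
        for name, n in [
            *counts.items(),
            ("n_inherited", self.n_inherited),
            ("n_recurrence_private", self.n_recurrence_private),
        ]:
            if n < 0:
                raise ValueError(f"count {name} must be >= 0, got {n}")
        for pair, n in self.n_shared_pairs.items():
            if n < 0:
                raise ValueError(f"shared count for {pair} must be >= 0")
            if len(set(pair)) != 2 or not set(pair) <= set(self.primaries):
                raise ValueError(f"shared pair {pair} must be two distinct primaries")
        for s in self.samples:
            purity = self.purity_per_sample.get(s)
            if purity is None or not (0 < purity <= 1):
                raise ValueError(f"purity for {s} must be in (0, 1]")
            depth = self.mean_depth_per_sample.get(s)
            if depth is None or depth <= 0:
                raise ValueError(f"mean depth for {s} must be positive")
            mixture = self.signature_mixture_per_sample.get(s)
            if not mixture:
                raise ValueError(f"no signature mixture for sample {s}")
            weights = np.array(list(mixture.values()), float)
            if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"mixture weights for {s} must be >= 0 and sum to 1"
                )
        if not (0 <= self.call_dropout < 1):
            raise ValueError("call_dropout must be in [0, 1)")
        if not (0 <= self.candidate_fraction <= 1):
            raise ValueError("candidate_fraction must be in [0, 1]")
        if not (0 <= self.error_rate < 0.001):
            raise ValueError("error_rate must be in [0, 0.001)")


# ---------------------------------------------------------------------------
# truth + observed containers


@dataclass
class PatientTruth:
    """Everything the generator knows that the pipeline must recover."""

    membership: dict[VariantKey, frozenset[str]]
    origin: str
    mixtures: dict[str, dict[str, float]]
    expected_exposures: dict[str, dict[str, float]]
    overexpressed: dict[str, set[str]]
    germline_final_keys: set[VariantKey]
    fractions: pd.DataFrame
    cn_truth: dict[str, pd.Series]

    def carried(self, sample: str) -> set[VariantKey]:
        return {k for k, members in self.membership.items() if sample in members}


@dataclass
class SimulatedPatient:
    config: ClonalScenarioConfig
    truth: PatientTruth
    variants: dict[VariantKey, SomaticVariant]
    calls: dict[str, list[SomaticVariant]]
    candidates: dict[str, set[VariantKey]]
    pileups: pd.DataFrame
    germline_replicates: tuple[pd.DataFrame, pd.DataFrame]
    cancer_genes: list[str]
    counts: pd.DataFrame
    gene_lengths: pd.Series
    mapped_totals: pd.Series
    normal_rpkm: pd.DataFrame
    fractions: pd.DataFrame
    ratio_profiles: dict[str, dict[int, pd.Series]]
    signatures: pd.DataFrame

    def sample_profile(self, sample: str, replicate: int = 1) -> pd.Series:
        return self.ratio_profiles[sample][replicate]


# ---------------------------------------------------------------------------
# somatic component


def _channel_parts(label: str) -> tuple[str, str, str]:
    """(ref, alt, context) of a canonical channel label like 'A[C>T]G'."""
    ref, alt = label[2], label[4]
    context = label[0] + ref + label[6]
    return ref, alt, context


def _draw_sites(rng: np.random.Generator, n: int) -> list[tuple[str, int]]:
    sites: set[tuple[str, int]] = set()
    while len(sites) < n:
        chroms = rng.choice(len(_CHROMS), size=n - len(sites))
        positions = rng.integers(10_000, 240_000_000, size=n - len(sites))
        for c, p in zip(chroms, positions):
            sites.add((_CHROMS[int(c)], int(p)))
            if len(sites) == n:
                break
    ordered = sorted(sites)
    perm = rng.permutation(len(ordered))
    return [ordered[i] for i in perm]


def _simulate_somatic(
    config: ClonalScenarioConfig,
    signatures: pd.DataFrame,
    rng: np.random.Generator,
):
    classes: list[tuple[frozenset[str], int, str]] = []
    for p in config.primaries:
        classes.append((frozenset({p}), config.n_private_per_primary[p], p))
    classes.append(
        (
            frozenset({config.origin_primary, config.recurrence}),
            config.n_inherited,
            config.origin_primary,
        )
    )
    classes.append((frozenset({config.recurrence}), config.n_recurrence_private,
                    config.recurrence))
    for (a, b), n in sorted(config.n_shared_pairs.items()):
        classes.append((frozenset({a, b}), n, a))

    n_total = sum(n for _, n, _ in classes)
    sites = _draw_sites(rng, n_total)

    channel_probs = {
        s: (signatures.to_numpy(float) @ _mixture_vector(
            config.signature_mixture_per_sample[s], signatures.columns))
        for s in config.samples
    }

    membership: dict[VariantKey, frozenset[str]] = {}
    variants: dict[VariantKey, SomaticVariant] = {}
    cursor = 0
    for members, n, generator_sample in classes:
        probs = channel_probs[generator_sample]
        probs = probs / probs.sum()
        channel_ids = rng.choice(96, size=n, p=probs)
        flips = rng.random(n) < 0.5
        genes = rng.integers(0, 20_000, size=n)
        effects = rng.choice(len(_EFFECTS), size=n, p=_EFFECT_PROBS)
        for i in range(n):
            chrom, pos = sites[cursor]
            cursor += 1
            ref, alt, context = _channel_parts(CHANNELS[int(channel_ids[i])])
            if flips[i]:  # present the purine-strand representation
                ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
                context = reverse_complement(context)
            v = SomaticVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=f"GENE{int(genes[i]):05d}",
                effect=_EFFECTS[int(effects[i])],
                context=context,
            )
            membership[v.key] = members
            variants[v.key] = v

    keys = sorted(membership)
    pile_rows = []
    calls: dict[str, list[SomaticVariant]] = {s: [] for s in config.samples}
    candidates: dict[str, set[VariantKey]] = {s: set() for s in config.samples}
    for sample in config.samples:
        purity = config.purity_per_sample[sample]
        depth_mean = config.mean_depth_per_sample[sample]
        depths = rng.poisson(depth_mean, size=len(keys))
        carried = np.array([sample in membership[k] for k in keys])
        p_alt = np.where(carried, purity / 2.0, config.error_rate)
        alts = rng.binomial(depths, p_alt)
        dropped = rng.random(len(keys)) < config.call_dropout
        as_candidate = rng.random(len(keys)) < config.candidate_fraction
        for i, key in enumerate(keys):
            pile_rows.append(
                (sample, key[0], key[1], key[2], key[3], int(depths[i]), int(alts[i]))
            )
            if carried[i]:
                if not dropped[i]:
                    calls[sample].append(variants[key])
                elif as_candidate[i]:
                    candidates[sample].add(key)
    pileups = pd.DataFrame(
        pile_rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "depth", "alt_count"],
    )
    return membership, variants, calls, candidates, pileups


def _mixture_vector(mixture: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    unknown = set(mixture) - set(names)
    if unknown:
        raise ValueError(f"mixture refers to unknown signatures: {sorted(unknown)}")
    return np.array([float(mixture.get(name, 0.0)) for name in names])


def simulate_catalog(
    mixture: Mapping[str, float] | Sequence[float],
    n_mutations: int,
    signatures: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
) -> CatalogVector:
    """Draw a 96-channel catalogue multinomially from the mixture S @ w.

    The returned counts always sum to ``n_mutations``.
    """
    validate_signature_matrix(signatures)
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if isinstance(mixture, Mapping):
        w = _mixture_vector(mixture, signatures.columns)
    else:
        w = np.asarray(mixture, float)
        if w.shape != (signatures.shape[1],):
            raise ValueError(
                f"mixture length {w.size} != number of signatures {signatures.shape[1]}"
            )
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be >= 0 and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = signatures.to_numpy(float) @ w
    p = p / p.sum()
    counts = rng.multinomial(n_mutations, p)
    return CatalogVector(
        sample="simulated",
        counts=pd.Series(counts, index=list(CHANNELS), name="simulated"),
    )


# ---------------------------------------------------------------------------
# germline component


def _simulate_germline(
    params: GermlineParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], set[VariantKey]]:
    n = params.n_records
    cancer_genes = [f"CGENE{i:03d}" for i in range(params.n_cancer_genes)]
    other_pool = 5000

    sites = _draw_sites(rng, n)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = bases[ref_idx]
    alts = bases[(ref_idx + alt_shift) % 4]
    multi = rng.random(n) < params.multiallelic_fraction
    second_shift = ((alt_shift + rng.integers(1, 3, size=n) - 1) % 3) + 1
    second_shift = np.where(second_shift == alt_shift,
                            (alt_shift % 3) + 1, second_shift)
    alts2 = bases[(ref_idx + second_shift) % 4]

    exonic = rng.random(n) < params.exonic_fraction
    is_cancer = rng.random(n) < params.cancer_gene_fraction
    gene_pick = rng.integers(0, max(params.n_cancer_genes, other_pool), size=n)
    genes = np.where(
        is_cancer,
        [cancer_genes[i % params.n_cancer_genes] for i in gene_pick],
        [f"GENE{i % other_pool:05d}" for i in gene_pick],
    )
    impact_names = list(params.impact_probs)
    impact_p = np.array(list(params.impact_probs.values()), float)
    impact_p = impact_p / impact_p.sum()
    impacts = rng.choice(impact_names, size=n, p=impact_p)

    af_true = rng.beta(*params.af_beta, size=n)
    af_wes = np.where(rng.random(n) < params.af_missing_wes, np.nan, af_true)
    af_genome = np.clip(af_true * np.exp(rng.normal(0, 0.2, size=n)), 0, 1)
    af_genome = np.where(rng.random(n) < params.af_missing_genome, np.nan, af_genome)
    clinvar = rng.choice(
        ["", "benign", "uncertain_significance", "pathogenic"],
        size=n, p=[0.7, 0.15, 0.1, 0.05],
    )

    low_depth = rng.random(n) < params.low_depth_fraction

    def one_replicate() -> pd.DataFrame:
        present = rng.random(n) < (1.0 - params.replicate_dropout)
        mean = np.where(low_depth, params.low_depth_mean, params.mean_depth)
        depth = rng.poisson(mean)
        qual = rng.gamma(params.qual_shape, params.qual_scale, size=n)
        filt = np.where(rng.random(n) < params.pass_fraction, "PASS", "LowConf")
        alt_col = np.where(multi, np.char.add(np.char.add(alts, ","), alts2), alts)
        frame = pd.DataFrame(
            {
                "chrom": [c for c, _ in sites],
                "pos": [p for _, p in sites],
                "ref": refs,
                "alt": alt_col,
                "filter": filt,
                "qual": np.round(qual, 2),
                "depth": depth,
                "exonic": exonic,
                "gene": genes,
                "impact": impacts,
                "af_wes": np.round(af_wes, 6),
                "af_genome": np.round(af_genome, 6),
                "clinvar": clinvar,
            }
        )
        return frame[present].reset_index(drop=True)

    rep1 = one_replicate()
    rep2 = one_replicate()
    truth = _germline_truth(rep1, rep2, set(cancer_genes))
    return rep1, rep2, cancer_genes, truth


def _germline_truth(
    rep1: pd.DataFrame, rep2: pd.DataFrame, cancer_genes: set[str]
) -> set[VariantKey]:
    """Generator-side bookkeeping of which records survive the filter rule."""

    def survivors(df: pd.DataFrame) -> pd.DataFrame:
        base = df["exonic"] & (df["filter"] == "PASS") & (df["depth"] >= 8)
        entering = df[base]
        cap = (
            float(np.quantile(entering["depth"].to_numpy(float), 0.99))
            if len(entering)
            else float("inf")
        )
        return df[base & (df["depth"] <= cap) & (df["qual"] >= 20)]

    merged = pd.concat([survivors(rep1), survivors(rep2)], ignore_index=True)
    merged = merged.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    merged = merged[~merged["alt"].astype(str).str.contains(",")]
    site_alleles = merged.groupby(["chrom", "pos"])["alt"].transform("nunique")
    merged = merged[site_alleles <= 1]
    keep = (
        merged["gene"].astype(str).str.upper().isin(cancer_genes)
        & merged["impact"].isin({"HIGH", "MODERATE"})
    )
    merged = merged[keep]
    eff = merged["af_wes"].where(merged["af_wes"].notna(), merged["af_genome"])
    merged = merged[eff.isna() | (eff < 0.05)]
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in merged.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# expression component


def _allocate_overexpressed(
    params: ExpressionParams, samples: Sequence[str], rng: np.random.Generator
) -> dict[str, set[str]]:
    gene_ids = [f"EXP{i:05d}" for i in range(params.n_genes)]
    order = rng.permutation(params.n_genes)
    sets: dict[str, set[str]] = {s: set() for s in samples}
    cursor = 0
    for (a, b), k in sorted(params.n_overexpressed_shared_pairs.items()):
        chunk = {gene_ids[order[cursor + i]] for i in range(k)}
        cursor += k
        sets[a] |= chunk
        sets[b] |= chunk
    for s in samples:
        k = params.n_overexpressed.get(s, 0)
        chunk = {gene_ids[order[cursor + i]] for i in range(k)}
        cursor += k
        sets[s] |= chunk
    return sets


def _simulate_expression(
    params: ExpressionParams, samples: Sequence[str], rng: np.random.Generator
):
    genes = [f"EXP{i:05d}" for i in range(params.n_genes)]
    lengths = pd.Series(
        rng.integers(params.gene_length_range[0], params.gene_length_range[1] + 1,
                     size=params.n_genes),
        index=genes, name="length",
    )
    baseline = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd,
                             size=params.n_genes)

    normal_cols = [f"N{i + 1:02d}" for i in range(params.n_normals)]
    normal_rpkm = pd.DataFrame(
        baseline[:, None] * np.exp(rng.normal(0, 0.3, size=(params.n_genes, params.n_normals))),
        index=genes, columns=normal_cols,
    )
    normal_median = normal_rpkm.median(axis=1)

    planted = _allocate_overexpressed(params, samples, rng)

    mapped = pd.Series(
        np.maximum(rng.normal(params.mapped_total_mean, params.mapped_total_sd,
                              size=len(samples)), 1e6),
        index=list(samples), name="mapped_total",
    )
    counts = pd.DataFrame(index=genes, columns=list(samples), dtype=float)
    for s in samples:
        target = baseline * np.exp(rng.normal(0, params.noise_sd, size=params.n_genes))
        planted_mask = pd.Index(genes).isin(planted[s])
        threshold = np.maximum(10.0 * normal_median.to_numpy(), 10.0)
        uplift = rng.uniform(*params.uplift_range, size=params.n_genes)
        target = np.where(planted_mask, threshold * uplift, target)
        lam = target * (lengths.to_numpy() / 1e3) * (mapped[s] / 1e6)
        counts[s] = rng.poisson(lam)
    counts = counts.astype(int)
    return counts, lengths, mapped, normal_rpkm, planted


# ---------------------------------------------------------------------------
# immune fractions


_HOT_WEIGHTS = {
    "B.cells": 0.20, "NK.cells": 0.18, "T.cells.CD8": 0.30, "T.cells.CD4": 0.10,
    "Dendritic.cells": 0.04, "Monocytes": 0.10, "Neutrophils": 0.08,
}
_COLD_WEIGHTS = {
    "B.cells": 0.10, "NK.cells": 0.25, "T.cells.CD8": 0.10, "T.cells.CD4": 0.15,
    "Dendritic.cells": 0.10, "Monocytes": 0.18, "Neutrophils": 0.12,
}


def _simulate_fractions(
    params: ImmuneParams, samples: Sequence[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = {}
    for i, s in enumerate(samples):
        total = params.total_immune[s]
        supp = params.suppressive_pct[s] / 100.0 * total
        m2 = supp / 2.0
        treg = supp - m2
        m1 = params.m1_m2_ratio[s] * m2
        remainder = total - supp - m1
        if remainder < 0:
            raise ValueError(
                f"immune targets for {s} are infeasible (remainder {remainder:.4f} < 0)"
            )
        weights = _HOT_WEIGHTS if i < len(samples) / 2 else _COLD_WEIGHTS
        row = {cell: remainder * w for cell, w in weights.items()}
        row.update(
            {"Macrophages.M1": m1, "Macrophages.M2": m2, "Tregs": treg,
             "Other": 1.0 - total}
        )
        rows[s] = [row[c] for c in CELL_TYPES]
    truth = pd.DataFrame.from_dict(rows, orient="index", columns=list(CELL_TYPES))
    observed = truth.copy()
    for s in samples:
        alpha = np.maximum(truth.loc[s].to_numpy(float), 1e-6) * params.noise_concentration
        observed.loc[s] = rng.dirichlet(alpha)
    return truth, observed


# ---------------------------------------------------------------------------
# copy-number ratio profiles


def _segment_profile(params: CopyNumberParams, rng: np.random.Generator) -> pd.Series:
    chroms, starts, values = [], [], []
    for c in range(1, params.n_chromosomes + 1):
        level = rng.choice(params.ratio_levels)
        for b in range(params.bins_per_chrom):
            if b > 0 and rng.random() < params.segment_switch_prob:
                level = rng.choice(params.ratio_levels)
            chroms.append(str(c))
            starts.append(b * 1_000_000 + 1)
            values.append(float(level))
    index = pd.MultiIndex.from_arrays([chroms, starts], names=["chrom", "start"])
    return pd.Series(values, index=index, name="ratio")


def _simulate_copy_number(
    params: CopyNumberParams,
    primaries: Sequence[str],
    recurrence: str,
    origin: str,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.Series], dict[str, dict[int, pd.Series]]]:
    truth: dict[str, pd.Series] = {p: _segment_profile(params, rng) for p in primaries}
    divergent = _segment_profile(params, rng)
    mask_profile = _segment_profile(params, rng)
    # segment-level divergence mask: reuse segment structure, threshold on rank
    levels = np.asarray(params.ratio_levels, float)
    cut = np.quantile(levels, params.recurrence_divergence)
    mask = mask_profile.to_numpy() <= cut
    rec = truth[origin].copy()
    rec[mask] = divergent.to_numpy()[mask]
    truth[recurrence] = rec

    observed: dict[str, dict[int, pd.Series]] = {}
    for s, base in truth.items():
        observed[s] = {}
        for rep in range(1, params.n_replicates + 1):
            noise = np.exp(rng.normal(0, params.noise_sd, size=len(base)))
            values = base.to_numpy() * noise
            missing = rng.random(len(base)) < params.missing_fraction
            values = np.where(missing, np.nan, np.round(values, 6))
            observed[s][rep] = pd.Series(values, index=base.index, name="MedianRatio")
    return truth, observed


# ---------------------------------------------------------------------------
# top level


def simulate_patient(config: ClonalScenarioConfig) -> SimulatedPatient:
    """Generate one fully ground-truthed synthetic patient.

    Deterministic given ``config.seed``: every component draws from its own
    stream spawned from the master seed.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    names = ["signatures", "somatic", "germline", "expression", "fractions", "copynumber"]
    streams = dict(zip(names, master.spawn(len(names))))
    rng = {k: np.random.default_rng(v) for k, v in streams.items()}

    signatures = synthetic_signature_matrix(config.n_signatures, seed=streams["signatures"])

    membership, variants, calls, candidates, pileups = _simulate_somatic(
        config, signatures, rng["somatic"]
    )
    rep1, rep2, cancer_genes, germline_truth = _simulate_germline(
        config.germline, rng["germline"]
    )
    counts, lengths, mapped, normal_rpkm, planted = _simulate_expression(
        config.expression, config.samples, rng["expression"]
    )
    fraction_truth, fractions = _simulate_fractions(
        config.immune, config.samples, rng["fractions"]
    )
    cn_truth, profiles = _simulate_copy_number(
        config.copy_number, config.primaries, config.recurrence,
        config.origin_primary, rng["copynumber"],
    )

    expected_exposures = {}
    for s in config.samples:
        n_carried = sum(1 for members in membership.values() if s in members)
        expected_exposures[s] = {
            sig: w * n_carried
            for sig, w in config.signature_mixture_per_sample[s].items()
        }

    truth = PatientTruth(
        membership=membership,
        origin=config.origin_primary,
        mixtures={s: dict(m) for s, m in config.signature_mixture_per_sample.items()},
        expected_exposures=expected_exposures,
        overexpressed=planted,
        germline_final_keys=germline_truth,
        fractions=fraction_truth,
        cn_truth=cn_truth,
    )
    return SimulatedPatient(
        config=config,
        truth=truth,
        variants=variants,
        calls=calls,
        candidates=candidates,
        pileups=pileups,
        germline_replicates=(rep1, rep2),
        cancer_genes=cancer_genes,
        counts=counts,
        gene_lengths=lengths,
        mapped_totals=mapped,
        normal_rpkm=normal_rpkm,
        fractions=fractions,
        ratio_profiles=profiles,
        signatures=signatures,
    )


_NESTED_FIELDS = {
    "germline": GermlineParams,
    "expression": ExpressionParams,
    "immune": ImmuneParams,
    "copy_number": CopyNumberParams,
}
_PAIR_KEY_FIELDS = {"n_shared_pairs", "n_overexpressed_shared_pairs"}


def _parse_pair_keys(mapping: Mapping) -> dict[tuple[str, str], int]:
    out = {}
    for key, value in mapping.items():
        if isinstance(key, str):
            parts = [p for p in key.replace("&", ",").split(",") if p]
            if len(parts) != 2:
                raise ValueError(f"pair key {key!r} must name two samples, e.g. 'T1,T3'")
            key = (parts[0].strip(), parts[1].strip())
        out[tuple(key)] = int(value)
    return out


def scenario_from_mapping(overrides: Mapping) -> ClonalScenarioConfig:
    """Build a scenario from a plain mapping (e.g. parsed YAML).

    Nested component settings may be given as plain dicts, sample pairs as
    ``"T1,T3"``-style string keys, and ``primaries`` as a list.
    """
    valid = {f.name for f in dataclasses.fields(ClonalScenarioConfig)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
    kwargs = {}
    for name, value in overrides.items():
        if name in _NESTED_FIELDS and isinstance(value, Mapping):
            value = dict(value)
            for pair_field in _PAIR_KEY_FIELDS & set(value):
                value[pair_field] = _parse_pair_keys(value[pair_field])
            value = _NESTED_FIELDS[name](**value)
        elif name == "primaries":
            value = tuple(value)
        elif name in _PAIR_KEY_FIELDS and isinstance(value, Mapping):
            value = _parse_pair_keys(value)
        elif name == "signature_mixture_per_sample":
            value = {s: dict(m) for s, m in value.items()}
        kwargs[name] = value
    return ClonalScenarioConfig(**kwargs)


def _key_str(key: VariantKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def write_patient(patient: SimulatedPatient, outdir) -> None:
    """Write all observed tables plus truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in patient.config.samples:
        sio.write_somatic_vcf(patient.calls[s], outdir / f"{s}_calls.vcf")
        sio.write_candidates_tsv(patient.candidates[s], outdir / f"{s}_candidates.tsv")
        for rep, profile in patient.ratio_profiles[s].items():
            sio.write_ratio_profile(profile, outdir / f"{s}_rep{rep}_ratio.txt")
    sio.write_pileups_tsv(patient.pileups, outdir / "pileups.tsv")
    sio.write_germline_vcf(patient.germline_replicates[0], outdir / "germline_rep1.vcf")
    sio.write_germline_vcf(patient.germline_replicates[1], outdir / "germline_rep2.vcf")
    sio.write_gene_list(patient.cancer_genes, outdir / "cancer_genes.txt")
    sio.write_matrix_tsv(patient.counts, outdir / "counts.tsv")
    sio.write_series_tsv(patient.gene_lengths, outdir / "gene_lengths.tsv", "gene", "length")
    sio.write_series_tsv(patient.mapped_totals, outdir / "mapped_totals.tsv",
                         "sample", "mapped_total")
    sio.write_matrix_tsv(patient.normal_rpkm, outdir / "normals_rpkm.tsv")
    sio.write_matrix_tsv(patient.fractions, outdir / "fractions.tsv", index_name="sample")
    sio.write_signature_matrix(patient.signatures, outdir / "signatures.tsv")

    truth = {
        "origin": patient.truth.origin,
        "samples": list(patient.config.samples),
        "recurrence": patient.config.recurrence,
        "membership": {
            _key_str(k): sorted(m) for k, m in sorted(patient.truth.membership.items())
        },
        "mixtures": patient.truth.mixtures,
        "expected_exposures": patient.truth.expected_exposures,
        "overexpressed": {s: sorted(g) for s, g in patient.truth.overexpressed.items()},
        "germline_final": sorted(_key_str(k) for k in patient.truth.germline_final_keys),
        "fractions": {
            s: dict(zip(patient.truth.fractions.columns,
                        map(float, patient.truth.fractions.loc[s])))
            for s in patient.truth.fractions.index
        },
        "seed": patient.config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
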