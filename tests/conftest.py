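"""Shared fixtures: scaled-down synthetic patients and signature matrices."""

from __future__ import annotations

import pytest

from spmtrace.signatures import block_signature_matrix, synthetic_signature_matrix
from spmtrace.simulate import (
    ClonalScenarioConfig,
    CopyNumberParams,
    ExpressionParams,
    GermlineParams,
    simulate_patient,
)

SAMPLES = ("T1", "T2", "T3", "R1")


def scaled_config(seed: int = 7, **overrides) -> ClonalScenarioConfig:
    """A small but structurally complete scenario for fast tests."""
    base = dict(
        n_private_per_primary={"T1": 25, "T2": 10, "T3": 20},
        n_inherited=20,
        n_recurrence_private=15,
        n_shared_pairs={("T1", "T3"): 2},
        purity_per_sample={"T1": 0.3, "T2": 0.35, "T3": 0.5, "R1": 0.4},
        mean_depth_per_sample={s: 200.0 for s in SAMPLES},
        germline=GermlineParams(n_records=1500),
        expression=ExpressionParams(
            n_genes=300,
            n_normals=10,
            n_overexpressed={"T1": 15, "T2": 8, "T3": 15, "R1": 10},
            n_overexpressed_shared_pairs={("T2", "R1"): 12},
        ),
        copy_number=CopyNumberParams(n_chromosomes=6, bins_per_chrom=40),
        seed=seed,
    )
    base.update(overrides)
    return ClonalScenarioConfig(**base)


@pytest.fixture(scope="session")
def patient():
    return simulate_patient(scaled_config())


@pytest.fixture(scope="session")
def orthogonal_signatures():
    """Well-conditioned 96 x 5 matrix with disjoint signature supports."""
    return block_signature_matrix(5, seed=42)


@pytest.fixture(scope="session")
def dense_signatures():
    """A 30-column COSMIC-shaped synthetic matrix (collinear, realistic)."""
    return synthetic_signature_matrix(30, seed=11)
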