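"""End-to-end orchestration: simulate -> analyse -> compare to truth.

The pipeline stages read and write the plain-text formats of
:mod:`spmtrace.io`, so a run directory is fully inspectable and re-runs
are byte-reproducible given the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .expression import call_overexpressed, compute_rpkm, immune_summary, overexpressed_union, zscore_cluster
from .germline import run_cascade
from .overlap import cluster_profiles, infer_origin, partition_overlaps, profile_spearman
from .presence import build_presence_matrix
from .signatures import build_catalog, decompose_nnls
from .simulate import ClonalScenarioConfig, SimulatedPatient, simulate_patient, write_patient

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "adjudicate", "partition", "origin",
    "germline", "signatures", "expression", "immune", "copynumber",
)


@dataclass
class Thresholds:
    """Decision thresholds of every stage; defaults are the case study's values."""

    min_depth: int = 50
    vaf_absent: float = 0.01
    vaf_present: float = 0.02
    germline_min_depth: int = 8
    germline_min_qual: float = 20.0
    germline_depth_quantile: float = 0.99
    af_threshold: float = 0.05
    min_rpkm: float = 10.0
    fold: float = 10.0
    exposure_cutoff: float = 0.0


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    thresholds: Thresholds = field(default_factory=Thresholds)
    scenario: ClonalScenarioConfig | None = None

    def enabled(self, stage: str) -> bool:
        return stage in self.stages


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write ``report.json``.

    Returns the report dict.  Any stage failure propagates (the CLI maps it
    to a non-zero exit naming the stage).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {"seed": config.seed, "stages": list(config.stages),
                    "thresholds": dataclasses.asdict(th)}

    patient: SimulatedPatient | None = None
    if config.enabled("simulate"):
        scenario = config.scenario or ClonalScenarioConfig()
        scenario = dataclasses.replace(scenario, seed=config.seed)
        logger.info("simulating patient (seed=%d)", config.seed)
        patient = simulate_patient(scenario)
        write_patient(patient, outdir)

    truth = None
    truth_path = outdir / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())

    samples: list[str] = (
        truth["samples"] if truth else sorted(
            p.name.removesuffix("_calls.vcf") for p in outdir.glob("*_calls.vcf")
        )
    )

    matrix = None
    if config.enabled("adjudicate"):
        logger.info("adjudicating presence (min depth %d, VAF %g/%g)",
                    th.min_depth, th.vaf_absent, th.vaf_present)
        callsets = {s: sio.read_somatic_vcf(outdir / f"{s}_calls.vcf") for s in samples}
        candidates = {
            s: sio.read_candidates_tsv(outdir / f"{s}_candidates.tsv") for s in samples
        }
        pileups = sio.read_pileups_tsv(outdir / "pileups.tsv")
        matrix = build_presence_matrix(
            callsets, candidates, pileups,
            min_depth=th.min_depth, vaf_absent=th.vaf_absent, vaf_present=th.vaf_present,
        )
        matrix.write_tsv(outdir / "presence_matrix.tsv")
        report["adjudicate"] = {
            "n_variants": int(matrix.statuses.shape[0]),
            "n_excluded": int(matrix.excluded.sum()),
        }

    partition = None
    if config.enabled("partition") and matrix is not None:
        partition = partition_overlaps(matrix)
        partition.to_records().to_csv(outdir / "partition.tsv", sep="\t", index=False)
        report["partition"] = {
            "counts": {"&".join(sorted(k)): v for k, v in partition.counts.items()},
            "n_excluded": partition.n_excluded,
            "totals_per_sample": {s: partition.total_in(s) for s in samples},
        }

    if config.enabled("origin") and partition is not None:
        recurrence = truth["recurrence"] if truth else samples[-1]
        primaries = [s for s in samples if s != recurrence]
        call = infer_origin(partition, recurrence, primaries)
        report["origin"] = {
            "recurrence": call.recurrence,
            "shared": call.shared,
            "best": call.best,
            "margin": call.margin,
        }
        if truth:
            report["origin"]["truth"] = truth["origin"]
            report["origin"]["correct"] = call.best == truth["origin"]

    if config.enabled("germline"):
        logger.info("germline cascade (DP>=%d, q%.0f cap, QUAL>=%g, AF<%g)",
                    th.germline_min_depth, 100 * th.germline_depth_quantile,
                    th.germline_min_qual, th.af_threshold)
        rep1 = sio.read_germline_vcf(outdir / "germline_rep1.vcf")
        rep2 = sio.read_germline_vcf(outdir / "germline_rep2.vcf")
        genes = sio.read_gene_list(outdir / "cancer_genes.txt")
        final, trace = run_cascade(
            rep1, rep2, genes,
            af_threshold=th.af_threshold, min_depth=th.germline_min_depth,
            min_qual=th.germline_min_qual, depth_quantile=th.germline_depth_quantile,
        )
        sio.write_germline_vcf(final, outdir / "germline_final.vcf")
        trace.write_tsv(outdir / "germline_trace.tsv")
        report["germline"] = {
            "n_final": int(len(final)),
            "trace": [(s.name, s.n_in, s.n_out) for s in trace.stages],
        }
        if truth:
            found = {
                f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}" for r in final.itertuples(index=False)
            }
            expected = set(truth["germline_final"])
            tp = len(found & expected)
            report["germline"]["precision"] = tp / len(found) if found else float("nan")
            report["germline"]["recall"] = tp / len(expected) if expected else float("nan")

    if config.enabled("signatures"):
        signatures = sio.read_signature_matrix(outdir / "signatures.tsv")
        exposures = {}
        for s in samples:
            calls = sio.read_somatic_vcf(outdir / f"{s}_calls.vcf")
            catalog = build_catalog(calls, s)
            exp = decompose_nnls(catalog, signatures)
            exposures[s] = exp
        table = pd.DataFrame({s: e.exposures for s, e in exposures.items()})
        sio.write_matrix_tsv(table, outdir / "exposures.tsv", index_name="signature")
        report["signatures"] = {
            s: {
                "total_exposure": e.total,
                "residual": e.residual,
                "support": e.support(),
            }
            for s, e in exposures.items()
        }

    if config.enabled("expression"):
        counts = sio.read_matrix_tsv(outdir / "counts.tsv").astype(int)
        lengths = sio.read_series_tsv(outdir / "gene_lengths.tsv")
        mapped = sio.read_series_tsv(outdir / "mapped_totals.tsv")
        normals = sio.read_matrix_tsv(outdir / "normals_rpkm.tsv")
        rpkm = compute_rpkm(counts, lengths, mapped)
        sio.write_matrix_tsv(rpkm.round(4), outdir / "rpkm.tsv")
        calls = call_overexpressed(rpkm, normals, min_rpkm=th.min_rpkm, fold=th.fold)
        union = sorted(overexpressed_union(calls))
        pd.DataFrame(
            {"gene": union,
             **{s: [g in calls[s] for g in union] for s in rpkm.columns}}
        ).to_csv(outdir / "overexpressed.tsv", sep="\t", index=False)
        report["expression"] = {
            "n_overexpressed_union": len(union),
            "per_sample": {s: len(g) for s, g in calls.items()},
        }
        if len(union) >= 2 and rpkm.shape[1] >= 2:
            clustering = zscore_cluster(rpkm.loc[union])
            report["expression"]["sample_leaf_order"] = clustering.col_order
        if truth:
            expected = {s: set(g) for s, g in truth["overexpressed"].items()}
            tp = sum(len(calls[s] & expected.get(s, set())) for s in calls)
            n_called = sum(len(g) for g in calls.values())
            n_expected = sum(len(g) for g in expected.values())
            report["expression"]["precision"] = tp / n_called if n_called else float("nan")
            report["expression"]["recall"] = tp / n_expected if n_expected else float("nan")

    if config.enabled("immune"):
        fractions = sio.read_matrix_tsv(outdir / "fractions.tsv")
        summary = immune_summary(fractions)
        sio.write_matrix_tsv(summary.round(6), outdir / "immune_summary.tsv",
                             index_name="sample")
        report["immune"] = {
            s: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for s, row in summary.iterrows()
        }

    if config.enabled("copynumber"):
        profiles = {}
        replicate_rho = {}
        for s in samples:
            reps = sorted(outdir.glob(f"{s}_rep*_ratio.txt"))
            loaded = [sio.read_ratio_profile(p) for p in reps]
            if loaded:
                profiles[s] = loaded[0]
            if len(loaded) >= 2:
                replicate_rho[s] = profile_spearman(loaded[0], loaded[1])
        report["copynumber"] = {"replicate_rho": replicate_rho}
        if len(profiles) >= 2:
            clustering = cluster_profiles(profiles)
            recurrence = truth["recurrence"] if truth else samples[-1]
            rhos = {
                s: profile_spearman(profiles[s], profiles[recurrence])
                for s in profiles if s != recurrence
            }
            report["copynumber"]["rho_vs_recurrence"] = rhos
            report["copynumber"]["leaf_order"] = clustering.leaf_order
            report["copynumber"]["first_merge"] = list(clustering.first_merge())

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_json_default)
    )
    return report
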