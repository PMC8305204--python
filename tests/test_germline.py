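"""Germline filter cascade: per-stage semantics, merge, and truth recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spmtrace.germline import (
    GERMLINE_COLUMNS,
    annotate_and_restrict,
    filter_replicate,
    merge_replicates,
    normalize_impact,
    population_af_filter,
    run_cascade,
)


def make_records(n, rng=None, **overrides) -> pd.DataFrame:
    """Random germline table with controllable columns."""
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "chrom": rng.choice(["1", "2", "3"], n),
            "pos": rng.choice(np.arange(1, 10 * n), size=n, replace=False),
            "ref": rng.choice(list("ACGT"), n),
            "alt": rng.choice(list("ACGT"), n),
            "filter": rng.choice(["PASS", "LowConf"], n, p=[0.8, 0.2]),
            "qual": rng.gamma(2.0, 30.0, n).round(2),
            "depth": rng.poisson(120, n),
            "exonic": rng.random(n) < 0.6,
            "gene": rng.choice(["TP53", "ATM", "OTHER1", "OTHER2"], n),
            "impact": rng.choice(["HIGH", "MODERATE", "LOW", "MODIFIER"], n),
            "af_wes": np.where(rng.random(n) < 0.3, np.nan, rng.beta(0.2, 1.8, n)),
            "af_genome": np.where(rng.random(n) < 0.3, np.nan, rng.beta(0.2, 1.8, n)),
            "clinvar": "",
        }
    )
    # keep ref != alt (identity of ref/alt is irrelevant to the cascade)
    same = df["ref"] == df["alt"]
    df.loc[same, "alt"] = df.loc[same, "ref"].map({"A": "C", "C": "A", "G": "T", "T": "G"})
    for col, val in overrides.items():
        df[col] = val
    return df[GERMLINE_COLUMNS]


def oracle_replicate_filter(df: pd.DataFrame) -> pd.DataFrame:
    """One-pass predicate oracle for the per-replicate stages."""
    base = df["exonic"] & (df["filter"] == "PASS") & (df["depth"] >= 8)
    entering = df[base]
    cap = float(np.quantile(entering["depth"], 0.99)) if len(entering) else np.inf
    return df[base & (df["depth"] <= cap) & (df["qual"] >= 20)]


class TestFilterReplicate:
    def test_boundary_record_retained(self):
        df = make_records(1, exonic=True, depth=8, qual=20.0)
        df["filter"] = "PASS"
        out, trace = filter_replicate(df)
        assert len(out) == 1  # "at least eight reads", "QUAL lower than 20" removed

    def test_depth_seven_removed_at_depth_stage(self):
        df = make_records(1, exonic=True, depth=7, qual=50.0)
        df["filter"] = "PASS"
        out, trace = filter_replicate(df)
        assert len(out) == 0
        stage = {s.name: (s.n_in, s.n_out) for s in trace.stages}
        assert stage["rep:min_depth"] == (1, 0)

    def test_quantile_stage_removes_exactly_the_tail(self):
        rng = np.random.default_rng(5)
        df = make_records(1000, rng=rng, exonic=True, qual=50.0)
        df["filter"] = "PASS"
        df["depth"] = rng.poisson(100, 1000) + 8
        out, _ = filter_replicate(df)
        oracle = oracle_replicate_filter(df)
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      oracle.reset_index(drop=True))
        cap = np.quantile(df["depth"], 0.99)
        assert (out["depth"] <= cap).all()
        assert len(out) == int((df["depth"] <= cap).sum())

    def test_degenerate_constant_depth_keeps_all(self):
        df = make_records(50, exonic=True, depth=100, qual=50.0)
        df["filter"] = "PASS"
        out, trace = filter_replicate(df)
        assert len(out) == 50

    def test_matches_oracle_on_random_tables(self):
        for seed in range(5):
            df = make_records(400, rng=np.random.default_rng(seed))
            out, _ = filter_replicate(df)
            oracle = oracle_replicate_filter(df)
            pd.testing.assert_frame_equal(
                out.reset_index(drop=True), oracle.reset_index(drop=True)
            )

    def test_empty_input(self):
        out, trace = filter_replicate(make_records(0))
        assert out.empty
        assert all(s.n_in == 0 and s.n_out == 0 for s in trace.stages)


class TestMergeReplicates:
    def _rec(self, pos, alt="T", **kw):
        row = dict(
            chrom="1", pos=pos, ref="C", alt=alt, filter="PASS", qual=50.0,
            depth=100, exonic=True, gene="TP53", impact="HIGH",
            af_wes=0.01, af_genome=0.01, clinvar="",
        )
        row.update(kw)
        return row

    def test_union_semantics(self):
        rep1 = pd.DataFrame([self._rec(1), self._rec(2)])
        rep2 = pd.DataFrame([self._rec(2), self._rec(3)])
        merged, _ = merge_replicates(rep1, rep2)
        assert sorted(merged["pos"]) == [1, 2, 3]
        prov = merged.set_index("pos")["provenance"]
        assert prov[1] == "rep1" and prov[2] == "both" and prov[3] == "rep2"

    def test_multiallelic_record_removed(self):
        rep1 = pd.DataFrame([self._rec(1, alt="T,G"), self._rec(2)])
        merged, trace = merge_replicates(rep1, pd.DataFrame([], columns=rep1.columns))
        assert list(merged["pos"]) == [2]

    def test_cross_replicate_multiallelic_site_removed(self):
        rep1 = pd.DataFrame([self._rec(1, alt="T")])
        rep2 = pd.DataFrame([self._rec(1, alt="G")])
        merged, _ = merge_replicates(rep1, rep2)
        assert merged.empty

    def test_empty_rep2_passthrough(self):
        rep1 = pd.DataFrame([self._rec(1), self._rec(2)])
        merged, _ = merge_replicates(rep1, pd.DataFrame([], columns=rep1.columns))
        assert sorted(merged["pos"]) == [1, 2]

    def test_conflicting_annotation_keeps_rep1(self, caplog):
        rep1 = pd.DataFrame([self._rec(1, gene="TP53")])
        rep2 = pd.DataFrame([self._rec(1, gene="ATM")])
        with caplog.at_level("WARNING"):
            merged, _ = merge_replicates(rep1, rep2)
        assert merged["gene"].iloc[0] == "TP53"
        assert any("conflicting annotations" in r.message for r in caplog.records)


class TestAnnotateAndRestrict:
    GENES = ["TP53", "ATM"]

    def test_predicate(self):
        df = pd.DataFrame(
            {
                "gene": ["TP53", "TP53", "OTHER", "atm"],
                "impact": ["HIGH", "LOW", "HIGH", "moderate"],
            }
        )
        out = annotate_and_restrict(df, self.GENES)
        assert list(out["gene"]) == ["TP53", "atm"]  # case-insensitive match

    def test_empty_gene_list_warns_and_empties(self, caplog):
        df = pd.DataFrame({"gene": ["TP53"], "impact": ["HIGH"]})
        with caplog.at_level("WARNING"):
            out = annotate_and_restrict(df, [])
        assert out.empty

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        df = make_records(200, rng=rng)
        out = annotate_and_restrict(df, self.GENES)
        expect = [
            i
            for i, r in df.iterrows()
            if r["gene"].upper() in self.GENES and r["impact"] in ("HIGH", "MODERATE")
        ]
        assert len(out) == len(expect)


def test_normalize_impact():
    assert normalize_impact("high") == "HIGH"
    assert normalize_impact(" Moderate ") == "MODERATE"
    assert normalize_impact("weird") == "unknown"
    assert normalize_impact(np.nan) == "unknown"


class TestPopulationAfFilter:
    def _df(self, af_wes, af_genome):
        return pd.DataFrame({"af_wes": [af_wes], "af_genome": [af_genome]})

    def test_common_removed(self):
        assert population_af_filter(self._df(0.2, np.nan)).empty

    def test_genome_fallback(self):
        assert len(population_af_filter(self._df(np.nan, 0.01))) == 1
        assert population_af_filter(self._df(np.nan, 0.2)).empty

    def test_boundary_is_removed(self):
        assert population_af_filter(self._df(0.05, np.nan)).empty

    def test_wes_takes_precedence_over_genome(self):
        assert len(population_af_filter(self._df(0.01, 0.9))) == 1

    def test_both_missing_retained(self):
        assert len(population_af_filter(self._df(np.nan, np.nan))) == 1

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            population_af_filter(self._df(0.1, 0.1), threshold=0.0)


class TestRunCascade:
    def test_trace_is_monotone_nonincreasing_per_stage(self):
        rng = np.random.default_rng(9)
        _, trace = run_cascade(
            make_records(500, rng=rng), make_records(500, rng=rng), ["TP53", "ATM"]
        )
        for s in trace.stages:
            assert s.n_out <= s.n_in

    def test_idempotent_with_recorded_caps(self):
        rng = np.random.default_rng(10)
        genes = ["TP53", "ATM"]
        final, trace = run_cascade(
            make_records(500, rng=rng), make_records(500, rng=rng), genes
        )
        again, _ = run_cascade(
            final.drop(columns="provenance"),
            final.drop(columns="provenance"),
            genes,
            depth_caps={
                "rep1:depth_quantile": trace.depth_caps["rep1:depth_quantile"],
                "rep2:depth_quantile": trace.depth_caps["rep2:depth_quantile"],
            },
        )
        assert len(again) == len(final)
        assert set(zip(again["chrom"], again["pos"])) == set(
            zip(final["chrom"], final["pos"])
        )

    def test_input_order_invariance(self):
        rng = np.random.default_rng(11)
        rep1 = make_records(300, rng=rng)
        rep2 = make_records(300, rng=np.random.default_rng(12))
        genes = ["TP53"]
        final_a, _ = run_cascade(rep1, rep2, genes)
        final_b, _ = run_cascade(
            rep1.sample(frac=1, random_state=4), rep2.sample(frac=1, random_state=5), genes
        )
        key = lambda df: set(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
        assert key(final_a) == key(final_b)

    def test_empty_inputs(self):
        from spmtrace.germline import empty_table

        final, trace = run_cascade(empty_table(), empty_table(), ["TP53"])
        assert final.empty
        assert all(s.n_in == 0 for s in trace.stages)

    def test_recovers_simulator_truth(self, patient):
        rep1, rep2 = patient.germline_replicates
        final, _ = run_cascade(rep1, rep2, patient.cancer_genes)
        found = {
            (r.chrom, r.pos, r.ref, r.alt) for r in final.itertuples(index=False)
        }
        assert found == patient.truth.germline_final_keys
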