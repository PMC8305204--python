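"""RPKM, overexpression calling, Z-score clustering, immune summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spmtrace.expression import (
    CELL_TYPES,
    IMMUNE_TYPES,
    call_overexpressed,
    compute_rpkm,
    immune_summary,
    overexpressed_union,
    zscore_cluster,
    zscore_rows,
)


def _frame(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestComputeRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (10, 1000, 1e6, 10.0),
            (0, 1000, 1e6, 0.0),
            (250, 2500, 5e7, 2.0),  # 250 / 2.5 kb / 50 M = 2
        ],
    )
    def test_closed_form(self, count, length, total, expected):
        rpkm = compute_rpkm(
            _frame([[count]]), pd.Series([length], index=["g0"]),
            pd.Series([total], index=["s0"]),
        )
        assert rpkm.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(_frame([[1]]), pd.Series([0], index=["g0"]),
                         pd.Series([1e6], index=["s0"]))
        with pytest.raises(ValueError):
            compute_rpkm(_frame([[1]]), pd.Series([100], index=["g0"]),
                         pd.Series([0], index=["s0"]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.integers(0, 10_000),
        st.integers(100, 100_000),
        st.floats(1e5, 1e9),
        st.integers(2, 7),
    )
    def test_linearity(self, count, length, total, k):
        base = compute_rpkm(
            _frame([[count]]), pd.Series([length], index=["g0"]),
            pd.Series([total], index=["s0"]),
        ).iloc[0, 0]
        scaled = compute_rpkm(
            _frame([[count * k]]), pd.Series([length], index=["g0"]),
            pd.Series([total], index=["s0"]),
        ).iloc[0, 0]
        assert scaled == pytest.approx(k * base, rel=1e-9)
        longer = compute_rpkm(
            _frame([[count]]), pd.Series([length * k], index=["g0"]),
            pd.Series([total], index=["s0"]),
        ).iloc[0, 0]
        assert longer == pytest.approx(base / k, rel=1e-9)


class TestCallOverexpressed:
    def test_threshold_semantics(self):
        tumour = _frame([[15.0], [15.0], [10.0]], genes=["a", "b", "c"], samples=["t"])
        normals = _frame(
            [[1.0, 1.0], [2.0, 2.0], [0.5, 0.5]], genes=["a", "b", "c"], samples=["n1", "n2"]
        )
        calls = call_overexpressed(tumour, normals)
        # a: 15 > 10 and 15 >= 10*1 -> yes; b: 15 < 10*2 -> no; c: 10 not > 10 -> no
        assert calls["t"] == {"a"}

    def test_zero_median_counts_as_overexpressed(self):
        tumour = _frame([[12.0]], genes=["a"], samples=["t"])
        normals = _frame([[0.0, 0.0]], genes=["a"], samples=["n1", "n2"])
        assert call_overexpressed(tumour, normals)["t"] == {"a"}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(200)]
        tumour = _frame(rng.lognormal(1.5, 1.5, (200, 3)), genes=genes,
                        samples=["t1", "t2", "t3"])
        normals = _frame(rng.lognormal(0.5, 1.0, (200, 7)), genes=genes,
                         samples=[f"n{i}" for i in range(7)])
        calls = call_overexpressed(tumour, normals)
        med = normals.median(axis=1)
        for s in tumour.columns:
            expected = {
                g for g in genes
                if tumour.loc[g, s] > 10.0 and tumour.loc[g, s] >= 10.0 * med[g]
            }
            assert calls[s] == expected

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError):
            call_overexpressed(
                _frame([[1.0]], genes=["a"]), _frame([[1.0]], genes=["b"])
            )

    def test_recovers_planted_truth(self, patient):
        rpkm = compute_rpkm(patient.counts, patient.gene_lengths, patient.mapped_totals)
        calls = call_overexpressed(rpkm, patient.normal_rpkm)
        for s in patient.config.samples:
            assert calls[s] == patient.truth.overexpressed[s]
        assert overexpressed_union(calls) == overexpressed_union(patient.truth.overexpressed)


class TestZscoreCluster:
    def test_rows_standardised(self):
        rng = np.random.default_rng(0)
        expr = _frame(rng.lognormal(1, 1, (20, 5)))
        z = zscore_rows(expr)
        assert np.allclose(z.to_numpy().mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.to_numpy().std(axis=1), 1, atol=1e-9)  # population sd

    def test_zero_variance_row_is_zeroed(self, caplog):
        expr = _frame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with caplog.at_level("WARNING"):
            z = zscore_rows(expr)
        assert (z.iloc[0] == 0).all()

    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        expr = _frame(
            np.column_stack([a, a, rng.normal(0, 1, 30)]),
            samples=["x", "y", "z"],
        )
        clustering = zscore_cluster(expr)
        assert set(clustering.first_col_merge()) == {"x", "y"}

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            zscore_cluster(_frame([[1.0, 2.0]]))

    def test_recurrence_and_origin_adjacent_on_simulated_expression(self, patient):
        rpkm = compute_rpkm(patient.counts, patient.gene_lengths, patient.mapped_totals)
        union = sorted(overexpressed_union(patient.truth.overexpressed))
        clustering = zscore_cluster(rpkm.loc[union])
        order = clustering.col_order
        assert abs(order.index("T2") - order.index("R1")) == 1


class TestImmuneSummary:
    def _table(self, **cells):
        row = {c: 0.0 for c in CELL_TYPES}
        row.update(cells)
        return pd.DataFrame([row], index=["s"])

    def test_formula_arithmetic(self):
        # Treg 0.10, M2 0.10, plus 0.20 of other immune cells: total 0.40
        table = self._table(
            **{"Tregs": 0.10, "Macrophages.M2": 0.10, "T.cells.CD8": 0.20, "Other": 0.60}
        )
        out = immune_summary(table)
        assert out.loc["s", "total_immune"] == pytest.approx(0.40)
        assert out.loc["s", "immunosuppressive_pct"] == pytest.approx(50.0)

    def test_m1_m2_ratio(self):
        table = self._table(**{"Macrophages.M1": 0.05, "Macrophages.M2": 0.10})
        assert immune_summary(table).loc["s", "m1_m2_ratio"] == pytest.approx(0.5)

    def test_undefined_cases_are_nan(self):
        no_m2 = self._table(**{"Macrophages.M1": 0.05, "T.cells.CD8": 0.1})
        assert np.isnan(immune_summary(no_m2).loc["s", "m1_m2_ratio"])
        empty = self._table(Other=1.0)
        assert np.isnan(immune_summary(empty).loc["s", "immunosuppressive_pct"])

    def test_matches_hand_arithmetic_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            fracs = rng.dirichlet(np.ones(len(CELL_TYPES)))
            table = pd.DataFrame([dict(zip(CELL_TYPES, fracs))], index=["s"])
            out = immune_summary(table)
            immune = sum(fracs[list(CELL_TYPES).index(c)] for c in IMMUNE_TYPES)
            m1 = fracs[list(CELL_TYPES).index("Macrophages.M1")]
            m2 = fracs[list(CELL_TYPES).index("Macrophages.M2")]
            treg = fracs[list(CELL_TYPES).index("Tregs")]
            assert out.loc["s", "total_immune"] == pytest.approx(immune, rel=1e-12)
            assert out.loc["s", "m1_m2_ratio"] == pytest.approx(m1 / m2, rel=1e-12)
            expected_pct = 100.0 * (treg + m2) / immune
            assert out.loc["s", "immunosuppressive_pct"] == pytest.approx(
                expected_pct, rel=1e-12
            )
            assert 0.0 <= out.loc["s", "immunosuppressive_pct"] <= 100.0

    def test_percentage_scale_invariant(self):
        base = self._table(
            **{"Tregs": 0.08, "Macrophages.M2": 0.04, "Macrophages.M1": 0.02,
               "NK.cells": 0.06, "Other": 0.80}
        )
        scaled = base.copy()
        for c in IMMUNE_TYPES:
            scaled[c] = base[c] * 0.5
        scaled["Other"] = 1.0 - scaled[list(IMMUNE_TYPES)].sum(axis=1)
        a = immune_summary(base).loc["s", "immunosuppressive_pct"]
        b = immune_summary(scaled).loc["s", "immunosuppressive_pct"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_cell_type_rejected(self):
        with pytest.raises(ValueError):
            immune_summary(pd.DataFrame({"Tregs": [0.1]}))
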