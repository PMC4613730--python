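"""Differential-expression screen, TFBS z-cutoff and miRNA-target merge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import welch_bh_oracle
from fflnet import (ExpressionMatrix, filter_de_genes, filter_tfbs,
                    merge_mirna_targets)
from fflnet.filters import welch_p_values


def _matrix(values, n_per_group):
    values = np.asarray(values, dtype=float)
    m = n_per_group
    samples = [f"A{i}" for i in range(m)] + [f"B{i}" for i in range(m)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, columns=samples,
                            index=[f"g{i}" for i in range(len(values))]),
        group_labels=pd.Series(["a"] * m + ["b"] * m, index=samples),
    )


class TestDEFilter:
    def test_identical_groups_pass_nothing(self, rng):
        half = rng.uniform(4, 12, size=(50, 5))
        expr = _matrix(np.hstack([half, half]), 5)
        results = filter_de_genes(expr)
        assert not any(r.passes for r in results)

    def test_clear_shift_passes_with_sign(self):
        base = np.full((3, 4), 8.0) + np.arange(4) * 0.01
        up = np.hstack([base, base + 3.0])       # log2FC = +3
        down = np.hstack([base, base - 3.0])     # log2FC = -3
        flat = np.hstack([base, base + 0.5])     # |FC| < 2
        expr = _matrix(np.vstack([up[:1], down[:1], flat[:1]]), 4)
        results = filter_de_genes(expr)
        assert [r.passes for r in results] == [True, True, False]
        assert results[0].log2_fold_change == pytest.approx(3.0)
        assert results[1].log2_fold_change == pytest.approx(-3.0)

    def test_zero_variance_equal_means_gives_p_one(self):
        rows = np.vstack([
            np.full(8, 5.0),                       # degenerate, equal
            np.r_[np.full(4, 5.0), np.full(4, 9.0)],  # degenerate, shifted
        ])
        expr = _matrix(rows, 4)
        results = filter_de_genes(expr)
        assert results[0].p_value == 1.0
        assert results[1].p_value == 0.0

    def test_results_in_input_gene_order(self, rng):
        expr = _matrix(rng.normal(8, 1, size=(20, 8)), 4)
        results = filter_de_genes(expr)
        assert [r.gene for r in results] == list(expr.values.index)

    def test_matches_independent_welch_bh_oracle(self, rng):
        a = rng.normal(8, 1, size=(200, 6))
        b = rng.normal(8, 1, size=(200, 6))
        b[:20] += 2.0
        expr = _matrix(np.hstack([a, b]), 6)
        results = filter_de_genes(expr)
        p_oracle, q_oracle = welch_bh_oracle(a, b)
        np.testing.assert_allclose([r.p_value for r in results], p_oracle,
                                   atol=1e-12)
        np.testing.assert_allclose([r.fdr for r in results], q_oracle,
                                   atol=1e-12)

    def test_single_sample_group_rejected(self):
        values = np.ones((3, 3))
        samples = ["A0", "A1", "B0"]
        with pytest.raises(ValueError, match=">= 2 samples"):
            ExpressionMatrix(
                values=pd.DataFrame(values, columns=samples),
                group_labels=pd.Series(["a", "a", "b"], index=samples))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bh_agrees_with_stepup_definition(self, p_list):
        """BH correction equals the from-scratch step-up on any p vector."""
        from statsmodels.stats.multitest import multipletests

        p = np.array(p_list)
        ours = multipletests(p, method="fdr_bh")[1]
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * n / rank)
            expected[idx] = running
        np.testing.assert_allclose(ours, expected, atol=1e-12)


class TestTFBSFilter:
    def _frame(self, z):
        return pd.DataFrame({"tf": [f"T{i}" for i in range(len(z))],
                             "gene": [f"g{i}" for i in range(len(z))],
                             "z": z})

    def test_cutoff_boundary_inclusive(self):
        kept = filter_tfbs(self._frame([2.33, 2.32, 5.0]))
        assert kept == {("T0", "g0"), ("T2", "g2")}

    def test_non_finite_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="non-finite"):
            kept = filter_tfbs(self._frame([np.nan, np.inf, 3.0]))
        assert kept == {("T2", "g2")}

    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(100_000)
        df = pd.DataFrame({"tf": np.repeat("T", z.size),
                           "gene": [f"g{i}" for i in range(z.size)],
                           "z": z})
        kept = filter_tfbs(df)
        naive = int(np.sum(z >= 2.33))
        assert len(kept) == naive
        assert 0.008 <= len(kept) / z.size <= 0.012

    @given(st.lists(st.floats(min_value=-4, max_value=4), min_size=1,
                    max_size=50),
           st.floats(min_value=-3, max_value=3),
           st.floats(min_value=0, max_value=1.5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_raising_cutoff_only_shrinks(self, z, cut, delta):
        df = self._frame(z)
        assert filter_tfbs(df, cut + delta) <= filter_tfbs(df, cut)


class TestMergeMirnaTargets:
    VER = {("mir-34a", "FOXP1")}
    SUPP = {("mir-17-5p", "CCND2"), ("mir-16-5p", "MYB")}

    def test_verified_bypasses_prediction_rule(self):
        merged = merge_mirna_targets(self.VER, set(),
                                     {"TargetScan": set(), "miRanda": set()})
        assert merged == {("mir-34a", "FOXP1"): "verified"}

    def test_single_tool_support_dropped(self):
        merged = merge_mirna_targets(
            set(), self.SUPP,
            {"TargetScan": self.SUPP, "miRanda": {("mir-16-5p", "MYB")}})
        assert merged == {("mir-16-5p", "MYB"): "predicted"}

    def test_both_tools_keep_with_predicted_label(self):
        merged = merge_mirna_targets(self.VER, self.SUPP,
                                     {"TargetScan": self.SUPP,
                                      "miRanda": self.SUPP})
        assert merged[("mir-17-5p", "CCND2")] == "predicted"
        assert merged[("mir-34a", "FOXP1")] == "verified"

    def test_missing_tool_is_error_only_when_needed(self):
        with pytest.raises(ValueError, match="miRanda"):
            merge_mirna_targets(set(), self.SUPP, {"TargetScan": self.SUPP})
        # no expression-supported edges -> tools not required
        assert merge_mirna_targets(self.VER, set(), {}) \
            == {("mir-34a", "FOXP1"): "verified"}

    def test_output_bracketed_by_inputs(self, rng):
        edges = [(f"mir-{i}", f"g{j}") for i in range(5) for j in range(5)]
        ver = {e for e in edges if rng.random() < 0.3}
        supp = {e for e in edges if rng.random() < 0.5}
        tools = {"TargetScan": {e for e in edges if rng.random() < 0.6},
                 "miRanda": {e for e in edges if rng.random() < 0.6}}
        merged = set(merge_mirna_targets(ver, supp, tools))
        assert ver <= merged <= ver | supp
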