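"""Fold change, t-test/BH machinery, DE calling and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from lnckit.diffexp import (
    bh_adjust,
    call_de,
    fold_change,
    hierarchical_cluster,
    intersect_common_de,
    student_t_test,
)
from lnckit.expression import ExpressionMatrix


def brute_force_bh(p):
    """O(m^2) step-up oracle straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos in range(m):
        i = order[rank_pos]
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def group_matrix(a_rows, b_rows, n_a=3, n_b=3):
    """Two-group FPKM matrix from per-group row values."""
    vals = np.column_stack([np.tile(a_rows, (n_a, 1)).T, np.tile(b_rows, (n_b, 1)).T])
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = {c: ("A" if c.startswith("a") else "B") for c in cols}
    idx = [f"t{i}" for i in range(vals.shape[0])]
    return ExpressionMatrix(pd.DataFrame(vals, index=idx, columns=cols), groups)


class TestFoldChange:
    def test_signed_convention(self):
        assert fold_change(20, 10) == pytest.approx(21 / 11)
        assert fold_change(10, 10) == pytest.approx(1.0)
        assert fold_change(10, 20) == pytest.approx(-21 / 11)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fold_change(-1, 1)
        with pytest.raises(ValueError):
            fold_change(1, 1, pseudocount=0)


class TestStudentT:
    def test_identical_groups_p_one(self):
        assert student_t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_separated_constant_groups(self):
        assert student_t_test([0, 0, 0], [10, 10, 10]) < 1e-10

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 8))
            ours = student_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1.0, 2.0])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_trivial_cases(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_step_up_properties_hold_for_arbitrary_p(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert (q <= 1.0 + 1e-12).all() and (q >= np.asarray(p) - 1e-12).all()
        # adjustment preserves the ordering of the order statistics
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)
            assert (bh_adjust(p) >= p - 1e-12).all()


class TestCallDe:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(41)
        rows = rng.uniform(1, 50, size=30)
        m = group_matrix(rows, rows)
        de = call_de(m, "A", "B")
        assert not de["significant"].any()
        assert (de["p_adj"] >= de["p_raw"] - 1e-12).all()

    def test_planted_upshift_recovered(self):
        """Planted up-shifts (3 vs 3, shift 4 within-SD) are recovered at a
        rate bracketed by the noncentral-t power at the Bonferroni and the
        unadjusted thresholds (BH sits between the two), with the planted
        direction and essentially no spurious down-calls."""
        rng = np.random.default_rng(43)
        n, n_up, sd, alpha = 300, 50, 0.3, 0.05
        base = rng.normal(4, 1, size=n)
        logged = np.tile(base, (6, 1)).T + rng.normal(0, sd, size=(n, 6))
        logged[:n_up, :3] += 4 * sd  # 4 SD shift in group A
        vals = np.power(2.0, logged)
        cols = ["a0", "a1", "a2", "b0", "b1", "b2"]
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"t{i}" for i in range(n)], columns=cols),
            {c: c[0].upper() for c in cols},
        )
        de = call_de(m, "A", "B", alpha=alpha).set_index("transcript_id")
        up_ids = {f"t{i}" for i in range(n_up)}
        called_up = set(de.query("significant and direction == 'up'").index)
        hits = len(called_up & up_ids)
        # per-test power at a p-value threshold x, df = 4, ncp from the shift
        ncp = 4 * sd / (sd * np.sqrt(2 / 3))
        df = 4

        def power(x):
            tcrit = sps.t.ppf(1 - x / 2, df)
            return sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)

        lo, hi = power(alpha / n), power(alpha)
        margin = 3 * np.sqrt(n_up * 0.25)
        assert n_up * lo - margin <= hits <= n_up * hi + margin
        # recovered calls are overwhelmingly the planted ones (FDR control)
        assert len(called_up - up_ids) <= max(2, 0.2 * len(called_up))
        assert len(de.query("significant and direction == 'down'")) <= 3

    def test_relabeling_flips_direction(self):
        rng = np.random.default_rng(47)
        vals = rng.uniform(1, 100, size=(20, 6))
        cols = ["a0", "a1", "a2", "b0", "b1", "b2"]
        m = ExpressionMatrix(
            pd.DataFrame(vals, columns=cols, index=[f"t{i}" for i in range(20)]),
            {c: c[0].upper() for c in cols},
        )
        ab = call_de(m, "A", "B")
        ba = call_de(m, "B", "A")
        np.testing.assert_allclose(ab["p_raw"], ba["p_raw"], atol=1e-12)
        np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"], atol=1e-12)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(53)
        vals = rng.uniform(1, 100, size=(15, 6))
        cols = ["a0", "a1", "a2", "b0", "b1", "b2"]
        idx = [f"t{i}" for i in range(15)]
        groups = {c: c[0].upper() for c in cols}
        m1 = ExpressionMatrix(pd.DataFrame(vals, index=idx, columns=cols), groups)
        perm = rng.permutation(15)
        m2 = ExpressionMatrix(
            pd.DataFrame(vals[perm], index=[idx[i] for i in perm], columns=cols), groups
        )
        de1 = call_de(m1, "A", "B").set_index("transcript_id").sort_index()
        de2 = call_de(m2, "A", "B").set_index("transcript_id").sort_index()
        pd.testing.assert_frame_equal(de1, de2)

    def test_unknown_group_errors(self):
        m = group_matrix([1.0], [2.0])
        with pytest.raises(ValueError):
            call_de(m, "A", "Z")


class TestIntersectCommonDe:
    def test_basic_and_order_stability(self):
        assert intersect_common_de(["a", "b", "c"], ["c", "b", "d"]) == ["b", "c"]
        assert intersect_common_de(["a"], ["b"]) == []
        assert intersect_common_de(["x", "y"], ["x", "y"]) == ["x", "y"]


class TestHierarchicalCluster:
    @staticmethod
    def _three_group_matrix(seed=59, n_transcripts=80, within_pcc=0.95):
        rng = np.random.default_rng(seed)
        shared = rng.normal(size=(n_transcripts, 3))
        w = np.sqrt(within_pcc)
        cols, data, groups = [], [], {}
        for gi, g in enumerate(["x", "y", "z"]):
            for r in range(3):
                col = f"{g}{r}"
                profile = w * shared[:, gi] + np.sqrt(1 - within_pcc) * rng.normal(
                    size=n_transcripts
                )
                data.append(4 + profile)
                cols.append(col)
                groups[col] = g
        vals = np.power(10.0, np.column_stack(data)) - 1
        vals = np.clip(vals, 0, None)
        return (
            ExpressionMatrix(
                pd.DataFrame(vals, index=[f"t{i}" for i in range(n_transcripts)], columns=cols),
                groups,
            ),
            groups,
        )

    def test_duplicated_samples_merge_first(self):
        rng = np.random.default_rng(61)
        col = rng.uniform(1, 50, size=30)
        other = rng.uniform(1, 50, size=30)
        vals = np.column_stack([col, col, other])
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"t{i}" for i in range(30)], columns=["a", "b", "c"]),
            {"a": "g", "b": "g", "c": "g"},
        )
        tree = hierarchical_cluster(m, m.transcript_ids)
        first = tree.linkage[0]
        assert sorted(first[:2]) == [0, 1] and first[2] == pytest.approx(0.0, abs=1e-12)

    def test_three_groups_recovered_exactly(self):
        m, groups = self._three_group_matrix()
        tree = hierarchical_cluster(m, m.transcript_ids)
        cut = tree.cut(3)
        truth = [groups[s] for s in cut]
        assert adjusted_rand_score(truth, [cut[s] for s in cut]) == pytest.approx(1.0)

    def test_newick_contains_all_samples(self):
        m, _ = self._three_group_matrix(seed=67)
        nwk = hierarchical_cluster(m, m.transcript_ids).to_newick()
        assert nwk.endswith(";")
        for s in m.samples:
            assert s in nwk
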