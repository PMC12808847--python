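import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import panorama as pn
from tests.conftest import make_cohort


class TestTwoSampleT:
    def test_identical_groups(self):
        r = pn.two_sample_t([1, 2, 3], [1, 2, 3])
        assert r.t_stat == 0 and r.p == 1 and not r.degenerate

    def test_constant_unequal_groups_degenerate(self):
        r = pn.two_sample_t([0, 0, 0], [1, 1, 1])
        assert r.p == 0 and r.degenerate

    def test_matches_textbook_pooled_formula(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])
        # independent oracle: the pooled-variance formula spelled out
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2)
        t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_exp = 2 * stats.t.sf(abs(t_exp), len(a) + len(b) - 2)
        r = pn.two_sample_t(a, b)
        assert r.t_stat == pytest.approx(t_exp)
        assert r.p == pytest.approx(p_exp)

    def test_small_group_undefined(self):
        with pytest.raises(pn.UndefinedStatistic):
            pn.two_sample_t([1.0], [1, 2, 3])

    def test_missing_values_removed_first(self):
        r1 = pn.two_sample_t([1, 2, np.nan, 3], [4, 5, 6])
        r2 = pn.two_sample_t([1, 2, 3], [4, 5, 6])
        assert r1.t_stat == pytest.approx(r2.t_stat)


def brute_force_bh(p):
    """Step-up definition applied literally: q_i = min_{j>=i} p_(j)·m/j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0)
    return q


class TestBHAdjust:
    def test_hand_example(self):
        out = pn.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_values(self):
        assert pn.bh_adjust([0.3]).tolist() == [0.3]
        assert pn.bh_adjust([0.5, 0.5]).tolist() == pytest.approx([0.5, 0.5])

    def test_missing_entries_restored(self):
        out = pn.bh_adjust([0.02, np.nan, 0.04])
        assert np.isnan(out[1])
        # family excludes the missing entry (m = 2)
        assert out[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(pn.ValidationError):
            pn.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force_definition(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(pn.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_permutation_invariance_and_monotonicity(self, p, rnd):
        p = np.asarray(p)
        q = pn.bh_adjust(p)
        # monotone non-decreasing along sorted p order
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = pn.bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestSignedScore:
    def test_fdr_005_reaches_cutoff(self):
        assert pn.signed_score(0.5, 0.05) == pytest.approx(1.30103, abs=1e-5)
        assert pn.signed_score(0.5, 0.05) >= pn.SIGNED_FDR_CUTOFF

    def test_zero_cases(self):
        assert pn.signed_score(0.7, 1.0) == 0
        assert pn.signed_score(0.0, 0.001) == 0

    def test_negative_direction(self):
        assert pn.signed_score(-2.0, 0.01) == pytest.approx(-2.0)


class TestCompareLayer:
    def test_null_layer_no_discoveries(self):
        cohort = make_cohort(seed=11, n_features=200)
        table = pn.compare_layer(cohort, "MUT1", "rna")
        assert (table.testable["fdr"] < 0.05).sum() == 0
        assert not table.any_significant

    def test_planted_feature_attains_max_signed_fdr(self):
        cohort = make_cohort(seed=12, n_features=200, shift_features={"F005": 3.0})
        table = pn.compare_layer(cohort, "MUT1", "rna")
        best = table.rows.loc[table.rows["signed_fdr"].idxmax(), "feature"]
        assert best == "F005"
        assert table.any_significant

    def test_sparse_feature_outside_bh_family(self):
        cohort = make_cohort(seed=13, n_samples=30, n_mut=5, n_features=10)
        vals = cohort.layer("rna").values.copy()
        vals.iloc[0, 1:5] = np.nan  # one non-missing mutant value left
        layer = pn.OmicsMatrix(vals, "rna", normalized=True)
        cohort = pn.assemble_cohort("X", cohort.mutations, {"rna": layer})
        table = pn.compare_layer(cohort, "MUT1", "rna")
        row = table.rows.iloc[0]
        assert np.isnan(row["p"]) and np.isnan(row["fdr"])
        assert len(table.testable) == 9

    def test_single_mutant_untestable(self):
        cohort = make_cohort(seed=14, n_mut=1)
        with pytest.raises(pn.UndefinedStatistic):
            pn.compare_layer(cohort, "MUT1", "rna")

    def test_requires_normalized_layer(self):
        cohort = make_cohort(seed=15)
        raw = pn.OmicsMatrix(cohort.layer("rna").values, "rna", normalized=False)
        cohort = pn.assemble_cohort("X", cohort.mutations, {"rna": raw})
        with pytest.raises(pn.ValidationError):
            pn.compare_layer(cohort, "MUT1", "rna")

    def test_label_flip_negates_signed_fdr(self):
        cohort = make_cohort(seed=16, n_features=50, shift_features={"F001": 2.0})
        table = pn.compare_layer(cohort, "MUT1", "rna")
        flipped_status = 1 - cohort.mutations.status
        flipped = pn.assemble_cohort(
            "X", pn.MutationMatrix(flipped_status), dict(cohort.layers))
        table_f = pn.compare_layer(flipped, "MUT1", "rna")
        np.testing.assert_allclose(table_f.rows["signed_fdr"],
                                   -table.rows["signed_fdr"], atol=1e-12)


class TestLogrank:
    def test_identical_groups(self):
        r = pn.logrank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert r.chi_sq == 0 and r.p == 1

    def test_hand_computed_four_subject_table(self):
        # risk tables by hand over event times 1..4:
        # O_mut = 2, E_mut = 1/2 + 1/3, Var = 1/4 + 2/9
        r = pn.logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        o_minus_e = 2 - (0.5 + 1 / 3)
        var = 0.25 + 2 / 9
        assert r.chi_sq == pytest.approx(o_minus_e**2 / var)
        assert r.p == pytest.approx(float(stats.chi2.sf(o_minus_e**2 / var, 1)))
        assert r.worse_in_mutant

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(21)
        t1, e1 = rng.exponential(5, 40), rng.integers(0, 2, 40)
        t2, e2 = rng.exponential(8, 60), rng.integers(0, 2, 60)
        if e1.sum() + e2.sum() == 0:
            e1[0] = 1
        ours = pn.logrank_test(t1, e1, t2, e2)
        ref = lifelines.statistics.logrank_test(t1, t2, e1, e2)
        assert ours.chi_sq == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_time_scale_invariance(self):
        t1, e1 = [1.0, 2, 5, 7], [1, 0, 1, 1]
        t2, e2 = [3.0, 4, 6, 9], [1, 1, 0, 1]
        a = pn.logrank_test(t1, e1, t2, e2)
        b = pn.logrank_test(np.array(t1) * 365.25, e1, np.array(t2) * 365.25, e2)
        assert a.chi_sq == pytest.approx(b.chi_sq)
        assert a.p == pytest.approx(b.p)

    def test_early_mutant_events_worse(self):
        r = pn.logrank_test([1, 2, 3], [1, 1, 1], [10, 11, 12], [1, 1, 1])
        assert r.worse_in_mutant

    def test_zero_events_undefined(self):
        with pytest.raises(pn.UndefinedStatistic):
            pn.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


def hypergeom_two_sided_p(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum of table probabilities <= observed."""
    from math import comb
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom
    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestCooccurrence:
    def mm(self, cols):
        genes = [f"G{i}" for i in range(len(cols))]
        samples = [f"S{i}" for i in range(len(cols[0]))]
        return pn.MutationMatrix(pd.DataFrame(cols, index=genes, columns=samples))

    def test_identical_columns_co_occur(self):
        col = [1] * 10 + [0] * 10
        out = pn.mutation_cooccurrence(self.mm([col, col]))
        assert out.loc[0, "label"] == "co_occurring"

    def test_disjoint_columns_mutually_exclusive(self):
        a = [1] * 10 + [0] * 10
        b = [0] * 10 + [1] * 10
        out = pn.mutation_cooccurrence(self.mm([a, b]))
        assert out.loc[0, "label"] == "mutually_exclusive"

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        a = [1] * 10 + [0] * 10
        out = pn.mutation_cooccurrence(self.mm([a, a]))
        # 2x2 table (10, 0, 0, 10)
        assert out.loc[0, "p"] == pytest.approx(hypergeom_two_sided_p(10, 0, 0, 10))

    @pytest.mark.parametrize("table", [(3, 5, 2, 8), (1, 0, 4, 9), (6, 2, 2, 6)])
    def test_fisher_p_random_margins(self, table):
        a, b, c, d = table
        g0 = [1] * (a + b) + [0] * (c + d)
        g1 = [1] * a + [0] * b + [1] * c + [0] * d
        out = pn.mutation_cooccurrence(self.mm([g0, g1]))
        assert out.loc[0, "p"] == pytest.approx(hypergeom_two_sided_p(a, b, c, d))

    def test_haldane_anscombe_on_zero_cell(self):
        a = [1] * 10 + [0] * 10
        out = pn.mutation_cooccurrence(self.mm([a, a]))
        assert out.loc[0, "odds_ratio"] == pytest.approx(10.5 * 10.5 / (0.5 * 0.5))
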