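import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import panorama as pn
from panorama.preprocess import SsgseaConfig


def om(values, features=None, samples=None, kind="rna"):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return pn.OmicsMatrix(pd.DataFrame(values, index=features, columns=samples), kind)


class TestZscoreNormalize:
    def test_basic_feature(self):
        m, report = pn.zscore_normalize(om([[1, 2, 3]]))
        assert m.values.iloc[0].tolist() == pytest.approx([-1, 0, 1])
        assert m.normalized and report == []

    def test_constant_feature_zeroed_and_flagged(self):
        m, report = pn.zscore_normalize(om([[4, 4, 4], [1, 2, 3]]))
        assert m.values.iloc[0].tolist() == [0, 0, 0]
        assert report == ["F0"]

    def test_missing_entries_preserved(self):
        # mean 2, SD(ddof=1) = sqrt(2) over the two observed values
        m, _ = pn.zscore_normalize(om([[1, np.nan, 3]]))
        row = m.values.iloc[0]
        assert row.iloc[0] == pytest.approx(-1 / np.sqrt(2))
        assert np.isnan(row.iloc[1])
        assert row.iloc[2] == pytest.approx(1 / np.sqrt(2))

    def test_single_observation_is_degenerate(self):
        m, report = pn.zscore_normalize(om([[5, np.nan, np.nan]]))
        assert report == ["F0"]
        assert m.values.iloc[0, 0] == 0 and np.isnan(m.values.iloc[0, 1])

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(0)
        m, _ = pn.zscore_normalize(om(rng.standard_normal((20, 15))))
        m2, _ = pn.zscore_normalize(
            pn.OmicsMatrix(m.values, m.layer_kind, normalized=False))
        np.testing.assert_allclose(m.values, m2.values, atol=1e-12)

    def test_refuses_normalized_input(self):
        m, _ = pn.zscore_normalize(om([[1, 2, 3]]))
        with pytest.raises(pn.ValidationError):
            pn.zscore_normalize(m)


class TestFrequencyFilter:
    def make(self, n_mut, n=100):
        status = np.zeros((1, n), dtype=int)
        status[0, :n_mut] = 1
        return pn.MutationMatrix(
            pd.DataFrame(status, index=["G"], columns=[f"S{i}" for i in range(n)]))

    def test_at_threshold_kept_when_inclusive(self):
        assert pn.filter_mutations_by_frequency(self.make(5), 0.05, True).genes == ["G"]

    def test_at_threshold_dropped_when_strict(self):
        assert pn.filter_mutations_by_frequency(self.make(5), 0.05, False).genes == []

    def test_below_threshold_dropped_either_way(self):
        for inclusive in (True, False):
            assert pn.filter_mutations_by_frequency(self.make(4), 0.05, inclusive).genes == []

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=8),
           st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inclusive_superset_of_strict(self, counts, threshold):
        n = 30
        status = np.zeros((len(counts), n), dtype=int)
        for i, k in enumerate(counts):
            status[i, :k] = 1
        m = pn.MutationMatrix(pd.DataFrame(
            status, index=[f"G{i}" for i in range(len(counts))],
            columns=[f"S{i}" for i in range(n)]))
        inc = set(pn.filter_mutations_by_frequency(m, threshold, True).genes)
        strict = set(pn.filter_mutations_by_frequency(m, threshold, False).genes)
        assert strict <= inc


def brute_force_ssgsea(values, features, members, alpha):
    """Independent running-sum oracle for a single sample, no missing values."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], features[i]))
    n = len(values)
    in_set = [features[i] in members for i in order]
    k = sum(in_set)
    if k == n:
        return 0.0
    weights = [(n - pos) ** alpha if in_set[pos] else 0.0 for pos in range(n)]
    wsum = sum(weights)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for pos in range(n):
        if in_set[pos]:
            p_in += weights[pos] / wsum
        else:
            p_out += 1.0 / (n - k)
        es += p_in - p_out
    return es


class TestSsgsea:
    cfg_raw = SsgseaConfig(alpha=0.25, normalize_range=False)

    def test_top_two_of_five_matches_oracle(self):
        vals = [5.0, 4.0, 3.0, 2.0, 1.0]
        m = om([[v, v] for v in vals])  # two identical samples (matrix minimum)
        sets = pn.GeneSetCollection({"TOP2": ["F0", "F1"]})
        got = pn.ssgsea_scores(m, sets, SsgseaConfig(alpha=0.0, normalize_range=False))
        expected = brute_force_ssgsea(vals, [f"F{i}" for i in range(5)], {"F0", "F1"}, 0.0)
        assert expected == pytest.approx(2.5)  # frozen hand value
        assert got.values.loc["TOP2", "S0"] == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_random_sets_match_oracle(self, alpha):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((12, 3))
        features = [f"F{i:02d}" for i in range(12)]
        m = om(vals, features=features)
        members = {"A": features[:4], "B": features[5:7]}
        got = pn.ssgsea_scores(m, pn.GeneSetCollection(members),
                               SsgseaConfig(alpha=alpha, normalize_range=False))
        for name, mem in members.items():
            for j, s in enumerate(m.samples):
                exp = brute_force_ssgsea(vals[:, j], features, set(mem), alpha)
                assert got.values.loc[name, s] == pytest.approx(exp)

    def test_all_features_set_scores_zero(self):
        m = om([[1, 4], [2, 5], [3, 6]])
        got = pn.ssgsea_scores(m, pn.GeneSetCollection({"ALL": ["F0", "F1", "F2"]}),
                               self.cfg_raw)
        assert (got.values == 0).all().all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((30, 4))
        features = [f"F{i:02d}" for i in range(30)]
        sets = pn.GeneSetCollection({"S1": features[:6], "S2": features[10:15]})
        base = pn.ssgsea_scores(om(vals, features=features), sets, self.cfg_raw)
        for transform in (np.exp, lambda x: 3 * x + 7):
            other = pn.ssgsea_scores(om(transform(vals), features=features), sets,
                                     self.cfg_raw)
            np.testing.assert_allclose(base.values, other.values, atol=1e-12)

    def test_missing_values_excluded_from_ranking(self):
        vals = np.array([[5.0, 5.0], [4.0, 4.0], [3.0, np.nan], [2.0, 2.0], [1.0, 1.0]])
        features = [f"F{i}" for i in range(5)]
        got = pn.ssgsea_scores(om(vals, features=features),
                               pn.GeneSetCollection({"T": ["F0", "F1"]}),
                               SsgseaConfig(alpha=0.0, normalize_range=False))
        exp = brute_force_ssgsea([5.0, 4.0, 2.0, 1.0], ["F0", "F1", "F3", "F4"],
                                 {"F0", "F1"}, 0.0)
        assert got.values.loc["T", "S1"] == pytest.approx(exp)

    def test_no_overlap_at_all_is_error(self):
        m = om([[1, 2], [3, 4]])
        with pytest.raises(pn.EmptyInputError):
            pn.ssgsea_scores(m, pn.GeneSetCollection({"X": ["NOPE"]}), self.cfg_raw)


class TestLinearSignatureScores:
    def normalized(self, vals, features):
        df = pd.DataFrame(np.asarray(vals, float),
                          index=features, columns=[f"S{i}" for i in range(len(vals[0]))])
        return pn.OmicsMatrix(df, "rna", normalized=True)

    def test_manual_dot_product(self):
        m = self.normalized([[0.5, 0.5], [0.5, 0.5], [1.0, 1.0]], ["A", "B", "C"])
        w = pn.SignatureWeights(pd.DataFrame({"SIG": [1.0, -1.0, 2.0]},
                                             index=["A", "B", "C"]))
        scores, used = pn.linear_signature_scores(m, w)
        assert scores.values.loc["SIG"].tolist() == pytest.approx([2.0, 2.0])
        assert used["SIG"] == 3

    def test_single_gene_weight_one_recovers_z(self):
        m = self.normalized([[0.3, -0.3]], ["A"])
        w = pn.SignatureWeights(pd.DataFrame({"SIG": [1.0]}, index=["A"]))
        scores, _ = pn.linear_signature_scores(m, w)
        assert scores.values.loc["SIG"].tolist() == pytest.approx([0.3, -0.3])

    def test_zero_shared_genes_is_error(self):
        m = self.normalized([[0.3, -0.3]], ["A"])
        w = pn.SignatureWeights(pd.DataFrame({"SIG": [1.0]}, index=["ZZZ"]))
        with pytest.raises(pn.EmptyInputError):
            pn.linear_signature_scores(m, w)
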