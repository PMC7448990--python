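"""Single-sample scoring, stratification, and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matam.inference import Regulon
from matam.scoring import (
    group_score_comparison,
    longitudinal_shift_analysis,
    regulator_activity,
    score_correlation,
    single_sample_score,
    stratify_samples,
)
from matam.types import ExpressionMatrix, GeneSet, LOG2P1, ScoreTable, ValidationError


def log_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), LOG2P1)


def score_table(values, samples=None, name="sig"):
    samples = samples or [f"s{j}" for j in range(len(values))]
    return ScoreTable(pd.Series(values, index=samples, dtype=float), name)


class TestSingleSampleScore:
    def test_single_gene_score_is_its_z(self):
        em = log_matrix([[0.0, 1.0, 2.0, 5.0]])
        st = single_sample_score(em, GeneSet("s", {"g0"}))
        z = stats.zscore(em.data.loc["g0"], ddof=1)
        np.testing.assert_allclose(st.scores.to_numpy(), z)

    def test_all_constant_set_genes_error(self):
        em = log_matrix([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ValidationError):
            single_sample_score(em, GeneSet("s", {"g0"}))

    def test_matches_mean_of_z_oracle(self, rng):
        em = log_matrix(rng.uniform(0, 8, (200, 10)))
        members = {f"g{i}" for i in rng.choice(200, size=25, replace=False)}
        st = single_sample_score(em, GeneSet("s", members))
        rows = em.data.loc[sorted(members)].to_numpy()
        z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, ddof=1,
                                                                 keepdims=True)
        np.testing.assert_allclose(st.scores.to_numpy(), z.mean(axis=0), atol=1e-12)
        assert st.n_genes_used == 25

    def test_affine_rescaling_of_gene_rows_leaves_scores_unchanged(self, rng):
        values = rng.uniform(0, 8, (30, 6))
        em = log_matrix(values)
        members = GeneSet("s", {f"g{i}" for i in range(10)})
        base = single_sample_score(em, members).scores
        a = rng.uniform(0.5, 3.0, size=(30, 1))
        b = rng.uniform(-2, 2, size=(30, 1))
        shifted = single_sample_score(log_matrix(np.abs(a) * values + b), members).scores
        np.testing.assert_allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-10)


class TestRegulatorActivity:
    def test_signed_difference(self):
        # positive targets all z=+1, negative all z=-1 in the first sample
        em = log_matrix([[2.0, 0.0, 1.0], [2.0, 0.0, 1.0],
                         [0.0, 2.0, 1.0], [0.0, 2.0, 1.0]])
        reg = Regulon("TF", frozenset({"g0", "g1"}), frozenset({"g2", "g3"}))
        st = regulator_activity(em, reg)
        assert st.scores.iloc[0] == pytest.approx(2.0)

    def test_empty_negative_half_is_mean_positive_z(self, rng):
        em = log_matrix(rng.uniform(0, 8, (20, 5)))
        reg = Regulon("TF", frozenset({"g0", "g1", "g2"}), frozenset())
        st = regulator_activity(em, reg)
        expected = single_sample_score(em, GeneSet("p", {"g0", "g1", "g2"})).scores
        np.testing.assert_allclose(st.scores.to_numpy(), expected.to_numpy())

    def test_matches_direct_recomputation(self, rng):
        em = log_matrix(rng.uniform(0, 8, (50, 8)))
        pos = frozenset(f"g{i}" for i in range(0, 12))
        neg = frozenset(f"g{i}" for i in range(12, 20))
        st = regulator_activity(em, Regulon("TF", pos, neg))
        z = em.data.sub(em.data.mean(axis=1), axis=0).div(
            em.data.std(axis=1, ddof=1), axis=0)
        expected = z.loc[sorted(pos)].mean() - z.loc[sorted(neg)].mean()
        np.testing.assert_allclose(st.scores.to_numpy(), expected.to_numpy(),
                                   atol=1e-12)

    def test_no_positive_targets_error(self, rng):
        em = log_matrix(rng.uniform(0, 8, (5, 4)))
        with pytest.raises(ValidationError):
            regulator_activity(em, Regulon("TF", frozenset({"absent"}), frozenset()))


class TestStratify:
    def test_median_rule(self):
        groups = stratify_samples(score_table([1.0, 2.0, 3.0, 4.0]))
        assert set(groups.index[groups == "high"]) == {"s2", "s3"}
        assert set(groups.index[groups == "low"]) == {"s0", "s1"}

    def test_all_equal_scores_error(self):
        with pytest.raises(ValidationError):
            stratify_samples(score_table([5.0, 5.0, 5.0]))

    def test_tertile_sizes_on_large_cohort(self, rng):
        n = 373
        groups = stratify_samples(score_table(rng.standard_normal(n)), rule="tertile")
        assert (groups == "high").sum() == n // 3
        assert (groups == "low").sum() == n // 3
        assert len(groups) == 2 * (n // 3)

    def test_median_rule_partitions_all_samples(self, rng):
        st = score_table(rng.standard_normal(11))
        groups = stratify_samples(st)
        assert set(groups.index) == set(st.samples)


class TestScoreCorrelation:
    def test_perfect_linear_relation(self):
        a = score_table([1.0, 2.0, 3.0, 4.0])
        b = score_table([3.0, 5.0, 7.0, 9.0])
        r, p = score_correlation(a, b)
        assert r == pytest.approx(1.0)

    def test_p_value_from_t_distribution(self, rng):
        # r = 0.7 at n = 9 corresponds to two-sided p ~ 0.036
        n, target_r = 9, 0.7
        x = rng.standard_normal(n)
        zx = (x - x.mean()) / x.std(ddof=1)
        e = rng.standard_normal(n)
        e = e - e.mean()
        e -= (e @ zx) / (zx @ zx) * zx
        y = target_r * zx + np.sqrt(1 - target_r**2) * e / e.std(ddof=1)
        r, p = score_correlation(score_table(x), score_table(y))
        assert r == pytest.approx(0.7, abs=1e-12)
        t = 0.7 * np.sqrt(n - 2) / np.sqrt(1 - 0.49)
        assert p == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-10)
        assert p == pytest.approx(0.036, abs=0.001)

    def test_matches_brute_force_pearson(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        r, _ = score_correlation(score_table(x), score_table(y))
        brute = (((x - x.mean()) * (y - y.mean())).sum()
                 / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        assert r == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(ValidationError):
            score_correlation(score_table([1.0, 1.0, 1.0]), score_table([1, 2, 3]))


def make_pairs(primary, recurrent):
    rows = []
    for i, (p, r) in enumerate(zip(primary, recurrent)):
        rows.append((f"P{i}", "primary", p))
        rows.append((f"P{i}", "recurrent", r))
    return pd.DataFrame(rows, columns=["pair_id", "timepoint", "score"])


class TestLongitudinalShift:
    def test_degenerate_identical_scores(self):
        pairs = make_pairs([1.0] * 6, [1.0] * 6)
        labels = pd.Series(["mes"] * 3 + ["non"] * 3,
                           index=[f"P{i}" for i in range(6)])
        deltas, t, p = longitudinal_shift_analysis(pairs, labels)
        assert (deltas == 0).all()
        assert (t, p) == (0.0, 1.0)

    def test_incomplete_pair_reported(self):
        pairs = make_pairs([1.0, 2.0], [2.0, 3.0]).drop(index=[3])
        labels = pd.Series(["a", "b"], index=["P0", "P1"])
        with pytest.raises(ValidationError, match="P1"):
            longitudinal_shift_analysis(pairs, labels)

    def test_planted_shift_detected_with_power(self):
        # delta = 1 sigma at 30+30 pairs: Welch t should reject at alpha=0.05
        # in the vast majority of replicates
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            primary = rng.standard_normal(60)
            shift = np.r_[np.ones(30), np.zeros(30)]
            recurrent = primary + shift + rng.standard_normal(60)
            labels = pd.Series(["mes"] * 30 + ["non"] * 30,
                               index=[f"P{i}" for i in range(60)])
            _, _, p = longitudinal_shift_analysis(make_pairs(primary, recurrent),
                                                  labels)
            hits += p < 0.05
        assert hits >= 80

    def test_null_labels_calibrated(self):
        rng = np.random.default_rng(42)
        primary = rng.standard_normal(60)
        recurrent = primary + rng.standard_normal(60)
        pairs = make_pairs(primary, recurrent)
        ids = [f"P{i}" for i in range(60)]
        rejections = 0
        n_perm = 500
        for _ in range(n_perm):
            labels = pd.Series(rng.permutation(["a"] * 30 + ["b"] * 30), index=ids)
            _, _, p = longitudinal_shift_analysis(pairs, labels)
            rejections += p < 0.05
        assert abs(rejections / n_perm - 0.05) <= 0.02


class TestGroupComparison:
    def test_identical_groups_give_zero_f(self):
        vals = [1.0, 2.0, 3.0] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        st = score_table(vals)
        f, p, _ = group_score_comparison(st, pd.Series(groups, index=st.samples))
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_pooled_t_squared(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(10) + 1
        st = score_table(np.r_[a, b])
        groups = pd.Series(["a"] * 8 + ["b"] * 10, index=st.samples)
        f, _, _ = group_score_comparison(st, groups)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_matches_sum_of_squares_oracle(self, rng):
        arrays = [rng.standard_normal(7) + d for d in (0, 0.5, 1.5)]
        st = score_table(np.concatenate(arrays))
        groups = pd.Series(["a"] * 7 + ["b"] * 7 + ["c"] * 7, index=st.samples)
        f, p, pairwise = group_score_comparison(st, groups)
        grand = np.concatenate(arrays).mean()
        ss_between = sum(len(a) * (a.mean() - grand)**2 for a in arrays)
        ss_within = sum(((a - a.mean())**2).sum() for a in arrays)
        f_oracle = (ss_between / 2) / (ss_within / (21 - 3))
        assert f == pytest.approx(f_oracle, rel=1e-10)
        assert len(pairwise) == 3
        assert (pairwise["q"] >= pairwise["p"] - 1e-15).all()

    def test_small_group_rejected(self):
        st = score_table([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            group_score_comparison(st, pd.Series(["a", "a", "b"], index=st.samples))
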