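"""Kaplan-Meier, log-rank, Fisher alteration tests, and limiting dilution.

Oracles: direct product-limit computation, the textbook hypergeometric
log-rank statistic, and exhaustive hypergeometric enumeration for the
two-sided Fisher p.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matam.simulate import simulate_limiting_dilution, simulate_survival
from matam.survival import (
    alteration_enrichment,
    km_estimate,
    limiting_dilution_frequency,
    logrank_test,
    survival_by_signature,
)
from matam.types import (
    AlterationMatrix,
    ExpressionMatrix,
    GeneSet,
    LOG2P1,
    SurvivalTable,
    ValidationError,
)


def surv_table(times, events, prefix="s"):
    return SurvivalTable(
        pd.DataFrame({"time": times, "event": events},
                     index=[f"{prefix}{i}" for i in range(len(times))]),
        time_unit="months",
    )


def km_oracle(times, events):
    """Direct product-limit estimator at each distinct event time."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    out = []
    s = 1.0
    for t in np.sort(np.unique(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out.append((t, s, n_at_risk))
    return out


def logrank_oracle(ta, ea, tb, eb):
    """Textbook hypergeometric expected-events log-rank chi-square."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    all_event_times = np.sort(np.unique(np.r_[ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in all_event_times:
        na, nb = (ta >= t).sum(), (tb >= t).sum()
        n = na + nb
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        d = da + db
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def fisher_p_oracle(table):
    """Two-sided Fisher p by point-probability enumeration of all tables."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, row1, col1)
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(kmin, kmax + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestKaplanMeier:
    def test_four_events_no_censoring(self):
        curve = km_estimate(surv_table([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(curve.n_at_risk, [4, 3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(surv_table([5, 6, 7], [0, 0, 0]))
        assert len(curve.event_times) == 0  # survival identically 1

    def test_matches_product_limit_oracle(self, rng):
        times = rng.integers(1, 30, size=60).astype(float)
        events = rng.integers(0, 2, size=60)
        curve = km_estimate(surv_table(times, events))
        oracle = km_oracle(times, events)
        np.testing.assert_allclose(curve.event_times, [t for t, _, _ in oracle])
        np.testing.assert_allclose(curve.survival, [s for _, s, _ in oracle],
                                   atol=1e-12)
        np.testing.assert_array_equal(curve.n_at_risk, [n for _, _, n in oracle])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 15, size=40).astype(float)
        curve = km_estimate(surv_table(times, np.ones(40, dtype=int)))
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        a = surv_table([1, 2, 3], [1, 1, 1], "a")
        b = surv_table([1, 2, 3], [1, 1, 1], "b")
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # A events at {1,2}, B events at {3,4}: O_A=2, E_A=5/6, V=17/36
        a = surv_table([1, 2], [1, 1], "a")
        b = surv_table([3, 4], [1, 1], "b")
        chi2, _ = logrank_test(a, b)
        expected = (2 - 5 / 6) ** 2 / (17 / 36)
        assert expected == pytest.approx(2.882, abs=0.001)
        assert chi2 == pytest.approx(expected, rel=1e-10)

    def test_matches_textbook_oracle_on_random_instances(self, rng):
        for _ in range(20):
            ta = rng.integers(1, 20, size=25).astype(float)
            ea = rng.integers(0, 2, size=25)
            tb = rng.integers(1, 20, size=30).astype(float)
            eb = rng.integers(0, 2, size=30)
            if ea.sum() + eb.sum() == 0:
                continue
            chi2, _ = logrank_test(surv_table(ta, ea, "a"), surv_table(tb, eb, "b"))
            assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-10)

    def test_invariant_under_monotone_time_transform(self, rng):
        ta = rng.integers(1, 20, size=20).astype(float)
        ea = np.ones(20, dtype=int)
        tb = rng.integers(1, 20, size=20).astype(float)
        eb = np.ones(20, dtype=int)
        chi2, _ = logrank_test(surv_table(ta, ea, "a"), surv_table(tb, eb, "b"))
        chi2_t, _ = logrank_test(surv_table(np.exp(ta / 5), ea, "a"),
                                 surv_table(np.exp(tb / 5), eb, "b"))
        assert chi2_t == pytest.approx(chi2, rel=1e-9)

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(surv_table([1], [0], "a"), surv_table([2], [0], "b"))


class TestSurvivalBySignature:
    def test_planted_hazard_detected(self, rng):
        n = 373
        scores = pd.Series(rng.standard_normal(n),
                           index=[f"p{i}" for i in range(n)])
        records = simulate_survival(scores, hazard_ratio_per_sd=2.0, seed=11)
        # build an expression matrix whose signature score reproduces `scores`
        sig_genes = [f"sig{i}" for i in range(5)]
        data = pd.DataFrame(
            np.vstack([scores.to_numpy() + 5] * 5
                      + [rng.standard_normal(n) + 5 for _ in range(5)]),
            index=sig_genes + [f"bg{i}" for i in range(5)],
            columns=scores.index)
        em = ExpressionMatrix(data, LOG2P1)
        groups, curves, (chi2, p) = survival_by_signature(
            em, GeneSet("sig", frozenset(sig_genes)), records)
        assert p < 0.05
        # the high-score group must fare worse
        median_high = curves["high"].event_times[curves["high"].survival <= 0.5][0]
        median_low = curves["low"].event_times[curves["low"].survival <= 0.5][0]
        assert median_high < median_low

    def test_single_group_rejected(self, rng):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        records = simulate_survival(scores, seed=1)
        data = pd.DataFrame(np.ones((3, 4)), index=["g1", "g2", "g3"],
                            columns=list("abcd"))
        with pytest.raises(ValidationError):
            survival_by_signature(ExpressionMatrix(data, LOG2P1),
                                  GeneSet("s", frozenset({"g1"})), records)


class TestAlterationEnrichment:
    @staticmethod
    def _calls(matrix, genes, samples):
        return AlterationMatrix(pd.DataFrame(matrix, index=genes, columns=samples))

    def test_balanced_table(self):
        samples = [f"s{i}" for i in range(20)]
        calls = self._calls([[1] * 5 + [0] * 5 + [1] * 5 + [0] * 5],
                            ["g"], samples)
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=samples)
        per_gene, _ = alteration_enrichment(calls, groups)
        assert per_gene.loc["g", "odds_ratio"] == pytest.approx(1.0)
        assert per_gene.loc["g", "p"] == pytest.approx(1.0)

    def test_enriched_table_or_and_enumeration_p(self):
        # 2x2 table [[8,2],[1,9]]: OR = 36, p from exhaustive enumeration
        samples = [f"s{i}" for i in range(20)]
        calls = self._calls([[1] * 8 + [0] * 2 + [1] * 1 + [0] * 9],
                            ["g"], samples)
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=samples)
        per_gene, _ = alteration_enrichment(calls, groups)
        assert per_gene.loc["g", "odds_ratio"] == pytest.approx(36.0)
        assert per_gene.loc["g", "p"] == pytest.approx(
            fisher_p_oracle([[8, 1], [2, 9]]), abs=1e-12)

    def test_fisher_matches_enumeration_on_all_small_tables(self, rng):
        samples = [f"s{i}" for i in range(16)]
        groups = pd.Series(["high"] * 7 + ["low"] * 9, index=samples)
        for _ in range(50):
            row = rng.integers(0, 2, size=16)
            per_gene, _ = alteration_enrichment(self._calls([row], ["g"], samples),
                                                groups)
            a = int(row[:7].sum())
            b = int(row[7:].sum())
            oracle = fisher_p_oracle([[a, b], [7 - a, 9 - b]])
            assert per_gene.loc["g", "p"] == pytest.approx(oracle, abs=1e-12)

    def test_pathway_union_fraction(self):
        samples = [f"s{i}" for i in range(10)]
        matrix = [[1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                  [0, 0, 1, 0, 0, 0, 0, 0, 0, 0]]
        calls = self._calls(matrix, ["g1", "g2"], samples)
        groups = pd.Series(["high"] * 10, index=samples)
        groups.iloc[5:] = "low"
        _, per_pathway = alteration_enrichment(
            calls, groups, [GeneSet("pw", frozenset({"g1", "g2"}))])
        # union of g1,g2 alterations covers samples s0-s2 -> 3/5 of 'high'
        assert per_pathway.loc["pw", "frac_high"] == pytest.approx(0.6)
        assert per_pathway.loc["pw", "frac_low"] == pytest.approx(0.0)


class TestLimitingDilution:
    def test_exact_single_hit_fractions(self):
        doses = [10, 100]
        total = [1000, 1000]
        neg = [round(1000 * np.exp(-0.01 * d)) for d in doses]
        res = limiting_dilution_frequency(doses, total, neg)
        assert res.frequency == pytest.approx(0.01, rel=2e-3)

    def test_all_degenerate_doses_rejected(self):
        with pytest.raises(ValidationError):
            limiting_dilution_frequency([10, 100], [96, 96], [96, 96])

    def test_recovery_from_simulated_counts(self):
        counts = simulate_limiting_dilution(0.01, [10, 100, 1000], 10_000, seed=5)
        res = limiting_dilution_frequency(counts["dose"], counts["wells_total"],
                                          counts["wells_negative"])
        assert abs(res.frequency - 0.01) / 0.01 <= 0.10
        assert res.ci_low <= 0.01 <= res.ci_high

    def test_zero_frequency_gives_all_negative_wells(self):
        counts = simulate_limiting_dilution(0.0, [10, 100], 96, seed=1)
        assert (counts["wells_negative"] == 96).all()
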