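"""Exact tests, Holm correction, survival analysis, proportion intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mistrans.phenotype_stats import (
    CountTable2x2,
    fisher_exact_2x2,
    holm_bonferroni,
    km_estimate,
    load_counts_csv,
    load_devtime_csv,
    load_survival_csv,
    logrank_test,
    proportion_ci,
    top_quantile_subset,
    welch_t_test,
    wilcoxon_rank_sum,
)


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_enumerated_example(self):
        # sum of hypergeometric point probabilities <= that of the observed
        # table, margins (10,10|10,10): (1+100+100+1)/184756
        assert fisher_exact_2x2([[1, 9], [9, 1]]) == pytest.approx(
            202 / 184756, rel=1e-9
        )

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2([[0, 10], [0, 10]]) == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 30, size=4)
            ours = fisher_exact_2x2([[a, b], [c, d]])
            ref = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-7)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CountTable2x2(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            CountTable2x2(0, 0, 0, 0)


class TestHolm:
    def test_stepdown_example(self):
        assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.2]) == pytest.approx([0.2])

    def test_all_ones_capped(self):
        assert holm_bonferroni([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(50):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            ours = holm_bonferroni(p)
            ref = multipletests(p, method="holm")[1]
            assert ours == pytest.approx(ref, rel=1e-12)
            assert (ours >= p - 1e-15).all()
            assert (ours <= 1.0).all()


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all C(4,2)=6 rank assignments; observed is one extreme -> p = 2/6
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, rel=1e-9)

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001

    def test_exact_vs_normal_agreement(self):
        # n=6 per group, no ties: the approximation stays within 0.02
        rng = np.random.default_rng(12)
        for _ in range(20):
            pooled = rng.permutation(np.arange(12, dtype=float))
            x, y = pooled[:6], pooled[6:]
            _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
            _, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
            assert abs(p_exact - p_norm) <= 0.02

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1, 1], [2, 3], mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_shifted_groups(self):
        t, p = welch_t_test([1, 2, 3], [11, 12, 13])
        # closed form: t = -10 / sqrt(1/3 + 1/3), df = 4
        expected_t = -10 / math.sqrt(2 / 3)
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), df=4), rel=1e-9)
        assert p < 0.01

    def test_zero_variance_equal_means(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = welch_t_test([2, 2, 2], [2, 2, 2])
        assert (t, p) == (0.0, 1.0)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1, 2])


class TestKaplanMeier:
    def test_all_deaths_product_limit(self):
        km = km_estimate([1, 2, 3], [True, True, True])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        km = km_estimate([1, 2, 3], [False, False, False])
        assert (km.survival == 1.0).all()
        assert km.survival_at(10) == 1.0

    def test_censoring_shrinks_risk_set(self):
        # 5 subjects: deaths at 1 and 4, censored at 2 and 3, death at 5
        # S(1)=4/5; censoring leaves 2 at risk at t=4: S(4)=4/5*1/2=2/5;
        # S(5)=0
        km = km_estimate([1, 2, 3, 4, 5], [True, False, False, True, True])
        assert km.survival_at(1) == pytest.approx(4 / 5)
        assert km.survival_at(4) == pytest.approx(2 / 5)
        assert km.survival_at(5) == pytest.approx(0.0)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 40).round(1)
        km = km_estimate(times, np.ones(40, bool))
        for t in km.timeline:
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_monotone_and_bounded_with_ci(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5, 30)
        observed = rng.random(30) < 0.7
        if not observed.any():
            observed[0] = True
        km = km_estimate(times, observed)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()
        assert (km.ci_lower <= km.survival + 1e-12).all()
        assert (km.ci_upper >= km.survival - 1e-12).all()

    def test_no_observations_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def _logrank_oracle(times_a, times_b):
    """Tiny independent log-rank: observed minus expected over death times."""
    events = sorted(set(times_a) | set(times_b))
    o_minus_e = 0.0
    var = 0.0
    for t in events:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        da = times_a.count(t)
        db = times_b.count(t)
        d, n = da + db, na + nb
        if n < 2:
            continue
        o_minus_e += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups(self):
        t = [3, 6, 9, 12]
        stat, p = logrank_test(t, [1, 1, 1, 1], t, [1, 1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        a, b = [1, 2, 3], [4, 5, 6]
        stat, p = logrank_test(a, [1] * 3, b, [1] * 3)
        expected = _logrank_oracle(a, b)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(sps.chi2.sf(expected, df=1), rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.exponential(10, 30)
        b = rng.exponential(15, 30)
        oa = rng.random(30) < 0.8
        ob = rng.random(30) < 0.8
        s1, p1 = logrank_test(a, oa, b, ob)
        s2, p2 = logrank_test(b, ob, a, oa)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_no_deaths_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3], [0])


class TestTopQuantile:
    def make_events(self, days, group="A", status="dead"):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(days))],
                "group": group,
                "sex": "F",
                "day": days,
                "status": status,
            }
        )

    def test_ceiling_count(self):
        out = top_quantile_subset(self.make_events(range(1, 9)), q=0.25)
        assert len(out) == 2  # ceil(0.25 * 8)
        assert sorted(out["day"]) == [7, 8]

    def test_q_one_keeps_all(self):
        out = top_quantile_subset(self.make_events(range(1, 9)), q=1.0)
        assert len(out) == 8

    def test_ties_broken_by_subject_id(self):
        events = self.make_events([5, 9, 9, 9])
        out = top_quantile_subset(events, q=0.5)
        assert list(out["subject_id"]) == ["s1", "s2"]

    def test_censored_excluded_and_per_group(self):
        a = self.make_events([1, 2, 3, 4])
        b = self.make_events([10, 20, 30, 40], group="B")
        b.loc[3, "status"] = "censored"
        out = top_quantile_subset(pd.concat([a, b]), q=0.5)
        assert sorted(out[out["group"] == "A"]["day"]) == [3, 4]
        # group B has 3 deaths -> ceil(1.5) = 2 kept, censored 40 excluded
        assert sorted(out[out["group"] == "B"]["day"]) == [20, 30]

    def test_bad_quantile(self):
        with pytest.raises(ValueError):
            top_quantile_subset(self.make_events([1]), q=0.0)


class TestProportionCI:
    def test_boundaries(self):
        lo, hi = proportion_ci(0, 20)
        assert lo == 0.0 and hi < 0.2
        lo, hi = proportion_ci(20, 20)
        assert hi == 1.0 and lo > 0.8

    def test_wilson_closed_form(self):
        # Wilson score interval computed directly from its formula
        k, n, z = 50, 100, sps.norm.ppf(0.975)
        phat = k / n
        denom = 1 + z**2 / n
        center = (phat + z**2 / (2 * n)) / denom
        half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
        lo, hi = proportion_ci(k, n)
        assert lo == pytest.approx(center - half, rel=1e-9)
        assert hi == pytest.approx(center + half, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)


class TestLoaders:
    def test_survival_loader_validates(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "subject_id,group,sex,day,status\n"
            "s1,A,F,3,dead\ns2,A,M,6,censored\n"
        )
        df = load_survival_csv(str(path))
        assert len(df) == 2
        path.write_text("subject_id,group,sex,day,status\ns1,A,F,3,escaped\n")
        with pytest.raises(ValueError, match="status"):
            load_survival_csv(str(path))

    def test_counts_loader_validates(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("group,success,failure\nA,5,5\nB,2,8\n")
        assert len(load_counts_csv(str(path))) == 2
        path.write_text("group,success\nA,5\n")
        with pytest.raises(ValueError, match="missing"):
            load_counts_csv(str(path))

    def test_devtime_loader_validates(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "subject_id,group,stage,hours\ns1,A,hatch,24\ns2,B,hatch,30\n"
        )
        assert len(load_devtime_csv(str(path))) == 2
        path.write_text("subject_id,group,stage,hours\ns1,A,hatch,-2\n")
        with pytest.raises(ValueError, match="negative"):
            load_devtime_csv(str(path))
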