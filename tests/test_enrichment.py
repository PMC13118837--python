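"""Enrichment statistics against exact rational oracles and library checks."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom
from statsmodels.stats.multitest import multipletests

from pansynteny.enrichment import (
    CategoryCounts,
    bh_fdr,
    enrich,
    fold_enrichment,
    hypergeom_pvalue,
    odds_ratio,
)


def exact_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Rational-arithmetic P(X >= k) for the hypergeometric distribution."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def cc(k, n, K, N, cat="c") -> CategoryCounts:
    return CategoryCounts(category_id=cat, k=k, n=n, K=K, N=N)


class TestFoldEnrichment:
    def test_proportional_case_is_one(self):
        assert fold_enrichment(cc(2, 5, 4, 10)) == pytest.approx(1.0)

    def test_worked_example(self):
        assert fold_enrichment(cc(3, 5, 4, 10)) == pytest.approx(1.5)

    def test_zero_k_is_zero(self):
        assert fold_enrichment(cc(0, 5, 4, 10)) == 0.0

    def test_undefined_category_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(cc(0, 5, 0, 10))

    def test_fe_above_one_iff_rate_above_population(self):
        for N in range(2, 12):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        fe = fold_enrichment(cc(k, n, K, N))
                        assert (fe > 1) == (k / n > K / N)


class TestHypergeomPvalue:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(cc(0, 5, 4, 10)) == 1.0

    def test_enumerated_examples(self):
        assert hypergeom_pvalue(cc(3, 5, 4, 10)) == pytest.approx(66 / 252, abs=1e-12)
        assert hypergeom_pvalue(cc(3, 3, 3, 6)) == pytest.approx(1 / 20, abs=1e-12)

    def test_exact_against_rational_oracle_all_small_parameters(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        p = hypergeom_pvalue(cc(k, n, K, N))
                        oracle = float(exact_tail(k, n, K, N))
                        assert abs(p - oracle) <= 1e-12, (k, n, K, N)

    def test_matches_scipy_at_scale(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(50, 5000))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            ours = hypergeom_pvalue(cc(k, n, K, N))
            ref = float(scipy_hypergeom.sf(k - 1, N, K, n))
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(cc(6, 5, 4, 10))


class TestOddsRatio:
    def test_cross_product_example(self):
        # a=3, b=2, c=1, d=4 -> (3*4)/(2*1) = 6
        or_, corrected = odds_ratio(cc(3, 5, 4, 10))
        assert or_ == pytest.approx(6.0) and not corrected

    def test_independence_gives_one(self):
        or_, _ = odds_ratio(cc(2, 5, 4, 10))  # 2*3 == 3*2
        assert or_ == pytest.approx(1.0)

    def test_zero_cell_triggers_correction(self):
        # k = n = K: c = 0
        or_, corrected = odds_ratio(cc(3, 3, 3, 10))
        assert corrected and math.isfinite(or_) and or_ > 0

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_column_swap(self, a, b, c, d):
        # table (a,b,c,d): k=a, n=a+b, K=a+c, N=a+b+c+d
        or1, c1 = odds_ratio(cc(a, a + b, a + c, a + b + c + d))
        # swapped columns: (b,a,d,c)
        or2, c2 = odds_ratio(cc(b, a + b, b + d, a + b + c + d))
        assert not c1 and not c2
        assert or1 * or2 == pytest.approx(1.0)


class TestBhFdr:
    def test_step_up_hand_computations(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert bh_fdr([0.005, 0.1, 0.9]) == pytest.approx([0.015, 0.15, 0.9])

    def test_single_p_is_itself(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_explicit_m_scales_up(self):
        assert bh_fdr([0.01], m=10) == pytest.approx([0.1])
        with pytest.raises(ValueError):
            bh_fdr([0.01, 0.02], m=1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(list(p)) == pytest.approx(list(ref))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_permutation_consistency_and_monotonicity(self, pvals, rand):
        q = bh_fdr(pvals)
        idx = list(range(len(pvals)))
        rand.shuffle(idx)
        q_perm = bh_fdr([pvals[i] for i in idx])
        assert q_perm == pytest.approx([q[i] for i in idx])
        order = np.argsort(pvals, kind="stable")
        q_sorted = [q[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(q_sorted, q_sorted[1:]))


class TestEnrich:
    def test_observation_equals_population(self):
        population = ["K1"] * 4 + ["K2"] * 6
        cat = {"K1": ["p1"], "K2": ["p2"]}
        df = enrich(population, population, cat)
        assert list(df["FE"]) == pytest.approx([1.0] * len(df))
        assert list(df["p"]) == pytest.approx([1.0] * len(df))

    def test_planted_four_fold_rate_recovered(self):
        # category A at 10% of population, 40% of observation -> FE = 4
        population = ["A"] * 10 + ["B"] * 90
        observation = ["A"] * 8 + ["B"] * 12
        cat = {"A": ["catA"], "B": ["catB"]}
        df = enrich(observation, population, cat).set_index("category")
        assert df.loc["catA", "FE"] == pytest.approx(4.0)

    def test_category_absent_from_population_excluded(self):
        population = ["B"] * 10 + ["C"] * 10
        observation = ["A", "B"]
        cat = {"A": ["only_obs"], "B": ["shared"], "C": ["other"]}
        df = enrich(observation, population, cat).set_index("category")
        assert bool(df.loc["only_obs", "excluded"])
        assert math.isnan(df.loc["only_obs", "q"])
        assert not df.loc["only_obs", "significant_q"]

    def test_per_cluster_mode_adjusts_independently(self):
        population = ["A"] * 5 + ["B"] * 5 + ["C"] * 90
        obs = {1: ["A"] * 4, 2: ["B"] * 4 + ["C"] * 4}
        df = enrich(obs, population, {x: [f"cat{x}"] for x in "ABC"},
                    mode="per_cluster")
        one = df[df.cluster_id == 1]
        # a single test in cluster 1: q == p
        assert one["q"].iloc[0] == pytest.approx(one["p"].iloc[0])
        two = df[df.cluster_id == 2].set_index("category")
        assert len(two) == 2  # m = 2 within cluster 2

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            enrich(["A"], [], {})
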