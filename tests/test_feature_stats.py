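"""Univariate statistics against independent oracles (closed forms,
brute-force enumeration) and the published demographic tables."""

import math

import numpy as np
import pytest

from desilipid import (
    anova_feature,
    bh_fdr,
    fisher_exact_2x2,
    fold_change,
    select_discriminatory,
    welch_t,
)
from desilipid.errors import FittingError, ValidationError
from desilipid.feature_stats import feature_table


# ------------------------------------------------------------- oracles

def pooled_t(a, b):
    """Hand-computed equal-variance two-sample t."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))


def bh_bruteforce(p):
    """min over suffix of p_(j) * n / j, returned in input order."""
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    for rank_i, i in enumerate(order, start=1):
        q[i] = min(
            min(p[j] * n / rank_j for rank_j, j in enumerate(order, start=1)
                if rank_j >= rank_i),
            1.0,
        )
    return q


def fisher_bruteforce(table):
    """Two-sided Fisher p by exhausting all tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # hypergeometric point probability for cell (0,0)=x
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def welch_oracle(a, b):
    """Hand-computed Welch t and Satterthwaite df; p from the t CDF."""
    from scipy.stats import t as tdist

    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * tdist.sf(abs(t), df)


# --------------------------------------------------------------- ANOVA

class TestAnova:
    def test_identical_groups(self):
        F, p = anova_feature([np.ones(4), np.ones(4)])
        assert (F, p) == (0.0, 1.0)

    def test_separated_groups_limit(self):
        F, p = anova_feature([np.array([0, 1e-9, 0, 1e-9]),
                              np.array([1, 1 + 1e-9, 1, 1 - 1e-9])])
        assert p < 1e-12

    def test_two_group_f_equals_pooled_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(loc=0.5, size=rng.integers(3, 12))
            F, _p = anova_feature([a, b])
            assert F == pytest.approx(pooled_t(a, b) ** 2, rel=1e-10)

    def test_degenerate_group(self):
        with pytest.raises(FittingError):
            anova_feature([np.array([1.0]), np.array([1.0, 2.0])])


# ----------------------------------------------------------------- BH

class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(15):
            p = rng.uniform(size=rng.integers(1, 50))
            np.testing.assert_allclose(bh_fdr(p), bh_bruteforce(p), rtol=1e-12)

    def test_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(size=30))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


# ------------------------------------------------------------- fold change

def test_fold_change_examples():
    assert fold_change(5.0, 5.0) == 1.0
    assert fold_change(6.2, 5.0) == pytest.approx(1.24)
    assert math.isnan(fold_change(3.0, 0.0))


def test_select_discriminatory_edges(small_matrix, small_cohort):
    import pandas as pd

    empty = pd.DataFrame(columns=["mz", "q_value"])
    assert len(select_discriminatory(empty)) == 0
    _i, _m, metas = small_cohort
    labels = np.array([m.diagnosis for m in metas])
    df = feature_table(small_matrix, labels, "cancer", "benign")
    high = df.assign(q_value=1.0)
    assert len(select_discriminatory(high)) == 0
    sel = select_discriminatory(df)
    assert (sel["q_value"] < 0.05).all()
    assert sel["q_value"].is_monotonic_increasing


# --------------------------------------------------------------- Fisher

class TestFisher:
    @pytest.mark.parametrize(
        "table, printed",
        [
            ([[7, 6], [43, 8]], 0.028),    # menopause status
            ([[40, 13], [10, 1]], 0.431),  # diabetes status
            ([[46, 14], [4, 0]], 0.568),   # smoking status
            ([[31, 11], [19, 3]], 0.346),  # family history
            ([[11, 6], [39, 8]], 0.170),   # BMI distribution
        ],
    )
    def test_published_cohort_tables(self, table, printed):
        assert round(fisher_exact_2x2(table), 3) == pytest.approx(printed)

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            t = rng.integers(1, 11, size=(2, 2))  # totals <= 40
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_bruteforce(t), rel=1e-9
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[0, 0], [3, 4]])


# ---------------------------------------------------------------- Welch

class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        _ta, pa = welch_t(a, b)
        _tb, pb = welch_t(b, a)
        assert pa == pytest.approx(pb)

    def test_matches_hand_formula(self, rng):
        for _ in range(10):
            a = rng.normal(size=9)
            b = rng.normal(loc=1.0, scale=2.0, size=6)
            t, p = welch_t(a, b)
            t0, p0 = welch_oracle(a, b)
            assert t == pytest.approx(t0, rel=1e-10)
            assert p == pytest.approx(p0, rel=1e-9)


# ------------------------------------------------------- type-I calibration

def test_null_features_have_calibrated_p_values(rng):
    """On exchangeable groups ~5% of features reach p<0.05."""
    hits = 0
    n_feat = 400
    for _ in range(n_feat):
        a, b = rng.normal(size=20), rng.normal(size=12)
        _F, p = anova_feature([a, b])
        hits += p < 0.05
    assert 0.02 <= hits / n_feat <= 0.09
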