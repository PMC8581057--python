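import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rrscan.differential import (
    bh_adjust,
    fisher_window_test,
    fold_change,
    nb_gene_test,
    significance_stars,
    two_group_t,
)


def bh_by_hand(p):
    """Step-up formula applied literally: q_i = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def fisher_enum(a, b, c, d):
    """Exhaustive hypergeometric enumeration in exact integer arithmetic."""
    r1, r2, col1 = a + b, c + d, a + c
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(max(0, col1 - r2), min(col1, r1) + 1):
        num = math.comb(r1, k) * math.comb(r2, col1 - k)
        if num <= obs:
            total += num
    return total / math.comb(r1 + r2, col1)


class TestFoldChange:
    def test_plain_ratio_without_pseudocount(self):
        assert fold_change(10, 2, eps=0) == 5.0

    def test_degenerate_zero_zero_is_one(self):
        assert fold_change(0, 0, eps=0.5) == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0.01, 10),
    )
    def test_reciprocal_identity(self, a, b, eps):
        assert fold_change(a, b, eps) * fold_change(b, a, eps) == pytest.approx(1.0, rel=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1, 2)


class TestFisherWindowTest:
    def test_balanced_table_is_one(self):
        assert fisher_window_test(5, 5, 5, 5) == 1.0

    def test_perfect_separation(self):
        # only the observed table and its mirror are as extreme
        assert fisher_window_test(10, 0, 0, 10) == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_zero_margin_convention(self):
        assert fisher_window_test(0, 0, 3, 4) == 1.0
        assert fisher_window_test(0, 5, 0, 7) == 1.0

    def test_matches_enumeration_on_small_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_window_test(a, b, c, d) == pytest.approx(
                fisher_enum(a, b, c, d), abs=1e-12
            )

    def test_matches_scipy_on_library_scale_tables(self, rng):
        # independent cross-check of the log-gamma path
        for _ in range(20):
            a = int(rng.integers(0, 2_000))
            c = int(rng.integers(0, 2_000))
            b, d = 1_000_000 - a, 1_100_000 - c
            ours = fisher_window_test(a, b, c, d)
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_row_and_column_swap_exchangeability(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
            p = fisher_window_test(a, b, c, d)
            assert fisher_window_test(c, d, a, b) == pytest.approx(p, abs=1e-12)
            assert fisher_window_test(b, a, d, c) == pytest.approx(p, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_window_test(-1, 2, 3, 4)


class TestBhAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03], abs=1e-15)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.0421]) == pytest.approx([0.0421])

    def test_matches_hand_formula_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 100))
            assert np.allclose(bh_adjust(p), bh_by_hand(p), atol=1e-12)

    def test_never_exceeds_one_and_dominates_input(self, rng):
        p = rng.uniform(size=500)
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= p - 1e-15)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def nb_counts(rng, n_genes, n_reps, mu, phi):
    lam = rng.gamma(1 / phi, mu * phi, size=(n_genes, n_reps))
    return rng.poisson(lam).astype(float)


class TestNbGeneTest:
    def test_identical_groups_null_identity(self):
        c = np.array([10.0, 20.0, 30.0])
        fc, p = nb_gene_test(c, c, np.ones(3), np.ones(3))
        assert fc == 1.0 and p == 1.0

    def test_all_zero_counts_give_p_one(self):
        z = np.zeros(3)
        fc, p = nb_gene_test(z, z, np.ones(3) * 1e6, np.ones(3) * 1e6)
        assert fc == 1.0 and p == 1.0

    def test_null_type_one_error_calibrated(self, rng):
        ca = nb_counts(rng, 2000, 3, 100, 0.1)
        cb = nb_counts(rng, 2000, 3, 100, 0.1)
        s = np.full(3, 1e6)
        _, p = nb_gene_test(ca, cb, s, s)
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_planted_fold_change_recovered(self, rng):
        ca = nb_counts(rng, 500, 3, 1000, 0.1)
        cb = nb_counts(rng, 500, 3, 100, 0.1)
        s = np.full(3, 1e6)
        fc, p = nb_gene_test(ca, cb, s, s)
        assert 7 <= np.median(fc) <= 13
        assert (p < 0.05).mean() > 0.99

    def test_approaches_poisson_wald_as_dispersion_vanishes(self, rng):
        # Poisson data: the moment dispersion estimate concentrates near 0,
        # and p-values approach those computed with the Poisson variance.
        mu = 500.0
        ca = rng.poisson(mu, size=(500, 50)).astype(float)
        cb = rng.poisson(mu, size=(500, 50)).astype(float)
        s = np.ones(50)
        fc, p = nb_gene_test(ca, cb, s, s)
        ma, mb = ca.mean(1), cb.mean(1)
        se = np.sqrt(ma / 50 / ma**2 + mb / 50 / mb**2)
        z = np.log((ma + 0.5) / (mb + 0.5)) / se
        p_pois = 2 * stats.t.sf(np.abs(z), df=98)
        assert np.corrcoef(p, p_pois)[0, 1] > 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nb_gene_test(np.zeros((1, 0)), np.ones((1, 2)), np.array([]), np.ones(2))


class TestTwoGroupT:
    def test_identical_groups(self):
        t, p = two_group_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form_t(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10
        t, p = two_group_t(a, b)
        df = 4
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / df
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df), rel=1e-12)

    def test_swap_negates_t_keeps_p(self, rng):
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        t1, p1 = two_group_t(a, b)
        t2, p2 = two_group_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_conventions(self):
        assert two_group_t([5, 5], [5, 5]) == (0.0, 1.0)
        t, p = two_group_t([5, 5], [7, 7])
        assert math.isinf(t) and p == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_t([1], [1, 2])


def test_significance_star_thresholds():
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.5) == "n.s."
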