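"""Detection-probability model: closed forms vs brute force and simulation."""

import math

import numpy as np
import pytest
from scipy import stats

from snpdiscover import theory

# Expected (correct calls, FP%) for the default assumptions: 800k true SNPs,
# 30k duplication differences, 2.3 mean copies.  Verified against the
# published model table before freezing.
TABLE1 = {
    (0.5, 4): (473, 54.8), (0.5, 5): (552, 65.0), (0.5, 6): (561, 68.3),
    (0.5, 7): (561, 69.0), (0.5, 8): (561, 69.1),
    (1.0, 4): (4598, 28.6), (1.0, 5): (6131, 37.9), (1.0, 6): (6450, 43.5),
    (1.0, 7): (6501, 45.9), (1.0, 8): (6508, 46.7),
    (1.5, 4): (14119, 14.9), (1.5, 5): (21179, 21.4), (1.5, 6): (23386, 26.8),
    (1.5, 7): (23915, 30.3), (1.5, 8): (24021, 32.0),
    (2.0, 4): (27067, 7.8), (2.0, 5): (45111, 11.8), (2.0, 6): (52630, 16.0),
    (2.0, 7): (55036, 19.5), (2.0, 8): (55675, 21.8),
    (2.5, 4): (40080, 4.1), (2.5, 5): (73481, 6.5), (2.5, 6): (90877, 9.4),
    (2.5, 7): (97835, 12.2), (2.5, 8): (100145, 14.6),
}


class TestFTwice:
    def test_zero(self):
        assert theory.f_twice(0.0) == 0.0

    def test_half_coverage_squared(self):
        # z = f(λ/2) at λ=1; z² is the identifiable genome fraction
        z = theory.f_twice(0.5)
        assert round(z * z, 4) == 0.0081

    def test_monotone(self):
        lams = np.linspace(0, 20, 100)
        vals = [theory.f_twice(l) for l in lams]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0 and vals[-1] > 0.999

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            theory.f_twice(-0.1)


class TestRule1:
    def test_single_individual(self):
        assert theory.detect_prob_rule1(1.0, 0.5) == pytest.approx(
            theory.f_twice(0.5) ** 2)

    def test_symmetric(self):
        assert theory.detect_prob_rule1(3.0, 0.3) == pytest.approx(
            theory.detect_prob_rule1(3.0, 0.7))

    def test_rare_allele_vanishes(self):
        assert theory.detect_prob_rule1(2.0, 1e-6) < 1e-9

    def test_het_plus_hom_matches_simulation(self, rng):
        # two individuals, one het one hom: allele proportions 3/4, 1/4
        lam, n = 4.0, 200_000
        closed = theory.detect_prob_rule1(lam, 0.75)
        k1 = rng.poisson(lam * 0.75, size=n)
        k2 = rng.poisson(lam * 0.25, size=n)
        hat = np.mean((k1 >= 2) & (k2 >= 2))
        se = math.sqrt(closed * (1 - closed) / n)
        assert abs(hat - closed) < 3 * se


class TestCallingProb:
    def test_table_cell_lambda1_x5(self):
        assert int(800_000 * theory.calling_prob_P(1.0, 5)) == 6131

    def test_table_cell_lambda05_x4(self):
        assert int(800_000 * theory.calling_prob_P(0.5, 4)) == 473

    def test_vanishes_at_zero(self):
        assert theory.calling_prob_P(0.0, 6) == 0.0
        assert theory.calling_prob_P(1e-4, 4) < 1e-12

    def test_x_below_four_rejected(self):
        with pytest.raises(ValueError):
            theory.calling_prob_P(1.0, 3)

    def test_bounded_by_uncapped_tail(self):
        for lam in (0.5, 2.0, 5.0):
            for x in (4, 6, 10):
                p = theory.calling_prob_P(lam, x)
                tail = 1.0 - stats.poisson.cdf(3, lam)
                assert 0.0 <= p <= tail + 1e-12

    def test_nondecreasing_in_x(self):
        for lam in (0.5, 2.0, 5.0):
            vals = [theory.calling_prob_P(lam, x) for x in range(4, 15)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_general_p_matches_binomial_form(self):
        # closed form with p=1/2 equals the explicit binomial evaluation
        for lam, x in [(1.0, 5), (2.5, 8)]:
            explicit = sum(
                stats.poisson.pmf(k, lam)
                * (stats.binom.cdf(k - 2, k, 0.5) - stats.binom.cdf(1, k, 0.5))
                for k in range(4, x + 1)
            )
            assert theory.calling_prob_P(lam, x) == pytest.approx(explicit, rel=1e-12)


def test_table1_reproduces_all_cells():
    grid = theory.table1()
    assert len(grid) == 25
    for key, (correct, fp) in TABLE1.items():
        got = grid[key]
        assert got == (correct, fp), f"cell {key}: {got} != {(correct, fp)}"


class TestDupCallingProb:
    def test_t1_reduces_to_P(self):
        assert theory.dup_calling_prob(1.5, 6, 1) == pytest.approx(
            theory.calling_prob_P(1.5, 6))

    def test_t2_is_P_of_2lambda(self):
        assert theory.dup_calling_prob(1.0, 5, 2) == pytest.approx(
            theory.calling_prob_P(2.0, 5))

    def test_star_tree_proportions_for_t3(self):
        assert theory.dup_calling_prob(1.0, 8, 3) == pytest.approx(
            theory.calling_prob_P(3.0, 8, p=2 / 3))

    def test_rises_then_falls_with_t(self):
        vals = [theory.dup_calling_prob(1.0, 5, t) for t in range(1, 30)]
        peak = int(np.argmax(vals))
        assert 0 < peak < 28
        assert all(b <= a for a, b in zip(vals[peak:], vals[peak + 1:]))


class TestSensitivitySpecificity:
    def test_single_class_perfect_specificity(self):
        p = theory.TheoryParams(lam=2.0, x=6, copy_classes=[(1, 1_000_000, 1e-3)])
        sens, spec, tp = theory.sensitivity_specificity(p)
        assert spec == 1.0 and tp == 1.0
        assert sens == pytest.approx(theory.calling_prob_P(2.0, 6))

    def test_two_class_specificity_matches_explicit_sums(self):
        # independent evaluation of N(t) = p_t l_t P(λt) with scipy sums
        def P(lam, x):
            return sum(
                stats.poisson.pmf(k, lam) * (1 - (2 + 2 * k) / 2**k)
                for k in range(4, x + 1)
            )

        classes = [(1, 800_000_000, 1e-3), (2, 13_000_000, 2.3e-3)]
        n1 = 1e-3 * 800_000_000 * P(1.0, 5)
        n2 = 2.3e-3 * 13_000_000 * P(2.0, 5)
        p = theory.TheoryParams(lam=1.0, x=5, copy_classes=classes)
        sens, spec, tp = theory.sensitivity_specificity(p)
        assert spec == pytest.approx(n1 / (n1 + n2), rel=1e-9)
        assert tp == pytest.approx(n1 / (n1 + n2), rel=1e-9)  # t=2 uses p=q=1/2

    def test_missing_unique_class_rejected(self):
        with pytest.raises(ValueError):
            theory.TheoryParams(lam=1.0, x=5, copy_classes=[(2, 100, 1e-3)])

    def test_watson_coverage_sensitivity_in_unit_interval(self):
        lam = theory.coverage_lambda(18_952_140_632, int(3.08e9))
        sens = theory.calling_prob_P(lam, max(4, theory.c_threshold(lam)))
        assert 0.0 < sens < 1.0


def test_plan_coverage_inverts_yield():
    lam = theory.plan_coverage(1000, 1e-3, 3e9)
    x = max(4, theory.c_threshold(lam))
    assert 1e-3 * 3e9 * theory.calling_prob_P(lam, x) == pytest.approx(1000, rel=0.01)
    assert theory.plan_coverage(10**12, 1e-3, 1e6) == float("inf")
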