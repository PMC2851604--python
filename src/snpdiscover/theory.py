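"""Closed-form model of SNP detection probability under Poisson coverage.

With reads scattered uniformly and independently over a genome of size L,
the number of reads covering a position is approximately Poisson with mean
λ = n·l/L.  A variant is callable under the pipeline's two core rules —
each allele observed at least twice, and at most x reads overlapping the
position — with probability

    P(λ, x; p, q) = Σ_{k=4..x}  e^{-λ} λ^k / k!  ·  Pr(2 ≤ B_k ≤ k−2)

where B_k ~ Binomial(k, p) counts reads carrying the first allele.  For a
single diploid individual p = q = ½ and the inner term reduces to
1 − (2 + 2k)/2^k.

A collapsed column of a segmental duplication with t near-identical copies
sees coverage λ·t, so inter-copy differences are miscalled as SNPs with
probability P(λt), which is what drives the duplication false-positive
rate at low coverage and its decline as coverage (and the pile-up cap)
grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "f_twice",
    "detect_prob_rule1",
    "calling_prob_P",
    "table1",
    "dup_calling_prob",
    "sensitivity_specificity",
    "coverage_lambda",
    "c_threshold",
    "TheoryParams",
    "plan_coverage",
]


def f_twice(lam: float) -> float:
    """Probability a genome position is sequenced at least twice.

    f(λ) = 1 − e^{−λ}(1 + λ); monotone increasing, → 1 as λ → ∞.
    """
    if lam < 0:
        raise ValueError("coverage must be non-negative")
    return 1.0 - math.exp(-lam) * (1.0 + lam)


def detect_prob_rule1(lam: float, p: float, q: float | None = None) -> float:
    """Probability both alleles of a biallelic site are sequenced >= twice.

    Under the two-observations rule alone (no pile-up cap) this is
    f(λp)·f(λq) with p + q = 1 the allele proportions over all sequenced
    individuals.  For one diploid individual p = q = ½; for a heterozygote
    plus a homozygote among two equally covered individuals (p, q) = (¾, ¼).
    """
    if q is None:
        q = 1.0 - p
    if not (0.0 < p < 1.0) or abs(p + q - 1.0) > 1e-9:
        raise ValueError("allele proportions must satisfy 0 < p < 1, p + q = 1")
    return f_twice(lam * p) * f_twice(lam * q)


def _both_alleles_twice(k: int, p: float) -> float:
    """Pr(both alleles supported by >= 2 of k reads), reads iid Bernoulli(p)."""
    if k < 4:
        return 0.0
    if p == 0.5:
        return 1.0 - (2.0 + 2.0 * k) / 2.0**k
    b = stats.binom(k, p)
    return float(b.cdf(k - 2) - b.cdf(1))


def calling_prob_P(lam: float, x: int, p: float = 0.5, q: float | None = None) -> float:
    """Probability a SNP is called: both alleles >= twice and coverage <= x.

    Truncated Poisson–binomial sum over coverage k = 4..x.  ``x`` is the
    pile-up cap on reads overlapping the site (the pipeline sets it to the
    99.5th Poisson percentile of coverage, see :func:`c_threshold`).
    """
    if x < 4:
        raise ValueError("the cap x must be at least 4 (two reads per allele)")
    if q is None:
        q = 1.0 - p
    if not (0.0 < p < 1.0) or abs(p + q - 1.0) > 1e-9:
        raise ValueError("allele proportions must satisfy 0 < p < 1, p + q = 1")
    if lam < 0:
        raise ValueError("coverage must be non-negative")
    if lam == 0:
        return 0.0
    total = 0.0
    for k in range(4, x + 1):
        pois = math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
        total += pois * _both_alleles_twice(k, p)
    return total


def table1(
    true_snps: int = 800_000,
    dup_diffs: int = 30_000,
    mean_copies: float = 2.3,
    lam_grid: tuple = (0.5, 1.0, 1.5, 2.0, 2.5),
    x_grid: tuple = (4, 5, 6, 7, 8),
) -> dict:
    """Expected correct calls and duplication false-positive percentages.

    For each (λ, x) cell: ``correct = floor(true_snps · P(λ, x))`` and
    ``fp_pct = 100 · dup_diffs · P(mean_copies·λ, x) / (true_snps · P(λ, x))``
    rounded to one decimal.  Defaults reflect rough human-genome numbers:
    800,000 true heterozygous sites in single-copy sequence, 30,000
    inter-copy differences in duplicated sequence, 2.3 copies on average.
    """
    out = {}
    for lam in lam_grid:
        for x in x_grid:
            p_call = calling_prob_P(lam, x)
            correct = math.floor(true_snps * p_call)
            fp = 100.0 * dup_diffs * calling_prob_P(mean_copies * lam, x) / (true_snps * p_call)
            out[(lam, x)] = (correct, round(fp, 1))
    return out


def dup_calling_prob(lam: float, x: int, t: int) -> float:
    """Probability an inter-copy difference in a t-copy region is miscalled.

    Collapsed columns of a t-copy duplication are covered at λ·t.  For
    t <= 2 the two variant forms are balanced (p = q = ½); for t > 2 a
    star-tree mutation model puts the derived variant on one copy, giving
    proportions (1 − 1/t, 1/t).
    """
    if t < 1:
        raise ValueError("copy number t must be >= 1")
    if t <= 2:
        p = 0.5
    else:
        p = 1.0 - 1.0 / t
    return calling_prob_P(lam * t, x, p)


@dataclass
class TheoryParams:
    """Inputs to the duplication-aware sensitivity/specificity model.

    ``copy_classes`` lists (t, l_t, p_t): copy number, total distinct
    length of t-copy sequence in bp, and density of variant positions per
    bp within it (heterozygous SNPs for t = 1, inter-copy differences for
    t > 1).  λ is coverage per distinct base pair.
    """

    lam: float
    x: int
    copy_classes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(t == 1 for t, _, _ in self.copy_classes):
            raise ValueError("a unique-sequence class (t=1) is required")


def sensitivity_specificity(params: TheoryParams) -> tuple:
    """(sensitivity, specificity, true-positive proportion) of SNP calling.

    Sensitivity is the probability a unique-region SNP is called, P(λ).
    With N(t) = p_t · l_t · P(λt) the expected calls from t-copy sequence,
    specificity (the proportion of calls that are real SNPs) is
    N(1) / Σ_t N(t); the true-positive proportion evaluates the same ratio
    with the per-class star-tree allele proportions of
    :func:`dup_calling_prob`.
    """
    lam, x = params.lam, params.x
    sens = calling_prob_P(lam, x)
    n_half = {}
    n_star = {}
    for t, l_t, p_t in params.copy_classes:
        n_half[t] = p_t * l_t * calling_prob_P(lam * t, x, 0.5)
        n_star[t] = p_t * l_t * dup_calling_prob(lam, x, t)
    spec = n_half[1] / sum(n_half.values())
    tp_prop = n_star[1] / sum(n_star.values())
    return sens, spec, tp_prop


def coverage_lambda(total_bases: int, expected_genome_length: int) -> float:
    """Fold coverage λ = total sequenced bases / expected genome length."""
    if expected_genome_length <= 0:
        raise ValueError("expected genome length must be positive")
    return total_bases / expected_genome_length


def c_threshold(lam: float, percentile: float = 0.995) -> int:
    """Pile-up cap: smallest c with Poisson-CDF(c; λ) >= the percentile.

    Clusters gathering more members than this are flagged as candidate
    repeats; the cap rises automatically as cumulative coverage grows.
    """
    if lam < 0:
        raise ValueError("coverage must be non-negative")
    if lam == 0:
        return 0
    return int(stats.poisson.ppf(percentile, lam))


def plan_coverage(
    target_snps: int,
    snp_density: float,
    genome_size: float,
    x: int | None = None,
    lam_max: float = 40.0,
) -> float:
    """Smallest coverage λ at which the expected SNP yield meets a target.

    Expected yield is snp_density · genome_size · P(λ, x) with
    x = c_threshold(λ) when not fixed.  Returns ``inf`` if the target is
    unreachable below ``lam_max``.
    """
    total_sites = snp_density * genome_size
    lo, hi = 0.0, lam_max

    def yield_at(lam: float) -> float:
        if lam <= 0:
            return 0.0
        cap = x if x is not None else max(4, c_threshold(lam))
        return total_sites * calling_prob_P(lam, cap)

    if yield_at(lam_max) < target_snps:
        return float("inf")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if yield_at(mid) >= target_snps:
            hi = mid
        else:
            lo = mid
    return hi


def poisson_coverage_pmf(k: np.ndarray, lam: float) -> np.ndarray:
    """Poisson(λ) pmf over an integer array (convenience for plots/tests)."""
    return stats.poisson.pmf(k, lam)
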