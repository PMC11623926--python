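"""Exclusive-detection power for group comparisons of specific CHIP variants.

The question: given two groups of gene-level CHIP carriers, what is the
probability that a particular variant (say, the DNMT3A p.Arg882 hotspot,
which makes up about 10% of DNMT3A CHIP) is observed in one group and not
the other? Conditional on the variant being absent from one group, the
detection probability with ``n`` carriers in the other group and
per-carrier variant frequency ``p`` is

    power(n, p) = 1 - (1 - p)^n

The minimum carrier count for a target power follows in closed form, and
the required number of CHIP-positive samples per group divides that by the
gene-level CHIP prevalence. A general Poisson-binomial engine (exact pmf of
a sum of independent, non-identical Bernoulli trials, by iterative
convolution) backs the unconditional two-group exclusive-detection
probability for heterogeneous per-sample carriage probabilities.

All computations are exact or log1p-stable; no normal approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class PowerQuery:
    """Parameters of an exclusive-detection power calculation.

    ``p_variant``: relative frequency of the specific variant among
    gene-level CHIP carriers. ``gene_prevalence``: fraction of CHIP-positive
    samples carrying a CHIP variant in the gene of interest; may be given
    as an exact count ratio (e.g. ``Fraction(8, 50)``).
    """

    p_variant: float
    target_power: float
    gene_prevalence: float | Fraction

    def __post_init__(self) -> None:
        if not 0 < self.p_variant <= 1:
            raise ValueError("require 0 < p_variant <= 1")
        if not 0 < self.target_power < 1:
            raise ValueError("require 0 < target_power < 1")
        if not 0 < float(self.gene_prevalence) <= 1:
            raise ValueError("require 0 < gene_prevalence <= 1")


@dataclass(frozen=True)
class PowerResult:
    min_carriers: int
    required_chip_samples: int
    achieved_power: float


def detection_power(n: int, p: float) -> float:
    """P(variant detected in >= 1 of n carriers) = 1 - (1 - p)^n.

    Evaluated as -expm1(n * log1p(-p)) for stability at small p.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n == 0:
        return 0.0
    if p == 1.0:
        return 1.0
    return -math.expm1(n * math.log1p(-p))


def min_group_size(p: float, target: float) -> int:
    """Smallest carrier count n with detection_power(n, p) >= target.

    Closed form ceil(log(1-target) / log(1-p)), then verified by direct
    evaluation at n and n-1 to guard against floating ceil-off-by-one.
    """
    if not 0 < p <= 1:
        raise ValueError("power target unattainable: require 0 < p <= 1")
    if not 0 < target < 1:
        raise ValueError("require 0 < target < 1")
    if p == 1.0:
        return 1
    n = math.ceil(math.log1p(-target) / math.log1p(-p))
    n = max(n, 1)
    while detection_power(n, p) < target:
        n += 1
    while n > 1 and detection_power(n - 1, p) >= target:
        n -= 1
    return n


def required_cohort_size(min_carriers: int, gene_prevalence: float | Fraction) -> int:
    """Smallest m with m * gene_prevalence >= min_carriers.

    With prevalence as an exact count ratio a/b the arithmetic is integer:
    ceil(min_carriers * b / a).
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    prev = Fraction(gene_prevalence) if not isinstance(gene_prevalence, Fraction) else gene_prevalence
    if prev <= 0:
        raise ValueError("cohort size unattainable: gene_prevalence must be > 0")
    return math.ceil(Fraction(min_carriers) / prev)


def solve_power(query: PowerQuery) -> PowerResult:
    """Minimum carriers and cohort size for an exclusive-detection query."""
    n = min_group_size(query.p_variant, query.target_power)
    m = required_cohort_size(n, query.gene_prevalence)
    return PowerResult(
        min_carriers=n,
        required_chip_samples=m,
        achieved_power=detection_power(n, query.p_variant),
    )


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoulli trials.

    Iterative convolution (dynamic programming): O(n^2) time, exact up to
    float rounding. The empty product is the point mass at zero.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must be in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(pmf.size + 1)
        nxt[: pmf.size] += pmf * (1.0 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def _prob_none(probs: Sequence[float]) -> float:
    """P(zero carriers) = prod(1 - p_i), via a stable sum of log1p terms."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        return 1.0
    if np.any(probs == 1.0):
        return 0.0
    return math.exp(np.sum(np.log1p(-probs)))


def exclusive_detection_prob(
    probs_a: Sequence[float], probs_b: Sequence[float]
) -> float:
    """P(variant seen in exactly one of two groups).

    = P(>=1 in A) P(0 in B) + P(0 in A) P(>=1 in B) for independent
    per-sample carriage probabilities.
    """
    pa0 = _prob_none(probs_a)
    pb0 = _prob_none(probs_b)
    return (1.0 - pa0) * pb0 + pa0 * (1.0 - pb0)


def power_curve(p: float, n_max: int) -> np.ndarray:
    """detection_power(n, p) for n = 0..n_max, for TSV export/plotting."""
    return np.array([detection_power(n, p) for n in range(n_max + 1)])
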