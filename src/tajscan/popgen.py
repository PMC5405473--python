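"""Closed-form population-genetic estimators and Tajima's D confidence limits.

Everything here is computed from per-site allele counts, never from phased
haplotypes: the number of segregating sites S, the mean number of pairwise
differences k-hat, and Tajima's D are all functions of unordered allele
frequencies, so unphased diploid genotypes carry all the information needed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TajimaConstants",
    "SiteAlleleCounts",
    "WindowDiversity",
    "BetaApproxLimits",
    "DReason",
    "TajimasD",
    "tajima_constants",
    "mean_pairwise_differences",
    "site_heterozygosity_sum",
    "watterson_theta",
    "tajimas_d",
    "beta_confidence_limits",
]


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of the D statistic for a sample of n sequences."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Compute the sample-size constants entering Tajima's D.

    Parameters
    ----------
    n : int
        Number of sequences sampled (haplotypes, not individuals). Must be
        at least 2; a finite variance term additionally requires n >= 4.

    Returns
    -------
    TajimaConstants

    Notes
    -----
    a1 and a2 are the harmonic and generalized-harmonic sums over 1..n-1;
    e1 and e2 weight the linear and quadratic terms of the variance of
    ``k_hat - S/a1``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 sequences, got n={n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


class SiteAlleleCounts(NamedTuple):
    """Allele counts at one site among the n sampled sequences.

    ``allele_counts`` holds the count of every observed allele (reference
    first by convention, but the statistics are label-free). ``callable``
    is False when any sample is missing a genotype at the site.
    """

    position: int
    allele_counts: tuple[int, ...]
    callable: bool = True

    @property
    def is_segregating(self) -> bool:
        return sum(1 for c in self.allele_counts if c > 0) >= 2


class DReason(enum.Enum):
    """Why a window's D value is undefined."""

    OK = "ok"
    NO_VARIATION = "no_variation"
    ZERO_VARIANCE = "zero_variance"


class TajimasD(NamedTuple):
    value: float | None
    reason: DReason


@dataclass(frozen=True)
class WindowDiversity:
    """Per-window summary: S, k-hat, per-site pi, Watterson theta, D."""

    S: int
    k_hat: float
    pi_site: float
    theta_w: float
    D: float | None
    d_reason: DReason = DReason.OK


def site_heterozygosity_sum(counts_per_site: Sequence[Sequence[int]], n: int) -> float:
    """Sum over sites of the unbiased expected heterozygosity n/(n-1)*(1 - sum p^2)."""
    total = 0.0
    bias = n / (n - 1.0)
    for counts in counts_per_site:
        s = sum(counts)
        if s != n:
            raise ValueError(f"allele counts sum to {s}, expected n={n}")
        h = 1.0 - sum((c / n) ** 2 for c in counts)
        total += bias * h
    return total


def mean_pairwise_differences(sites: Sequence[SiteAlleleCounts], n: int) -> float:
    """Mean number of pairwise differences (k-hat) over a window.

    Equivalent to averaging, over all C(n,2) pairs of sequences, the number
    of sites at which the pair differs — but computed from allele
    frequencies so no phasing is required. Non-callable sites are skipped.
    """
    callable_counts = [s.allele_counts for s in sites if s.callable]
    return site_heterozygosity_sum(callable_counts, n)


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S/a1, on the per-window scale of S."""
    if S < 0:
        raise ValueError("S must be non-negative")
    return S / tajima_constants(n).a1


def tajimas_d(S: int, k_hat: float, n: int) -> TajimasD:
    """Tajima's D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Undefined (value None) when the window has no variation (S = 0), or
    when the variance term vanishes (S = 1 with n <= 3, where e1 = 0);
    the two cases carry distinct reason codes.
    """
    if S == 0:
        return TajimasD(None, DReason.NO_VARIATION)
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return TajimasD(None, DReason.ZERO_VARIANCE)
    return TajimasD((k_hat - S / c.a1) / math.sqrt(var), DReason.OK)


@dataclass(frozen=True)
class BetaApproxLimits:
    """Confidence limits for D under the rescaled-beta approximation.

    The density is supported on [Dmin, Dmax] and its shape parameters are
    the unique pair giving mean 0 and variance 1. ``alpha`` is the exponent
    attached to (Dmax - D) and ``beta_shape`` to (D - Dmin); in scipy's
    parameterization the scaled variable (D - Dmin)/(Dmax - Dmin) is
    Beta(beta_shape, alpha).
    """

    n: int
    Dmin: float
    Dmax: float
    alpha: float
    beta_shape: float
    coverage: float
    lower: float
    upper: float

    def _dist(self):
        return stats.beta(self.beta_shape, self.alpha, loc=self.Dmin,
                          scale=self.Dmax - self.Dmin)

    def pdf(self, d):
        return self._dist().pdf(d)

    def cdf(self, d):
        return self._dist().cdf(d)


def beta_confidence_limits(n: int, coverage: float = 0.95) -> BetaApproxLimits:
    """Theoretical confidence limits of D for sample size n.

    D is bounded: the most negative value Dmin is attained when every
    segregating site is a singleton, the most positive Dmax when every site
    is at frequency 1/2 (as S grows). A beta density on [Dmin, Dmax],
    rescaled to mean 0 and variance 1, approximates the null distribution;
    the limits are its symmetric tail quantiles.

    For five diploid strains (n = 10) at 95% coverage this gives
    (-1.733, 1.975).
    """
    if n < 4:
        raise ValueError("beta approximation requires n >= 4")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    c = tajima_constants(n)
    sqrt_e2 = math.sqrt(c.e2)
    dmin = (2.0 / n - 1.0 / c.a1) / sqrt_e2
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / c.a1) / sqrt_e2
    rng = dmax - dmin
    # Mean 0 requires beta_shape/(alpha+beta_shape) = -Dmin/range; variance 1
    # then fixes alpha+beta_shape = (-Dmin*Dmax - 1)/range. Closed form:
    scale = (-dmin * dmax - 1.0) / rng
    if scale <= 0:
        raise ValueError(f"degenerate support for n={n}")
    alpha = dmax * scale
    beta_shape = -dmin * scale
    dist = stats.beta(beta_shape, alpha, loc=dmin, scale=rng)
    tail = (1.0 - coverage) / 2.0
    lower = float(dist.ppf(tail))
    upper = float(dist.ppf(1.0 - tail))
    # ppf is a numerical inversion; guard against silent non-convergence.
    for q, x in ((tail, lower), (1.0 - tail, upper)):
        if abs(float(dist.cdf(x)) - q) > 1e-8:
            raise ArithmeticError("beta quantile inversion did not converge")
    return BetaApproxLimits(n=n, Dmin=dmin, Dmax=dmax, alpha=alpha,
                            beta_shape=beta_shape, coverage=coverage,
                            lower=lower, upper=upper)
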