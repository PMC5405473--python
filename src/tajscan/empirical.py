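"""Observed genome-wide D distribution and empirically corrected limits.

Demographic processes shift the whole genome's D distribution, so the
theoretical beta limits misclassify windows under non-equilibrium
demography. The correction used here is the empirical-percentile device:
take a fixed tail fraction of the *observed* distribution on each side as
the significance region. Because windowed D takes discrete values, a tied
run of values can straddle the nominal percentile; tied runs are included
or excluded as a block, never split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .popgen import BetaApproxLimits, beta_confidence_limits
from .windows import Significance, WindowStats, WindowStatus

log = logging.getLogger(__name__)

__all__ = ["TailConfig", "DistributionSummary", "build_distribution",
           "empirical_limits", "classify_windows"]


@dataclass(frozen=True)
class TailConfig:
    """Per-tail mass of the significance region (2% per tail by default)."""

    tail_fraction: float = 0.02
    tie_policy: Literal["exclude", "include"] = "exclude"

    def __post_init__(self):
        if not 0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")


@dataclass
class DistributionSummary:
    """The observed genome-wide distribution of D over analysed windows."""

    values: np.ndarray
    count: int
    mean: float
    min: float
    max: float
    theoretical_limits: BetaApproxLimits | None = None
    empirical_lower: float | None = None
    empirical_upper: float | None = None
    achieved_lower_mass: float = 0.0
    achieved_upper_mass: float = 0.0
    tail: TailConfig | None = None


def build_distribution(stats: Sequence[WindowStats], n_sequences: int,
                       include_partial: bool = False,
                       coverage: float = 0.95) -> DistributionSummary:
    """Collect D over ANALYSED windows (discarded/invariable excluded).

    Trailing partial windows are excluded by default: their shorter span
    deflates S-based statistics relative to full windows.
    """
    values = np.asarray([
        s.D for s in stats
        if s.status is WindowStatus.ANALYSED and s.D is not None
        and (include_partial or not s.window.is_partial)
    ], dtype=float)
    if len(values) == 0:
        raise ValueError("no analysed windows: cannot build a D distribution")
    if len(values) < 50:
        log.warning("only %d analysed windows; empirical limits will be "
                    "unstable", len(values))
    theo = beta_confidence_limits(n_sequences, coverage) if n_sequences >= 4 else None
    return DistributionSummary(
        values=values, count=len(values), mean=float(values.mean()),
        min=float(values.min()), max=float(values.max()),
        theoretical_limits=theo,
    )


def _tail_threshold(sorted_desc: np.ndarray, tail_fraction: float,
                    policy: str) -> tuple[float | None, float]:
    """Smallest value v with mass{x >= v} <= tail_fraction, ties blocked.

    ``sorted_desc`` must be sorted from most to least extreme (descending
    for the upper tail; pass the negated array for the lower tail).
    Returns (threshold, achieved_mass); threshold is None when even the
    most extreme tied run overshoots the tail under the "exclude" policy.
    """
    N = len(sorted_desc)
    k_max = int(np.floor(tail_fraction * N))
    if k_max == 0:
        return None, 0.0
    distinct, first_idx = np.unique(-sorted_desc, return_index=True)
    # np.unique sorts ascending on the negated array == descending original.
    cum_counts = np.append(first_idx[1:], N)  # mass{x >= distinct value}
    if policy == "include":
        # Include the tied run containing the k-th most extreme value,
        # even if that overshoots the requested tail.
        j = int(np.searchsorted(cum_counts, k_max))
        m = int(cum_counts[j])
        return float(-distinct[j]), m / N
    ok = cum_counts <= k_max
    if not ok.any():
        return None, 0.0
    j = int(np.max(np.nonzero(ok)[0]))
    return float(-distinct[j]), int(cum_counts[j]) / N


def empirical_limits(dist: DistributionSummary,
                     tail: TailConfig = TailConfig()) -> DistributionSummary:
    """Set empirical lower/upper limits on the distribution summary.

    The upper limit is the smallest observed D such that the mass at or
    above it does not exceed ``tail_fraction`` (the flagged block's least
    extreme member); symmetrically for the lower tail. With
    ``tie_policy="include"`` a tied run straddling the percentile is
    flagged wholesale instead of dropped.
    """
    x = np.sort(dist.values)
    if len(np.unique(x)) <= 2:
        log.warning("degenerate D distribution (<= 2 distinct values); "
                    "empirical limits undefined")
        dist.empirical_lower = dist.empirical_upper = None
        dist.achieved_lower_mass = dist.achieved_upper_mass = 0.0
        dist.tail = tail
        return dist
    upper, up_mass = _tail_threshold(x[::-1], tail.tail_fraction, tail.tie_policy)
    lower_neg, lo_mass = _tail_threshold(-x, tail.tail_fraction, tail.tie_policy)
    dist.empirical_upper = upper
    dist.empirical_lower = None if lower_neg is None else -lower_neg
    dist.achieved_upper_mass = up_mass
    dist.achieved_lower_mass = lo_mass
    dist.tail = tail
    return dist


def classify_windows(stats: Sequence[WindowStats],
                     dist: DistributionSummary) -> dict[str, int]:
    """Flag analysed windows beyond the empirical limits, in place.

    Returns counts per significance class.
    """
    if dist.tail is None:
        raise ValueError("empirical limits not set; call empirical_limits first")
    n_pos = n_neg = 0
    for s in stats:
        if s.status is not WindowStatus.ANALYSED or s.D is None:
            continue
        if dist.empirical_upper is not None and s.D >= dist.empirical_upper:
            s.significance = Significance.SIGNIFICANT_POSITIVE
            n_pos += 1
        elif dist.empirical_lower is not None and s.D <= dist.empirical_lower:
            s.significance = Significance.SIGNIFICANT_NEGATIVE
            n_neg += 1
        else:
            s.significance = Significance.NOT_SIGNIFICANT
    return {"significant_positive": n_pos, "significant_negative": n_neg,
            "significant_total": n_pos + n_neg}
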