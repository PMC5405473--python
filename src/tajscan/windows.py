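"""Tile the genome into windows, apply coverage filters, compute diversity.

A window is DISCARDED when less than ``min_callable_fraction`` of its bases
are callable (unmasked and fully genotyped across all strains), INVARIABLE
when it is covered but carries no segregating site, and ANALYSED otherwise.
Only ANALYSED windows have a defined Tajima's D.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import MaskSet, ReferenceIndex, VariantSite
from .popgen import (DReason, WindowDiversity, mean_pairwise_differences,
                     SiteAlleleCounts, tajima_constants, tajimas_d)

__all__ = ["ScanConfig", "Window", "WindowStatus", "Significance",
           "WindowStats", "partition_genome", "window_callable_fraction",
           "scan_windows", "scan_summary"]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters; defaults mirror a 1-kb, 90%-coverage, diploid scan."""

    window_size: int = 1000
    min_callable_fraction: float = 0.90
    ploidy: int = 2
    step: int | None = None  # None -> non-overlapping (step = window_size)
    include_partial: bool = False  # trailing partial windows in distribution

    def __post_init__(self):
        if not 0 < self.min_callable_fraction <= 1:
            raise ValueError("min_callable_fraction must be in (0, 1]")
        if self.step is not None and self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else self.window_size


@dataclass(frozen=True)
class Window:
    id: int
    chrom: str
    start: int
    end: int
    is_partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


class WindowStatus(enum.Enum):
    DISCARDED_LOW_COVERAGE = "discarded_low_coverage"
    INVARIABLE = "invariable"
    ANALYSED = "analysed"


class Significance(enum.Enum):
    NOT_SIGNIFICANT = "ns"
    SIGNIFICANT_POSITIVE = "positive"
    SIGNIFICANT_NEGATIVE = "negative"


@dataclass
class WindowStats:
    window: Window
    callable_fraction: float
    status: WindowStatus
    diversity: WindowDiversity | None = None
    significance: Significance = Significance.NOT_SIGNIFICANT

    @property
    def D(self) -> float | None:
        return self.diversity.D if self.diversity is not None else None


def partition_genome(index: ReferenceIndex, config: ScanConfig) -> list[Window]:
    """Tile every chromosome; a trailing remainder becomes a flagged partial."""
    windows: list[Window] = []
    step = config.effective_step
    wid = 0
    for chrom in index.names:
        length = index.lengths[chrom]
        start = 0
        while start < length:
            end = min(start + config.window_size, length)
            windows.append(Window(id=wid, chrom=chrom, start=start, end=end,
                                  is_partial=(end - start < config.window_size)))
            wid += 1
            start += step
    return windows


def window_callable_fraction(window: Window, mask: MaskSet,
                             missing_positions: Iterable[int] = ()) -> float:
    """Fraction of the window callable after masking and missing genotypes.

    ``missing_positions`` are sites inside the window at which at least one
    strain lacks a genotype; positions already masked are not double-counted.
    """
    masked = mask.masked_bases(window.chrom, window.start, window.end)
    missing = sum(
        1 for p in missing_positions
        if window.start <= p < window.end and not mask.is_masked(window.chrom, p)
    )
    return (window.length - masked - missing) / window.length


@dataclass
class _WindowAccumulator:
    sites: list[SiteAlleleCounts] = field(default_factory=list)
    missing_positions: list[int] = field(default_factory=list)


def scan_windows(windows: Sequence[Window], variants: Iterable[VariantSite],
                 mask: MaskSet, config: ScanConfig,
                 n_sequences: int | None = None) -> list[WindowStats]:
    """Assign variants to windows and compute WindowStats for each.

    Variants must arrive sorted by position within each chromosome. A site
    with any missing genotype is uncallable and subtracts from the callable
    length; masked sites are ignored entirely. ``n_sequences`` (strains x
    ploidy) is inferred from the first variant when not given.
    """
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for ws in by_chrom.values():
        ws.sort(key=lambda w: w.start)
    starts = {c: [w.start for w in ws] for c, ws in by_chrom.items()}

    acc: dict[int, _WindowAccumulator] = {w.id: _WindowAccumulator() for w in windows}
    last_pos: dict[str, int] = {}
    n = n_sequences

    for v in variants:
        if v.chrom in last_pos and v.position < last_pos[v.chrom]:
            raise ValueError(
                f"variant stream not sorted at {v.chrom}:{v.position + 1}")
        last_pos[v.chrom] = v.position
        if v.chrom not in by_chrom or mask.is_masked(v.chrom, v.position):
            continue
        if n is None:
            n = sum(len(gt) for gt in v.genotypes)
        ws = by_chrom[v.chrom]
        # Windows covering pos form a contiguous run ending at the last
        # window whose start <= pos (a single window at the default step).
        idx = bisect_right(starts[v.chrom], v.position) - 1
        while idx >= 0 and ws[idx].end > v.position:
            w = ws[idx]
            a = acc[w.id]
            if not v.fully_called:
                a.missing_positions.append(v.position)
            else:
                counts = v.allele_counts()
                if sum(1 for c in counts if c > 0) >= 2:
                    a.sites.append(SiteAlleleCounts(v.position, counts))
            idx -= 1

    if n is None:
        n = 10  # no variants anywhere: fall back to five diploid strains
    a1 = tajima_constants(n).a1

    out: list[WindowStats] = []
    for w in windows:
        a = acc[w.id]
        frac = window_callable_fraction(w, mask, a.missing_positions)
        if frac < config.min_callable_fraction:
            out.append(WindowStats(w, frac, WindowStatus.DISCARDED_LOW_COVERAGE))
            continue
        S = len(a.sites)
        if S == 0:
            out.append(WindowStats(
                w, frac, WindowStatus.INVARIABLE,
                WindowDiversity(S=0, k_hat=0.0, pi_site=0.0, theta_w=0.0,
                                D=None, d_reason=DReason.NO_VARIATION)))
            continue
        k_hat = mean_pairwise_differences(a.sites, n)
        callable_sites = round(frac * w.length)
        d = tajimas_d(S, k_hat, n)
        status = (WindowStatus.ANALYSED if d.value is not None
                  else WindowStatus.INVARIABLE)
        out.append(WindowStats(
            w, frac, status,
            WindowDiversity(S=S, k_hat=k_hat,
                            pi_site=k_hat / callable_sites if callable_sites else 0.0,
                            theta_w=S / a1, D=d.value, d_reason=d.reason)))
    return out


def scan_summary(stats: Sequence[WindowStats]) -> dict[str, int]:
    """Table-style bookkeeping: total, covered, invariable, analysed counts."""
    counts = {s: 0 for s in WindowStatus}
    for st in stats:
        counts[st.status] += 1
    total = len(stats)
    covered = total - counts[WindowStatus.DISCARDED_LOW_COVERAGE]
    return {
        "total_windows": total,
        "windows_covered": covered,
        "windows_discarded": counts[WindowStatus.DISCARDED_LOW_COVERAGE],
        "windows_invariable": counts[WindowStatus.INVARIABLE],
        "windows_with_d": counts[WindowStatus.ANALYSED],
    }
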