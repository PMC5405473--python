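"""Cross-cutting statistics: 2x2 contrasts and two-sample comparisons.

The chi-square here is the plain Pearson statistic without continuity
correction (the convention that reproduces published 2x2 scan contrasts);
Fisher's exact test defaults to the minimum-likelihood two-sided
convention. Distribution comparisons (K-S, rank-sum, t) delegate to scipy.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneClass, GeneClassification

log = logging.getLogger(__name__)

__all__ = ["ContingencyTable2x2", "TestResult", "ExpressionClass",
           "chi_square_2x2", "fisher_exact_2x2", "ks_two_sample",
           "rank_sum_test", "two_sample_t", "selection_by_expression_contrast",
           "load_expression_table"]


class ContingencyTable2x2(NamedTuple):
    """Counts (a, b; c, d): row = group, column = success/failure."""

    a: int
    b: int
    c: int
    d: int

    def margins_positive(self) -> bool:
        return min(self.a + self.b, self.c + self.d,
                   self.a + self.c, self.b + self.d) > 0


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    a, b, c, d = table
    if not table.margins_positive():
        raise ValueError("chi-square undefined: a margin is zero")
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return TestResult(statistic=float(stat), df=1,
                      p_value=float(stats.chi2.sf(stat, 1)),
                      method="chi_square_2x2")


def fisher_exact_2x2(table: ContingencyTable2x2,
                     convention: str = "min_likelihood") -> TestResult:
    """Two-sided Fisher exact test.

    ``min_likelihood`` (default) sums hypergeometric point probabilities
    not exceeding that of the observed table; ``doubling`` doubles the
    smaller one-sided tail (capped at 1). Computed in log space by scipy's
    hypergeometric machinery, so large totals never overflow.
    """
    a, b, c, d = table
    if not table.margins_positive():
        raise ValueError("Fisher test undefined: a margin is zero")
    if convention == "min_likelihood":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    elif convention == "doubling":
        M, nn, N = a + b + c + d, a + b, a + c
        hg = stats.hypergeom(M, nn, N)
        p = min(1.0, 2.0 * min(hg.cdf(a), hg.sf(a - 1)))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return TestResult(statistic=float(odds), df=None, p_value=float(p),
                      method=f"fisher_exact_{convention}")


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("K-S test needs non-empty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(statistic=float(res.statistic), df=None,
                      p_value=float(res.pvalue), method="ks_two_sample")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney test, W on the pair-count scale.

    W counts pairs (xi, yj) with xi > yj, plus half of the tied pairs —
    the statistic common statistical software prints. Normal approximation
    with tie correction.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(statistic=float(res.statistic), df=None,
                      p_value=float(res.pvalue), method="rank_sum")


def two_sample_t(x: Sequence[float], y: Sequence[float],
                 pooled: bool = True) -> TestResult:
    """Two-sample t test; pooled-variance Student t by default.

    The sign follows mean(x) - mean(y). With ``pooled`` the df is
    n1 + n2 - 2; otherwise Welch's approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t test needs at least 2 observations per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("t test undefined: zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    df = len(x) + len(y) - 2 if pooled else float(res.df)
    return TestResult(statistic=float(res.statistic), df=df,
                      p_value=float(res.pvalue),
                      method="t_pooled" if pooled else "t_welch")


class ExpressionClass(enum.Enum):
    DIFFERENTIAL = "differential"
    NON_DIFFERENTIAL = "non_differential"


def load_expression_table(path) -> dict[str, ExpressionClass]:
    """Read a two-column TSV: gene_id, expression class."""
    df = pd.read_csv(path, sep="\t")
    gene_col, class_col = df.columns[:2]
    mapping = {}
    for gid, cls in zip(df[gene_col], df[class_col]):
        key = str(cls).strip().lower()
        if key in ("differential", "diff", "de"):
            mapping[str(gid)] = ExpressionClass.DIFFERENTIAL
        elif key in ("non_differential", "nondiff", "non-differential", "nde"):
            mapping[str(gid)] = ExpressionClass.NON_DIFFERENTIAL
        else:
            raise ValueError(f"unknown expression class {cls!r} for {gid}")
    return mapping


_SIG_CLASSES = {GeneClass.SIGNIFICANT_POSITIVE, GeneClass.SIGNIFICANT_NEGATIVE}


def selection_by_expression_contrast(
    gene_classes: Sequence[GeneClassification],
    expression: dict[str, ExpressionClass],
    global_counts: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contrast selection classes across expression classes.

    Builds the per-expression-class counts of significant /
    significant-positive / significant-negative genes among analysed
    genes, then runs the six Fisher comparisons: each of the three
    selection categories, differential vs non-differential and
    differential vs the global scan. ``global_counts`` defaults to the
    counts derived from ``gene_classes`` itself.

    Returns (counts table, test table).
    """
    rows = {}
    for label, want in (("differential", ExpressionClass.DIFFERENTIAL),
                        ("non_differential", ExpressionClass.NON_DIFFERENTIAL)):
        sel = [gc for gc in gene_classes
               if expression.get(gc.gene.gene_id) is want
               and gc.gene_class is not GeneClass.NOT_ANALYSED]
        rows[label] = {
            "n": len(sel),
            "significant": sum(gc.gene_class in _SIG_CLASSES for gc in sel),
            "significant_positive": sum(
                gc.gene_class is GeneClass.SIGNIFICANT_POSITIVE for gc in sel),
            "significant_negative": sum(
                gc.gene_class is GeneClass.SIGNIFICANT_NEGATIVE for gc in sel),
        }
    if not any(r["n"] for r in rows.values()):
        log.warning("no analysed genes join the expression table")

    if global_counts is None:
        analysed = [gc for gc in gene_classes
                    if gc.gene_class is not GeneClass.NOT_ANALYSED]
        global_counts = {
            "n": len(analysed),
            "significant": sum(gc.gene_class in _SIG_CLASSES for gc in analysed),
            "significant_positive": sum(
                gc.gene_class is GeneClass.SIGNIFICANT_POSITIVE for gc in analysed),
            "significant_negative": sum(
                gc.gene_class is GeneClass.SIGNIFICANT_NEGATIVE for gc in analysed),
        }

    counts_rows = []
    for label, r in list(rows.items()) + [("global_scan", global_counts)]:
        row = {"class": label, "n": r["n"]}
        for cat in ("significant", "significant_positive", "significant_negative"):
            row[cat] = r[cat]
            row[f"{cat}_pct"] = 100.0 * r[cat] / r["n"] if r["n"] else float("nan")
        counts_rows.append(row)
    counts = pd.DataFrame(counts_rows)

    test_rows = []
    diff = rows["differential"]
    for cat in ("significant", "significant_positive", "significant_negative"):
        for other_label, other in (("non_differential", rows["non_differential"]),
                                   ("global_scan", global_counts)):
            if diff["n"] == 0 or other["n"] == 0:
                log.warning("skipping %s vs %s: empty class", cat, other_label)
                continue
            t = ContingencyTable2x2(diff[cat], diff["n"] - diff[cat],
                                    other[cat], other["n"] - other[cat])
            try:
                res = fisher_exact_2x2(t)
            except ValueError:
                log.warning("skipping %s vs %s: zero margin", cat, other_label)
                continue
            test_rows.append({
                "category": cat,
                "comparison": f"differential_vs_{other_label}",
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "odds_ratio": res.statistic, "p_value": res.p_value,
                "method": res.method,
            })
    return counts, pd.DataFrame(test_rows)
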