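"""Agreement between two gene-level tests: overlap, enrichment, concordance.

Two tests applied to the same gene universe each call a significant set.  If
both detect true adaptive genes, their calls should overlap more than the
independence expectation |A|*|B|/N.  The module quantifies the overlap
(hypergeometric enrichment), computes the concordance rate (overlap divided
by the MK-significant set), supports the relaxed joint threshold
sqrt(alpha) per test, and compares conditional p-value distributions
(one test's p-values before and after pre-filtering by the other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConcordanceReport",
    "overlap_stats",
    "expected_overlap_fraction",
    "relaxed_threshold",
    "concordance_rate",
    "conditional_p_distributions",
]


@dataclass
class ConcordanceReport:
    universe: int
    size_a: int
    size_b: int
    overlap: int
    expected_overlap: float
    enrichment_p: float
    concordance: float  # overlap / |A| (the MK set); nan when |A| = 0
    threshold: float | None = None

    def as_dict(self) -> dict:
        return {
            "universe": self.universe,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "overlap": self.overlap,
            "expected_overlap": self.expected_overlap,
            "enrichment_p": self.enrichment_p,
            "concordance": self.concordance,
            "threshold": self.threshold,
        }


def overlap_stats(
    set_a: set, set_b: set, universe: set, threshold: float | None = None
) -> ConcordanceReport:
    """Observed vs expected overlap of two significant gene sets.

    The expected overlap under independence is |A|*|B|/N; enrichment is the
    one-sided (over-enrichment) hypergeometric tail, i.e. Fisher's exact test
    on the 2x2 membership table.  The concordance rate follows the
    overlap/|A| convention with A the MK-significant set.
    """
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("significant sets must be subsets of the universe")
    n = len(universe)
    a, b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = a * b / n
    # P(X >= k) for X ~ Hypergeom(N=n, K=a, n=b)
    enrichment = float(stats.hypergeom.sf(k - 1, n, a, b)) if k > 0 else 1.0
    conc = k / a if a > 0 else math.nan
    return ConcordanceReport(
        universe=n, size_a=a, size_b=b, overlap=k,
        expected_overlap=expected, enrichment_p=min(enrichment, 1.0),
        concordance=conc, threshold=threshold,
    )


def expected_overlap_fraction(frac_a: float, frac_b: float) -> float:
    """Chance overlap fraction of two independent random picks."""
    for f in (frac_a, frac_b):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    return frac_a * frac_b


def relaxed_threshold(joint_alpha: float) -> float:
    """Per-test cutoff whose square is the joint false-call rate.

    Calling a gene only when both tests pass P < sqrt(alpha) gives an
    expected chance overlap of alpha under independence (0.05 -> 0.224).
    """
    if not 0.0 < joint_alpha <= 1.0:
        raise ValueError("joint_alpha must be in (0, 1]")
    return math.sqrt(joint_alpha)


def concordance_rate(report: ConcordanceReport) -> float:
    """Overlap divided by the MK-significant set size (set A)."""
    if report.size_a == 0:
        return math.nan
    return report.overlap / report.size_a


def conditional_p_distributions(
    pvals_a: dict[str, float], prefilter_b: set
) -> dict:
    """Shift of one test's p-values after pre-filtering by the other test.

    ``pvals_a`` maps every universe gene to its p-value in test A;
    ``prefilter_b`` is the set of genes significant in test B.  Returns the
    two empirical distributions (sorted arrays) plus a rank-based
    (Mann-Whitney) statistic for a leftward shift of the pre-filtered
    distribution, with its one-sided p-value.
    """
    if not prefilter_b:
        raise ValueError("empty pre-filter set")
    all_p = np.array(sorted(pvals_a.values()))
    filt = np.array(sorted(pvals_a[g] for g in prefilter_b if g in pvals_a))
    if filt.size == 0:
        raise ValueError("pre-filter set shares no genes with the p-value map")
    rest = np.array(sorted(p for g, p in pvals_a.items() if g not in prefilter_b))
    if rest.size == 0:
        u_stat, p = math.nan, math.nan
    else:
        u_stat, p = stats.mannwhitneyu(filt, rest, alternative="less")
    return {
        "all": all_p,
        "prefiltered": filt,
        "shift_statistic": float(u_stat),
        "shift_p": float(p),
    }
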