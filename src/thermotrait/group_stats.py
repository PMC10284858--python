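"""Two-group comparisons of genomic properties.

Implements the Wilcoxon rank-sum (Mann–Whitney) test with an exact
two-sided p-value for small tie-free samples and a tie-corrected,
continuity-corrected normal approximation otherwise, plus Pearson /
Spearman correlation. These are the statistics used to contrast
thermal against non-thermal genomes property by property.

Exact p-values come from the null distribution of the group-1 rank sum
W: the number of n1-subsets of ranks {1..N} with a given sum, computed
by the standard count recursion and cached per (n1, n2) — equivalent
to full enumeration of all C(N, n1) rank assignments but polynomial
time. Two-sided p is 2·min(P(W ≤ w), P(W ≥ w)) capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import Habitat

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "ranksum_test",
    "correlate",
    "compare_cohort",
    "comparisons_table",
    "DEFAULT_PROPERTIES",
]

logger = logging.getLogger(__name__)

# properties compared between habitat groups, in report order
DEFAULT_PROPERTIES = (
    "size_bp", "gc_pct", "ogt_pred_c", "gene_count", "avg_gene_len_bp",
    "coding_density_pct", "ivywrel", "polar", "nonpolar", "charged",
)


@dataclass(frozen=True)
class GroupComparison:
    property_name: str
    n1: int
    n2: int
    statistic_w: float  # rank-sum of group 1
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    median1: float
    median2: float
    range1: tuple[float, float]
    range2: tuple[float, float]
    direction: str  # "group1>group2" | "group2>group1" | "none"


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    n: int
    p_two_sided: float


@lru_cache(maxsize=64)
def _ranksum_null_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the tie-free null rank-sum W of a size-n1 group.

    Entry [w] is P(W ≤ w); indices below the minimal sum are 0. Built
    from the subset-sum count recursion over ranks 1..n1+n2.
    """
    n = n1 + n2
    max_w = n * (n + 1) // 2
    # counts[k, s] = number of k-subsets of processed ranks summing to s
    counts = np.zeros((n1 + 1, max_w + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        upper = min(n1, rank)
        for k in range(upper, 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank or None]
    pmf = counts[n1]
    cdf = np.cumsum(pmf)
    return cdf / cdf[-1]


def _exact_p(w: int, n1: int, n2: int) -> float:
    cdf = _ranksum_null_cdf(n1, n2)
    p_le = cdf[w]
    p_ge = 1.0 - (cdf[w - 1] if w >= 1 else 0.0)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_approx_p(w: float, ranks: np.ndarray, n1: int,
                     n2: int) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    # continuity correction of 0.5 toward the mean
    delta = w - mu
    if delta == 0:
        return 1.0
    z = (abs(delta) - 0.5) / np.sqrt(var)
    return min(1.0, 2.0 * float(stats.norm.sf(z)))


def ranksum_test(x, y, property_name: str = "",
                 method: str = "auto") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test of two samples.

    ``method``:

    * ``"auto"`` (default): exact when n1 + n2 ≤ 20 and the pooled data
      are tie-free, otherwise the tie-corrected normal approximation
      with continuity correction;
    * ``"exact"``: force the exact distribution (tie-free data only);
    * ``"normal_approx"``: force the approximation.

    Identical pooled values give p = 1 with direction "none" (no
    signal, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # average ranks for ties
    w = float(ranks[:n1].sum())
    tie_free = len(np.unique(pooled)) == n1 + n2

    if method == "auto":
        method = ("exact" if tie_free and n1 + n2 <= 20
                  else "normal_approx")
    if method == "exact":
        if not tie_free:
            raise ValueError("exact method requires tie-free data")
        p = _exact_p(int(round(w)), n1, n2)
    elif method == "normal_approx":
        p = _normal_approx_p(w, ranks, n1, n2)
    else:
        raise ValueError(f"unknown method {method!r}")

    mu = n1 * (n1 + n2 + 1) / 2.0
    if np.all(pooled == pooled[0]) or w == mu:
        direction = "none"
    elif w > mu:
        direction = "group1>group2"
    else:
        direction = "group2>group1"
    return GroupComparison(
        property_name=property_name, n1=n1, n2=n2, statistic_w=w,
        p_two_sided=p, method=method,
        median1=float(np.median(x)), median2=float(np.median(y)),
        range1=(float(x.min()), float(x.max())),
        range2=(float(y.min()), float(y.max())),
        direction=direction,
    )


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need ≥3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), n=len(x),
                             p_two_sided=float(p))


def compare_cohort(table: pd.DataFrame,
                   properties=DEFAULT_PROPERTIES,
                   group1: Habitat | str = Habitat.thermal,
                   group2: Habitat | str = Habitat.non_thermal,
                   method: str = "auto") -> list[GroupComparison]:
    """Rank-sum comparison of each property between two habitat groups.

    ``table`` carries one row per genome with a ``habitat`` column plus
    the property columns; genomes missing a property are excluded
    pairwise with a logged warning. No multiple-testing correction is
    applied (per-property p-values are reported raw); see
    :func:`holm_correction` for an optional adjustment.
    """
    g1 = str(getattr(group1, "value", group1))
    g2 = str(getattr(group2, "value", group2))
    hab = table["habitat"].astype(str)
    out = []
    for prop in properties:
        if prop not in table.columns:
            logger.warning("property %r absent from table; skipped", prop)
            continue
        vals = pd.to_numeric(table[prop], errors="coerce")
        keep = vals.notna()
        dropped = int((~keep).sum())
        if dropped:
            logger.warning(
                "property %r: excluded %d genome(s) with missing values",
                prop, dropped,
            )
        x = vals[keep & (hab == g1)].to_numpy()
        y = vals[keep & (hab == g2)].to_numpy()
        if len(x) == 0 or len(y) == 0:
            logger.warning("property %r: a group is empty; skipped", prop)
            continue
        out.append(ranksum_test(x, y, property_name=prop, method=method))
    return out


def holm_correction(comparisons: list[GroupComparison]) -> dict[str, float]:
    """Holm step-down adjusted p-values keyed by property name."""
    ordered = sorted(comparisons, key=lambda c: c.p_two_sided)
    m = len(ordered)
    adjusted: dict[str, float] = {}
    running = 0.0
    for i, c in enumerate(ordered):
        running = max(running, min(1.0, (m - i) * c.p_two_sided))
        adjusted[c.property_name] = running
    return adjusted


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Report table of group comparisons, one property per row."""
    rows = []
    for c in comparisons:
        rows.append({
            "property": c.property_name, "n1": c.n1, "n2": c.n2,
            "statistic_w": c.statistic_w, "p_two_sided": c.p_two_sided,
            "method": c.method,
            "median1": c.median1, "median2": c.median2,
            "min1": c.range1[0], "max1": c.range1[1],
            "min2": c.range2[0], "max2": c.range2[1],
            "direction": c.direction,
        })
    return pd.DataFrame(rows)
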