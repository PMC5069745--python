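"""Cross-sample statistics: replicate contrasts, concordance, and growth.

Replicate-level labeling metrics are compared between incubation time
points with a pooled-variance Student t-test; replicate agreement of
protein relative abundances is quantified with Lin's concordance
correlation coefficient (CCC); community growth is summarized as percent
increase / fold change of direct cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psm_io import SampleTable


@dataclass(frozen=True)
class CellCountSeries:
    """Direct cell counts (cells per ml) at successive time points."""

    location: str
    counts: tuple[float, ...]
    times_h: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts):
            raise ValueError("cell counts must be positive")
        if list(self.times_h) != sorted(set(self.times_h)):
            raise ValueError("time points must be strictly increasing")
        if len(self.counts) != len(self.times_h):
            raise ValueError("counts and time points must align")


@dataclass(frozen=True)
class ContrastResult:
    statistic: str
    estimate: float
    stat_value: float
    p_value: float
    df: float
    n_a: int
    n_b: int


def pooled_t_test(
    group_a: Sequence[float], group_b: Sequence[float], tails: int = 2
) -> ContrastResult:
    """Student's two-sample t-test with pooled variance.

    ``tails=1`` halves the two-sided p (test in the direction of the
    observed difference).  Zero pooled variance gives t = 0, p = 1 for
    equal means and an infinite t (p = 0) otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = a.size + b.size - 2
    estimate = float(a.mean() - b.mean())
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        t = 0.0 if estimate == 0 else math.copysign(math.inf, estimate)
        p = 1.0 if estimate == 0 else 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    if tails == 1:
        p = p / 2
    return ContrastResult(
        statistic="t", estimate=estimate, stat_value=t, p_value=p,
        df=float(df), n_a=a.size, n_b=b.size,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with
    population (n-denominator) moments — the original estimator.  It
    penalizes both scale and location departures from the identity line, so
    |rho_c| <= |Pearson r| with equality only when means and variances
    match.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    var_x = x.var()  # ddof=0
    var_y = y.var()
    denom = var_x + var_y + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("CCC undefined for identical constant vectors")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)


def percent_increase(count_start: float, count_end: float) -> float:
    """100 * (end/start - 1); requires positive counts."""
    if count_start <= 0 or count_end <= 0:
        raise ValueError("counts must be positive")
    return float(100.0 * (count_end / count_start - 1.0))


def fold_change(count_start: float, count_end: float) -> float:
    if count_start <= 0 or count_end <= 0:
        raise ValueError("counts must be positive")
    return float(count_end / count_start)


def concordance_matrix(tables: Sequence[SampleTable]) -> pd.DataFrame:
    """Pairwise CCC of protein relative abundances across samples.

    Proteins are aligned on the union of identifiers; a protein absent from
    a sample contributes relative abundance 0 there.
    """
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    series = {
        t.sample_id: {p.protein_id: p.relative_abundance for p in t.proteins}
        for t in tables
    }
    ids = [t.sample_id for t in tables]
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        union = sorted(set(series[a]) | set(series[b]))
        xa = [series[a].get(p, 0.0) for p in union]
        xb = [series[b].get(p, 0.0) for p in union]
        ccc = lin_ccc(xa, xb)
        mat.loc[a, b] = mat.loc[b, a] = ccc
    return mat


def growth_summary(series: CellCountSeries) -> pd.DataFrame:
    """Fold change and percent increase over successive count intervals."""
    rows = []
    for (t0, c0), (t1, c1) in zip(
        zip(series.times_h, series.counts), zip(series.times_h[1:], series.counts[1:])
    ):
        rows.append(
            {
                "location": series.location,
                "t_start_h": t0,
                "t_end_h": t1,
                "fold_change": fold_change(c0, c1),
                "percent_increase": percent_increase(c0, c1),
            }
        )
    return pd.DataFrame(rows)
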