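"""Permutation null distributions and differential-labeling calls.

The null hypothesis for a taxon (or a COG category within a taxon) is that
its PSMs are an exchangeable random subset of the pool they were drawn
from: the whole sample's spectra for taxon tests, the taxon's spectra for
COG tests.  For each tested group, the engine draws (by default) 1,000
random subsets of the pool matched on total weight — PSMs are taken
uniformly without replacement until the cumulative weight first reaches the
group's weight, which with unit weights is exact size matching — and
computes label frequency and average enrichment on every draw.  The
observed group value is called significant when it is as extreme or more
extreme than the empirical inner-95% critical values (inclusive 2.5th /
97.5th percentiles); Z-scores against the null mean and SD are reported for
illustration, mirroring common practice for these tests.

Draws on which average enrichment is undefined (no labeled PSM selected)
are recorded as undefined and excluded from the null's moments and
percentiles; their count is kept.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .labeling import LabelingSummary, summarize
from .psm_io import LABEL_THRESHOLD_PCT, SampleTable

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 0.05
#: Smallest group weight tested by default.  Labeled PSMs were detectable
#: for taxa with more than 12 protein identifications, so groups of at
#: least 13 PSM-equivalents are considered testable.
DEFAULT_MIN_WEIGHT = 13.0


class DegenerateNullError(ValueError):
    """Target weight is not strictly inside (0, pool weight)."""


def derive_seed(master_seed: int, *context) -> int:
    """Stable sub-seed from a master seed and a hashable context.

    Uses SHA-256 of the repr so adding one group to a batch never shifts
    another group's draws.
    """
    digest = hashlib.sha256(repr((int(master_seed),) + context).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class NullDistribution:
    """Permutation null for one metric at one matched weight."""

    metric: str
    values: np.ndarray  # defined draws only
    n_perm: int
    n_undefined: int
    seed: int
    target_weight: float
    mean: float = field(init=False)
    sd: float = field(init=False)
    q025: float = field(init=False)
    q975: float = field(init=False)

    def __post_init__(self) -> None:
        if self.values.size:
            self.mean = float(self.values.mean())
            self.sd = float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0
            # linear-interpolation percentile definition
            self.q025, self.q975 = (
                float(q) for q in np.percentile(self.values, [2.5, 97.5])
            )
        else:
            self.mean = self.sd = self.q025 = self.q975 = float("nan")

    def quantiles(self, alpha: float) -> tuple[float, float]:
        lo, hi = np.percentile(self.values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)


@dataclass
class PermutationResult:
    """Observed metrics, Z-scores and inner-95% calls for one group."""

    sample_id: str
    group_type: str
    group_id: str
    observed: LabelingSummary
    null_frequency: NullDistribution
    null_enrichment: NullDistribution
    z_frequency: Optional[float]
    z_enrichment: Optional[float]
    p_frequency: float
    p_enrichment: Optional[float]
    call_frequency: str  # low | ns | high
    call_enrichment: Optional[str]
    n_perm: int
    seed: int


def _draw_metrics(
    enrichments: np.ndarray,
    weights: np.ndarray,
    target_weight: float,
    n_perm: int,
    rng: np.random.Generator,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw (label frequency, average enrichment or NaN) arrays."""
    n = enrichments.size
    unit = bool(np.all(weights == 1.0))
    k = int(np.ceil(target_weight)) if unit else None
    freq = np.empty(n_perm)
    avg = np.full(n_perm, np.nan)
    for i in range(n_perm):
        perm = rng.permutation(n)
        if unit:
            idx = perm[:k]
        else:
            cw = np.cumsum(weights[perm])
            stop = int(np.searchsorted(cw, target_weight, side="left"))
            idx = perm[: stop + 1]
        e = enrichments[idx]
        w = weights[idx]
        labeled = e >= threshold
        lw = w[labeled].sum()
        total = w.sum()
        freq[i] = 100.0 * lw / total
        if lw > 0:
            avg[i] = np.sum(e[labeled] * w[labeled]) / lw
    return freq, avg


def draw_null(
    pool,
    target_weight: float,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    metric: str = "label_frequency",
    weights: Optional[Sequence[float]] = None,
    threshold: float = LABEL_THRESHOLD_PCT,
) -> NullDistribution:
    """Null distribution of one metric over weight-matched random subsets.

    ``pool`` may be an array of enrichment percents or an iterable of
    PsmRecords.  Identical (pool, target, n_perm, seed) give bit-identical
    value lists regardless of which metric is requested, because both
    metrics are computed from the same sequence of subsets.
    """
    from .labeling import _as_arrays  # shared coercion

    enr, w = _as_arrays(pool, weights)
    total = w.sum()
    if not 0 < target_weight < total:
        raise DegenerateNullError(
            f"target weight {target_weight} not inside (0, {total})"
        )
    if metric not in ("label_frequency", "average_enrichment"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    freq, avg = _draw_metrics(enr, w, target_weight, n_perm, rng, threshold)
    if metric == "label_frequency":
        values, n_undef = freq, 0
    else:
        defined = ~np.isnan(avg)
        values, n_undef = avg[defined], int(n_perm - defined.sum())
    return NullDistribution(
        metric=metric,
        values=values,
        n_perm=n_perm,
        n_undefined=n_undef,
        seed=seed,
        target_weight=float(target_weight),
    )


def z_score(observed: float, null: NullDistribution) -> Optional[float]:
    """(observed - null mean) / null sd; None when the null sd is zero."""
    if not np.isfinite(null.sd) or null.sd == 0:
        return None
    return float((observed - null.mean) / null.sd)


def empirical_p(observed: float, null: NullDistribution) -> float:
    """Two-sided empirical p with the standard +1 correction."""
    n = null.values.size
    if n == 0:
        return float("nan")
    p_hi = (1 + np.sum(null.values >= observed)) / (n + 1)
    p_lo = (1 + np.sum(null.values <= observed)) / (n + 1)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


def _call(observed: Optional[float], null: NullDistribution, alpha: float) -> Optional[str]:
    if observed is None or null.values.size == 0:
        return None
    lo, hi = (null.q025, null.q975) if alpha == DEFAULT_ALPHA else null.quantiles(alpha)
    if observed >= hi:
        return "high"
    if observed <= lo:
        return "low"
    return "ns"


def _test_one_group(
    sample_id: str,
    group_type: str,
    group_id: str,
    pool_enr: np.ndarray,
    pool_w: np.ndarray,
    group_mask: np.ndarray,
    threshold: float,
    n_perm: int,
    seed: int,
    alpha: float,
) -> PermutationResult:
    observed = summarize(pool_enr[group_mask], pool_w[group_mask], threshold)
    total = pool_w.sum()
    if not 0 < observed.n_weight < total:
        raise DegenerateNullError(
            f"group {group_id!r} weight {observed.n_weight} not inside (0, {total})"
        )
    rng = np.random.default_rng(seed)
    freq, avg = _draw_metrics(
        pool_enr, pool_w, observed.n_weight, n_perm, rng, threshold
    )
    null_f = NullDistribution(
        "label_frequency", freq, n_perm, 0, seed, observed.n_weight
    )
    defined = ~np.isnan(avg)
    null_e = NullDistribution(
        "average_enrichment",
        avg[defined],
        n_perm,
        int(n_perm - defined.sum()),
        seed,
        observed.n_weight,
    )
    obs_avg = observed.average_enrichment_pct
    return PermutationResult(
        sample_id=sample_id,
        group_type=group_type,
        group_id=group_id,
        observed=observed,
        null_frequency=null_f,
        null_enrichment=null_e,
        z_frequency=z_score(observed.label_frequency_pct, null_f),
        z_enrichment=None if obs_avg is None else z_score(obs_avg, null_e),
        p_frequency=empirical_p(observed.label_frequency_pct, null_f),
        p_enrichment=None if obs_avg is None else empirical_p(obs_avg, null_e),
        call_frequency=_call(observed.label_frequency_pct, null_f, alpha),
        call_enrichment=_call(obs_avg, null_e, alpha),
        n_perm=n_perm,
        seed=seed,
    )


def test_groups(
    sample: SampleTable,
    grouping: str = "taxon_order",
    threshold: float = LABEL_THRESHOLD_PCT,
    n_perm: int = DEFAULT_N_PERM,
    master_seed: int = 0,
    min_weight: float = DEFAULT_MIN_WEIGHT,
    alpha: float = DEFAULT_ALPHA,
    weight_kind: str = "unit",
) -> list[PermutationResult]:
    """Test every taxon of a sample against the whole-sample null.

    ``grouping`` is ``taxon_order`` or ``taxon_genus``.  PSMs without the
    grouping annotation stay in the pool but form no group.  Groups lighter
    than ``min_weight`` are skipped; a group spanning the whole pool raises
    :class:`DegenerateNullError` (propagated).
    """
    if grouping not in ("taxon_order", "taxon_genus"):
        raise ValueError(f"unknown grouping {grouping!r}")
    enr = sample.enrichments()
    w = sample.weights(weight_kind)
    labels = np.array(
        [getattr(p, grouping) or "" for p in sample.psms], dtype=object
    )
    groups = [g for g in dict.fromkeys(labels) if g]
    results = []
    for group_id in groups:
        mask = labels == group_id
        if w[mask].sum() < min_weight:
            logger.info(
                "sample %s: %s %r below min weight, skipped",
                sample.sample_id, grouping, group_id,
            )
            continue
        seed = derive_seed(master_seed, sample.sample_id, grouping, group_id)
        results.append(
            _test_one_group(
                sample.sample_id, grouping, str(group_id),
                enr, w, mask, threshold, n_perm, seed, alpha,
            )
        )
    if not results:
        logger.warning(
            "sample %s: no %s group reaches min weight %s",
            sample.sample_id, grouping, min_weight,
        )
    return results


def test_cogs_within_taxon(
    sample: SampleTable,
    taxon_id: str,
    grouping: str = "taxon_order",
    threshold: float = LABEL_THRESHOLD_PCT,
    n_perm: int = DEFAULT_N_PERM,
    master_seed: int = 0,
    min_weight: float = DEFAULT_MIN_WEIGHT,
    alpha: float = DEFAULT_ALPHA,
    weight_kind: str = "unit",
) -> list[PermutationResult]:
    """Test COG categories of one taxon against the taxon-restricted null.

    The null pool is only the taxon's PSMs, so a significant category means
    its labeling departs from the taxon's own, i.e. 13C enrichment within
    the taxon is not independent of functional category.  A PSM with
    several COG letters counts once per category (membership, not a
    partition of its weight).
    """
    in_taxon = [
        (i, p) for i, p in enumerate(sample.psms)
        if getattr(p, grouping) == taxon_id
    ]
    if not in_taxon:
        raise ValueError(f"sample {sample.sample_id}: no PSMs for {grouping}={taxon_id!r}")
    idx = np.array([i for i, _ in in_taxon])
    enr = sample.enrichments()[idx]
    w = sample.weights(weight_kind)[idx]
    categories = sorted({c for _, p in in_taxon for c in p.cog_categories})
    results = []
    for cat in categories:
        mask = np.array([cat in p.cog_categories for _, p in in_taxon])
        if w[mask].sum() < min_weight:
            logger.info(
                "sample %s taxon %s: COG %s below min weight, skipped",
                sample.sample_id, taxon_id, cat,
            )
            continue
        seed = derive_seed(master_seed, sample.sample_id, "cog", taxon_id, cat)
        results.append(
            _test_one_group(
                sample.sample_id, f"cog_within_{taxon_id}", cat,
                enr, w, mask, threshold, n_perm, seed, alpha,
            )
        )
    return results


def results_to_frame(results: Iterable[PermutationResult]) -> pd.DataFrame:
    """Flatten results to the tab-separated report layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "group_type": r.group_type,
                "group_id": r.group_id,
                "n_weight": r.observed.n_weight,
                "label_frequency_pct": r.observed.label_frequency_pct,
                "avg_enrichment_pct": r.observed.average_enrichment_pct,
                "z_freq": r.z_frequency,
                "z_enrich": r.z_enrichment,
                "p_freq": r.p_frequency,
                "p_enrich": r.p_enrichment,
                "call_freq": r.call_frequency,
                "call_enrich": r.call_enrichment,
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default in reports)."""
    from scipy.stats import false_discovery_control

    return false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
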