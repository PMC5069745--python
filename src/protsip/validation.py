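"""Seeded statistical-calibration experiments for the permutation test.

The paper-scale quantities that matter for trusting the test — type-I
error of the inner-95% rule, power against a genuinely better-labeled
taxon, and agreement of the Monte-Carlo null with exact enumeration — are
estimated here on synthetic pools whose sizes reflect a single sample's
taxa (pools of a few thousand PSMs, groups of a few hundred).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .labeling import average_enrichment, label_frequency
from .permutation import (
    derive_seed,
    draw_null,
    test_groups,
)
from .psm_io import PsmRecord, SampleTable


def enumerate_null(
    enrichments, subset_size: int, threshold: float = 2.0
) -> tuple[dict, dict]:
    """Exhaustive null over all C(n, k) equal-weight subsets.

    Returns (frequency stats, average-enrichment stats) dicts with keys
    ``mean``, ``sd``, ``n`` where draws with no labeled PSM are excluded
    from the average-enrichment moments — the same convention the
    Monte-Carlo engine uses.  Intended for tiny pools only.
    """
    values = np.asarray(enrichments, dtype=float)
    freqs, avgs = [], []
    for idx in combinations(range(values.size), subset_size):
        subset = values[list(idx)]
        freqs.append(label_frequency(subset, threshold=threshold))
        avg = average_enrichment(subset, threshold=threshold)
        if avg is not None:
            avgs.append(avg)
    freqs = np.array(freqs)
    avgs = np.array(avgs)

    def _stats(arr):
        return {
            "mean": float(arr.mean()) if arr.size else float("nan"),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size),
        }

    return _stats(freqs), _stats(avgs)


def _exchangeable_sample(
    sample_id: str, n: int, p_label: float, group_size: int,
    rng: np.random.Generator,
) -> SampleTable:
    """A pool with iid labeling and a taxon label independent of it."""
    labeled = rng.random(n) < p_label
    enr = np.where(labeled, 35.0 + rng.normal(0, 8, n), 1.109)
    enr = np.clip(enr, 0.0, 100.0)
    enr[labeled] = np.maximum(enr[labeled], 2.0)
    members = rng.permutation(n) < group_size
    psms = [
        PsmRecord(
            sample_id=sample_id,
            spectrum_id=f"s{i}",
            peptide="PEPTIDEK",
            protein_ids=("p1",),
            enrichment_pct=float(enr[i]),
            taxon_order="GroupA" if members[i] else "Rest",
        )
        for i in range(n)
    ]
    return SampleTable(sample_id=sample_id, psms=psms)


def type_i_error_rate(
    n_replicates: int = 250,
    pool_size: int = 3000,
    group_size: int = 300,
    p_label: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of exchangeable-label replicates called significant.

    Labels are iid and the tested group is an independent random subset, so
    the null holds and the inner-95% rule should reject ~5% of the time.
    """
    n_significant = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(derive_seed(seed, "type1", r))
        sample = _exchangeable_sample(f"rep{r}", pool_size, p_label, group_size, rng)
        results = test_groups(
            sample, "taxon_order", n_perm=n_perm,
            master_seed=derive_seed(seed, "type1-test", r), min_weight=1.0,
        )
        (result,) = [x for x in results if x.group_id == "GroupA"]
        if result.call_frequency != "ns":
            n_significant += 1
    return n_significant / n_replicates


def detection_power(
    n_replicates: int = 100,
    pool_size: int = 2000,
    group_size: int = 500,
    p_label_background: float = 0.05,
    effect_fold: float = 3.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of replicates where an elevated-labeling taxon is called high."""
    n_high = 0
    p_group = effect_fold * p_label_background
    for r in range(n_replicates):
        rng = np.random.default_rng(derive_seed(seed, "power", r))
        in_group = np.arange(pool_size) < group_size
        p = np.where(in_group, p_group, p_label_background)
        labeled = rng.random(pool_size) < p
        enr = np.where(labeled, np.maximum(35.0 + rng.normal(0, 8, pool_size), 2.0), 1.109)
        enr = np.clip(enr, 0.0, 100.0)
        psms = [
            PsmRecord(
                sample_id=f"rep{r}",
                spectrum_id=f"s{i}",
                peptide="PEPTIDEK",
                protein_ids=("p1",),
                enrichment_pct=float(enr[i]),
                taxon_order="Elevated" if in_group[i] else "Rest",
            )
            for i in range(pool_size)
        ]
        sample = SampleTable(sample_id=f"rep{r}", psms=psms)
        results = test_groups(
            sample, "taxon_order", n_perm=n_perm,
            master_seed=derive_seed(seed, "power-test", r), min_weight=1.0,
        )
        (result,) = [x for x in results if x.group_id == "Elevated"]
        if result.call_frequency == "high":
            n_high += 1
    return n_high / n_replicates


def null_vs_enumeration(
    pool=(50.0, 30.0, 1.1, 1.1, 1.1),
    subset_size: int = 2,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo vs exhaustive null means on a tiny pool.

    Returns the enumerated and sampled label-frequency means plus the
    Monte-Carlo standard error, for a 3-SE agreement check.
    """
    freq_stats, _ = enumerate_null(pool, subset_size)
    null = draw_null(
        np.asarray(pool, dtype=float), target_weight=float(subset_size),
        n_perm=n_perm, seed=seed, metric="label_frequency",
    )
    se = freq_stats["sd"] / np.sqrt(n_perm)
    return {
        "enumerated_mean": freq_stats["mean"],
        "monte_carlo_mean": null.mean,
        "se": float(se),
        "abs_diff": abs(null.mean - freq_stats["mean"]),
    }
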