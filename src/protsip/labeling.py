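"""Label frequency, average enrichment, and the labeled-enrichment histogram.

Two metrics summarize 13C assimilation for any weighted set of PSMs:

* **label frequency** — the proportion (percent) of PSM weight whose 13C
  enrichment is at or above the labeling threshold (default 2%, just above
  the 1.109% natural abundance).  It measures the breadth of de novo
  protein synthesis from any carbon source.
* **average enrichment** — the weighted mean percent 13C among labeled PSMs
  only.  It measures how much of the labeled substrate's carbon entered
  newly made protein, and is undefined when nothing is labeled.

The histogram of labeled spectra uses half-open 3%-wide bins from 4% to
100%; its denominator is the *total* labeled weight, so barely-labeled mass
in [2, 4) counts toward the denominator but falls in no bin and the bin
proportions need not sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .psm_io import LABEL_THRESHOLD_PCT, PsmRecord

#: Half-open histogram bin edges: [4,7), [7,10), ..., [97,100).
HISTOGRAM_BIN_EDGES = np.arange(4.0, 101.0, 3.0)


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. empty subset)."""


@dataclass(frozen=True)
class LabelingSummary:
    """Weighted labeling metrics for one PSM subset."""

    n_weight: float
    n_labeled_weight: float
    label_frequency_pct: float
    average_enrichment_pct: Optional[float]  # None when nothing is labeled


@dataclass(frozen=True)
class EnrichmentHistogram:
    bin_edges: np.ndarray
    proportions: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "proportion": self.proportions,
            }
        )


def _as_arrays(
    psms: Iterable[PsmRecord] | Sequence[float] | np.ndarray,
    weights: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Accept either PsmRecords (weights from balanced_weight) or raw values."""
    items = list(psms) if not isinstance(psms, np.ndarray) else psms
    if len(items) and isinstance(items[0], PsmRecord):
        values = np.array([p.enrichment_pct for p in items], dtype=float)
        if weights is None:
            weights = np.array([p.balanced_weight for p in items], dtype=float)
    else:
        values = np.asarray(items, dtype=float)
    w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != values.shape:
        raise ValueError("weights must match the subset length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return values, w


def label_frequency(
    psms, weights=None, threshold: float = LABEL_THRESHOLD_PCT
) -> float:
    """Percent of subset weight with enrichment >= ``threshold``."""
    values, w = _as_arrays(psms, weights)
    total = w.sum()
    if values.size == 0 or total == 0:
        raise UndefinedMetricError("label frequency undefined on empty subset")
    return float(100.0 * w[values >= threshold].sum() / total)


def average_enrichment(
    psms, weights=None, threshold: float = LABEL_THRESHOLD_PCT
) -> Optional[float]:
    """Weighted mean enrichment over labeled PSMs; None when none labeled."""
    values, w = _as_arrays(psms, weights)
    if values.size == 0 or w.sum() == 0:
        raise UndefinedMetricError("average enrichment undefined on empty subset")
    labeled = values >= threshold
    lw = w[labeled].sum()
    if lw == 0:
        return None
    return float(np.sum(values[labeled] * w[labeled]) / lw)


def summarize(
    psms, weights=None, threshold: float = LABEL_THRESHOLD_PCT
) -> LabelingSummary:
    """Bundle both metrics (with weights) for one PSM subset."""
    values, w = _as_arrays(psms, weights)
    total = w.sum()
    if values.size == 0 or total == 0:
        raise UndefinedMetricError("labeling summary undefined on empty subset")
    labeled = values >= threshold
    lw = float(w[labeled].sum())
    avg = float(np.sum(values[labeled] * w[labeled]) / lw) if lw > 0 else None
    return LabelingSummary(
        n_weight=float(total),
        n_labeled_weight=lw,
        label_frequency_pct=float(100.0 * lw / total),
        average_enrichment_pct=avg,
    )


def enrichment_histogram(
    psms, weights=None, threshold: float = LABEL_THRESHOLD_PCT
) -> EnrichmentHistogram:
    """Histogram of labeled weight over 3% bins from 4% to 100%."""
    values, w = _as_arrays(psms, weights)
    labeled = values >= threshold
    lw = w[labeled].sum()
    if lw == 0:
        raise UndefinedMetricError("histogram undefined without labeled PSMs")
    counts, _ = np.histogram(
        values[labeled], bins=HISTOGRAM_BIN_EDGES, weights=w[labeled]
    )
    # np.histogram closes the last bin; keep [97,100) half-open by moving
    # exact-100 mass out of the final bin.
    at_max = labeled & (values == HISTOGRAM_BIN_EDGES[-1])
    if at_max.any():
        counts[-1] -= w[at_max].sum()
    return EnrichmentHistogram(
        bin_edges=HISTOGRAM_BIN_EDGES.copy(), proportions=counts / lw
    )


def replicate_mean_sd(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Arithmetic mean and sample (n-1) standard deviation of replicates.

    A single value has an undefined SD (returned as None).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("replicate_mean_sd requires at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd
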