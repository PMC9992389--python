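"""Concordance with manual measurements and per-sample summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .density_filter import FilterResult
from .errors import DegenerateSampleError
from .io_lpfc import (
    STATUS_DEBRIS,
    STATUS_MISALIGNED_BAND,
    STATUS_MISALIGNED_MODE,
    SampleSet,
)


@dataclass(frozen=True)
class ConcordanceResult:
    method: str
    coefficient: float
    p_value: float
    n: int


def concordance(manual_um, lpfc_um, method: str = "spearman") -> ConcordanceResult:
    """Correlation between paired manual and automated length measurements.

    ``spearman`` uses average-rank ties; both methods report the standard
    large-sample two-sided p-value (t approximation). Requires >= 3 pairs
    and non-constant columns.
    """
    x = np.asarray(manual_um, dtype=float)
    y = np.asarray(lpfc_um, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("manual and LPFC measurements must be 1-D and paired")
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("measurements must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("correlation undefined for a constant column")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown method {method!r}; use 'spearman' or 'pearson'")
    return ConcordanceResult(method=method, coefficient=float(r), p_value=float(p), n=len(x))


def sample_summary(
    sample: SampleSet,
    results: Sequence[FilterResult] = (),
    elapsed_s: float | None = None,
) -> dict:
    """Per-sample pipeline summary: counts, thresholds, and retained-size stats.

    Statuses partition the raw events, so
    ``n_raw = n_debris + n_misaligned + n_retained`` always holds. Throughput
    fields appear only when an elapsed time is supplied (they depend on the
    instrument, never on this software).
    """
    counts = sample.status_counts()
    n_raw = len(sample)
    n_debris = counts[STATUS_DEBRIS]
    n_band = counts[STATUS_MISALIGNED_BAND]
    n_mode = counts[STATUS_MISALIGNED_MODE]
    n_retained = n_raw - n_debris - n_band - n_mode
    assert n_retained == counts["retained"] + counts["raw"]

    summary: dict = {
        "sample_id": sample.sample_id,
        "n_raw": n_raw,
        "n_debris": n_debris,
        "n_misaligned_band": n_band,
        "n_misaligned_mode": n_mode,
        "n_misaligned": n_band + n_mode,
        "n_retained": n_retained,
    }
    for res in results:
        if res.stage == "debris":
            summary["debris_threshold_um"] = res.threshold_um
            summary["mode1_mean_um"] = res.mode_mean_dropped_um
            summary["mode2_mean_um"] = res.mode_mean_kept_um
        elif res.stage == "band":
            summary["band_ei"] = list(res.band_ei) if res.band_ei else None
            summary["band_wl"] = list(res.band_wl) if res.band_wl else None
        elif res.stage == "misalign_mode":
            summary["misalign_threshold_um"] = res.threshold_um

    if n_retained > 0 and "size_um" in sample.events.columns:
        sizes = sample.events.loc[sample.active_mask, "size_um"].to_numpy(dtype=float)
        summary["retained_mean_um"] = float(sizes.mean())
        summary["retained_median_um"] = float(np.median(sizes))
        summary["retained_sd_um"] = float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0
        if "size_um" in sample.events.columns:
            summary["n_negative_size"] = int((sample.events["size_um"] < 0).sum())

    if elapsed_s is not None and elapsed_s > 0:
        summary["events_per_min"] = 60.0 * n_raw / elapsed_s
        summary["retained_per_min"] = 60.0 * n_retained / elapsed_s
    return summary


def multi_sample_summary(summaries: Iterable[dict]) -> pd.DataFrame:
    """One row per sample plus a trailing ``mean`` row over numeric columns."""
    table = pd.DataFrame(list(summaries))
    if table.empty:
        return table
    means = table.mean(numeric_only=True)
    mean_row = {c: means.get(c, pd.NA) for c in table.columns}
    mean_row["sample_id"] = "mean"
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
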