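"""Removal of misaligned eggs via EI / W-over-L bands plus a second valley pass.

A prolate egg transiting on its short axis has its length underestimated by
TOF. Such objects stand out in profile shape space: their W/L is larger and
their ellipticalness index departs from the aligned population. Stage one
keeps only objects whose EI *and* W/L both lie within half a standard
deviation of the respective medians (computed on the debris-filtered subset);
stage two reruns the cross-validated KDE first-valley filter on the
survivors' sizes to excise the residual low-size mode of misaligned eggs.
Stage two finding no valley is a clean no-op — a well-behaved sample with
few misaligned eggs is unimodal after the band filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .density_filter import DEFAULT_GRID_POINTS, DEFAULT_N_FOLDS, FilterResult, mode_filter
from .errors import MissingFeaturesError, NoValleyError
from .io_lpfc import STATUS_MISALIGNED_BAND, STATUS_MISALIGNED_MODE, SampleSet

DEFAULT_HALF_WIDTH = 0.5  # band half-width as a multiple of the sample SD


def band_filter(values, half_width: float = DEFAULT_HALF_WIDTH) -> tuple[np.ndarray, tuple[float, float]]:
    """Keep values within ``median ± half_width·SD`` (closed interval).

    SD uses the n−1 denominator; with a single value or zero spread the band
    collapses to the median and every (equal) value is kept.

    Returns the boolean keep mask (input order) and the ``(low, high)`` band.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("band_filter needs at least one value")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    med = float(np.median(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    low, high = med - half_width * sd, med + half_width * sd
    keep = (arr >= low) & (arr <= high)
    return keep, (low, high)


def misalign_filter(
    sample: SampleSet,
    features: pd.DataFrame,
    *,
    seed: int = 0,
    half_width: float = DEFAULT_HALF_WIDTH,
    grid=None,
    n_folds: int = DEFAULT_N_FOLDS,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> tuple[FilterResult, FilterResult]:
    """Two-stage misalignment filter on the debris-filtered events (in place).

    Stage "band": events outside the EI band *or* outside the W/L band are
    marked ``misaligned_band`` (kept = intersection of both bands; medians
    and SDs are computed on the currently active, i.e. debris-filtered,
    subset only). Stage "misalign_mode": the KDE first-valley filter reruns
    on the band survivors' sizes, marking the sub-threshold mode
    ``misaligned_mode``; if no valley exists, nothing is marked and the
    result records no threshold.

    ``features`` must cover every active event (columns ``object_id``,
    ``ei``, ``w_over_l``); missing ids raise
    :class:`~eggflow.errors.MissingFeaturesError`.
    """
    events = sample.events
    active = sample.active_mask
    active_ids = events.loc[active, "object_id"]

    feat = features.set_index("object_id")
    missing = [oid for oid in active_ids if oid not in feat.index]
    if missing:
        raise MissingFeaturesError(missing)
    feat = feat.loc[active_ids]

    keep_ei, band_ei = band_filter(feat["ei"].to_numpy(), half_width)
    keep_wl, band_wl = band_filter(feat["w_over_l"].to_numpy(), half_width)
    keep = keep_ei & keep_wl

    drop_ids = active_ids[~keep].tolist()
    events.loc[events["object_id"].isin(drop_ids), "status"] = STATUS_MISALIGNED_BAND

    sizes = (
        events.loc[active, "size_um"].to_numpy(dtype=float)
        if "size_um" in events.columns
        else None
    )
    band_result = FilterResult(
        stage="band",
        n_in=int(active.sum()),
        n_dropped=len(drop_ids),
        drop_ids=drop_ids,
        band_ei=band_ei,
        band_wl=band_wl,
        mode_mean_dropped_um=float(sizes[~keep].mean()) if sizes is not None and (~keep).any() else None,
        mode_mean_kept_um=float(sizes[keep].mean()) if sizes is not None and keep.any() else None,
    )

    try:
        mode_result = mode_filter(
            sample,
            STATUS_MISALIGNED_MODE,
            grid=grid,
            n_folds=n_folds,
            seed=seed,
            grid_points=grid_points,
            stage="misalign_mode",
        )
    except NoValleyError:
        mode_result = FilterResult(
            stage="misalign_mode",
            n_in=int(sample.active_mask.sum()),
            n_dropped=0,
            drop_ids=[],
            threshold_um=None,
        )
    return band_result, mode_result
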