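"""Cross-validated Gaussian KDE and first-valley mode thresholding.

The size distribution of a raw sample is bimodal: a low mode of debris and
yeast particles and a high mode of eggs. The border between the modes is
found empirically by fitting a Gaussian-kernel density whose bandwidth is
chosen by K-fold cross-validation (highest mean held-out log-likelihood),
evaluating the log-density on a uniform grid, and taking the first strict
local minimum after the first local maximum — the "first valley" — as the
size threshold. The same machinery is reused later to excise the residual
low-size mode of misaligned eggs.

Numerical conventions (the procedure leaves these open):

* bandwidth grid — 30 log-spaced values from 1% to 50% of the sample SD;
* CV score — total held-out log-likelihood, averaged over folds; ties go to
  the smaller bandwidth;
* evaluation grid — 512 uniform points spanning the sample range extended by
  3 bandwidths on each side;
* a flat valley plateau resolves to its left edge;
* a local maximum only counts as a mode when its density reaches 5% of the
  global maximum, and a minimum only separates two modes when it dips to at
  most 50% of the smaller flanking mode's density. Fixed-bandwidth KDEs
  always grow spurious bumps where the data thin out and shallow wiggles
  near a mode top; without these qualifications the "valley" next to such
  an artifact can land beyond (or inside) the main mode and the
  sub-threshold cut would mutilate a unimodal sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.neighbors import KernelDensity

from .errors import DegenerateSampleError, NoValleyError
from .io_lpfc import SampleSet

DEFAULT_GRID_POINTS = 512
DEFAULT_N_FOLDS = 5
#: a local maximum below this fraction of the peak density is tail noise, not a mode
MIN_MODE_HEIGHT_FRAC = 0.05
#: a minimum separates two modes only if its density is at most this fraction
#: of the smaller flanking mode's density
DEFAULT_VALLEY_DEPTH_FRAC = 0.5
_BANDWIDTH_GRID_SIZE = 30
_BANDWIDTH_SD_RANGE = (0.01, 0.50)
_GRID_PAD_BANDWIDTHS = 3.0


@dataclass
class KDEFit:
    """A fitted Gaussian-kernel density over a 1-D sample.

    ``cv_scores[i]`` is the mean (over folds) total held-out log-likelihood
    for ``bandwidth_grid[i]``; ``bandwidth`` maximizes it (ties resolve to
    the smallest bandwidth). ``log_density`` is the fitted log-density on
    ``eval_grid``.
    """

    bandwidth: float
    bandwidth_grid: np.ndarray = field(repr=False)
    cv_scores: np.ndarray = field(repr=False)
    eval_grid: np.ndarray = field(repr=False)
    log_density: np.ndarray = field(repr=False)
    n: int = 0


@dataclass(frozen=True)
class ValleyThreshold:
    """First valley of a fitted log-density: the empirical mode border."""

    threshold_um: float
    valley_index: int
    modes_detected: int


@dataclass
class FilterResult:
    """Outcome of one filtering stage (debris, band, or misalign-mode)."""

    stage: str
    n_in: int
    n_dropped: int
    drop_ids: list[str]
    threshold_um: float | None = None
    band_ei: tuple[float, float] | None = None
    band_wl: tuple[float, float] | None = None
    mode_mean_dropped_um: float | None = None
    mode_mean_kept_um: float | None = None
    kde: KDEFit | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        assert self.n_dropped == len(self.drop_ids) <= self.n_in
        for band in (self.band_ei, self.band_wl):
            if band is not None:
                assert band[0] <= band[1]

    def to_report(self) -> dict:
        rep = {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_dropped": self.n_dropped,
            "threshold_um": self.threshold_um,
            "mode_mean_dropped_um": self.mode_mean_dropped_um,
            "mode_mean_kept_um": self.mode_mean_kept_um,
        }
        if self.band_ei is not None:
            rep["band_ei"] = list(self.band_ei)
        if self.band_wl is not None:
            rep["band_wl"] = list(self.band_wl)
        if self.kde is not None:
            rep["bandwidth"] = self.kde.bandwidth
        return rep


def default_bandwidth_grid(values: np.ndarray) -> np.ndarray:
    sd = float(np.std(values, ddof=1))
    lo, hi = _BANDWIDTH_SD_RANGE
    return np.geomspace(lo * sd, hi * sd, _BANDWIDTH_GRID_SIZE)


def select_bandwidth(
    values,
    grid=None,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> KDEFit:
    """Choose a KDE bandwidth by K-fold cross-validated held-out log-likelihood.

    Folds are a seeded random permutation of the data; for each candidate
    bandwidth the density is fitted on the training folds and scored as the
    total log-likelihood of the held-out fold, averaged over folds. The
    returned fit also carries the log-density evaluated on a uniform grid
    spanning the sample range (padded by 3 bandwidths per side).
    """
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if values.size and np.ptp(values) == 0:
        raise DegenerateSampleError("all values identical; no density to estimate")
    if len(values) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} values, got {len(values)}")

    if grid is None:
        grid = default_bandwidth_grid(values)
    grid = np.sort(np.asarray(grid, dtype=float).ravel())
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("bandwidth grid must be non-empty and positive")

    X = values[:, None]
    splits = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X))
    # Gaussian-kernel held-out log-likelihood, vectorized over the bandwidth
    # grid by reusing each fold's squared-distance matrix (identical to
    # sklearn KernelDensity.score; cross-checked in the tests).
    scores = np.zeros(grid.size)
    for train, test in splits:
        d2 = (values[test][:, None] - values[train][None, :]) ** 2
        rowmin = d2.min(axis=1)  # stabilizer: max of -d2/(2h²) per test point
        buf = np.empty_like(d2)
        for i, bw in enumerate(grid):
            inv = -1.0 / (2.0 * bw * bw)
            np.multiply(d2, inv, out=buf)
            buf -= (rowmin * inv)[:, None]
            np.exp(buf, out=buf)
            ll = np.log(buf.sum(axis=1)) + rowmin * inv
            ll -= math.log(len(train)) + 0.5 * math.log(2.0 * math.pi * bw * bw)
            scores[i] += ll.sum()
    scores /= n_folds

    # ascending grid + strict '>' ties toward the smallest bandwidth
    best = 0
    for i in range(1, grid.size):
        if scores[i] > scores[best]:
            best = i
    bandwidth = float(grid[best])

    pad = _GRID_PAD_BANDWIDTHS * bandwidth
    eval_grid = np.linspace(values.min() - pad, values.max() + pad, grid_points)
    log_density = (
        KernelDensity(kernel="gaussian", bandwidth=bandwidth)
        .fit(X)
        .score_samples(eval_grid[:, None])
    )
    return KDEFit(
        bandwidth=bandwidth,
        bandwidth_grid=grid,
        cv_scores=scores,
        eval_grid=eval_grid,
        log_density=log_density,
        n=len(values),
    )


def _plateau_compressed(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal values to their left edge."""
    keep = np.concatenate(([True], np.diff(y) != 0))
    return y[keep], np.flatnonzero(keep)


def first_valley(
    fit: KDEFit,
    min_mode_frac: float = MIN_MODE_HEIGHT_FRAC,
    valley_depth_frac: float = DEFAULT_VALLEY_DEPTH_FRAC,
) -> ValleyThreshold:
    """Locate the first valley of the fitted log-density.

    Scanning from the low end of the grid, the first strict local minimum of
    the log-density separating the first two modes is the valley; its grid
    position is the empirical size threshold. Two qualification rules keep
    KDE artifacts from masquerading as mode borders:

    * a local maximum counts as a mode only when its density reaches
      ``min_mode_frac`` of the global maximum (bumps where the data thin out
      are not modes);
    * a minimum only separates two modes when its density is at most
      ``valley_depth_frac`` of the smaller flanking mode's density; peaks
      divided by a shallower dip (sampling wiggle near a mode top) are
      merged into one mode, keeping the taller peak.

    A flat plateau at a minimum resolves to its left edge. Raises
    :class:`~eggflow.errors.NoValleyError` (carrying the number of modes
    found after merging) when fewer than two modes remain.
    """
    z, idx = _plateau_compressed(np.asarray(fit.log_density, dtype=float))
    if z.size < 2:
        raise NoValleyError(modes_detected=1)
    d = np.sign(np.diff(z))  # strictly +1/-1 after plateau compression

    maxima = [i for i in range(1, z.size - 1) if d[i - 1] > 0 and d[i] < 0]
    if d[0] < 0:
        maxima.insert(0, 0)  # curve starts at a peak
    if d[-1] > 0:
        maxima.append(z.size - 1)  # curve ends rising into a peak

    floor = z.max() + math.log(min_mode_frac)
    candidates = [i for i in maxima if z[i] >= floor]
    if not candidates:
        raise NoValleyError(modes_detected=1)

    depth = math.log(valley_depth_frac)
    mode_peaks = [candidates[0]]
    separators: list[int] = []
    for peak in candidates[1:]:
        prev = mode_peaks[-1]
        between = prev + int(np.argmin(z[prev : peak + 1]))  # ties -> left edge
        if z[between] <= min(z[prev], z[peak]) + depth:
            mode_peaks.append(peak)
            separators.append(between)
        elif z[peak] > z[prev]:
            mode_peaks[-1] = peak  # shallow dip: same mode, keep taller peak
    if len(mode_peaks) < 2:
        raise NoValleyError(modes_detected=len(mode_peaks))
    return ValleyThreshold(
        threshold_um=float(fit.eval_grid[idx[separators[0]]]),
        valley_index=int(idx[separators[0]]),
        modes_detected=len(mode_peaks),
    )


def mode_filter(
    sample: SampleSet,
    which_status: str,
    *,
    grid=None,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    grid_points: int = DEFAULT_GRID_POINTS,
    stage: str | None = None,
) -> FilterResult:
    """Remove the sub-threshold mode from the currently active events.

    Fits the cross-validated KDE to the active events' calibrated sizes,
    finds the first valley, and marks every active event with
    ``size_um < threshold`` with ``which_status`` (in place). Events at or
    above the threshold keep their status. The result records the threshold
    and the mean size on either side of it (the two mode means).

    Propagates :class:`~eggflow.errors.NoValleyError` when the active size
    distribution is unimodal; the caller decides policy.
    """
    events = sample.events
    active = sample.active_mask
    if "size_um" not in events.columns or events.loc[active, "size_um"].isna().any():
        raise ValueError("events must be calibrated (size_um) before mode filtering")
    sizes = events.loc[active, "size_um"].to_numpy(dtype=float)

    fit = select_bandwidth(sizes, grid=grid, n_folds=n_folds, seed=seed, grid_points=grid_points)
    valley = first_valley(fit)  # NoValleyError propagates

    below = active & (events["size_um"].to_numpy() < valley.threshold_um)
    drop_ids = events.loc[below, "object_id"].tolist()
    events.loc[below, "status"] = which_status

    dropped = sizes[sizes < valley.threshold_um]
    kept = sizes[sizes >= valley.threshold_um]
    return FilterResult(
        stage=stage or which_status,
        n_in=int(active.sum()),
        n_dropped=len(drop_ids),
        drop_ids=drop_ids,
        threshold_um=valley.threshold_um,
        mode_mean_dropped_um=float(dropped.mean()) if dropped.size else None,
        mode_mean_kept_um=float(kept.mean()) if kept.size else None,
        kde=fit,
    )
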