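"""Synthetic LPFC samples with ground truth: debris, aligned and misaligned eggs.

The generator emulates what a large-particle flow cytometer sees when a
suspension of fly eggs plus debris passes the laser:

* **debris** — small irregular particles (yeast, fragments). Sizes are
  normal around 90 µm; profiles are short reflected random walks whose
  ellipticalness is far from 1.
* **aligned eggs** — prolate ellipsoids transiting on the long axis. The
  measured extent equals the true length (normal around 440 µm, inside the
  400–600 µm literature range for the melanogaster subgroup); the optical
  profile is a half-ellipse whose peak is proportional to the egg *width*.
* **misaligned eggs** — the same ellipsoids transiting on the short axis,
  so the measured extent is the width plus a small positive jitter and the
  length is underestimated. Their profile peak is proportional to the
  *length* (the long axis lies across the beam), giving the larger W/L that
  flags them; the profile is a flattened half-ellipse (a sideways prolate
  object occludes near-maximally for most of its short transit), so their
  ellipticalness index sits above the aligned population's.

TOF is derived by inverting the calibration line, TOF = (extent − b)/a with
the instrument constants a = 5.94 µm per TOF unit and b = −491.78 µm, so a
round-trip through calibration recovers the generated extents exactly.
Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_lpfc import DROPPED_STATUSES, SampleSet

KLASS_DEBRIS = "debris"
KLASS_ALIGNED = "aligned_egg"
KLASS_MISALIGNED = "misaligned_egg"
KLASSES = (KLASS_DEBRIS, KLASS_ALIGNED, KLASS_MISALIGNED)

_ALIGNED_EXPONENT = 0.5  # (1 - x^2)^0.5: a true half-ellipse profile


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    ``class_proportions`` orders (debris, aligned_egg, misaligned_egg) and
    must sum to 1. Egg lengths are N(mean, sd²) in µm with width =
    ``egg_aspect``·length (prolate: aspect < 1). ``slope``/``intercept``
    are the µm-per-TOF calibration constants used to invert extents into
    instrument TOF units. ``peak_per_um`` converts a transverse extent to
    the profile's peak extinction; ``profile_noise_sd`` is additive Gaussian
    noise on each profile sample (truncated at 0). ``misaligned_flatten``
    is the half-ellipse exponent of misaligned-egg profiles (0.5 would be a
    true half-ellipse; smaller is boxier). ``orientation_mode`` is
    ``"binary"`` (aligned vs short-axis transit) or ``"angle"`` (continuous
    transit angle θ ~ U(0, π/2) with extent = ℓ·cosθ + w·sinθ).
    """

    n_objects: int = 3000
    class_proportions: tuple[float, float, float] = (0.30, 0.55, 0.15)
    egg_length_mean: float = 440.0
    egg_length_sd: float = 35.0
    egg_aspect: float = 0.40
    debris_size_mean: float = 90.0
    debris_size_sd: float = 20.0
    slope: float = 5.94
    intercept: float = -491.78
    profile_noise_sd: float = 0.02
    peak_per_um: float = 0.01
    misaligned_flatten: float = 0.2
    misalign_jitter_sd: float = 10.0
    orientation_mode: str = "binary"
    debris_walk_sd: float = 0.3
    debris_len_range: tuple[int, int] = (5, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != 3 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_proportions must be 3 non-negative values summing to 1")
        if self.n_objects < 1:
            raise ValueError("n_objects must be positive")
        if not 0 < self.egg_aspect < 1:
            raise ValueError("egg_aspect must be in (0, 1): eggs are prolate")
        for name in ("egg_length_mean", "debris_size_mean", "slope", "peak_per_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.orientation_mode not in ("binary", "angle"):
            raise ValueError("orientation_mode must be 'binary' or 'angle'")


def _ellipse_profile(rng, n_samples: int, peak: float, exponent: float, noise_sd: float) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_samples)
    base = peak * (1.0 - x**2) ** exponent
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, n_samples)
    return np.clip(base, 0.0, None)


def _debris_profile(rng, walk_sd: float, len_range: tuple[int, int]) -> np.ndarray:
    n = int(rng.integers(len_range[0], len_range[1] + 1))
    walk = np.abs(np.cumsum(rng.normal(0.0, walk_sd, n)))
    return walk + 0.05  # keep W strictly positive


def simulate_sample(config: SimConfig, sample_id: str = "synthetic") -> tuple[SampleSet, pd.DataFrame]:
    """Generate one sample (events + profiles) and its ground-truth table.

    Returns the :class:`~eggflow.io_lpfc.SampleSet` (all events raw, EXT set
    to the profile sum) and a truth DataFrame with columns ``object_id``,
    ``klass``, ``true_length_um``, ``true_width_um``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_objects
    klass_idx = rng.choice(3, size=n, p=np.asarray(cfg.class_proportions, dtype=float))

    ids, tofs, exts, profiles = [], [], [], {}
    truth_rows = []
    for i in range(n):
        oid = f"obj{i:05d}"
        k = KLASSES[klass_idx[i]]
        if k == KLASS_DEBRIS:
            extent = max(float(rng.normal(cfg.debris_size_mean, cfg.debris_size_sd)), 10.0)
            length = width = extent
            profile = _debris_profile(rng, cfg.debris_walk_sd, cfg.debris_len_range)
        else:
            length = float(rng.normal(cfg.egg_length_mean, cfg.egg_length_sd))
            length = max(length, 0.2 * cfg.egg_length_mean)  # guard absurd tail draws
            width = cfg.egg_aspect * length
            if k == KLASS_ALIGNED:
                extent, peak, exponent = length, cfg.peak_per_um * width, _ALIGNED_EXPONENT
            elif cfg.orientation_mode == "binary":
                extent = width + abs(float(rng.normal(0.0, cfg.misalign_jitter_sd)))
                peak, exponent = cfg.peak_per_um * length, cfg.misaligned_flatten
            else:  # continuous transit angle
                theta = float(rng.uniform(0.0, np.pi / 2.0))
                extent = length * np.cos(theta) + width * np.sin(theta)
                frac = np.sin(theta)  # 0 = aligned, 1 = fully sideways
                peak = cfg.peak_per_um * (width + (length - width) * frac)
                exponent = _ALIGNED_EXPONENT + (cfg.misaligned_flatten - _ALIGNED_EXPONENT) * frac
            tof_tmp = (extent - cfg.intercept) / cfg.slope
            profile = _ellipse_profile(
                rng, max(int(round(tof_tmp)), 3), peak, exponent, cfg.profile_noise_sd
            )
        tof = (extent - cfg.intercept) / cfg.slope
        ids.append(oid)
        tofs.append(tof)
        exts.append(float(profile.sum()))
        profiles[oid] = profile
        truth_rows.append((oid, k, length, width))

    events = pd.DataFrame({"object_id": ids, "tof": tofs, "ext": exts, "status": "raw"})
    truth = pd.DataFrame(
        truth_rows, columns=["object_id", "klass", "true_length_um", "true_width_um"]
    )
    return SampleSet(sample_id=sample_id, events=events, profiles=profiles), truth


@dataclass
class TruthMetrics:
    """Per-class recovery of the pipeline's status labels against the truth."""

    per_class: pd.DataFrame
    confusion: pd.DataFrame = field(repr=False)

    @property
    def aligned_retention(self) -> float:
        return float(self.per_class.loc[KLASS_ALIGNED, "retention"])

    @property
    def debris_removal(self) -> float:
        return float(self.per_class.loc[KLASS_DEBRIS, "removal"])

    @property
    def misaligned_removal(self) -> float:
        return float(self.per_class.loc[KLASS_MISALIGNED, "removal"])


def truth_metrics(truth: pd.DataFrame, sample: SampleSet) -> TruthMetrics:
    """Confusion summary of filtered statuses vs ground-truth classes.

    ``retention`` is the fraction of a class whose events survive every
    filter stage; ``removal`` = 1 − retention. Ids must match exactly.
    """
    t_ids = set(truth["object_id"])
    e_ids = set(sample.events["object_id"])
    if t_ids != e_ids:
        raise ValueError(
            f"id mismatch: {len(t_ids - e_ids)} truth-only, {len(e_ids - t_ids)} event-only ids"
        )
    merged = truth.merge(sample.events[["object_id", "status"]], on="object_id")
    merged["dropped"] = merged["status"].isin(DROPPED_STATUSES)

    rows = {}
    for k in KLASSES:
        sub = merged[merged["klass"] == k]
        n_k = len(sub)
        n_drop = int(sub["dropped"].sum())
        rows[k] = {
            "n": n_k,
            "n_dropped": n_drop,
            "n_retained": n_k - n_drop,
            "retention": (n_k - n_drop) / n_k if n_k else np.nan,
            "removal": n_drop / n_k if n_k else np.nan,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    confusion = pd.crosstab(merged["klass"], merged["status"])
    return TruthMetrics(per_class=per_class, confusion=confusion)
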