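"""Shape descriptors of optical-density profiles: W, L, Area, EI and W/L.

For each object transiting the laser the instrument records a time-ordered
sequence of extinction values. From that profile:

* ``W``  — the maximum extinction recorded for the object;
* ``L``  — the number of extinction measurements along the transit (a
  discrete proxy of time of flight);
* ``Area`` — the sum of the extinction values (area under the profile at
  unit sample spacing);
* ``EI = Area / ((π/4)·L·W)`` — the ellipticalness index, the ratio of the
  profile's area to that of the closest half-ellipse. A smooth ellipsoidal
  object transiting along its long axis gives EI ≈ 1.
* ``W/L`` — peak height per unit transit length; a prolate object passing on
  its short axis blocks more light over a shorter transit, so misaligned
  eggs show a larger W/L than aligned eggs.

Area uses the plain sum (rectangle rule): the measurements are discrete and
L is a count, so unit spacing is the only consistent convention, and the
L·W denominator of EI uses the same spacing so the choice cancels to first
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ZeroSignalError

FEATURE_COLUMNS = ("object_id", "W", "L", "area", "ei", "w_over_l")


@dataclass(frozen=True)
class ProfileFeatures:
    object_id: str
    W: float
    L: int
    area: float
    ei: float
    w_over_l: float


def compute_features(object_id: str, samples: Iterable[float]) -> ProfileFeatures:
    """Compute W, L, Area, EI and W/L for one optical profile.

    Raises ``ValueError`` on an empty profile and
    :class:`~eggflow.errors.ZeroSignalError` when no sample is positive
    (W = 0 would make EI undefined).
    """
    arr = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples, dtype=float)
    if arr.size == 0:
        raise ValueError(f"object {object_id!r}: empty profile")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"object {object_id!r}: profile samples must be finite and >= 0")
    w = float(arr.max())
    if w == 0.0:
        raise ZeroSignalError(f"object {object_id!r}: all-zero profile (W = 0)")
    L = int(arr.size)
    area = float(arr.sum())
    ei = area / ((math.pi / 4.0) * L * w)
    return ProfileFeatures(object_id=object_id, W=w, L=L, area=area, ei=ei, w_over_l=w / L)


def features_table(profiles: Mapping[str, np.ndarray], ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Feature rows for many profiles, as a DataFrame in ``FEATURE_COLUMNS`` order.

    ``ids`` restricts (and orders) the output; by default all profiles are
    processed in mapping order.
    """
    if ids is None:
        ids = list(profiles)
    rows = [compute_features(oid, profiles[oid]) for oid in ids]
    return pd.DataFrame(
        [(f.object_id, f.W, f.L, f.area, f.ei, f.w_over_l) for f in rows],
        columns=list(FEATURE_COLUMNS),
    )


def write_features(features: pd.DataFrame, path, *, sep: str = ",") -> None:
    features.to_csv(path, sep=sep, index=False)
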