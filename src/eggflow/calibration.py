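"""Bead-based TOF-to-size calibration.

Reference beads of known diameter are measured on the instrument, an
ordinary-least-squares line TOF = a + b·size is fitted with TOF as the
response variable, and the fit is inverted algebraically to
size = (1/b)·TOF − a/b. The regression direction matters with noisy beads
(errors-in-variables): the instrument observes TOF given a known bead size,
so TOF is the response.

Negative calibrated sizes are deliberately kept rather than clamped — they
belong to sub-threshold debris that the density filter removes, and clamping
would distort the kernel density estimate near zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError
from .io_lpfc import SampleSet


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from TOF (instrument units) to size (µm).

    ``slope`` is µm per TOF unit (must be positive: larger objects block the
    beam longer), ``fit_residual_sd`` is the residual standard deviation of
    the underlying TOF-on-size fit, in TOF units (0 when the fit has no
    residual degrees of freedom).
    """

    slope: float
    intercept: float
    n_beads: int
    fit_residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(f"slope must be positive, got {self.slope}")

    def predict_size(self, tof) -> np.ndarray:
        return self.slope * np.asarray(tof, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            n_beads=int(d.get("n_beads", 0)),
            fit_residual_sd=float(d.get("fit_residual_sd", 0.0)),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_calibration(beads: pd.DataFrame) -> CalibrationModel:
    """Fit TOF = a + b·size by OLS and invert to a size-from-TOF model.

    Parameters
    ----------
    beads
        Table with columns ``known_size_um`` and ``tof``; at least two beads
        with at least two distinct known sizes.
    """
    size = np.asarray(beads["known_size_um"], dtype=float)
    tof = np.asarray(beads["tof"], dtype=float)
    n = len(size)
    if n < 2 or np.unique(size).size < 2:
        raise CalibrationError(
            "need >= 2 beads with >= 2 distinct known sizes (singular fit)"
        )
    fit = stats.linregress(size, tof)
    b, a = fit.slope, fit.intercept
    if b <= 0:
        raise CalibrationError(f"non-monotone beads: fitted TOF-per-µm slope {b:.4g} <= 0")
    resid = tof - (a + b * size)
    residual_sd = math.sqrt(float(resid @ resid) / (n - 2)) if n > 2 else 0.0
    return CalibrationModel(
        slope=1.0 / b, intercept=-a / b, n_beads=n, fit_residual_sd=residual_sd
    )


def apply_calibration(model: CalibrationModel, sample: SampleSet) -> SampleSet:
    """Return a copy of ``sample`` with ``size_um = slope·tof + intercept``.

    TOF values and event order are untouched. Negative sizes are permitted
    (downstream debris filtering removes them).
    """
    out = sample.copy()
    out.events["size_um"] = model.predict_size(out.events["tof"].to_numpy())
    return out
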