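"""Ellipticalness index on archetypal optical-density profiles.

EI = Area / ((π/4)·L·W) compares a profile's area to the half-ellipse with
the same length and peak: 1.0 for a perfect half-ellipse (an ellipsoid
transiting smoothly), 4/π ≈ 1.27 for a flat-top (boxy) profile, 2/π ≈ 0.64
for a triangular one.
"""

import numpy as np

from eggflow import compute_features

x = np.linspace(-1, 1, 201)
profiles = {
    "half-ellipse": 10.0 * np.sqrt(1 - x**2),
    "rectangle": np.full(201, 10.0),
    "triangle": 10.0 * (1 - np.abs(x)),
    "flattened (sideways egg)": 10.0 * (1 - x**2) ** 0.2,
}
for name, prof in profiles.items():
    f = compute_features(name, prof)
    print(f"{name:25s} W={f.W:5.1f}  L={f.L}  EI={f.ei:.3f}  W/L={f.w_over_l:.4f}")
# Aligned eggs cluster at EI ≈ 1; misaligned (sideways) eggs sit above it and
# carry a larger W/L — the two handles the band filter uses.
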