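# Methods

## The measurement problem

A large-particle flow cytometer (LPFC) estimates the size of objects up to
~1500 µm from two optical signals recorded as each object transits the
interrogating laser: **TOF** (time of flight — how long the object blocks
the beam, proportional to its extent along the flow axis) and **EXT**
(extinction — the integrated blocked-light signal). For fly eggs, which are
prolate ellipsoids roughly 400–600 µm long, three things corrupt a naive
TOF-based length estimate:

1. **debris** (yeast particles, fragments) populates a low size mode;
2. **misaligned eggs** transit on their short axis, so TOF reflects the
   egg's *width* and the length is underestimated;
3. TOF is in instrument time units and must be calibrated to µm.

eggflow implements the corresponding computational pipeline: bead
calibration, kernel-density valley thresholding of debris, optical-profile
shape filtering of misaligned eggs, a second valley pass, size gating, and
concordance checks against manual measurements.

## Calibration

Reference beads of known diameter (e.g. 200 and 430 µm polystyrene) are
measured, and an OLS line **TOF = a + b·size** is fitted with TOF as the
response — the instrument observes TOF given a known size, so this is the
regression direction with the right error structure. The fit is inverted
algebraically to `size_um = (1/b)·TOF − a/b`. With noisy beads this is *not*
identical to regressing size on TOF; the stated procedure wins. A fitted
slope b ≤ 0 (size not increasing with TOF) or beads of a single size are
errors. Negative calibrated sizes are kept, not clamped: they belong to
sub-threshold debris that the density filter removes, and clamping would
pile probability mass at zero and distort the KDE.

## Debris filtering: cross-validated KDE and the first valley

The calibrated size distribution of a raw sample is bimodal (debris mode,
egg mode). The border between the modes is found empirically:

1. A Gaussian-kernel density is fitted to the sizes. The bandwidth is chosen
   by K-fold cross-validation (default K = 5, seeded shuffled folds): for
   each candidate bandwidth the density is fitted on the training folds and
   scored by the total log-likelihood of the held-out fold, averaged over
   folds; the maximizing bandwidth wins, ties going to the smaller value.
2. The log-density is evaluated on a uniform grid and scanned from the low
   end; the first strict local minimum after the first mode is the
   **valley**, used as the sample-specific size threshold.
3. Objects below the threshold are marked `debris`.

Numerical choices, where the procedure itself is silent:

* **Bandwidth grid** — 30 log-spaced values from 1% to 50% of the sample SD.
  This brackets the plug-in optimum `1.06·σ·n^(−1/5)` for any n this
  instrument produces (hundreds to tens of thousands of events) while
  allowing much smaller bandwidths for strongly multimodal samples.
* **Evaluation grid** — 512 uniform points over the sample range padded by
  3 bandwidths per side; at µm scale this resolves valleys to ~2 µm.
* **CV scoring** — computed from each fold's squared-distance matrix with a
  log-sum-exp, reusing the matrix across the bandwidth grid; this equals
  scikit-learn's `KernelDensity(...).score()` (asserted in the tests) at a
  fraction of the cost. The final grid density is evaluated with
  scikit-learn's `KernelDensity`.
* **Mode qualification** — a local maximum of the density counts as a mode
  only if its height reaches **5% of the global peak**, and a minimum only
  separates two modes if it dips to at most **50% of the smaller flanking
  mode's density**; peaks divided by a shallower dip are merged into one
  mode (keeping the taller peak). A fixed-bandwidth KDE always grows small
  bumps where the data thin out and shallow wiggles near a mode top; taking
  "first local minimum after the first local maximum" literally on a
  unimodal sample can then place the "valley" beyond or inside the main
  mode and the sub-threshold cut would mutilate the sample. Real debris/egg
  mode borders dip orders of magnitude below either mode, so qualification
  changes nothing on genuinely bimodal data; it only makes unimodal samples
  correctly raise "no valley". Both factors are exposed (`min_mode_frac`,
  `valley_depth_frac`).
* **Plateaus** — a flat run at a minimum resolves to its left edge
  (deterministic tie-break).

A sample with no valley (already debris-free) is a no-op for the pipeline,
not an error.

## Misalignment filtering: EI and W/L bands, then a second valley

From each object's **optical-density profile** (the time-ordered extinction
trace) three primitives are read off: `W` — the maximum extinction; `L` —
the number of measurements (a discrete proxy of TOF); `Area` — the sum of
the trace. Area uses the plain rectangle rule at unit spacing: the
measurements are discrete and L is a count, and since the reference area
`(π/4)·L·W` uses the same spacing the convention cancels to first order.
Two derived shape descriptors:

* **EI = Area / ((π/4)·L·W)** — the *ellipticalness index*, the ratio of the
  profile's area to that of the half-ellipse with the same footprint. A
  smooth ellipsoid transiting on its long axis gives EI ≈ 1.
* **W/L** — peak extinction per unit transit. A prolate object passing
  sideways blocks more light over a shorter transit, so misaligned eggs
  have larger W/L (and debris, being irregular, scatters in both).

The filter retains objects whose EI **and** W/L both lie within **half a
standard deviation of the median** (closed interval, SD with n−1
denominator), computed on the debris-filtered subset. Intersection rather
than union of the two bands is the conservative choice for downstream
sorting. The bands are scale-free: on a *homogeneous* population they
retain only the central ~38%, so the filter's selectivity comes entirely
from the misaligned cluster inflating the SD while the median stays inside
the aligned cluster — which is exactly the regime after debris filtering,
where the retained set is a ~4:1 mixture of aligned and misaligned eggs.
Finally, the KDE/valley filter reruns on the band survivors' sizes (with a
freshly cross-validated bandwidth — the subset is a new sample) to excise
any residual low-size mode of misaligned eggs; finding no valley there is
the expected outcome for a well-filtered sample and is a clean no-op.

## Gating and sort recovery

Gates are half-open µm intervals [low, high) on calibrated size; contiguous
gates partition the size axis with no double assignment (the boundary
convention is tested at exact edges). Sort recovery — the percentage of
gate-eligible objects the instrument actually dispensed — is
`100·n_sorted/n_eligible`, undefined at zero eligible objects.

## The synthetic generator

`simulate_sample` draws each object's class from fixed proportions
(defaults: 30% debris, 55% aligned eggs, 15% misaligned eggs, n = 3000) and
builds events and profiles:

| parameter | default | meaning |
|---|---|---|
| `egg_length_mean/sd` | 440 / 35 µm | true egg length ~ N(mean, sd²), inside the 400–600 µm literature range |
| `egg_aspect` | 0.40 | width/length of the prolate egg |
| `debris_size_mean/sd` | 90 / 20 µm | debris extent, matching the observed first mode (~92 µm) |
| `slope`, `intercept` | 5.94, −491.78 | instrument calibration constants used to invert extents to TOF |
| `peak_per_um` | 0.01 | extinction units per µm of transverse extent (profile peak) |
| `profile_noise_sd` | 0.02 | additive Gaussian noise per profile sample, truncated at 0 |
| `misaligned_flatten` | 0.2 | half-ellipse exponent of misaligned profiles (0.5 = true half-ellipse) |
| `misalign_jitter_sd` | 10 µm | positive jitter on the misaligned apparent extent |

The profile noise default (0.02 extinction units against aligned peaks of
~1.8) is set by a construction constraint: `W` is the *maximum* of the noisy
trace, so additive noise biases `W` upward by roughly two noise SDs and
pushes EI down; 0.02 keeps the bias ~2% so that constructed aligned
profiles verifiably stay in EI ∈ [0.9, 1.1], while still exercising the
noise-truncation path.

Aligned eggs present their length to the TOF measurement and a half-ellipse
profile of `L = round(TOF)` samples with peak ∝ width. Misaligned eggs
(binary orientation model: long-axis vs short-axis transit) present their
width plus |N(0, 10²)| µm, with peak ∝ length — hence the larger W/L — and a
*flattened* half-ellipse profile, `(1 − x²)^0.2` instead of `(1 − x²)^0.5`,
giving EI ≈ 1.15: a sideways prolate object occludes near-maximally for
most of its short transit, so its profile is boxier than an aligned one's.
Without this shape contrast EI would carry no information about orientation
and the EI band would only thin the aligned population. Debris profiles are
short reflected random walks (5–40 samples) whose EI scatters far from 1.
An optional continuous-angle mode (`orientation_mode="angle"`) draws a
transit angle θ ~ U(0, π/2) and interpolates extent (ℓcosθ + w sinθ), peak
and flattening; it is off by default because the binary model is the one
the filtering rationale is built on.

With the default geometry the misaligned apparent size is ≈ 185 ± 16 µm
(width of a 440 µm egg at aspect 0.40 plus jitter). Real misaligned eggs on
the instrument average ~362 µm, i.e. partially aligned transits that a
binary orientation model does not produce; the angle mode moves apparent
sizes into that range. Consequences for interpreting passing tests: the
synthetic misaligned mode is *more* separable from the aligned mode than
the instrument's, so label-recovery rates here certify the machinery
(threshold placement, band logic, bookkeeping), not instrument performance.
Other real-data features the generator does not emulate: doublets,
saturated profiles, drift in the extinction baseline, and any correlation
between debris load and egg density.

## What the pipeline reports

Per sample: counts per status (`raw → debris | misaligned_band |
misaligned_mode | retained`; the statuses partition the events — asserted
on every run), the debris and misalign thresholds, both band intervals, the
mode means on either side of the debris threshold, and retained-size
statistics. Throughput (events/min) is only derived when the caller
supplies an elapsed time, since it is a property of the instrument.

Concordance between manual and automated lengths uses Spearman's rank
correlation (average-rank ties) or Pearson's r, with the standard
large-sample two-sided p-value; both come from scipy.stats.

## Problem sizes and determinism

The packaged study conditions are n = 3000 events per synthetic sample
(binomially split ~900 debris / ~1650 aligned / ~450 misaligned), 5-fold CV
over 30 bandwidths, and 10-seed replication for label-recovery checks; the
valley-placement check uses 20 seeds of a 5000-point two-Gaussian mixture.
All randomness flows through explicit seeds (`numpy.random.default_rng` in
the generator, seeded `KFold` shuffling in CV), so identical inputs and
seed reproduce thresholds, masks and reports bit for bit.

## Known limitations

* The first-valley threshold assumes the minority mode lies *below* the
  majority mode; a sample dominated by debris (egg mode under 5% of the
  peak) is treated as unimodal.
* The EI/W-L bands assume misaligned eggs are a minority; past roughly
  equal proportions the median itself migrates and the bands lose meaning.
* Orientation correction (recovering the true length of a misaligned egg)
  is out of scope — misaligned eggs are removed, not repaired.
* The W-given-orientation model in the generator is a stylized stand-in;
  no instrument-optics simulation is attempted.
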