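"""End-to-end filtering pipeline: calibrate → debris valley → EI/W-L bands → second valley.

``run_pipeline`` is the one-call entry point used by the CLI, the examples
and the acceptance machinery. It never mutates the caller's sample; the
returned sample has every event in a terminal status (``debris``,
``misaligned_band``, ``misaligned_mode`` or ``retained``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calibration import CalibrationModel, apply_calibration
from .density_filter import (
    DEFAULT_GRID_POINTS,
    DEFAULT_N_FOLDS,
    FilterResult,
    mode_filter,
)
from .errors import NoValleyError
from .io_lpfc import STATUS_DEBRIS, STATUS_RAW, STATUS_RETAINED, SampleSet
from .misalign_filter import DEFAULT_HALF_WIDTH, misalign_filter
from .profile_features import features_table
from .validation import sample_summary


@dataclass
class PipelineResult:
    sample: SampleSet
    debris: FilterResult
    band: FilterResult
    misalign_mode: FilterResult
    features: pd.DataFrame = field(repr=False)
    summary: dict = field(repr=False)

    @property
    def results(self) -> list[FilterResult]:
        return [self.debris, self.band, self.misalign_mode]

    def to_report(self) -> dict:
        return {
            "summary": self.summary,
            "stages": [r.to_report() for r in self.results],
        }


def run_pipeline(
    sample: SampleSet,
    model: CalibrationModel | None = None,
    *,
    seed: int = 0,
    half_width: float = DEFAULT_HALF_WIDTH,
    n_folds: int = DEFAULT_N_FOLDS,
    grid_points: int = DEFAULT_GRID_POINTS,
    bandwidth_grid=None,
) -> PipelineResult:
    """Run calibration (optional) and all three filter stages on a sample.

    Requires profiles for every event that survives the debris stage. A
    unimodal size distribution at the debris stage (no valley) is treated as
    "nothing to remove" rather than an error; the same policy applies inside
    the misalignment stage. ``seed`` drives the cross-validation fold
    shuffling of both KDE stages; identical input and seed give identical
    thresholds, masks and reports.
    """
    work = sample.copy()
    if model is not None:
        work = apply_calibration(model, work)
    if "size_um" not in work.events.columns:
        raise ValueError("events must be calibrated or a CalibrationModel supplied")
    if work.profiles is None:
        raise ValueError("misalignment filtering needs optical profiles")

    try:
        debris = mode_filter(
            work,
            STATUS_DEBRIS,
            grid=bandwidth_grid,
            n_folds=n_folds,
            seed=seed,
            grid_points=grid_points,
            stage="debris",
        )
    except NoValleyError:
        debris = FilterResult(
            stage="debris",
            n_in=int(work.active_mask.sum()),
            n_dropped=0,
            drop_ids=[],
            threshold_um=None,
        )

    features = features_table(work.profiles, ids=work.active_ids)
    band, misalign_mode = misalign_filter(
        work,
        features,
        seed=seed,
        half_width=half_width,
        grid=bandwidth_grid,
        n_folds=n_folds,
        grid_points=grid_points,
    )

    events = work.events
    events.loc[events["status"] == STATUS_RAW, "status"] = STATUS_RETAINED

    summary = sample_summary(work, [debris, band, misalign_mode])
    return PipelineResult(
        sample=work,
        debris=debris,
        band=band,
        misalign_mode=misalign_mode,
        features=features,
        summary=summary,
    )
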