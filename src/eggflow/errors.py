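"""Exception hierarchy for the eggflow pipeline."""

from __future__ import annotations

from typing import Sequence


class EggflowError(Exception):
    """Base class for all eggflow errors."""


class FormatError(EggflowError):
    """A file violates the documented table dialect (missing column, duplicate id, ...)."""


class RowError(FormatError):
    """A specific data row is invalid; carries the 1-based line number in the file."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class CalibrationError(EggflowError):
    """Bead fit is singular or non-monotone (fitted TOF-per-µm slope <= 0)."""


class DegenerateSampleError(EggflowError):
    """A sample has no spread (all values identical or constant column)."""


class NoValleyError(EggflowError):
    """The fitted log-density has no interior local minimum after the first mode."""

    def __init__(self, modes_detected: int = 1):
        super().__init__(
            f"no valley found in log-density ({modes_detected} mode(s) detected)"
        )
        self.modes_detected = modes_detected


class ZeroSignalError(EggflowError):
    """An optical profile carries no positive extinction (W = 0)."""


class MissingFeaturesError(EggflowError):
    """Retained events lack profile features; carries the offending ids."""

    def __init__(self, ids: Sequence[str]):
        ids = list(ids)
        shown = ", ".join(ids[:10]) + (", ..." if len(ids) > 10 else "")
        super().__init__(f"{len(ids)} retained event(s) missing features: {shown}")
        self.ids = ids


class UndefinedRecoveryError(EggflowError):
    """Sort recovery is undefined when no objects fulfil the sorting criteria."""
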