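"""Size gates on calibrated length, gate assignment, and sort recovery.

Gates are half-open µm intervals [low, high) on the calibrated size — the
half-open convention guarantees contiguous gates partition the size axis
with no double assignment. Sort recovery is the percentage of gate-eligible
objects actually sorted and dispensed by the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import UndefinedRecoveryError
from .io_lpfc import SampleSet


@dataclass(frozen=True)
class Gate:
    """A half-open size interval [low_um, high_um) in µm."""

    name: str
    low_um: float
    high_um: float

    def __post_init__(self) -> None:
        if not self.low_um < self.high_um:
            raise ValueError(f"gate {self.name!r}: low_um must be < high_um")

    def contains(self, size_um: float) -> bool:
        return self.low_um <= size_um < self.high_um


def _check_non_overlapping(gates: list[Gate]) -> None:
    ordered = sorted(gates, key=lambda g: g.low_um)
    for a, b in zip(ordered, ordered[1:]):
        if b.low_um < a.high_um:
            raise ValueError(f"gates {a.name!r} and {b.name!r} overlap")


def make_gates(low: float, high: float, step: float) -> list[Gate]:
    """Contiguous half-open gates [low, low+step), ..., [high−step, high).

    ``high − low`` must be an integer multiple of ``step``; names are
    ``G<low>-<high>``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    span = high - low
    n = round(span / step)
    if n < 1 or abs(n * step - span) > 1e-9 * max(abs(span), step):
        raise ValueError(f"span {span} is not a positive integer multiple of step {step}")
    gates = []
    for i in range(n):
        lo = low + i * step
        hi = low + (i + 1) * step
        gates.append(Gate(name=f"G{lo:g}-{hi:g}", low_um=lo, high_um=hi))
    return gates


def assign_gates(sample: SampleSet, gates: list[Gate]) -> SampleSet:
    """Return a copy with a ``gate`` column on the active (retained) events.

    An event whose ``size_um`` falls in no gate — or a dropped event — gets
    a missing gate value.
    """
    _check_non_overlapping(gates)
    out = sample.copy()
    events = out.events
    if "size_um" not in events.columns:
        raise ValueError("events must be calibrated (size_um) before gating")
    gate_col = pd.Series(pd.NA, index=events.index, dtype="object")
    active = out.active_mask
    sizes = events["size_um"]
    for g in gates:
        in_gate = active & (sizes >= g.low_um) & (sizes < g.high_um)
        gate_col[in_gate] = g.name
    events["gate"] = gate_col
    return out


def gate_counts(sample: SampleSet, gates: list[Gate]) -> dict[str, int]:
    """Number of active events per gate (events must be gate-assigned)."""
    counts = sample.events.loc[sample.active_mask, "gate"].value_counts()
    return {g.name: int(counts.get(g.name, 0)) for g in gates}


def sort_recovery(n_sorted: int, n_eligible: int) -> float:
    """Percentage of gate-eligible objects that were sorted and dispensed."""
    if n_eligible == 0:
        raise UndefinedRecoveryError("no objects fulfil the sorting criteria")
    if not 0 <= n_sorted <= n_eligible:
        raise ValueError(f"need 0 <= n_sorted ({n_sorted}) <= n_eligible ({n_eligible})")
    return 100.0 * n_sorted / n_eligible
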