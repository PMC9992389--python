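"""Reading and writing event tables, optical profiles, bead tables and reports.

Canonical dialect: comma-separated UTF-8 text with a mandatory header row and
"." as the decimal separator (``sep="\\t"`` switches to tab-separated).
Unrecognized columns are preserved and written back unchanged, since real
instrument exports carry many extra channels.

Files
-----
events   : ``object_id,tof,ext[,...]`` — one detected object per row.
profiles : ``object_id,sample_index,extinction`` — long format, one extinction
           measurement per row, ``sample_index`` contiguous from 0 per object.
beads    : ``known_size_um,tof`` — reference-bead calibration table.
report   : JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, RowError

# Filtering statuses. An event starts "raw" and moves forward to exactly one
# terminal status as the pipeline runs.
STATUS_RAW = "raw"
STATUS_DEBRIS = "debris"
STATUS_MISALIGNED_BAND = "misaligned_band"
STATUS_MISALIGNED_MODE = "misaligned_mode"
STATUS_RETAINED = "retained"

ALL_STATUSES = frozenset(
    {STATUS_RAW, STATUS_DEBRIS, STATUS_MISALIGNED_BAND, STATUS_MISALIGNED_MODE, STATUS_RETAINED}
)
DROPPED_STATUSES = frozenset({STATUS_DEBRIS, STATUS_MISALIGNED_BAND, STATUS_MISALIGNED_MODE})
#: statuses of events still in play (not dropped by any filter stage)
ACTIVE_STATUSES = frozenset({STATUS_RAW, STATUS_RETAINED})

REQUIRED_EVENT_COLUMNS = ("object_id", "tof", "ext")
REQUIRED_PROFILE_COLUMNS = ("object_id", "sample_index", "extinction")
REQUIRED_BEAD_COLUMNS = ("known_size_um", "tof")

#: measurable size range of the instrument's flow cell, µm
INSTRUMENT_RANGE_UM = (10.0, 1500.0)


@dataclass
class SampleSet:
    """Events (and optionally optical profiles) of one measured sample.

    ``events`` is a DataFrame with at least ``object_id``, ``tof``, ``ext``
    and ``status`` columns; ``size_um`` appears after calibration and
    ``gate`` after gating. ``profiles`` maps object_id to a 1-D float array
    of extinction measurements at unit time spacing.
    """

    sample_id: str
    events: pd.DataFrame
    profiles: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = self.events["object_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique()
            raise FormatError(f"duplicate object_id(s): {', '.join(map(str, dups[:5]))}")
        if "status" not in self.events.columns:
            self.events = self.events.assign(status=STATUS_RAW)
        bad = set(self.events["status"]) - ALL_STATUSES
        if bad:
            raise FormatError(f"unknown status value(s): {sorted(bad)}")
        if self.profiles is not None:
            orphans = set(self.profiles) - set(ids)
            if orphans:
                raise FormatError(
                    f"profiles for unknown object_id(s): {sorted(orphans)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def active_mask(self) -> np.ndarray:
        """Boolean mask of events not dropped by any filter stage."""
        return self.events["status"].isin(ACTIVE_STATUSES).to_numpy()

    @property
    def active_ids(self) -> list[str]:
        return self.events.loc[self.active_mask, "object_id"].tolist()

    def copy(self) -> "SampleSet":
        profiles = None if self.profiles is None else {k: v.copy() for k, v in self.profiles.items()}
        return replace(self, events=self.events.copy(), profiles=profiles)

    def status_counts(self) -> dict[str, int]:
        counts = self.events["status"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in sorted(ALL_STATUSES)}


def _read_table(path, sep: str, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    # round_trip: the default float parser can be off by one ulp, breaking
    # the write∘read identity the dialect guarantees
    df = pd.read_csv(path, sep=sep, dtype={"object_id": str}, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r} in {path.name}")
    return df


def _coerce_numeric(df: pd.DataFrame, col: str, *, non_negative: bool = True) -> pd.DataFrame:
    raw = df[col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header is line 1, first data row is line 2
        raise RowError(f"non-numeric {col} value {raw.iloc[i]!r}", line=i + 2)
    if values.isna().any():
        i = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise RowError(f"missing {col} value", line=i + 2)
    if non_negative and (values < 0).any():
        i = int(np.flatnonzero((values < 0).to_numpy())[0])
        raise RowError(f"negative {col} value {values.iloc[i]}", line=i + 2)
    return df.assign(**{col: values.astype(float)})


def read_events(path, *, sep: str = ",", sample_id: str | None = None) -> SampleSet:
    """Read an event table into a :class:`SampleSet` of raw events.

    Row order is preserved and no row is ever silently dropped: a malformed
    row raises :class:`~eggflow.errors.RowError` with its line number.
    """
    df = _read_table(path, sep, REQUIRED_EVENT_COLUMNS)
    df = _coerce_numeric(df, "tof")
    df = _coerce_numeric(df, "ext")
    if "size_um" in df.columns:
        df = df.assign(size_um=pd.to_numeric(df["size_um"], errors="raise").astype(float))
    if sample_id is None:
        sample_id = Path(path).stem
    return SampleSet(sample_id=sample_id, events=df)


def write_events(sample: SampleSet, path, *, sep: str = ",") -> None:
    sample.events.to_csv(path, sep=sep, index=False)


def read_profiles(path, *, sep: str = ",") -> dict[str, np.ndarray]:
    """Read long-format optical profiles, ordered by ``sample_index``.

    Raises on a gap in ``sample_index`` or a negative/non-finite extinction.
    """
    df = _read_table(path, sep, REQUIRED_PROFILE_COLUMNS)
    df = _coerce_numeric(df, "extinction")
    idx = pd.to_numeric(df["sample_index"], errors="coerce")
    if idx.isna().any() or (idx != idx.round()).any():
        i = int(np.flatnonzero((idx.isna() | (idx != idx.round())).to_numpy())[0])
        raise RowError("sample_index must be an integer", line=i + 2)
    df = df.assign(sample_index=idx.astype(int))
    if not np.isfinite(df["extinction"]).all():
        raise FormatError("non-finite extinction value")

    profiles: dict[str, np.ndarray] = {}
    for oid, grp in df.groupby("object_id", sort=False):
        grp = grp.sort_values("sample_index")
        found = grp["sample_index"].to_numpy()
        if not np.array_equal(found, np.arange(len(found))):
            raise FormatError(
                f"object {oid!r}: sample_index not contiguous from 0 (got {found[:5].tolist()}...)"
            )
        profiles[str(oid)] = grp["extinction"].to_numpy(dtype=float)
    return profiles


def write_profiles(profiles: Mapping[str, np.ndarray], path, *, sep: str = ",") -> None:
    frames = [
        pd.DataFrame(
            {
                "object_id": oid,
                "sample_index": np.arange(len(samples)),
                "extinction": np.asarray(samples, dtype=float),
            }
        )
        for oid, samples in profiles.items()
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(REQUIRED_PROFILE_COLUMNS))
    )
    out.to_csv(path, sep=sep, index=False)


def read_beads(path, *, sep: str = ",") -> pd.DataFrame:
    """Read a bead calibration table (``known_size_um,tof``)."""
    df = _read_table(path, sep, REQUIRED_BEAD_COLUMNS)
    df = _coerce_numeric(df, "known_size_um")
    df = _coerce_numeric(df, "tof")
    lo, hi = INSTRUMENT_RANGE_UM
    if ((df["known_size_um"] < lo) | (df["known_size_um"] > hi)).any():
        raise FormatError(f"bead size outside instrument range [{lo}, {hi}] µm")
    if (df["tof"] <= 0).any() or (df["known_size_um"] <= 0).any():
        raise FormatError("bead sizes and TOF values must be positive")
    return df


def write_beads(beads: pd.DataFrame, path, *, sep: str = ",") -> None:
    beads.to_csv(path, sep=sep, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_report(report: dict, path) -> None:
    """Serialize a pipeline report (thresholds, counts, bands, statistics) as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
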