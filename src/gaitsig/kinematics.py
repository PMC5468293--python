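"""Stride-to-stride gait kinematics.

Converts footfall events (swing onset/offset times plus touchdown positions
along the runway) into per-stride spatial and temporal gait parameters, and
derives trial-average parameters for human walkway records.

Conventions
-----------
* A stride runs from one swing onset to the next swing onset of the *same*
  paw; stride length is the distance between the consecutive touchdown
  positions.  This makes ``stride = swing + stance`` exact by construction.
* Units: positions and lengths in mm, times and durations in s, stride
  velocity in cm/s, cadence in strides/s, swing speed in mm/s.  Human trial
  averages use m and m/s as recorded by instrumented walkways.
* Cadence is per-stride (1 / stride duration).  For human reporting multiply
  by :data:`STEPS_PER_MIN_PER_STRIDES_PER_S` to get steps/min (two steps per
  stride, 60 s per min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MOUSE_PAWS = ("LH", "RH", "LF", "RF")
HUMAN_SIDES = ("L", "R")
CUE_CATEGORIES = ("uncued", "olfactory", "touch")

#: strides/s -> steps/min conversion for bipeds (2 steps per stride).
STEPS_PER_MIN_PER_STRIDES_PER_S = 120.0

#: Columns of the footfall-event CSV schema (one row per paw-lift event).
FOOTFALL_COLUMNS = (
    "subject_id",
    "trial_id",
    "paw",
    "swing_onset_s",
    "swing_offset_s",
    "touchdown_mm",
    "lateral_mm",  # optional (may be empty) -- used for base width only
    "cue",
)

#: Columns of the stride CSV schema (one row per stride).
STRIDE_COLUMNS = (
    "subject_id",
    "trial_id",
    "paw",
    "cue",
    "stride_velocity_cm_s",
    "stride_length_mm",
    "stride_s",
    "swing_s",
    "stance_s",
    "cadence_per_s",
    "swing_speed_mm_s",
    "base_width_mm",
)

#: Gait parameters eligible for velocity-dependence modelling.
GAIT_PARAMETERS = (
    "stride_length_mm",
    "stride_s",
    "swing_s",
    "stance_s",
    "cadence_per_s",
    "swing_speed_mm_s",
    "base_width_mm",
)

_CONTRALATERAL = {"LH": "RH", "RH": "LH", "LF": "RF", "RF": "LF", "L": "R", "R": "L"}


@dataclass(frozen=True)
class FootfallEvent:
    """One paw-lift / paw-land event.

    ``swing_onset_s`` marks the paw leaving the ground, ``swing_offset_s``
    the subsequent touchdown at ``touchdown_mm`` along the runway axis.
    """

    subject_id: str
    trial_id: str
    paw: str
    swing_onset_s: float
    swing_offset_s: float
    touchdown_mm: float
    lateral_mm: float | None = None
    cue: str = "uncued"

    def __post_init__(self) -> None:
        if not self.swing_offset_s > self.swing_onset_s:
            raise ValueError(
                f"swing_offset_s must exceed swing_onset_s for event "
                f"{self.subject_id}/{self.trial_id}/{self.paw} at "
                f"t={self.swing_onset_s}"
            )
        if self.cue not in CUE_CATEGORIES:
            raise ValueError(f"unknown cue category {self.cue!r}")


@dataclass
class StrideTable:
    """Ordered collection of stride records plus acquisition metadata.

    ``data`` is a :class:`pandas.DataFrame` following :data:`STRIDE_COLUMNS`
    (``base_width_mm`` optional).  ``metadata`` carries cohort/condition
    labels and, for footfall-derived tables, ``frame_rate`` (frames/s) and
    ``mm_per_pixel``.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in STRIDE_COLUMNS[:-1] if c not in self.data.columns]
        if missing:
            raise ValueError(f"stride table missing required columns: {missing}")
        fr = self.metadata.get("frame_rate")
        if fr is not None and not fr > 0:
            raise ValueError("frame_rate must be > 0")
        mpp = self.metadata.get("mm_per_pixel")
        if mpp is not None and not mpp > 0:
            raise ValueError("mm_per_pixel must be > 0")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "StrideTable":
        return StrideTable(self.data.copy(), dict(self.metadata))

    def identity_violations(self, rtol: float = 1e-9) -> pd.DataFrame:
        """Rows violating the stride identities beyond relative tolerance.

        Checks stride = swing + stance, velocity = length/duration,
        cadence = 1/duration, swing speed = length/swing, and positivity.
        """
        d = self.data
        checks = {
            "duration_sum": d["stride_s"] - (d["swing_s"] + d["stance_s"]),
            "velocity": d["stride_velocity_cm_s"]
            - d["stride_length_mm"] / 10.0 / d["stride_s"],
            "cadence": d["cadence_per_s"] - 1.0 / d["stride_s"],
            "swing_speed": d["swing_speed_mm_s"]
            - d["stride_length_mm"] / d["swing_s"],
        }
        scales = {
            "duration_sum": d["stride_s"].abs(),
            "velocity": d["stride_velocity_cm_s"].abs(),
            "cadence": d["cadence_per_s"].abs(),
            "swing_speed": d["swing_speed_mm_s"].abs(),
        }
        bad = pd.Series(False, index=d.index)
        for name, resid in checks.items():
            bad |= resid.abs() > rtol * np.maximum(scales[name], 1e-30)
        for col in ("stride_s", "swing_s", "stance_s", "stride_length_mm"):
            bad |= ~(d[col] > 0)
        return d[bad]


def _events_frame(events: Iterable[FootfallEvent] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        df = events.copy()
        missing = [
            c for c in FOOTFALL_COLUMNS if c not in df.columns and c != "lateral_mm"
        ]
        if missing:
            raise ValueError(f"footfall table missing required columns: {missing}")
        if "lateral_mm" not in df.columns:
            df["lateral_mm"] = np.nan
        return df
    rows = [
        (
            e.subject_id,
            e.trial_id,
            e.paw,
            e.swing_onset_s,
            e.swing_offset_s,
            e.touchdown_mm,
            np.nan if e.lateral_mm is None else e.lateral_mm,
            e.cue,
        )
        for e in events
    ]
    return pd.DataFrame(rows, columns=FOOTFALL_COLUMNS)


def strides_from_footfalls(
    events: Iterable[FootfallEvent] | pd.DataFrame,
    frame_rate: float | None = None,
    drop_boundary_strides: bool = True,
    times_in_frames: bool = False,
) -> StrideTable:
    """Derive per-stride parameters from footfall events.

    Consecutive events of one paw within one trial delimit a stride:
    swing duration from the leading event, stride duration to the next swing
    onset, stance as the remainder, stride length between the touchdowns.
    With ``drop_boundary_strides`` the first and last stride of each
    trial/paw sequence are removed (starting and stopping steps).

    Raises ``ValueError`` when events of one paw are unordered or overlap,
    identifying the offending event.  A single event per paw yields zero
    strides, not an error.
    """
    df = _events_frame(events)
    if times_in_frames:
        if not frame_rate or frame_rate <= 0:
            raise ValueError("times_in_frames requires a positive frame_rate")
        df["swing_onset_s"] = df["swing_onset_s"] / frame_rate
        df["swing_offset_s"] = df["swing_offset_s"] / frame_rate

    out: list[dict] = []
    for (subj, trial, paw), grp in df.groupby(
        ["subject_id", "trial_id", "paw"], sort=False
    ):
        g = grp.reset_index(drop=True)
        onset = g["swing_onset_s"].to_numpy(float)
        offset = g["swing_offset_s"].to_numpy(float)
        if np.any(offset <= onset):
            i = int(np.argmax(offset <= onset))
            raise ValueError(
                f"swing offset <= onset for {subj}/{trial}/{paw} at "
                f"t={onset[i]:g}"
            )
        if len(g) >= 2:
            if np.any(np.diff(onset) <= 0):
                i = int(np.argmax(np.diff(onset) <= 0)) + 1
                raise ValueError(
                    f"events out of order for {subj}/{trial}/{paw} at "
                    f"t={onset[i]:g}"
                )
            if np.any(onset[1:] < offset[:-1]):
                i = int(np.argmax(onset[1:] < offset[:-1])) + 1
                raise ValueError(
                    f"overlapping swing phases for {subj}/{trial}/{paw} at "
                    f"t={onset[i]:g}"
                )
        pos = g["touchdown_mm"].to_numpy(float)
        cue = g["cue"].to_numpy()
        lat = g["lateral_mm"].to_numpy(float)

        strides = []
        for i in range(len(g) - 1):
            swing = offset[i] - onset[i]
            stride = onset[i + 1] - onset[i]
            stance = onset[i + 1] - offset[i]
            length = abs(pos[i + 1] - pos[i])
            base = _base_width(df, subj, trial, paw, offset[i], lat[i])
            strides.append(
                {
                    "subject_id": subj,
                    "trial_id": trial,
                    "paw": paw,
                    "cue": cue[i],
                    "stride_velocity_cm_s": length / 10.0 / stride,
                    "stride_length_mm": length,
                    "stride_s": stride,
                    "swing_s": swing,
                    "stance_s": stance,
                    "cadence_per_s": 1.0 / stride,
                    "swing_speed_mm_s": length / swing,
                    "base_width_mm": base,
                }
            )
        if drop_boundary_strides and strides:
            strides = strides[1:-1]
        out.extend(strides)

    data = pd.DataFrame(out, columns=list(STRIDE_COLUMNS))
    meta = {"source": "footfalls"}
    if frame_rate:
        meta["frame_rate"] = frame_rate
    return StrideTable(data, meta)


def _base_width(
    df: pd.DataFrame,
    subj: str,
    trial: str,
    paw: str,
    touchdown_time: float,
    lateral: float,
) -> float:
    """Absolute lateral distance to the nearest-in-time contralateral touchdown."""
    if np.isnan(lateral):
        return np.nan
    other = _CONTRALATERAL.get(paw)
    if other is None:
        return np.nan
    cand = df[
        (df["subject_id"] == subj)
        & (df["trial_id"] == trial)
        & (df["paw"] == other)
        & df["lateral_mm"].notna()
    ]
    if cand.empty:
        return np.nan
    i = (cand["swing_offset_s"] - touchdown_time).abs().idxmin()
    return abs(lateral - float(cand.loc[i, "lateral_mm"]))


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_trials`."""

    n_input: int
    n_touch_removed: int
    n_trials_removed_few_strides: int
    n_removed_few_strides: int
    n_trials_capped: int
    n_removed_capped: int
    cue_percentages: dict
    n_output: int
    empty: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_trials(
    table: StrideTable,
    min_strides: int = 3,
    exclude_touch_cued: bool = True,
    trials_per_condition: int | None = 4,
) -> tuple[StrideTable, FilterReport]:
    """Apply trial-level inclusion rules.

    Touch-cued strides are removed (erratic measures), trials with fewer
    than ``min_strides`` strides are dropped, and at most
    ``trials_per_condition`` trials per subject are retained (first by
    trial_id order; pass ``None`` to disable the cap).  The report gives the
    cue composition of the input and the counts removed by each rule.
    Idempotent: filtering an already-filtered table is a no-op.
    """
    d = table.data
    n_input = len(d)
    cue_counts = d["cue"].value_counts()
    cue_pct = {
        c: 100.0 * cue_counts.get(c, 0) / n_input if n_input else 0.0
        for c in CUE_CATEGORIES
    }

    if exclude_touch_cued:
        kept = d[d["cue"] != "touch"]
    else:
        kept = d
    n_touch_removed = n_input - len(kept)

    sizes = kept.groupby(["subject_id", "trial_id"], sort=False).size()
    small = sizes[sizes < min_strides]
    if len(small):
        idx = kept.set_index(["subject_id", "trial_id"]).index
        mask = ~idx.isin(small.index)
        after_small = kept[np.asarray(mask)]
    else:
        after_small = kept
    n_removed_few = len(kept) - len(after_small)

    n_trials_capped = 0
    n_removed_capped = 0
    if trials_per_condition is not None and len(after_small):
        keep_rows = []
        for subj, grp in after_small.groupby("subject_id", sort=False):
            trials = sorted(grp["trial_id"].unique(), key=str)
            keep = set(trials[:trials_per_condition])
            n_trials_capped += max(0, len(trials) - trials_per_condition)
            keep_rows.append(grp[grp["trial_id"].isin(keep)])
        result = pd.concat(keep_rows) if keep_rows else after_small.iloc[:0]
        n_removed_capped = len(after_small) - len(result)
    else:
        result = after_small

    report = FilterReport(
        n_input=n_input,
        n_touch_removed=n_touch_removed,
        n_trials_removed_few_strides=len(small),
        n_removed_few_strides=n_removed_few,
        n_trials_capped=n_trials_capped,
        n_removed_capped=n_removed_capped,
        cue_percentages=cue_pct,
        n_output=len(result),
        empty=len(result) == 0,
    )
    return StrideTable(result.reset_index(drop=True), dict(table.metadata)), report


def select_paws(table: StrideTable, paws: Sequence[str] = ("LH", "RH")) -> StrideTable:
    """Restrict a table to the given paws (e.g. pooled hindlimbs).

    Left/right pooling is explicit: hindlimb analyses pass both sides,
    single-side human analyses pass one.
    """
    d = table.data[table.data["paw"].isin(list(paws))].reset_index(drop=True)
    meta = dict(table.metadata)
    meta["paws"] = tuple(paws)
    return StrideTable(d, meta)


def human_trial_params(
    gait_speed_m_s: float, stride_s: float, swing_s: float
) -> dict:
    """Derive trial-average parameters from a human walkway record.

    Stride length is gait speed times stride duration; stance is the
    remainder of the stride after swing; ``log_stance_s`` is the natural log
    of stance duration (used when modelling stance on the log scale).
    """
    if not (gait_speed_m_s > 0 and stride_s > 0 and swing_s > 0):
        raise ValueError("gait speed and durations must be strictly positive")
    if swing_s >= stride_s:
        raise ValueError("swing duration must be shorter than stride duration")
    stride_length = gait_speed_m_s * stride_s
    stance = stride_s - swing_s
    return {
        "stride_length_m": stride_length,
        "stance_s": stance,
        "cadence_per_s": 1.0 / stride_s,
        "cadence_steps_min": STEPS_PER_MIN_PER_STRIDES_PER_S / stride_s,
        "swing_speed_m_s": stride_length / swing_s,
        "log_stance_s": math.log(stance),
    }
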