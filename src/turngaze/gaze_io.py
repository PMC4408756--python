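"""Eye-tracker sample I/O, validity rules, and area-of-interest resolution.

Sample streams are stored per trial (participant x conversation) as numpy
arrays; ``GazeSample`` is the per-sample view. A look counts as valid when
the tracker marked at least one eye valid. AOI resolution maps each sample
to LEFT / RIGHT (the two puppet regions), OTHER (on screen, neither region)
or OFFSCREEN (invalid, missing, or outside the screen).

Everything downstream consumes milliseconds, never sample counts, so 50 Hz
and 120 Hz recordings flow through the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .design import Side


class Group(str, Enum):
    TODDLER = "toddler"
    ADULT = "adult"


class AOI(IntEnum):
    LEFT = 0
    RIGHT = 1
    OTHER = 2
    OFFSCREEN = 3


AOI_OF_SIDE = {Side.LEFT: AOI.LEFT, Side.RIGHT: AOI.RIGHT}


class GazeSample(NamedTuple):
    time_ms: float
    validity_left: int
    validity_right: int
    x: float  # normalized [0, 1]; NaN when absent
    y: float


@dataclass(frozen=True)
class Rect:
    """Closed rectangle in normalized screen coordinates."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2


@dataclass(frozen=True)
class AOILayout:
    left_region: Rect = Rect(0.02, 0.10, 0.47, 0.90)
    right_region: Rect = Rect(0.53, 0.10, 0.98, 0.90)
    screen: Rect = Rect(0.0, 0.0, 1.0, 1.0)

    def __post_init__(self):
        if (self.left_region.x1 >= self.right_region.x0
                and self.left_region.y1 >= self.right_region.y0
                and self.right_region.x1 >= self.left_region.x0
                and self.right_region.y1 >= self.left_region.y0):
            raise ValueError("AOI regions must be disjoint")
        for name, r in (("left", self.left_region), ("right", self.right_region)):
            if not (self.screen.x0 <= r.x0 <= r.x1 <= self.screen.x1
                    and self.screen.y0 <= r.y0 <= r.y1 <= self.screen.y1):
                raise ValueError(f"{name} region outside screen bounds")


DEFAULT_LAYOUT = AOILayout()


@dataclass(frozen=True)
class Dialect:
    """Column mapping and validity convention of a gaze table export.

    ``valid_codes`` follows common binocular exports where code 0 (and 1)
    mean a found eye. The ``aoi`` dialect carries pre-resolved AOI labels
    instead of coordinates.
    """

    name: str
    columns: dict
    valid_codes: frozenset = frozenset({0, 1})
    has_aoi_labels: bool = False


STANDARD_DIALECT = Dialect(
    name="standard",
    columns={c: c for c in ("participant_id", "group", "conversation_id",
                            "trial_index", "time_ms", "validity_left",
                            "validity_right", "x", "y")},
)

AOI_DIALECT = Dialect(
    name="aoi",
    columns={c: c for c in ("participant_id", "group", "conversation_id",
                            "trial_index", "time_ms", "aoi")},
    has_aoi_labels=True,
)

DIALECTS = {d.name: d for d in (STANDARD_DIALECT, AOI_DIALECT)}


@dataclass
class TrialRecording:
    """One participant watching one conversation."""

    participant_id: str
    group: Group
    conversation_id: str
    presentation_index: int  # 1-8, position in that participant's session
    time_ms: np.ndarray
    validity_left: np.ndarray
    validity_right: np.ndarray
    x: np.ndarray
    y: np.ndarray
    aoi_labels: np.ndarray | None = None  # pre-resolved AOIs (aoi dialect)

    @property
    def n_samples(self) -> int:
        return len(self.time_ms)

    @property
    def nominal_rate_hz(self) -> float:
        """Sampling rate inferred from the median inter-sample interval,
        snapped to 50 or 120 Hz when within 5%."""
        if self.n_samples < 2:
            return float("nan")
        dt = float(np.median(np.diff(self.time_ms)))
        rate = 1000.0 / dt
        for nominal in (50.0, 120.0):
            if abs(rate - nominal) / nominal < 0.05:
                return nominal
        return rate

    @property
    def samples(self) -> Iterator[GazeSample]:
        for i in range(self.n_samples):
            yield GazeSample(float(self.time_ms[i]),
                             int(self.validity_left[i]),
                             int(self.validity_right[i]),
                             float(self.x[i]), float(self.y[i]))


class GazeParseError(ValueError):
    pass


def is_valid(sample: GazeSample, valid_codes=STANDARD_DIALECT.valid_codes) -> bool:
    """A look is valid when at least one eye carries a valid code."""
    return (sample.validity_left in valid_codes
            or sample.validity_right in valid_codes)


def resolve_aoi(sample: GazeSample, layout: AOILayout = DEFAULT_LAYOUT,
                valid_codes=STANDARD_DIALECT.valid_codes) -> AOI:
    """Classify one sample; total over the four labels."""
    if not is_valid(sample, valid_codes):
        return AOI.OFFSCREEN
    if np.isnan(sample.x) or np.isnan(sample.y):
        return AOI.OFFSCREEN
    if not layout.screen.contains(sample.x, sample.y):
        return AOI.OFFSCREEN
    if layout.left_region.contains(sample.x, sample.y):
        return AOI.LEFT
    if layout.right_region.contains(sample.x, sample.y):
        return AOI.RIGHT
    return AOI.OTHER


def resolve_aoi_stream(trial: TrialRecording,
                       layout: AOILayout = DEFAULT_LAYOUT,
                       valid_codes=STANDARD_DIALECT.valid_codes) -> np.ndarray:
    """Vectorized AOI labels for a whole trial (int8 array of AOI codes)."""
    if trial.aoi_labels is not None:
        return trial.aoi_labels
    valid = (np.isin(trial.validity_left, list(valid_codes))
             | np.isin(trial.validity_right, list(valid_codes)))
    x, y = trial.x, trial.y
    present = valid & ~np.isnan(x) & ~np.isnan(y)
    on_screen = present & layout.screen.contains(np.nan_to_num(x, nan=-1),
                                                 np.nan_to_num(y, nan=-1))
    out = np.full(trial.n_samples, AOI.OFFSCREEN, dtype=np.int8)
    left = on_screen & layout.left_region.contains(x, y)
    right = on_screen & layout.right_region.contains(x, y)
    out[on_screen] = AOI.OTHER
    out[left] = AOI.LEFT
    out[right] = AOI.RIGHT
    return out


_REQUIRED_ANY = ("participant_id", "group", "conversation_id", "trial_index",
                 "time_ms")


def read_gaze_table(path, dialect: str | Dialect = "standard"
                    ) -> list[TrialRecording]:
    """Read a delimited gaze export into one TrialRecording per
    participant x conversation, time-sorted and validated."""
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise GazeParseError(f"unknown dialect {dialect!r}; "
                                 f"available: {sorted(DIALECTS)}")
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in dialect.columns.values() if c not in df.columns]
    if missing:
        raise GazeParseError(f"{path}: missing required column(s) {missing}")
    inv = {v: k for k, v in dialect.columns.items()}
    df = df.rename(columns=inv)

    recordings = []
    for (pid, conv), g in df.groupby(["participant_id", "conversation_id"],
                                     sort=False):
        g = g.sort_values("time_ms", kind="stable")
        t = g["time_ms"].to_numpy(dtype=float)
        dup = np.nonzero(np.diff(t) <= 0)[0]
        if dup.size:
            row = g.index[dup[0] + 1]
            raise GazeParseError(
                f"{path}: non-increasing timestamp at row {row} "
                f"(participant {pid}, conversation {conv})")
        group = Group(str(g["group"].iloc[0]).lower())
        n = len(g)
        if dialect.has_aoi_labels:
            labels = np.array([AOI[str(a).upper()] for a in g["aoi"]],
                              dtype=np.int8)
            rec = TrialRecording(
                str(pid), group, str(conv), int(g["trial_index"].iloc[0]),
                t, np.zeros(n, dtype=int), np.zeros(n, dtype=int),
                np.full(n, np.nan), np.full(n, np.nan), aoi_labels=labels)
        else:
            rec = TrialRecording(
                str(pid), group, str(conv), int(g["trial_index"].iloc[0]),
                t,
                g["validity_left"].to_numpy(dtype=int),
                g["validity_right"].to_numpy(dtype=int),
                g["x"].to_numpy(dtype=float),
                g["y"].to_numpy(dtype=float))
        recordings.append(rec)
    return recordings


def write_gaze_table(recordings: list[TrialRecording], path) -> None:
    """Write trials back out in the standard dialect (CSV)."""
    frames = []
    for r in recordings:
        frames.append(pd.DataFrame({
            "participant_id": r.participant_id,
            "group": r.group.value,
            "conversation_id": r.conversation_id,
            "trial_index": r.presentation_index,
            "time_ms": r.time_ms,
            "validity_left": r.validity_left,
            "validity_right": r.validity_right,
            "x": r.x,
            "y": r.y,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6g")
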