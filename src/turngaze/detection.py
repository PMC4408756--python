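"""Fixation segmentation and anticipatory gaze-switch detection.

An anticipatory switch at a target turn transition satisfies three criteria:

1. the participant fixates the prior speaker for at least 100 ms at the end
   of the prior turn (a fixation overlapping the pre-silence part of the
   analysis window);
2. sometime thereafter the participant fixates the upcoming speaker for at
   least 100 ms;
3. that gaze shift is initiated no later than 300 ms (toddlers) or 200 ms
   (adults) after the onset of the response turn, where the response turn
   starts at the end of the 500 ms target silence.

The analysis window is centered on the target silence:
``[silence_onset - lead, silence_offset + lead]`` with the group-specific
lead, clipped to the conversation; the criterion-3 deadline is
``response_onset + lead``. "Initiated" is operationalized as the onset of
the responder-AOI fixation, since AOI streams carry no saccade velocities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import SILENCE_MS, TargetEvent
from .gaze_io import AOI, AOI_OF_SIDE, Group

MIN_FIXATION_MS = 100
GAP_TOLERANCE_MS = 75  # ~1 sample at 50 Hz; tracker recovery < 100 ms
GROUP_LEAD_MS = {Group.TODDLER: 300, Group.ADULT: 200}


@dataclass(frozen=True)
class Fixation:
    """A maximal constant-AOI dwell segment (half-open interval)."""

    aoi: AOI
    onset_ms: float
    offset_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class AnalysisWindow:
    start_ms: float
    end_ms: float
    prior_side: AOI
    responder_side: AOI
    silence_onset_ms: float
    response_onset_ms: float
    deadline_ms: float
    group_lead_ms: float


def segment_fixations(time_ms: np.ndarray, aoi: np.ndarray,
                      gap_tolerance_ms: float = GAP_TOLERANCE_MS
                      ) -> list[Fixation]:
    """Collapse a sampled AOI stream into maximal constant-AOI dwells.

    Same-AOI runs separated by an intervening run no longer than
    ``gap_tolerance_ms`` are merged (the gap is absorbed into the dwell);
    tracker blips shorter than one or two samples thus do not break a
    fixation. Output covers the whole trial, with consecutive dwells on
    distinct AOIs; minimum-duration filtering happens in the detector.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    aoi = np.asarray(aoi)
    if len(time_ms) == 0:
        return []
    # run-length encode; sample i covers [t_i, t_{i+1}), last gets median dt
    if len(time_ms) > 1:
        end = time_ms[-1] + float(np.median(np.diff(time_ms)))
    else:
        end = time_ms[-1] + 1.0
    bounds = np.append(time_ms, end)
    change = np.nonzero(aoi[1:] != aoi[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    runs = [[aoi[s], bounds[s], bounds[e]]
            for s, e in zip(starts, np.append(change, len(aoi)))]

    # absorb short intervening runs between same-AOI neighbours, then coalesce
    changed = True
    while changed:
        changed = False
        out = []
        i = 0
        while i < len(runs):
            if (i + 2 < len(runs)
                    and runs[i][0] == runs[i + 2][0]
                    and runs[i + 1][2] - runs[i + 1][1] <= gap_tolerance_ms):
                runs[i + 2] = [runs[i][0], runs[i][1], runs[i + 2][2]]
                i += 2
                changed = True
                continue
            out.append(runs[i])
            i += 1
        runs = out
        # coalesce adjacent same-AOI runs that merging may have created
        merged = [runs[0]]
        for r in runs[1:]:
            if r[0] == merged[-1][0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged
    return [Fixation(AOI(int(a)), float(s), float(e)) for a, s, e in runs]


def build_analysis_window(target: TargetEvent, group: Group,
                          conversation_duration_ms: float,
                          lead_ms: float | None = None) -> AnalysisWindow:
    """Window centered on the target silence, clipped to the conversation."""
    lead = GROUP_LEAD_MS[group] if lead_ms is None else lead_ms
    return AnalysisWindow(
        start_ms=max(0.0, target.silence_onset_ms - lead),
        end_ms=min(float(conversation_duration_ms),
                   target.silence_offset_ms + lead),
        prior_side=AOI_OF_SIDE[target.prior_speaker],
        responder_side=AOI_OF_SIDE[target.responder],
        silence_onset_ms=float(target.silence_onset_ms),
        response_onset_ms=float(target.silence_offset_ms),
        deadline_ms=float(target.silence_offset_ms) + lead,
        group_lead_ms=float(lead),
    )


def detect_anticipatory_switch(fixations: list[Fixation],
                               window: AnalysisWindow,
                               min_fix_ms: float = MIN_FIXATION_MS,
                               strict_prior_end: bool = False) -> int:
    """Apply the three-criterion checklist; returns 0/1.

    With ``strict_prior_end`` the prior-speaker fixation must cover the final
    ``min_fix_ms`` of the prior turn instead of merely overlapping the
    pre-silence part of the window.
    """
    aoi = np.array([f.aoi for f in fixations], dtype=np.int8)
    onset = np.array([f.onset_ms for f in fixations])
    offset = np.array([f.offset_ms for f in fixations])
    return int(_detect_arrays(
        aoi, onset, offset,
        np.array([window.start_ms]), np.array([window.silence_onset_ms]),
        np.array([window.deadline_ms]),
        np.array([window.prior_side], dtype=np.int8),
        np.array([window.responder_side], dtype=np.int8),
        min_fix_ms, strict_prior_end)[0])


def _detect_arrays(aoi, onset, offset, w_start, w_silence, w_deadline,
                   w_prior, w_resp, min_fix_ms=MIN_FIXATION_MS,
                   strict_prior_end=False) -> np.ndarray:
    """Vectorized detector: one 0/1 per window, shared fixation stream.

    Criterion 1 reduces to the prior-side fixation with the *earliest*
    offset among eligible ones: any responder fixation that pairs with some
    eligible F1 also pairs with that one, so existence of a pair is
    equivalent to existence of a responder fixation starting in
    ``[min eligible F1 offset, deadline]``.
    """
    if len(aoi) == 0:
        return np.zeros(len(w_start), dtype=np.int8)
    dur_ok = (offset - onset) >= min_fix_ms
    f1 = ((aoi[None, :] == w_prior[:, None]) & dur_ok[None, :]
          & (onset[None, :] < w_silence[:, None])
          & (offset[None, :] > w_start[:, None]))
    if strict_prior_end:
        f1 &= ((onset[None, :] <= w_silence[:, None] - min_fix_ms)
               & (offset[None, :] >= w_silence[:, None]))
    min_off = np.where(f1, offset[None, :], np.inf).min(axis=1)
    f2 = ((aoi[None, :] == w_resp[:, None]) & dur_ok[None, :]
          & (onset[None, :] >= min_off[:, None])
          & (onset[None, :] <= w_deadline[:, None]))
    return (f1.any(axis=1) & f2.any(axis=1)).astype(np.int8)


def windows_to_arrays(windows: list[AnalysisWindow]):
    """Pack windows for the vectorized detector."""
    return (np.array([w.start_ms for w in windows]),
            np.array([w.silence_onset_ms for w in windows]),
            np.array([w.deadline_ms for w in windows]),
            np.array([w.prior_side for w in windows], dtype=np.int8),
            np.array([w.responder_side for w in windows], dtype=np.int8))


def detect_many(fixations: list[Fixation], windows: list[AnalysisWindow],
                min_fix_ms: float = MIN_FIXATION_MS,
                strict_prior_end: bool = False) -> np.ndarray:
    """Detector over many windows of one trial at once."""
    aoi = np.array([f.aoi for f in fixations], dtype=np.int8)
    onset = np.array([f.onset_ms for f in fixations])
    offset = np.array([f.offset_ms for f in fixations])
    return _detect_arrays(aoi, onset, offset, *windows_to_arrays(windows),
                          min_fix_ms, strict_prior_end)
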