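"""Trial- and participant-level attention exclusions.

A trial is excluded when the participant attended to the screen for less
than 75% of the trial duration (strict inequality: exactly 75% is kept);
a participant is excluded entirely when more than four of their trials were
excluded. Attention is measured on the time axis: each sample carries its
inter-sample interval as dwell (the last sample gets the median interval),
and only tracker-valid, on-screen samples count as attended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import AOI, AOILayout, DEFAULT_LAYOUT, TrialRecording, \
    resolve_aoi_stream

ATTENTION_THRESHOLD = 0.75
MAX_EXCLUDED_TRIALS = 4


def sample_dwell_ms(time_ms: np.ndarray) -> np.ndarray:
    """Per-sample nominal dwell: interval to the next sample; the last
    sample gets the median interval."""
    if len(time_ms) == 0:
        raise ValueError("empty trial: no samples")
    if len(time_ms) == 1:
        return np.array([1.0])
    dt = np.diff(time_ms)
    return np.append(dt, np.median(dt))


def attention_fraction(trial: TrialRecording,
                       layout: AOILayout = DEFAULT_LAYOUT) -> float:
    """Fraction of trial duration spent on screen (AOI in {LEFT, RIGHT,
    OTHER})."""
    if trial.n_samples == 0:
        raise ValueError(
            f"empty trial for participant {trial.participant_id}, "
            f"conversation {trial.conversation_id}")
    aoi = resolve_aoi_stream(trial, layout)
    dwell = sample_dwell_ms(trial.time_ms)
    return float(dwell[aoi != AOI.OFFSCREEN].sum() / dwell.sum())


def apply_trial_exclusion(recordings: list[TrialRecording],
                          layout: AOILayout = DEFAULT_LAYOUT,
                          threshold: float = ATTENTION_THRESHOLD,
                          ) -> tuple[list[TrialRecording],
                                     list[TrialRecording], pd.DataFrame]:
    """Partition trials into (kept, excluded) by the attention rule and
    return the per-trial audit table."""
    kept, excluded, rows = [], [], []
    for r in recordings:
        frac = attention_fraction(r, layout)
        drop = frac < threshold
        (excluded if drop else kept).append(r)
        rows.append({"participant_id": r.participant_id,
                     "group": r.group.value,
                     "conversation_id": r.conversation_id,
                     "trial_index": r.presentation_index,
                     "on_screen_fraction": frac,
                     "excluded": drop})
    audit = pd.DataFrame(rows)
    return kept, excluded, audit


def apply_participant_exclusion(kept: list[TrialRecording],
                                audit: pd.DataFrame,
                                max_excluded: int = MAX_EXCLUDED_TRIALS,
                                ) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Drop all data of participants with more than ``max_excluded``
    excluded trials; returns retained trials and the participant audit."""
    per = (audit.groupby(["participant_id", "group"], sort=False)["excluded"]
           .sum().reset_index()
           .rename(columns={"excluded": "n_excluded_trials"}))
    per["participant_excluded"] = per["n_excluded_trials"] > max_excluded
    dropped = set(per.loc[per["participant_excluded"], "participant_id"])
    retained = [r for r in kept if r.participant_id not in dropped]
    return retained, per


def preprocess(recordings, layout=DEFAULT_LAYOUT,
               threshold=ATTENTION_THRESHOLD,
               max_excluded=MAX_EXCLUDED_TRIALS,
               drop_participants: set | None = None):
    """Full exclusion pass. ``drop_participants`` is the input-level list for
    equipment failures (not computed from the data). Returns
    (retained trials, trial audit, participant audit)."""
    if drop_participants:
        recordings = [r for r in recordings
                      if r.participant_id not in drop_participants]
    kept, _excluded, audit = apply_trial_exclusion(recordings, layout,
                                                   threshold)
    retained, per = apply_participant_exclusion(kept, audit, max_excluded)
    return retained, audit, per
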