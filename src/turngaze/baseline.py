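"""Shuffled-window chance baseline and corrected switch values.

Random between-speaker gaze can satisfy the three-criterion checklist by
chance. The chance rate is estimated empirically: the four analysis windows
of a conversation are repositioned uniformly at random over the conversation
100 times, the detector is re-run on every repositioned window, and the
per-target mean detection rate over the 100 replicates is that target's
baseline. The corrected switch value is the observed 0/1 indicator minus
this baseline, in [-1, 1].

Shuffled windows keep their original duration and speaker roles and use the
same group-lead geometry (pre-silence lead, 500 ms "silence", post-silence
deadline) as the originals; they may overlap each other and real silences.
By default one set of 100 placements is drawn per conversation x group and
reused for every participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import SILENCE_MS, ConversationDesign
from .detection import (AnalysisWindow, Fixation, GROUP_LEAD_MS,
                        MIN_FIXATION_MS, _detect_arrays,
                        build_analysis_window, windows_to_arrays)
from .gaze_io import AOI_OF_SIDE, Group

N_SHUFFLES = 100


@dataclass
class ShuffledWindowSet:
    """One shuffled replicate: repositioned windows, same durations/roles."""

    replicate_index: int  # 1-based
    windows: list[AnalysisWindow]


def shuffle_windows(design: ConversationDesign, group: Group,
                    n_reps: int = N_SHUFFLES,
                    rng: np.random.Generator | None = None,
                    lead_ms: float | None = None) -> list[ShuffledWindowSet]:
    """Draw ``n_reps`` random placements of the conversation's analysis
    windows, each start uniform over [0, duration - window_length]."""
    if rng is None:
        rng = np.random.default_rng()
    lead = GROUP_LEAD_MS[group] if lead_ms is None else lead_ms
    length = SILENCE_MS + 2 * lead
    duration = design.duration_ms
    if length > duration:
        raise ValueError(
            f"window length {length} ms exceeds conversation duration "
            f"{duration} ms")
    sets = []
    for rep in range(1, n_reps + 1):
        windows = []
        for t in design.targets:
            start = float(rng.integers(0, duration - length + 1))
            windows.append(AnalysisWindow(
                start_ms=start,
                end_ms=start + length,
                prior_side=AOI_OF_SIDE[t.prior_speaker],
                responder_side=AOI_OF_SIDE[t.responder],
                silence_onset_ms=start + lead,
                response_onset_ms=start + lead + SILENCE_MS,
                deadline_ms=start + length,
                group_lead_ms=float(lead),
            ))
        sets.append(ShuffledWindowSet(rep, windows))
    return sets


def baseline_rate(fixations: list[Fixation],
                  shuffled_sets: list[ShuffledWindowSet],
                  min_fix_ms: float = MIN_FIXATION_MS,
                  strict_prior_end: bool = False) -> np.ndarray:
    """Per-original-target mean detection rate over the shuffled replicates
    (values in [0, 1], one per target of the conversation)."""
    if not shuffled_sets:
        raise ValueError("no shuffled window sets supplied")
    all_windows = [w for s in shuffled_sets for w in s.windows]
    aoi = np.array([f.aoi for f in fixations], dtype=np.int8)
    onset = np.array([f.onset_ms for f in fixations])
    offset = np.array([f.offset_ms for f in fixations])
    hits = _detect_arrays(aoi, onset, offset, *windows_to_arrays(all_windows),
                          min_fix_ms, strict_prior_end)
    n_targets = len(shuffled_sets[0].windows)
    return hits.reshape(len(shuffled_sets), n_targets).mean(axis=0)


def corrected_score(actual: int, baseline: float) -> float:
    """Observed indicator minus chance baseline, in [-1, 1]."""
    if actual not in (0, 1):
        raise ValueError(f"actual must be 0 or 1, got {actual}")
    if not (0.0 <= baseline <= 1.0):
        raise ValueError(f"baseline must lie in [0, 1], got {baseline}")
    return float(actual) - float(baseline)
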