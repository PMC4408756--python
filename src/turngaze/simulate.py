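"""Synthetic gaze cohorts with known ground-truth anticipation.

The simulator emulates what the analysis assumes about viewing behavior:

* a speaker-following background process — gaze re-orients at exponentially
  distributed renewal times (and whenever speakership changes), moving to
  the current speaker with probability ``follow_bias`` and otherwise to an
  AOI drawn from a transition matrix (occasional excursions to the other
  puppet, the screen background, or off screen);
* reactive following of a new speaker lags the turn onset by a saccade
  latency that is never faster than the group's anticipation deadline —
  the deadline itself encodes the minimum time needed to plan a shift
  (300 ms for toddlers, 200 ms for adults), so a purely reactive shift can
  never be scored as anticipatory;
* at each target, with the condition's switch propensity, an anticipatory
  glance to the upcoming responder (>= 150 ms) is launched at silence onset
  plus a group-specific planning latency (toddler draws floored at the
  300 ms planning minimum); draws that land past the deadline are kept and
  produce intended-but-late switches that score 0;
* tracker noise: per-sample binocular dropout, single-eye dropout, and
  off-screen attention lapses.

Ground truth per target is whether an anticipatory glance was launched and
its first on-grid sample lies on or before the deadline; with noise
switched off the three-criterion detector reproduces these labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (SILENCE_MS, Condition, ConversationDesign,
                     ExperimentDesign, Outcome, Side)
from .detection import GROUP_LEAD_MS
from .gaze_io import (AOI, AOI_OF_SIDE, DEFAULT_LAYOUT, Group,
                      TrialRecording)

#: Invalid-eye code used in the exported tables (Tobii-style: 0 = found).
INVALID_CODE = 4


@dataclass(frozen=True)
class GroupParams:
    """Group-specific timing and noise parameters (milliseconds)."""

    latency_mean_ms: float      # anticipatory glance latency from silence onset
    latency_sd_ms: float
    latency_floor_ms: float     # minimum planning time for a gaze shift
    reaction_mean_ms: float     # reactive follow of a new speaker
    reaction_sd_ms: float
    dropout: float = 0.05       # P(both eyes lost) per sample
    one_eye_dropout: float = 0.10
    lapse_rate_per_s: float = 0.02
    lapse_mean_ms: float = 800.0
    rate_hz: float = 50.0


#: Study-like per-condition anticipatory switch propensities: most switches
#: after fully complete targets, fewest when both cues signal incompleteness.
DEFAULT_SWITCH_PROB = {
    Condition.FULLY_INCOMPLETE: 0.15,
    Condition.INCOMPLETE_SYNTAX: 0.25,
    Condition.INCOMPLETE_PROSODY: 0.40,
    Condition.FULLY_COMPLETE: 0.55,
}

#: Symmetric background transition matrix over (LEFT, RIGHT, OTHER,
#: OFFSCREEN): mostly puppet-to-puppet with occasional excursions.
DEFAULT_TRANSITION = np.array([
    [0.10, 0.70, 0.15, 0.05],
    [0.70, 0.10, 0.15, 0.05],
    [0.45, 0.45, 0.05, 0.05],
    [0.45, 0.45, 0.10, 0.00],
])


def _default_groups() -> dict:
    return {
        Group.TODDLER: GroupParams(latency_mean_ms=450.0, latency_sd_ms=100.0,
                                   latency_floor_ms=300.0,
                                   reaction_mean_ms=550.0,
                                   reaction_sd_ms=100.0,
                                   dropout=0.08, rate_hz=50.0),
        Group.ADULT: GroupParams(latency_mean_ms=380.0, latency_sd_ms=100.0,
                                 latency_floor_ms=200.0,
                                 reaction_mean_ms=450.0,
                                 reaction_sd_ms=100.0,
                                 dropout=0.03, rate_hz=50.0),
    }


@dataclass
class SimParams:
    """Generative model parameters; defaults emulate the study conditions."""

    switch_prob: dict = field(default_factory=lambda: dict(DEFAULT_SWITCH_PROB))
    follow_bias: float = 0.85
    mean_dwell_ms: float = 1500.0
    transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION.copy())
    glance_mean_ms: float = 600.0
    glance_min_ms: float = 150.0
    groups: dict = field(default_factory=_default_groups)

    def __post_init__(self):
        for c, p in self.switch_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"switch probability for {c} is {p}")
        if self.mean_dwell_ms <= 0:
            raise ValueError("mean dwell must be positive")

    @classmethod
    def null(cls, rate_hz: float = 50.0, dropout: float = 0.0) -> "SimParams":
        """AOI-symmetric random gaze with no anticipation: gaze wanders
        between the puppets independently of who is speaking."""
        groups = {g: replace(p, dropout=dropout, one_eye_dropout=0.0,
                             lapse_rate_per_s=0.0, rate_hz=rate_hz)
                  for g, p in _default_groups().items()}
        return cls(switch_prob={c: 0.0 for c in Condition},
                   follow_bias=0.0,
                   transition=np.array([[0.0, 0.9, 0.1, 0.0],
                                        [0.9, 0.0, 0.1, 0.0],
                                        [0.5, 0.5, 0.0, 0.0],
                                        [0.5, 0.5, 0.0, 0.0]]),
                   groups=groups)

    @classmethod
    def strong_effects(cls) -> "SimParams":
        """Clear-effect regime for parameter-recovery studies: well-ordered
        per-condition propensities (fully complete 0.85 > incomplete prosody
        0.50 > incomplete syntax 0.15 > fully incomplete 0.02), strong
        speaker following, low tracker noise, and planning latencies that
        rarely overrun the deadline. Chosen a priori by a power analysis so
        the implied syntax/prosody effects are detectable at small cohort
        sizes after chance-level and late-glance attenuation."""
        groups = {
            Group.TODDLER: GroupParams(latency_mean_ms=450.0,
                                       latency_sd_ms=80.0,
                                       latency_floor_ms=300.0,
                                       reaction_mean_ms=550.0,
                                       reaction_sd_ms=100.0,
                                       dropout=0.02, one_eye_dropout=0.05,
                                       lapse_rate_per_s=0.005),
            Group.ADULT: GroupParams(latency_mean_ms=380.0,
                                     latency_sd_ms=80.0,
                                     latency_floor_ms=200.0,
                                     reaction_mean_ms=450.0,
                                     reaction_sd_ms=100.0,
                                     dropout=0.01, one_eye_dropout=0.05,
                                     lapse_rate_per_s=0.005),
        }
        return cls(switch_prob={Condition.FULLY_COMPLETE: 0.85,
                                Condition.INCOMPLETE_PROSODY: 0.50,
                                Condition.INCOMPLETE_SYNTAX: 0.15,
                                Condition.FULLY_INCOMPLETE: 0.02},
                   follow_bias=0.90, groups=groups)

    @classmethod
    def noiseless(cls, **kw) -> "SimParams":
        """Deterministic speaker following with no tracker noise; only the
        anticipatory glances are stochastic (closed-loop testing)."""
        groups = {g: replace(p, dropout=0.0, one_eye_dropout=0.0,
                             lapse_rate_per_s=0.0)
                  for g, p in _default_groups().items()}
        return cls(follow_bias=1.0, groups=groups, **kw)


@dataclass
class TargetTruth:
    conversation_id: str
    condition: Condition
    outcome: Outcome
    intended: int          # glance launched?
    glance_onset_ms: float # NaN if not launched (on-grid onset)
    label: int             # intended and initiated by the deadline


@dataclass
class SimulatedTrial:
    recording: TrialRecording
    truth: list[TargetTruth]


@dataclass
class CohortSpec:
    """Cohort layout; participant counts default to a study-sized sample."""

    design: ExperimentDesign
    n_toddlers: int = 21
    n_adults: int = 16
    params: SimParams = field(default_factory=SimParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_toddlers < 0 or self.n_adults < 0:
            raise ValueError("cohort counts must be non-negative")


def _stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of the embedded AOI renewal chain (dwell
    means are equal across states, so the embedded chain's stationary
    vector is also the time-stationary one)."""
    vals, vecs = np.linalg.eig(transition.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _follow_track(conversation: ConversationDesign, gp: GroupParams,
                  lead: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant 'where an attentive viewer would look': the
    current speaker, with reactive lag at each speakership change floored
    just above the anticipation deadline."""
    times = [0.0]
    sides = [AOI_OF_SIDE[conversation.utterances[0].speaker]]
    prev = conversation.utterances[0].speaker
    for u in conversation.utterances[1:]:
        if u.speaker != prev:
            reaction = max(lead + 50.0,
                           rng.normal(gp.reaction_mean_ms, gp.reaction_sd_ms))
            times.append(u.onset_ms + reaction)
            sides.append(AOI_OF_SIDE[u.speaker])
            prev = u.speaker
    return np.array(times), np.array(sides, dtype=np.int8)


def sample_gaze_trial(conversation: ConversationDesign, group: Group,
                      params: SimParams, rng: np.random.Generator,
                      participant_id: str = "sim",
                      presentation_index: int = 1) -> SimulatedTrial:
    """Simulate one trial; returns the recording and per-target truth."""
    gp: GroupParams = params.groups[group]
    lead = GROUP_LEAD_MS[group]
    duration = float(conversation.duration_ms)
    dt = 1000.0 / gp.rate_hz
    times = np.arange(int(np.floor(duration / dt))) * dt

    ft, fs = _follow_track(conversation, gp, lead, rng)

    def follow_at(t):
        return fs[np.searchsorted(ft, t, side="right") - 1]

    # --- background renewal process -------------------------------------
    seg_t = [0.0]
    if params.follow_bias > 0:
        cur = int(follow_at(0.0))
    else:
        # start in the renewal chain's stationary distribution so the pure
        # background process is stationary from t = 0 (no trial-start edge
        # effect in chance-rate estimates)
        cur = int(rng.choice(4, p=_stationary(params.transition)))
    seg_a = [cur]
    follow_changes = list(ft[1:])
    t = 0.0
    next_renewal = rng.exponential(params.mean_dwell_ms)
    while True:
        next_change = follow_changes[0] if follow_changes else np.inf
        e = min(next_renewal, next_change)
        if e >= duration:
            break
        is_renewal = next_renewal <= next_change
        if is_renewal:
            next_renewal = e + rng.exponential(params.mean_dwell_ms)
        else:
            follow_changes.pop(0)
        if rng.random() < params.follow_bias:
            nxt = int(follow_at(e))
        elif is_renewal:
            nxt = int(rng.choice(4, p=params.transition[cur]))
        else:
            nxt = cur  # ignored speaker change
        if nxt != cur:
            seg_t.append(e)
            seg_a.append(nxt)
            cur = nxt
        t = e

    aoi = np.asarray(seg_a, dtype=np.int8)[
        np.searchsorted(seg_t, times, side="right") - 1]

    # --- anticipatory glances at targets --------------------------------
    truth = []
    for target in conversation.targets:
        cond = target.condition
        deadline = target.silence_offset_ms + lead
        intended = int(rng.random() < params.switch_prob[cond])
        onset_grid = np.nan
        label = 0
        if intended:
            latency = max(gp.latency_floor_ms,
                          rng.normal(gp.latency_mean_ms, gp.latency_sd_ms))
            onset = target.silence_onset_ms + latency
            dur = max(params.glance_min_ms,
                      rng.exponential(params.glance_mean_ms))
            i0 = int(np.searchsorted(times, onset, side="left"))
            i1 = int(np.searchsorted(times, onset + dur, side="left"))
            if i0 < len(times):
                aoi[i0:max(i1, i0 + 1)] = AOI_OF_SIDE[target.responder]
                onset_grid = float(times[i0])
                label = int(onset_grid <= deadline)
        truth.append(TargetTruth(conversation.id, cond, target.outcome,
                                 intended, onset_grid, label))

    # --- attention lapses and tracker dropout ---------------------------
    n_lapses = rng.poisson(gp.lapse_rate_per_s * duration / 1000.0)
    for _ in range(n_lapses):
        t0 = rng.uniform(0, duration)
        t1 = t0 + rng.exponential(gp.lapse_mean_ms)
        aoi[(times >= t0) & (times < t1)] = AOI.OFFSCREEN

    n = len(times)
    lost = rng.random(n) < gp.dropout
    one_eye = rng.random(n) < gp.one_eye_dropout
    offscreen = (aoi == AOI.OFFSCREEN) | lost

    vl = np.zeros(n, dtype=int)
    vr = np.zeros(n, dtype=int)
    vl[offscreen] = INVALID_CODE
    vr[offscreen] = INVALID_CODE
    which = rng.random(n) < 0.5
    vl[one_eye & ~offscreen & which] = INVALID_CODE
    vr[one_eye & ~offscreen & ~which] = INVALID_CODE

    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    centers = {AOI.LEFT: DEFAULT_LAYOUT.left_region.center,
               AOI.RIGHT: DEFAULT_LAYOUT.right_region.center,
               AOI.OTHER: (0.5, 0.5)}
    for code, (cx, cy) in centers.items():
        m = (aoi == code) & ~offscreen
        k = int(m.sum())
        jx = 0.02 if code != AOI.OTHER else 0.008
        x[m] = np.clip(rng.normal(cx, jx, k), 0.0, 1.0)
        y[m] = np.clip(rng.normal(cy, jx, k), 0.0, 1.0)

    rec = TrialRecording(
        participant_id=participant_id, group=group,
        conversation_id=conversation.id,
        presentation_index=presentation_index,
        time_ms=np.round(times, 3),
        validity_left=vl, validity_right=vr, x=x, y=y)
    return SimulatedTrial(rec, truth)


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Simulate every participant x conversation trial.

    Participants alternate between the design's two presentation orders.
    Returns the recordings and the ground-truth table (one row per
    participant x target). Deterministic given ``spec.seed``.
    """
    roster = ([(f"t{i + 1:02d}", Group.TODDLER)
               for i in range(spec.n_toddlers)]
              + [(f"a{i + 1:02d}", Group.ADULT)
                 for i in range(spec.n_adults)])
    seeds = np.random.SeedSequence(spec.seed).spawn(len(roster))
    recordings, rows = [], []
    for (pid, group), ss in zip(roster, seeds):
        rng = np.random.default_rng(ss)
        order = spec.design.presentation_orders[
            int(pid[1:]) % len(spec.design.presentation_orders)]
        for idx, conv_id in enumerate(order, start=1):
            conv = spec.design.conversation(conv_id)
            sim = sample_gaze_trial(conv, group, spec.params, rng,
                                    participant_id=pid,
                                    presentation_index=idx)
            recordings.append(sim.recording)
            for tt in sim.truth:
                rows.append({
                    "participant_id": pid,
                    "group": group.value,
                    "conversation_id": conv_id,
                    "presentation_index": idx,
                    "item": f"{conv_id}:{tt.condition.name}",
                    "condition": tt.condition.name,
                    "outcome": tt.outcome.value,
                    "intended": tt.intended,
                    "glance_onset_ms": tt.glance_onset_ms,
                    "label": tt.label,
                })
    return recordings, pd.DataFrame(rows)
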