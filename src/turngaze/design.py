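"""Stimulus design for dyadic turn-taking experiments.

Eight ~30 s scripted conversations between two on-screen speakers (left and
right puppet). Each conversation holds six filler utterances and four target
utterances, one per condition of the 2x2 completeness design
(lexicosyntactic x prosodic). Every target is followed by a 500 ms silence;
after lexicosyntactically incomplete targets the same speaker always
continues, after lexicosyntactically complete targets the other speaker
responds 50% of the time (balanced per condition across the experiment).

All times are integer milliseconds from conversation onset; intervals are
half-open ``[onset, offset)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
import yaml

SILENCE_MS = 500
N_CONVERSATIONS = 8
N_TARGETS_PER_CONVERSATION = 4
N_FILLERS_PER_CONVERSATION = 6
N_UTTERANCES = N_TARGETS_PER_CONVERSATION + N_FILLERS_PER_CONVERSATION
CONVERSATION_MS = 30_000


class Side(str, Enum):
    """Which puppet is speaking (screen half)."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Outcome(str, Enum):
    """What happens after a target's 500 ms silence."""

    SWITCH = "switch"        # the other speaker takes the turn
    CONTINUE = "continue"    # the same speaker keeps the turn


class Condition(Enum):
    """Target-utterance condition: (lexicosyntactic, prosodic) completeness."""

    FULLY_INCOMPLETE = (False, False)
    INCOMPLETE_SYNTAX = (False, True)
    INCOMPLETE_PROSODY = (True, False)
    FULLY_COMPLETE = (True, True)

    def __init__(self, syntax_complete: bool, prosody_complete: bool):
        self.syntax_complete = syntax_complete
        self.prosody_complete = prosody_complete

    @property
    def label(self) -> str:
        return self.name


CONDITIONS = tuple(Condition)


@dataclass(frozen=True)
class Utterance:
    speaker: Side
    onset_ms: int
    offset_ms: int
    is_target: bool = False
    condition: Condition | None = None

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class TargetEvent:
    """One target turn transition: a condition-controlled 500 ms silence."""

    conversation_id: str
    condition: Condition
    prior_speaker: Side
    responder: Side
    silence_onset_ms: int
    silence_offset_ms: int
    outcome: Outcome


@dataclass
class ConversationDesign:
    id: str
    duration_ms: int
    utterances: list[Utterance]
    targets: list[TargetEvent]

    @property
    def n_transitions(self) -> int:
        """Number of speaker changes between consecutive utterances."""
        speakers = [u.speaker for u in self.utterances]
        return sum(a != b for a, b in zip(speakers, speakers[1:]))


@dataclass
class ExperimentDesign:
    conversations: list[ConversationDesign]
    presentation_orders: list[list[str]]

    @property
    def targets(self) -> list[TargetEvent]:
        return [t for c in self.conversations for t in c.targets]

    def conversation(self, conv_id: str) -> ConversationDesign:
        for c in self.conversations:
            if c.id == conv_id:
                return c
        raise KeyError(f"no conversation {conv_id!r} in design")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

# The 5 ways to pick 4 mutually non-adjacent target slots out of utterance
# slots 1..8 (slot 0 and 9 stay fillers, so every target is followed by an
# utterance and preceded by some context).
_TARGET_SLOT_SETS = [s for s in itertools.combinations(range(1, 9), 4)
                     if all(b - a >= 2 for a, b in zip(s, s[1:]))]


def _condition_orders(rng: np.random.Generator) -> list[tuple[Condition, ...]]:
    """Position-counterbalanced condition orders for the 8 conversations.

    Two cyclic Latin squares over the four conditions, rows shuffled, so each
    condition occupies each serial target position exactly twice.
    """
    orders: list[tuple[Condition, ...]] = []
    for _ in range(2):
        base = list(rng.permutation(4))
        square = [tuple(CONDITIONS[base[(i + j) % 4]] for j in range(4))
                  for i in range(4)]
        orders.extend(square)
    rng.shuffle(orders)
    return orders


def _conversation_plan(rng, cond_order, l_rem, sw_rem, convs_left):
    """Pick target slots, speakers, outcomes and filler speakers for one
    conversation, honoring the global speaker/outcome quotas and the 5-7
    transition constraint. Returns (slots, speakers10, per-target info)."""
    syn_ix = [i for i, c in enumerate(cond_order) if c.syntax_complete]
    plans = []
    for slots in _TARGET_SLOT_SETS:
        # 2 left / 2 right targets per conversation ("equally divided").
        for left_ix in itertools.combinations(range(4), 2):
            spk = tuple(Side.LEFT if i in left_ix else Side.RIGHT
                        for i in range(4))
            # outcomes free only for the two +SYN targets
            for out_bits in itertools.product(
                    (Outcome.SWITCH, Outcome.CONTINUE), repeat=len(syn_ix)):
                outs = [Outcome.CONTINUE] * 4
                for i, o in zip(syn_ix, out_bits):
                    outs[i] = o
                plans.append((slots, spk, tuple(outs)))
    order = rng.permutation(len(plans))
    for k in order:
        slots, spk, outs = plans[k]
        # global quota feasibility
        feasible = True
        for i, cond in enumerate(cond_order):
            used_left = 1 if spk[i] is Side.LEFT else 0
            rem = l_rem[cond] - used_left
            if not (0 <= rem <= convs_left - 1):
                feasible = False
                break
            if cond.syntax_complete:
                used_sw = 1 if outs[i] is Outcome.SWITCH else 0
                rem_sw = sw_rem[cond] - used_sw
                if not (0 <= rem_sw <= convs_left - 1):
                    feasible = False
                    break
        if not feasible:
            continue
        assignment = _speaker_sequence(rng, slots, spk, outs)
        if assignment is None:
            continue
        return slots, assignment, spk, outs
    return None


def _speaker_sequence(rng, slots, target_speakers, outcomes):
    """Fill the 10-slot speaker sequence around fixed targets so that the
    total number of speaker changes lands in [5, 7]."""
    speakers: list[Side | None] = [None] * N_UTTERANCES
    for i, s in enumerate(slots):
        speakers[s] = target_speakers[i]
        nxt = target_speakers[i] if outcomes[i] is Outcome.CONTINUE \
            else target_speakers[i].other
        speakers[s + 1] = nxt
    free = [i for i, s in enumerate(speakers) if s is None]
    combos = list(itertools.product((Side.LEFT, Side.RIGHT), repeat=len(free)))
    rng.shuffle(combos)
    for combo in combos:
        cand = list(speakers)
        for i, s in zip(free, combo):
            cand[i] = s
        n_trans = sum(a != b for a, b in zip(cand, cand[1:]))
        if 5 <= n_trans <= 7:
            return cand
    return None


def generate_design(seed: int) -> ExperimentDesign:
    """Generate a full experiment design satisfying every design constraint.

    Deterministic given ``seed``. Filler/target utterance durations are drawn
    uniformly from 1.5-3.5 s and rescaled so each conversation lasts 30 s
    including the 500 ms inter-utterance silences.
    """
    for attempt in range(64):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        design = _try_generate(rng)
        if design is not None and not validate_design(design):
            return design
    raise RuntimeError("design generation failed to satisfy constraints")


def _try_generate(rng) -> ExperimentDesign | None:
    cond_orders = _condition_orders(rng)
    l_rem = {c: 4 for c in CONDITIONS}      # left-speaker quota per condition
    sw_rem = {c: 4 for c in CONDITIONS if c.syntax_complete}
    conversations = []
    for ci in range(N_CONVERSATIONS):
        cond_order = cond_orders[ci]
        plan = _conversation_plan(rng, cond_order, l_rem, sw_rem,
                                  N_CONVERSATIONS - ci)
        if plan is None:
            return None
        slots, speakers, tgt_speakers, outcomes = plan
        for i, cond in enumerate(cond_order):
            if tgt_speakers[i] is Side.LEFT:
                l_rem[cond] -= 1
            if cond.syntax_complete and outcomes[i] is Outcome.SWITCH:
                sw_rem[cond] -= 1
        conversations.append(_build_timeline(
            rng, f"conv{ci + 1}", slots, speakers, cond_order, outcomes))
    order1 = [c.id for c in conversations]
    perm = list(rng.permutation(N_CONVERSATIONS))
    order2 = [conversations[i].id for i in perm]
    if order1 == order2:
        order2 = order2[::-1]
    return ExperimentDesign(conversations, [order1, order2])


def _build_timeline(rng, conv_id, slots, speakers, cond_order, outcomes
                    ) -> ConversationDesign:
    durs = rng.uniform(1500.0, 3500.0, N_UTTERANCES)
    speech_budget = CONVERSATION_MS - SILENCE_MS * N_UTTERANCES
    durs = np.round(durs * speech_budget / durs.sum()).astype(int)
    durs[-1] += speech_budget - int(durs.sum())  # exact 30 s after rounding
    utterances, targets = [], []
    t = 0
    slot_to_target = {s: i for i, s in enumerate(slots)}
    for u in range(N_UTTERANCES):
        onset, offset = t, t + int(durs[u])
        is_target = u in slot_to_target
        cond = cond_order[slot_to_target[u]] if is_target else None
        utterances.append(Utterance(speakers[u], onset, offset, is_target, cond))
        if is_target:
            i = slot_to_target[u]
            targets.append(TargetEvent(
                conversation_id=conv_id,
                condition=cond,
                prior_speaker=speakers[u],
                responder=speakers[u].other,
                silence_onset_ms=offset,
                silence_offset_ms=offset + SILENCE_MS,
                outcome=outcomes[i],
            ))
        t = offset + SILENCE_MS
    return ConversationDesign(conv_id, t, utterances, targets)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_design(design: ExperimentDesign) -> list[str]:
    """Return a list of constraint violations (empty list means valid)."""
    v: list[str] = []
    if len(design.conversations) != N_CONVERSATIONS:
        v.append(f"experiment: expected {N_CONVERSATIONS} conversations, "
                 f"got {len(design.conversations)}")
    for conv in design.conversations:
        v.extend(_validate_conversation(conv))
    targets = design.targets
    if len(targets) != 32:
        v.append(f"experiment: expected 32 targets, got {len(targets)}")
    for cond in CONDITIONS:
        ts = [t for t in targets if t.condition is cond]
        if len(ts) != 8:
            v.append(f"experiment: condition {cond.label} has {len(ts)} "
                     "targets, expected 8")
        n_left = sum(t.prior_speaker is Side.LEFT for t in ts)
        if len(ts) == 8 and n_left != 4:
            v.append(f"experiment: condition {cond.label} has {n_left} "
                     "left-speaker targets, expected 4")
        if cond.syntax_complete:
            n_sw = sum(t.outcome is Outcome.SWITCH for t in ts)
            if len(ts) == 8 and n_sw != 4:
                v.append(f"experiment: condition {cond.label} has {n_sw} "
                         "switch outcomes, expected 4 of 8")
    for side in Side:
        n = sum(t.prior_speaker is side for t in targets)
        if len(targets) == 32 and n != 16:
            v.append(f"experiment: speaker {side.value} has {n} targets, "
                     "expected 16")
    if len(design.presentation_orders) != 2:
        v.append("experiment: expected two presentation orders")
    ids = sorted(c.id for c in design.conversations)
    for k, order in enumerate(design.presentation_orders):
        if sorted(order) != ids:
            v.append(f"experiment: presentation order {k + 1} is not a "
                     "permutation of the conversation ids")
    return v


def _validate_conversation(conv: ConversationDesign) -> list[str]:
    v: list[str] = []
    loc = f"conversation {conv.id}"
    utts = conv.utterances
    for i, u in enumerate(utts):
        if u.onset_ms >= u.offset_ms:
            v.append(f"{loc}: utterance {i} has onset >= offset")
        if u.is_target != (u.condition is not None):
            v.append(f"{loc}: utterance {i} condition present iff target "
                     "violated")
    for i, (a, b) in enumerate(zip(utts, utts[1:])):
        gap = b.onset_ms - a.offset_ms
        if gap != SILENCE_MS:
            v.append(f"{loc}: gap between utterances {i} and {i + 1} is "
                     f"{gap} ms, expected {SILENCE_MS}")
    n_targets = sum(u.is_target for u in utts)
    if n_targets != N_TARGETS_PER_CONVERSATION:
        v.append(f"{loc}: {n_targets} target utterances, expected "
                 f"{N_TARGETS_PER_CONVERSATION}")
    if len(utts) != N_UTTERANCES:
        v.append(f"{loc}: {len(utts)} utterances, expected {N_UTTERANCES}")
    conds = [t.condition for t in conv.targets]
    if sorted(c.label for c in conds) != sorted(c.label for c in CONDITIONS):
        v.append(f"{loc}: targets do not cover each condition exactly once")
    if not (29_000 <= conv.duration_ms <= 31_000):
        v.append(f"{loc}: duration {conv.duration_ms} ms outside [29, 31] s")
    if not (5 <= conv.n_transitions <= 7):
        v.append(f"{loc}: {conv.n_transitions} turn transitions, expected 5-7")
    for t in conv.targets:
        if t.silence_offset_ms - t.silence_onset_ms != SILENCE_MS:
            v.append(f"{loc}: target {t.condition.label} silence is "
                     f"{t.silence_offset_ms - t.silence_onset_ms} ms, "
                     f"expected {SILENCE_MS}")
        if t.responder == t.prior_speaker:
            v.append(f"{loc}: target {t.condition.label} responder equals "
                     "prior speaker")
        if not t.condition.syntax_complete and t.outcome is not Outcome.CONTINUE:
            v.append(f"{loc}: lexicosyntactically incomplete target "
                     f"{t.condition.label} marked {t.outcome.value}; the "
                     "current speaker always completes her turn")
    return v


# ---------------------------------------------------------------------------
# Serialization (YAML, round-trip stable)
# ---------------------------------------------------------------------------

def _design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "presentation_orders": [list(o) for o in design.presentation_orders],
        "conversations": [
            {
                "id": c.id,
                "duration_ms": c.duration_ms,
                "utterances": [
                    {
                        "speaker": u.speaker.value,
                        "onset_ms": u.onset_ms,
                        "offset_ms": u.offset_ms,
                        "is_target": u.is_target,
                        **({"condition": u.condition.label,
                            "outcome": nxt.outcome.value}
                           if u.is_target else {}),
                    }
                    for u, nxt in zip(
                        c.utterances,
                        [_target_for(c, u) for u in c.utterances])
                ],
            }
            for c in design.conversations
        ],
    }


def _target_for(conv: ConversationDesign, utt: Utterance):
    if not utt.is_target:
        return None
    for t in conv.targets:
        if t.silence_onset_ms == utt.offset_ms:
            return t
    raise ValueError(f"conversation {conv.id}: target utterance at "
                     f"{utt.onset_ms} ms has no matching target event")


def save_design(design: ExperimentDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_design_to_dict(design), fh, sort_keys=False)


class DesignParseError(ValueError):
    pass


def load_design(path) -> ExperimentDesign:
    """Load a design file; raises on malformed input or invariant breaches."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise DesignParseError(f"{path}: not valid YAML: {e}") from e
    if not isinstance(doc, dict) or "conversations" not in doc:
        raise DesignParseError(f"{path}: missing 'conversations' section")
    conversations = []
    for cd in doc["conversations"]:
        utterances, targets = [], []
        for i, ud in enumerate(cd.get("utterances", [])):
            try:
                cond = (Condition[ud["condition"]]
                        if ud.get("is_target") else None)
                utt = Utterance(Side(ud["speaker"]), int(ud["onset_ms"]),
                                int(ud["offset_ms"]), bool(ud.get("is_target")),
                                cond)
            except (KeyError, ValueError) as e:
                raise DesignParseError(
                    f"{path}: conversation {cd.get('id')}, utterance {i}: "
                    f"{e}") from e
            utterances.append(utt)
            if utt.is_target:
                nxt = cd["utterances"][i + 1] if i + 1 < len(cd["utterances"]) \
                    else None
                silence_end = (int(nxt["onset_ms"]) if nxt
                               else utt.offset_ms + SILENCE_MS)
                targets.append(TargetEvent(
                    conversation_id=cd["id"],
                    condition=cond,
                    prior_speaker=utt.speaker,
                    responder=utt.speaker.other,
                    silence_onset_ms=utt.offset_ms,
                    silence_offset_ms=silence_end,
                    outcome=Outcome(ud["outcome"]),
                ))
        conversations.append(ConversationDesign(
            cd["id"], int(cd["duration_ms"]), utterances, targets))
    design = ExperimentDesign(conversations,
                              [list(o) for o in
                               doc.get("presentation_orders", [])])
    violations = validate_design(design)
    if violations:
        raise DesignParseError(
            f"{path}: design violates constraints:\n  " +
            "\n  ".join(violations))
    return design
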