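import dataclasses

import numpy as np
import pytest

from conftest import brute_force_detect, random_fixation_sequence
from turngaze.design import Condition, Outcome, Side, TargetEvent
from turngaze.detection import (AnalysisWindow, Fixation,
                                build_analysis_window,
                                detect_anticipatory_switch, detect_many,
                                segment_fixations)
from turngaze.gaze_io import AOI, Group


def _target(onset=10000, conv="c1"):
    return TargetEvent(conv, Condition.FULLY_COMPLETE, Side.LEFT, Side.RIGHT,
                       onset, onset + 500, Outcome.SWITCH)


TODDLER_WINDOW = build_analysis_window(_target(), Group.TODDLER, 30000)


class TestSegmentation:
    def test_constant_aoi_single_fixation(self):
        t = np.arange(10) * 20.0  # 200 ms at 50 Hz
        fix = segment_fixations(t, np.full(10, AOI.LEFT, dtype=np.int8))
        assert len(fix) == 1
        assert fix[0].aoi is AOI.LEFT
        assert fix[0].duration_ms == 200.0

    def test_short_gap_merged_into_fixation(self):
        # LEFT 80 ms, OFFSCREEN 20 ms, LEFT 80 ms; tolerance 25 ms
        t = np.arange(18) * 10.0
        aoi = np.array([AOI.LEFT] * 8 + [AOI.OFFSCREEN] * 2 + [AOI.LEFT] * 8,
                       dtype=np.int8)
        fix = segment_fixations(t, aoi, gap_tolerance_ms=25)
        assert len(fix) == 1
        assert fix[0].aoi is AOI.LEFT and fix[0].duration_ms == 180.0

    def test_gap_beyond_tolerance_not_merged(self):
        t = np.arange(18) * 10.0
        aoi = np.array([AOI.LEFT] * 8 + [AOI.OFFSCREEN] * 2 + [AOI.LEFT] * 8,
                       dtype=np.int8)
        fix = segment_fixations(t, aoi, gap_tolerance_ms=15)
        assert [f.aoi for f in fix] == [AOI.LEFT, AOI.OFFSCREEN, AOI.LEFT]

    def test_strict_alternation_leaves_no_long_dwell(self):
        t = np.arange(100) * 20.0
        aoi = np.tile([AOI.LEFT, AOI.RIGHT], 50).astype(np.int8)
        fix = segment_fixations(t, aoi, gap_tolerance_ms=0)
        assert max(f.duration_ms for f in fix) < 100

    def test_consecutive_fixations_have_distinct_aois(self):
        rng = np.random.default_rng(0)
        t = np.arange(500) * 20.0
        aoi = rng.choice(4, size=500).astype(np.int8)
        fix = segment_fixations(t, aoi, gap_tolerance_ms=75)
        assert all(a.aoi != b.aoi for a, b in zip(fix, fix[1:]))
        assert fix[0].onset_ms == 0.0
        assert all(a.offset_ms == b.onset_ms for a, b in zip(fix, fix[1:]))


class TestAnalysisWindow:
    def test_toddler_window_geometry(self):
        w = build_analysis_window(_target(10000), Group.TODDLER, 30000)
        assert (w.start_ms, w.end_ms) == (9700, 10800)
        assert w.response_onset_ms == 10500 and w.deadline_ms == 10800

    def test_adult_window_geometry(self):
        w = build_analysis_window(_target(10000), Group.ADULT, 30000)
        assert (w.start_ms, w.end_ms) == (9800, 10700)
        assert w.deadline_ms == 10700

    def test_clipping_at_conversation_start(self):
        w = build_analysis_window(_target(100), Group.TODDLER, 30000)
        assert w.start_ms == 0.0


class TestDetector:
    def test_never_leaving_prior_speaker_scores_zero(self):
        fix = [Fixation(AOI.LEFT, 9000, 12000)]
        assert detect_anticipatory_switch(fix, TODDLER_WINDOW) == 0

    def test_timely_switch_scores_one(self):
        fix = [Fixation(AOI.LEFT, 9500, 10100),
               Fixation(AOI.OTHER, 10100, 10200),
               Fixation(AOI.RIGHT, 10200, 10400)]
        assert detect_anticipatory_switch(fix, TODDLER_WINDOW) == 1

    def test_switch_after_deadline_scores_zero(self):
        fix = [Fixation(AOI.LEFT, 9500, 10100),
               Fixation(AOI.OTHER, 10100, 10850),
               Fixation(AOI.RIGHT, 10850, 11050)]
        assert detect_anticipatory_switch(fix, TODDLER_WINDOW) == 0

    def test_responder_fixation_before_prior_offset_ignored(self):
        # F2 must start at or after F1 ends
        fix = [Fixation(AOI.RIGHT, 9000, 9600),
               Fixation(AOI.LEFT, 9600, 10400)]
        assert detect_anticipatory_switch(fix, TODDLER_WINDOW) == 0

    def test_short_fixations_do_not_count(self):
        fix = [Fixation(AOI.LEFT, 9950, 10040),   # 90 ms < 100 ms
               Fixation(AOI.RIGHT, 10040, 10340)]
        assert detect_anticipatory_switch(fix, TODDLER_WINDOW) == 0

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(123)
        for _ in range(2000):
            fix = random_fixation_sequence(rng)
            span = fix[-1].offset_ms
            t = _target(int(rng.integers(0, max(int(span), 1) + 500)))
            group = Group.TODDLER if rng.random() < 0.5 else Group.ADULT
            w = build_analysis_window(t, group, span + 2000)
            strict = bool(rng.random() < 0.3)
            assert detect_anticipatory_switch(fix, w, strict_prior_end=strict) \
                == brute_force_detect(fix, w, strict_prior_end=strict)

    def test_detect_many_matches_scalar_detector(self):
        rng = np.random.default_rng(7)
        fix = random_fixation_sequence(rng, max_len=12)
        windows = [build_analysis_window(
            _target(int(rng.integers(0, 4000))), Group.TODDLER, 10000)
            for _ in range(50)]
        many = detect_many(fix, windows)
        each = [detect_anticipatory_switch(fix, w) for w in windows]
        assert list(many) == each

    def test_monotonicity_in_min_fixation_and_deadline(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            fix = random_fixation_sequence(rng)
            t = _target(int(rng.integers(0, int(fix[-1].offset_ms) + 500)))
            w = build_analysis_window(t, Group.TODDLER, 10**6)
            base = detect_anticipatory_switch(fix, w)
            # raising the minimum fixation never converts a 0 into a 1
            assert detect_anticipatory_switch(fix, w, min_fix_ms=160) <= base
            # shrinking the window (earlier deadline, later start) likewise
            narrow = dataclasses.replace(w, start_ms=w.start_ms + 100,
                                         deadline_ms=w.deadline_ms - 100)
            assert detect_anticipatory_switch(fix, narrow) <= base

    def test_rate_invariance_50_vs_120hz(self):
        # same underlying AOI trajectory sampled at both tracker rates
        def trajectory(ts):
            out = np.full(len(ts), AOI.OTHER, dtype=np.int8)
            out[(ts >= 9000) & (ts < 10150)] = AOI.LEFT
            out[(ts >= 10150) & (ts < 10650)] = AOI.RIGHT
            return out

        results = []
        for rate in (50.0, 120.0):
            ts = np.arange(0, 30000, 1000.0 / rate)
            fix = segment_fixations(ts, trajectory(ts))
            results.append(detect_anticipatory_switch(fix, TODDLER_WINDOW))
        assert results[0] == results[1] == 1
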