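import numpy as np
import pytest

from turngaze.design import generate_design
from turngaze.detection import Fixation
from turngaze.gaze_io import AOI


@pytest.fixture(scope="session")
def design():
    return generate_design(0)


def brute_force_detect(fixations, window, min_fix_ms=100.0,
                       strict_prior_end=False):
    """Literal three-criterion search over all (F1, F2) fixation pairs;
    the independent oracle for the anticipatory-switch detector."""
    for f1 in fixations:
        if f1.aoi != window.prior_side:
            continue
        if f1.duration_ms < min_fix_ms:
            continue
        # criterion 1: fixation on the prior speaker overlapping the
        # pre-silence part of the window
        if not (f1.onset_ms < window.silence_onset_ms
                and f1.offset_ms > window.start_ms):
            continue
        if strict_prior_end and not (
                f1.onset_ms <= window.silence_onset_ms - min_fix_ms
                and f1.offset_ms >= window.silence_onset_ms):
            continue
        for f2 in fixations:
            if f2.aoi != window.responder_side:
                continue
            if f2.duration_ms < min_fix_ms:
                continue
            # criteria 2 + 3: later fixation on the responder, initiated
            # no later than the deadline
            if f1.offset_ms <= f2.onset_ms <= window.deadline_ms:
                return 1
    return 0


def random_fixation_sequence(rng, max_len=12):
    """A random dwell sequence over the four AOI labels: consecutive AOIs
    distinct, durations on a 20 ms grid between 20 and 400 ms."""
    n = int(rng.integers(1, max_len + 1))
    aois, prev = [], None
    for _ in range(n):
        choices = [a for a in AOI if a != prev]
        prev = AOI(int(rng.choice(choices)))
        aois.append(prev)
    durs = rng.integers(1, 21, size=n) * 20
    t = float(rng.integers(0, 30)) * 100
    fixations = []
    for a, d in zip(aois, durs):
        fixations.append(Fixation(a, t, t + float(d)))
        t += float(d)
    return fixations
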