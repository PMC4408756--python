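"""Published cohort bookkeeping for the two reference experiments.

The original Dutch and English studies report raw counts (participants
tested, participants and trials excluded, stimulus pre-test outcomes) and
the percentages derived from them. These counts enter the pipeline as
inputs — e.g. equipment-failure drop lists — and the percentage arithmetic
is reproduced here so audit reports can be checked against the published
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StudyCounts:
    """Counts printed for one experiment's cohort."""

    language: str
    toddlers_tested: int
    toddlers_excluded_equipment: int
    toddlers_excluded_inattention: int
    adults: int
    trials_excluded: int
    trials_analyzed: int

    @property
    def toddlers_analyzed(self) -> int:
        return (self.toddlers_tested - self.toddlers_excluded_equipment
                - self.toddlers_excluded_inattention)

    @property
    def pct_toddlers_excluded_inattention(self) -> int:
        """Share of tested toddlers excluded for inattention, as printed
        (integer percent)."""
        return round(100 * self.toddlers_excluded_inattention
                     / self.toddlers_tested)

    @property
    def pct_trials_excluded(self) -> float:
        """Share of candidate trials excluded, as printed (one decimal):
        excluded / (analyzed + excluded)."""
        total = self.trials_analyzed + self.trials_excluded
        return round(100 * self.trials_excluded / total, 1)


DUTCH = StudyCounts(
    language="Dutch",
    toddlers_tested=33,
    toddlers_excluded_equipment=1,
    toddlers_excluded_inattention=11,
    adults=16,
    trials_excluded=27,
    trials_analyzed=1056,
)

ENGLISH = StudyCounts(
    language="English",
    toddlers_tested=25,
    toddlers_excluded_equipment=1,
    toddlers_excluded_inattention=4,
    adults=20,
    trials_excluded=27,
    trials_analyzed=1144,
)


@dataclass(frozen=True)
class ProsodyPretest:
    """Low-pass-filtered listening pre-test of the prosodic contours."""

    n_targets: int = 32
    n_ambiguous: int = 11  # contours misjudged in > 25% of judgments (Dutch)

    @property
    def pct_ambiguous(self) -> int:
        return round(100 * self.n_ambiguous / self.n_targets)


DUTCH_PROSODY_PRETEST = ProsodyPretest()
ENGLISH_PROSODY_PRETEST = ProsodyPretest(n_targets=32, n_ambiguous=2)
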