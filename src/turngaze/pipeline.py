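"""End-to-end orchestration: design -> gaze -> exclusions -> detection ->
chance correction -> model suite -> report.

A single run seed fans out into named substreams (design, cohort, window
shuffles) so each stage is independently reproducible; runs are fully
deterministic given the configuration.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline as bl
from . import design as dz
from . import detection as det
from . import stats
from .preprocess import (ATTENTION_THRESHOLD, MAX_EXCLUDED_TRIALS,
                         preprocess as preprocess_recordings)
from .gaze_io import (DEFAULT_LAYOUT, Group, TrialRecording, read_gaze_table,
                      resolve_aoi_stream, write_gaze_table)
from .simulate import CohortSpec, SimParams, simulate_cohort

log = logging.getLogger("turngaze")


@dataclass
class RunConfig:
    out_dir: str = "turngaze_run"
    seed: int = 0
    simulate: bool = True
    design_path: str | None = None
    gaze_path: str | None = None
    dialect: str = "standard"
    n_toddlers: int = 21
    n_adults: int = 16
    sim_regime: str = "default"  # default | null | noiseless | strong_effects
    n_shuffles: int = bl.N_SHUFFLES
    attention_threshold: float = ATTENTION_THRESHOLD
    max_excluded_trials: int = MAX_EXCLUDED_TRIALS
    min_fixation_ms: float = det.MIN_FIXATION_MS
    gap_tolerance_ms: float = det.GAP_TOLERANCE_MS
    group_leads_ms: dict = field(
        default_factory=lambda: {"toddler": 300.0, "adult": 200.0})
    exclude_items: list = field(default_factory=list)
    drop_participants: list = field(default_factory=list)
    shared_shuffles: bool = True   # one shuffle set per conversation x group
    strict_prior_end: bool = False
    write_gaze: bool = False
    models: list = field(
        default_factory=lambda: [s.name for s in stats.MODEL_SUITE])

    def __post_init__(self):
        for name, v in (("n_shuffles", self.n_shuffles),
                        ("min_fixation_ms", self.min_fixation_ms),
                        ("attention_threshold", self.attention_threshold)):
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.gap_tolerance_ms < 0 or self.max_excluded_trials < 0:
            raise ValueError("tolerances must be non-negative")
        for g in Group:
            if g.value not in self.group_leads_ms:
                raise ValueError(f"no group lead defined for {g.value}")

    def lead_ms(self, group: Group) -> float:
        return float(self.group_leads_ms[group.value])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class PipelineError(RuntimeError):
    """Raised with the failing stage name in the message."""


def derive_seeds(seed: int) -> dict:
    """Named integer substreams (< 2**31) from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(3) & 0x7FFFFFFF
    return {"design": int(seed), "cohort": int(state[1]),
            "shuffles": int(state[2])}


@dataclass
class PipelineResult:
    design: dz.ExperimentDesign
    observations: pd.DataFrame
    fits: dict
    summary: pd.DataFrame
    trial_audit: pd.DataFrame
    participant_audit: pd.DataFrame
    truth: pd.DataFrame | None
    report: str


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_design(config: RunConfig) -> dz.ExperimentDesign:
    if config.design_path:
        return dz.load_design(config.design_path)
    return dz.generate_design(derive_seeds(config.seed)["design"])


def stage_data(config: RunConfig, design: dz.ExperimentDesign):
    """Simulate or ingest the gaze recordings (returns truth for simulated
    cohorts, None otherwise)."""
    if config.simulate:
        regimes = {"default": SimParams, "null": SimParams.null,
                   "noiseless": SimParams.noiseless,
                   "strong_effects": SimParams.strong_effects}
        if config.sim_regime not in regimes:
            raise PipelineError(f"stage data: unknown sim_regime "
                                f"{config.sim_regime!r}")
        spec = CohortSpec(design=design, n_toddlers=config.n_toddlers,
                          n_adults=config.n_adults,
                          params=regimes[config.sim_regime](),
                          seed=derive_seeds(config.seed)["cohort"])
        return simulate_cohort(spec)
    if not config.gaze_path:
        raise PipelineError("stage data: no gaze_path and simulate=False")
    return read_gaze_table(config.gaze_path, config.dialect), None


def stage_detect(config: RunConfig, design: dz.ExperimentDesign,
                 recordings: list[TrialRecording]) -> pd.DataFrame:
    """Segment fixations and score every target of every retained trial;
    adds the shuffled-window chance baseline and the corrected value."""
    shuffle_seed = derive_seeds(config.seed)["shuffles"]
    shuffle_cache: dict = {}
    rows = []
    conv_index = {c.id: i for i, c in enumerate(design.conversations)}
    for rec in recordings:
        conv = design.conversation(rec.conversation_id)
        aoi = resolve_aoi_stream(rec)
        fixations = det.segment_fixations(rec.time_ms, aoi,
                                          config.gap_tolerance_ms)
        lead = config.lead_ms(rec.group)
        windows = [det.build_analysis_window(t, rec.group, conv.duration_ms,
                                             lead_ms=lead)
                   for t in conv.targets]
        actual = det.detect_many(fixations, windows, config.min_fixation_ms,
                                 config.strict_prior_end)
        key = (rec.conversation_id, rec.group)
        if not config.shared_shuffles:
            key = key + (rec.participant_id,)
        if key not in shuffle_cache:
            rng = np.random.default_rng(np.random.SeedSequence(
                (shuffle_seed, conv_index[rec.conversation_id],
                 0 if rec.group is Group.TODDLER else 1)
                + ((zlib.crc32(rec.participant_id.encode()),)
                   if not config.shared_shuffles else ())))
            shuffle_cache[key] = bl.shuffle_windows(
                conv, rec.group, config.n_shuffles, rng, lead_ms=lead)
        rates = bl.baseline_rate(fixations, shuffle_cache[key],
                                 config.min_fixation_ms,
                                 config.strict_prior_end)
        for t, a, b in zip(conv.targets, actual, rates):
            rows.append({
                "participant_id": rec.participant_id,
                "group": rec.group.value,
                "conversation_id": rec.conversation_id,
                "presentation_index": rec.presentation_index,
                "item": f"{rec.conversation_id}:{t.condition.name}",
                "condition": t.condition.name,
                "outcome": t.outcome.value,
                "actual": int(a),
                "baseline": float(b),
                "corrected": bl.corrected_score(int(a), float(b)),
            })
    if not rows:
        raise PipelineError("stage detect: no trials to score")
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    log.info("run seed %d; substreams %s", config.seed,
             derive_seeds(config.seed))

    design = stage_design(config)
    violations = dz.validate_design(design)
    if violations:
        raise PipelineError("stage design: invalid design:\n" +
                            "\n".join(violations))
    dz.save_design(design, out / "design.yaml")

    recordings, truth = stage_data(config, design)
    log.info("stage data: %d trial recordings", len(recordings))
    if config.write_gaze:
        write_gaze_table(recordings, out / "gaze.csv")
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)

    retained, trial_audit, participant_audit = preprocess_recordings(
        recordings, DEFAULT_LAYOUT, config.attention_threshold,
        config.max_excluded_trials, set(config.drop_participants))
    trial_audit.to_csv(out / "audit_trials.csv", index=False)
    participant_audit.to_csv(out / "audit_participants.csv", index=False)
    for _, row in participant_audit.iterrows():
        if row["participant_excluded"]:
            log.info("excluded participant %s (%d trials below threshold)",
                     row["participant_id"], row["n_excluded_trials"])
    log.info("stage preprocess: %d/%d trials retained, %d/%d participants",
             len(retained), len(recordings),
             int((~participant_audit["participant_excluded"]).sum()),
             len(participant_audit))
    if not retained:
        raise PipelineError(
            "stage preprocess: no trials left after exclusions "
            f"(attention threshold {config.attention_threshold})")

    scored = stage_detect(config, design, retained)
    observations = stats.make_observation_table(scored)
    observations.to_csv(out / "observations.csv", index=False)
    log.info("stage detect: %d observations", len(observations))

    specs = [s for s in stats.MODEL_SUITE if s.name in config.models]
    try:
        fits = stats.run_model_suite(observations, config.exclude_items,
                                     specs)
    except ValueError as e:
        raise PipelineError(f"stage fit: {e}") from e
    for name, fit in fits.items():
        fit.terms.to_csv(out / f"model_{name}.csv")
        log.info("stage fit: %s on %d observations (N=%d)",
                 name, fit.n_observations, fit.n_subjects)
    summary = stats.condition_summary(observations)
    summary.to_csv(out / "condition_summary.csv", index=False)

    report = build_report(config, trial_audit, participant_audit, summary,
                          fits)
    (out / "report.txt").write_text(report)
    return PipelineResult(design, observations, fits, summary, trial_audit,
                          participant_audit, truth, report)


def build_report(config, trial_audit, participant_audit, summary, fits) -> str:
    n_trials = len(trial_audit)
    n_excl = int(trial_audit["excluded"].sum())
    n_part = len(participant_audit)
    n_part_excl = int(participant_audit["participant_excluded"].sum())
    lines = [
        "Anticipatory gaze-switch analysis",
        "=" * 50,
        f"seed: {config.seed}   shuffles: {config.n_shuffles}",
        f"trials: {n_trials} scored candidates, {n_excl} excluded "
        f"(< {config.attention_threshold:.0%} attention)",
        f"participants: {n_part} total, {n_part_excl} excluded "
        f"(> {config.max_excluded_trials} dropped trials)",
        "",
        "Condition means (per condition x group; SEM over participants)",
        summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
    ]
    for fit in fits.values():
        lines.append(stats.format_fit(fit))
        lines.append("")
    return "\n".join(lines)


def _setup_logging(path):
    log.setLevel(logging.INFO)
    have = {getattr(h, "baseFilename", None) for h in log.handlers}
    if str(path) not in have:
        fh = logging.FileHandler(path)
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler())
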