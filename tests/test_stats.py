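import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from turngaze.design import Condition
from turngaze.stats import (MODEL_SUITE, ModelSpec, code_contrasts,
                            condition_summary, fit_mixed_model,
                            make_observation_table, run_model_suite)

CONDS = ["FULLY_INCOMPLETE", "INCOMPLETE_SYNTAX", "INCOMPLETE_PROSODY",
         "FULLY_COMPLETE"]


def synthetic_observations(n_subj=20, n_conv=8, seed=0, intercept=0.15,
                           syn=0.20, pros=0.075, subj_sd=0.08, item_sd=0.03,
                           resid_sd=0.45):
    """Observation-level generator with known fixed effects and crossed
    subject/item random intercepts (no gaze simulation involved)."""
    rng = np.random.default_rng(seed)
    rows = []
    items = [f"c{c}:{cond}" for c in range(n_conv) for cond in CONDS]
    item_re = dict(zip(items, rng.normal(0, item_sd, len(items))))
    for s in range(n_subj):
        pid = f"s{s:02d}"
        group = "toddler" if s < n_subj // 2 else "adult"
        b_s = rng.normal(0, subj_sd)
        for c in range(n_conv):
            for cond in CONDS:
                cobj = Condition[cond]
                xs = 1 if cobj.syntax_complete else -1
                xp = 1 if cobj.prosody_complete else -1
                y = (intercept + syn * xs + pros * xp + b_s
                     + item_re[f"c{c}:{cond}"] + rng.normal(0, resid_sd))
                rows.append({
                    "participant_id": pid, "group": group,
                    "conversation_id": f"c{c}",
                    "presentation_index": c + 1,
                    "item": f"c{c}:{cond}", "condition": cond,
                    "outcome": "switch" if (xs == 1 and c % 2 == 0)
                    else "continue",
                    "actual": 1 if y > 0.2 else 0,
                    "baseline": 0.2, "corrected": y})
    return make_observation_table(pd.DataFrame(rows))


@pytest.fixture(scope="module")
def observations():
    return synthetic_observations(seed=1)


class TestContrasts:
    @pytest.mark.parametrize("factor, level, code", [
        ("syntax", "complete", 1),
        ("syntax", "incomplete", -1),
        ("prosody", "complete", 1),
        ("group", "toddler", -1),
        ("group", "adult", 1),
        ("speaker_change", "no", -1),
        ("speaker_change", "yes", 1),
        ("partial_condition", "INCOMPLETE_PROSODY", 1),
        ("partial_condition", "INCOMPLETE_SYNTAX", -1),
    ])
    def test_coding_table(self, factor, level, code):
        assert code_contrasts(factor, level) == code

    def test_unknown_level_or_factor_rejected(self):
        with pytest.raises(ValueError):
            code_contrasts("syntax", "partial")
        with pytest.raises(ValueError):
            code_contrasts("tempo", "fast")

    def test_observation_table_codes(self, observations):
        assert set(observations["syn"]) == {-1, 1}
        assert set(observations["grp"]) == {-1, 1}
        # speaker change undefined for lexicosyntactically incomplete items
        assert observations.loc[observations["syn"] == -1, "change"] \
            .isna().all()
        assert observations.loc[observations["syn"] == 1, "change"] \
            .notna().all()


class TestFitMixedModel:
    def test_zero_response_gives_zero_betas(self, observations):
        obs = observations.copy()
        obs["corrected"] = 0.0
        fit = fit_mixed_model(obs, MODEL_SUITE[0])
        assert np.abs(fit.terms["beta"]).max() < 1e-8
        assert fit.singular

    def test_two_variance_components_plus_residual(self, observations):
        fit = fit_mixed_model(observations, MODEL_SUITE[0])
        assert set(fit.variance_components) == {"subject", "item", "residual"}
        assert fit.variance_components["residual"] > 0

    def test_known_effects_recovered_and_z_rule(self, observations):
        fit = fit_mixed_model(observations, MODEL_SUITE[0])
        syn = fit.term("syn")
        assert syn["beta"] == pytest.approx(0.20, abs=0.05)
        assert syn["significant"] and abs(syn["z"]) > 1.96
        # significance flag is exactly the |z| > 1.96 rule
        for _, row in fit.terms.iterrows():
            assert row["significant"] == (abs(row["z"]) > 1.96)

    def test_sign_flip_symmetry(self, observations):
        flipped = observations.copy()
        flipped["pros"] = -flipped["pros"]
        a = fit_mixed_model(observations, MODEL_SUITE[0])
        b = fit_mixed_model(flipped, MODEL_SUITE[0])
        assert b.term("pros")["beta"] == pytest.approx(
            -a.term("pros")["beta"], abs=1e-6)
        assert abs(b.term("pros")["z"]) == pytest.approx(
            abs(a.term("pros")["z"]), abs=1e-4)

    def test_too_few_subjects_rejected(self, observations):
        one = observations[observations["participant_id"] == "s00"]
        with pytest.raises(ValueError, match="subjects"):
            fit_mixed_model(one, MODEL_SUITE[0])

    def test_matches_lme4_reference(self, observations, tmp_path):
        """REML estimates must agree with lme4's for the same model."""
        csv = tmp_path / "obs.csv"
        observations.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- lmer(corrected ~ syn*pros*grp + (1|participant_id) + (1|item),
          data=d, REML=TRUE)
co <- summary(m)$coefficients
write.csv(co, "{tmp_path / 'ref.csv'}")
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
        fit = fit_mixed_model(observations, MODEL_SUITE[0])
        # columns: Estimate, Std. Error, t value
        np.testing.assert_allclose(fit.term("syn")["beta"],
                                   ref.loc["syn"].iloc[0], atol=1e-4)
        np.testing.assert_allclose(fit.term("syn")["se"],
                                   ref.loc["syn"].iloc[1], atol=1e-4)
        np.testing.assert_allclose(fit.term("Intercept")["beta"],
                                   ref.loc["(Intercept)"].iloc[0], atol=1e-4)


class TestModelSuite:
    def test_suite_structure(self, observations):
        fits = run_model_suite(observations)
        assert list(fits) == ["main", "partial", "syn_complete",
                              "speaker_change", "first_two", "last_two"]
        assert set(fits["main"].terms.index) == {
            "Intercept", "syn", "pros", "grp", "syn:pros", "syn:grp",
            "pros:grp", "syn:pros:grp"}
        assert set(fits["partial"].terms.index) == {
            "Intercept", "partial_cond", "grp", "partial_cond:grp"}
        assert set(fits["syn_complete"].terms.index) == {
            "Intercept", "pros", "grp", "pros:grp"}
        assert set(fits["speaker_change"].terms.index) == {
            "Intercept", "pros", "grp", "change", "pros:grp", "pros:change",
            "grp:change", "pros:grp:change"}

    def test_subsets(self, observations):
        fits = run_model_suite(observations)
        n = len(observations)
        assert fits["partial"].n_observations == n // 2
        assert fits["syn_complete"].n_observations == n // 2
        assert fits["speaker_change"].n_observations == n // 2
        assert fits["first_two"].n_observations == n // 4
        assert fits["last_two"].n_observations == n // 4

    def test_item_exclusion_list(self, observations):
        drop = ["c0:FULLY_COMPLETE", "c1:FULLY_COMPLETE"]
        fits = run_model_suite(observations, exclude_items=drop)
        assert fits["main"].n_items == 30

    def test_empty_subset_is_descriptive(self, observations):
        spec = ModelSpec("empty", "corrected ~ syn",
                         "presentation_index > 99")
        with pytest.raises(ValueError, match="no observations"):
            fit_mixed_model(observations, spec)


class TestConditionSummary:
    def test_hand_computed_mean_and_sem(self):
        df = pd.DataFrame({
            "participant_id": ["p1", "p2", "p3", "p4"],
            "group": "toddler",
            "condition": "FULLY_COMPLETE",
            "actual": [0, 0, 1, 1],
            "baseline": [0.1, 0.1, 0.1, 0.1],
            "corrected": [-0.1, -0.1, 0.9, 0.9],
        })
        out = condition_summary(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["actual_mean"] == pytest.approx(0.5)
        # SEM by the standard formula: sd([0,0,1,1], ddof=1)/sqrt(4)
        assert row["actual_sem"] == pytest.approx(
            np.std([0, 0, 1, 1], ddof=1) / 2)
        assert row["baseline_sem"] == pytest.approx(0.0)

    def test_one_row_per_condition_and_group(self, observations):
        out = condition_summary(observations)
        assert len(out) == 8
        assert set(out["condition"]) == set(CONDS)

    def test_constant_corrected_yields_zero_sem(self, observations):
        obs = observations.copy()
        obs["corrected"] = 0.3
        out = condition_summary(obs)
        assert np.allclose(out["corrected_mean"], 0.3)
        assert np.allclose(out["corrected_sem"], 0.0)


class TestParameterRecovery:
    def test_mean_recovered_betas_unbiased(self):
        """Across replicate simulations at study-like size, mean recovered
        fixed effects sit within 2 Monte-Carlo SEs of the generative values
        (intercept 0.15, syntax 0.20, prosody 0.075)."""
        est = {"Intercept": [], "syn": [], "pros": []}
        for seed in range(100):
            obs = synthetic_observations(n_subj=37, seed=1000 + seed)
            fit = fit_mixed_model(obs, MODEL_SUITE[0])
            for k in est:
                est[k].append(fit.term(k)["beta"])
        for k, truth in (("Intercept", 0.15), ("syn", 0.20), ("pros", 0.075)):
            mean = np.mean(est[k])
            mc_se = np.std(est[k], ddof=1) / 10
            assert abs(mean - truth) < 2 * mc_se + 1e-12, \
                f"{k}: mean {mean:.4f} vs {truth} (mc_se {mc_se:.4f})"

    def test_null_prosody_effect_rarely_flagged(self):
        """With a real syntax effect and no prosody effect, syntax must be
        detected and prosody not, in at least 95 of 100 replicates."""
        ok = 0
        for seed in range(100):
            obs = synthetic_observations(n_subj=20, pros=0.0,
                                         seed=2000 + seed)
            fit = fit_mixed_model(obs, MODEL_SUITE[0])
            syn_hit = fit.term("syn")["significant"] \
                and fit.term("syn")["beta"] > 0
            pros_quiet = not fit.term("pros")["significant"]
            ok += int(syn_hit and pros_quiet)
        assert ok >= 95
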