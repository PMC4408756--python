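"""Mixed-effects model suite and condition summaries.

All models are linear mixed-effects regressions of baseline-corrected
anticipatory switch values with -1/+1 contrast-coded two-level predictors
and crossed random intercepts for subject (participant) and item (target).
Estimation is REML; a fixed effect is flagged significant when |z| > 1.96
(two-sided Wald test at alpha = 0.05), with z = beta / SE.

The suite mirrors a factorial turn-transition experiment:

* ``main``            corrected ~ syn * pros * group, all targets;
* ``partial``         condition (incomplete-syntax -1 / incomplete-prosody
                      +1) * group on the two partially complete conditions;
* ``syn_complete``    pros * group on lexicosyntactically complete targets;
* ``speaker_change``  pros * group * change on the same subset (speaker
                      change is only defined there: incomplete-syntax
                      targets are always followed by continuation);
* ``first_two`` / ``last_two``  the main model refit on presentation
                      positions {1, 2} and {7, 8}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .design import Condition, Outcome
from .gaze_io import Group

Z_CRITICAL = 1.96

# -1/+1 contrast codes, exactly as reported in factorial tables
SYNTAX_CODE = {"incomplete": -1, "complete": 1}
PROSODY_CODE = {"incomplete": -1, "complete": 1}
GROUP_CODE = {"toddler": -1, "adult": 1}
CHANGE_CODE = {"no": -1, "yes": 1}
PARTIAL_CONDITION_CODE = {"INCOMPLETE_SYNTAX": -1, "INCOMPLETE_PROSODY": 1}

_FACTORS = {"syntax": SYNTAX_CODE, "prosody": PROSODY_CODE,
            "group": GROUP_CODE, "speaker_change": CHANGE_CODE,
            "partial_condition": PARTIAL_CONDITION_CODE}


def code_contrasts(factor: str, level) -> int:
    """Map a two-level factor level to its -1/+1 contrast code."""
    try:
        codes = _FACTORS[factor]
    except KeyError:
        raise ValueError(f"unknown factor {factor!r}; "
                         f"available: {sorted(_FACTORS)}")
    key = level.value if hasattr(level, "value") else \
        (level.name if isinstance(level, Condition) else str(level))
    if key not in codes:
        raise ValueError(f"unknown level {level!r} for factor {factor!r}; "
                         f"expected one of {sorted(codes)}")
    return codes[key]


@dataclass
class ModelSpec:
    name: str
    formula: str                 # fixed-effects part, patsy syntax
    subset: str | None = None    # pandas query on the observation table
    description: str = ""


MODEL_SUITE: list[ModelSpec] = [
    ModelSpec("main", "corrected ~ syn * pros * grp", None,
              "full factorial: syntactic x prosodic completeness x group"),
    ModelSpec("partial", "corrected ~ partial_cond * grp",
              "condition in ('INCOMPLETE_SYNTAX', 'INCOMPLETE_PROSODY')",
              "relative cue weight on the two partially complete conditions"),
    ModelSpec("syn_complete", "corrected ~ pros * grp",
              "syn == 1",
              "prosody x group on lexicosyntactically complete targets"),
    ModelSpec("speaker_change", "corrected ~ pros * grp * change",
              "syn == 1",
              "adds speaker change/continuation (defined only for "
              "lexicosyntactically complete targets)"),
    ModelSpec("first_two", "corrected ~ syn * pros * grp",
              "presentation_index in (1, 2)",
              "main model, first two conversations presented"),
    ModelSpec("last_two", "corrected ~ syn * pros * grp",
              "presentation_index in (7, 8)",
              "main model, last two conversations presented"),
]


@dataclass
class ModelFit:
    name: str
    terms: pd.DataFrame          # index: term; columns: beta, se, z, significant
    variance_components: dict    # subject, item, residual
    n_observations: int
    n_subjects: int
    n_items: int
    converged: bool
    singular: bool               # a variance component collapsed to ~0

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def make_observation_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Attach -1/+1 contrast codes to a raw observation table with columns
    participant_id, group, item, condition, outcome, presentation_index,
    actual, baseline, corrected."""
    df = observations.copy()
    df["syn"] = [code_contrasts("syntax",
                                "complete" if Condition[c].syntax_complete
                                else "incomplete")
                 for c in df["condition"]]
    df["pros"] = [code_contrasts("prosody",
                                 "complete" if Condition[c].prosody_complete
                                 else "incomplete")
                  for c in df["condition"]]
    df["grp"] = [code_contrasts("group", g) for g in df["group"]]
    # speaker change only defined for lexicosyntactically complete targets
    df["change"] = [
        code_contrasts("speaker_change",
                       "yes" if o == Outcome.SWITCH.value else "no")
        if s == 1 else np.nan
        for o, s in zip(df["outcome"], df["syn"])]
    df["partial_cond"] = [
        PARTIAL_CONDITION_CODE.get(c, np.nan) for c in df["condition"]]
    return df


def fit_mixed_model(observations: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one model of the suite with crossed random intercepts for
    subject and item. Degenerate fits are reported with flags, not raised."""
    df = observations.query(spec.subset) if spec.subset else observations
    df = df.dropna(subset=_formula_vars(spec.formula))
    if df.empty:
        raise ValueError(f"model {spec.name!r}: no observations left after "
                         f"subset {spec.subset!r}")
    n_subj = df["participant_id"].nunique()
    n_item = df["item"].nunique()
    if n_subj < 2 or n_item < 2:
        raise ValueError(f"model {spec.name!r}: needs >= 2 subjects and "
                         f">= 2 items, got {n_subj} and {n_item}")
    md = smf.mixedlm(
        spec.formula, df, groups=np.ones(len(df)),
        vc_formula={"subject": "0 + C(participant_id)",
                    "item": "0 + C(item)"},
        re_formula="0")
    # Powell reaches the same REML optimum as lme4 on these near-boundary
    # variance-component problems; gradient-based optimizers tend to stall.
    res = None
    last_error = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("powell", "nm", "cg"):
            try:
                res = md.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError as e:  # boundary-degenerate fit
                last_error = e
    if res is None:
        raise ValueError(f"model {spec.name!r}: estimation failed "
                         f"({last_error})")
    beta = res.fe_params
    se = res.bse_fe
    z = beta / se
    terms = pd.DataFrame({
        "beta": beta, "se": se, "z": z,
        "significant": np.abs(z) > Z_CRITICAL,
    })
    vc = {name: float(v) for name, v in zip(md.exog_vc.names, res.vcomp)}
    vc["residual"] = float(res.scale)
    return ModelFit(
        name=spec.name, terms=terms, variance_components=vc,
        n_observations=len(df), n_subjects=n_subj, n_items=n_item,
        converged=bool(res.converged),
        singular=any(v < 1e-10 for v in res.vcomp),
    )


def _formula_vars(formula: str) -> list[str]:
    rhs = formula.split("~")[1]
    names = {tok.strip() for part in rhs.split("+")
             for tok in part.split("*")}
    return [n for n in names if n]


def run_model_suite(observations: pd.DataFrame,
                    exclude_items: list | None = None,
                    specs: list[ModelSpec] = MODEL_SUITE
                    ) -> dict[str, ModelFit]:
    """Fit the whole suite; ``exclude_items`` drops listed items first
    (e.g. targets whose prosodic contour pre-tested as ambiguous)."""
    df = observations
    if exclude_items:
        df = df[~df["item"].isin(exclude_items)]
    return {spec.name: fit_mixed_model(df, spec) for spec in specs}


def condition_summary(observations: pd.DataFrame,
                      over_participants: bool = True) -> pd.DataFrame:
    """Mean and SEM of actual, baseline, and corrected switch values per
    condition x group (one row each, 8 rows for a two-group experiment).

    By default the SEM is computed over participant means, matching error
    bars that describe participant-level variability; with
    ``over_participants=False`` it is computed over raw observations.
    """
    measures = ["actual", "baseline", "corrected"]
    if over_participants:
        per = (observations
               .groupby(["condition", "group", "participant_id"],
                        sort=True, observed=True)[measures].mean())
        g = per.groupby(["condition", "group"], observed=True)
    else:
        g = observations.groupby(["condition", "group"], sort=True,
                                 observed=True)[measures]
    mean = g.mean()
    sem = g.sem(ddof=1)
    out = mean.join(sem, lsuffix="_mean", rsuffix="_sem").reset_index()
    return out


def format_fit(fit: ModelFit) -> str:
    """Plain-text coefficient table in the familiar journal layout."""
    lines = [f"Model: {fit.name}  "
             f"({fit.n_observations} observations, N = {fit.n_subjects}, "
             f"{fit.n_items} items)"]
    if not fit.converged:
        lines.append("  [warning: optimizer did not report convergence]")
    if fit.singular:
        lines.append("  [note: a random-effect variance collapsed to zero]")
    lines.append(f"  {'Predictor':<28}{'beta':>10}{'t (z)':>10}  sig")
    for term, row in fit.terms.iterrows():
        sig = "*" if row["significant"] else ""
        lines.append(f"  {term:<28}{row['beta']:>10.4g}{row['z']:>10.3g}  {sig}")
    vc = fit.variance_components
    lines.append(f"  variance components: subject {vc['subject']:.4g}, "
                 f"item {vc['item']:.4g}, residual {vc['residual']:.4g}")
    return "\n".join(lines)
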