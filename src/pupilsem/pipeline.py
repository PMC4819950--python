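"""End-to-end drivers: traces → responses → adjusted responses → report.

Two entry points:

* :func:`preprocess_cohort` reduces raw traces to the ResponseRecord table;
* :func:`analyze_responses` runs confound adjustment and the full group
  analysis on any ResponseRecord table (measured or simulated record-level).

Both are thin compositions of the module functions, so the analysis scripts,
the CLI and the simulation studies all exercise identical code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import confound, groups, preprocess

__all__ = ["preprocess_cohort", "build_sound_covariates", "analyze_responses",
           "run_full_analysis"]


def preprocess_cohort(traces, trials: pd.DataFrame) -> pd.DataFrame:
    """Artifact-mask every trace and compute per-trial metrics, with metadata."""
    responses = preprocess.process_trials(traces, trials)
    if "group" in trials.columns and "group" not in responses.columns:
        responses = responses.merge(
            trials[["trial_id", "group"]], on="trial_id", how="left"
        )
    return responses


def build_sound_covariates(
    trials: pd.DataFrame, participants: pd.DataFrame, sounds: pd.DataFrame
) -> pd.DataFrame:
    """Per-sound confound covariates: measured peak level + control-group
    mean pleasantness/arousal ratings."""
    ratings = confound.summarize_control_ratings(trials, participants)
    return sounds[["sound_id", "condition", "peak_db"]].merge(
        ratings, on="sound_id", how="left", validate="one_to_one"
    )


def analyze_responses(
    responses: pd.DataFrame,
    participants: pd.DataFrame,
    covariates: pd.DataFrame,
) -> dict:
    """Confound-adjust crude responses and run the group analysis.

    Returns a dict with the confound fit, adjusted responses, participant
    summaries, and the inference report (paired condition tests, group
    contrasts, semantic correlation, habituation and drift trends).
    """
    if "group" not in responses.columns:
        responses = responses.merge(
            participants[["participant_id", "group"]], on="participant_id", how="left"
        )
    fit = confound.fit_crossed_mixed_model(responses, covariates)
    adjustments = confound.compute_sound_adjustments(fit, covariates)
    adjusted = confound.adjust_pupil_max(responses, adjustments)
    summaries = groups.summarize_participants(adjusted, participants)

    present = [g for g in groups.KNOWN_GROUPS if g in set(summaries["group"])]
    paired = {}
    for g in present:
        try:
            paired[g] = groups.paired_condition_test(summaries, g)
        except ValueError as exc:
            paired[g] = {"group": g, "error": str(exc)}
    contrasts = groups.group_differential_contrast(summaries)

    sem = None
    if summaries["semantic_score"].notna().any():
        try:
            sem = groups.semantic_correlation(summaries, scope="patients")
        except ValueError:
            sem = None
    ancillary = groups.ancillary_correlations(summaries)

    habituation = []
    drift = []
    for g in present:
        for cond in ("M+", "M-"):
            try:
                habituation.append(groups.habituation_test(adjusted, g, cond))
            except ValueError:
                pass
        try:
            drift.append(groups.baseline_drift_test(adjusted, g))
        except ValueError:
            pass

    return {
        "confound_fit": fit,
        "adjustments": adjustments,
        "adjusted": adjusted,
        "summaries": summaries,
        "paired_tests": paired,
        "group_contrasts": contrasts,
        "semantic_correlation": sem,
        "ancillary_correlations": ancillary,
        "habituation": habituation,
        "baseline_drift": drift,
    }


def run_full_analysis(cohort) -> dict:
    """Trace-level pipeline on a :class:`~pupilsem.simulate.SyntheticCohort`
    (or any object with the same attributes)."""
    responses = preprocess_cohort(cohort.traces, cohort.trials)
    qc = preprocess.qc_artifact_balance(responses)
    covariates = build_sound_covariates(
        cohort.trials, cohort.participants, cohort.sounds
    )
    result = analyze_responses(responses, cohort.participants, covariates)
    result["responses"] = responses
    result["qc"] = qc
    result["covariates"] = covariates
    return result


def report_to_jsonable(result: dict) -> dict:
    """Strip the heavy tables and return a JSON-serialisable report."""
    fit = result["confound_fit"]
    out = {
        "confound_fit": {
            "betas": fit.betas,
            "se": fit.se,
            "variance_components": fit.vcomp,
            "residual_variance": fit.sigma2_resid,
        },
        "paired_tests": result["paired_tests"],
        "group_contrasts": result["group_contrasts"].to_dict(orient="records"),
        "semantic_correlation": result["semantic_correlation"],
        "ancillary_correlations": result["ancillary_correlations"].to_dict(
            orient="records"
        ),
        "habituation": result["habituation"],
        "baseline_drift": result["baseline_drift"],
    }
    if "qc" in result:
        out["qc_artifact_balance"] = result["qc"]

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating, float)):
            f = float(obj)
            return f if np.isfinite(f) else None
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    return clean(out)
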