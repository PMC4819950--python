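"""Validation studies: oracle checks and parameter-recovery simulations.

Each function runs one self-contained study of the pipeline against an
independent reference — a brute-force per-sample oracle, an analytic
identity, or the synthetic generator's ground truth — and returns a small
dict of summary numbers.  The test suite asserts on these numbers; the
reproduction script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import confound, groups, pipeline, preprocess
from .audio import Waveform, spectral_invert
from .preprocess import (
    PupilTrace,
    apply_artifact_margins,
    compute_baseline,
    compute_pupil_max,
    detect_artifacts,
    mask_membership,
)
from .simulate import (
    GeneratorConfig,
    generate_cohort,
    generate_responses,
    generate_trace,
    null_config,
)

TIMES = np.arange(0, 11000, 4, dtype=np.int64)

__all__ = [
    "masking_oracle_study",
    "metric_exactness_study",
    "spectral_inversion_study",
    "confound_recovery_study",
    "bias_correction_study",
    "type_one_error_study",
    "structure_recovery_study",
    "scoring_identity_study",
]


# ---------------------------------------------------------------------------
# artifact masking vs brute-force oracle


def _random_artifact_trace(rng) -> PupilTrace:
    areas = 1000.0 + np.cumsum(rng.normal(0.0, 2.0, TIMES.size))
    valid = np.ones(TIMES.size, dtype=bool)
    for _ in range(rng.integers(0, 4)):
        s = rng.integers(0, TIMES.size - 130)
        ln = rng.integers(5, 120)
        areas[s : s + ln] = 0.0
        valid[s : s + ln] = False
    for _ in range(rng.integers(0, 3)):
        j = rng.integers(1, TIMES.size - 1)
        areas[j] += rng.choice([-1.0, 1.0]) * rng.uniform(300.0, 900.0)
    return PupilTrace("t", TIMES, np.maximum(areas, 0.0), valid & (areas > 0))


def _oracle_kept_mask(trace: PupilTrace, pre=50, post=750) -> np.ndarray:
    """Per-sample oracle: flag bad samples, then remove every sample falling
    in any bad sample's margin window directly — no run or merge logic."""
    from .preprocess import _bad_samples

    bad = _bad_samples(trace, 8.0, 0.01)
    step = trace.step_ms
    removed = np.zeros(len(trace), dtype=bool)
    for tb in trace.times_ms[bad]:
        removed |= (trace.times_ms >= tb - pre) & (trace.times_ms < tb + step + post)
    return trace.valid & ~removed


def masking_oracle_study(n_traces: int = 1000, seed: int = 0) -> dict:
    """Compare detect → margin-extend → merge against the per-sample oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_traces):
        tr = _random_artifact_trace(rng)
        masked = apply_artifact_margins(detect_artifacts(tr))
        kept = tr.valid & ~mask_membership(tr.times_ms, masked)
        agree += bool(np.array_equal(kept, _oracle_kept_mask(tr)))
    return {"n_traces": n_traces, "n_agreeing": agree,
            "agreement_rate": agree / n_traces}


# ---------------------------------------------------------------------------
# metric exactness on noiseless traces


def metric_exactness_study(amplitudes=(0.0, 0.1, 0.3, 1.0)) -> dict:
    """Noiseless traces with known log-ratio amplitude R must return
    pupil_max = R; the metric must be invariant to rescaling all areas."""
    rng = np.random.default_rng(0)
    max_err = 0.0
    rescale_err = 0.0
    for amp in amplitudes:
        tr = generate_trace("t", 1400.0, amp, rng, noise_sd=0.0)
        masked = apply_artifact_margins(detect_artifacts(tr))
        b = compute_baseline(tr, masked)
        pm = compute_pupil_max(tr, b, masked)
        max_err = max(max_err, abs(pm - amp))
        for c in (0.25, 7.5):
            scaled = PupilTrace("t", tr.times_ms, tr.areas * c, tr.valid)
            m2 = apply_artifact_margins(detect_artifacts(scaled))
            pm2 = compute_pupil_max(scaled, compute_baseline(scaled, m2), m2)
            rescale_err = max(rescale_err, abs(pm2 - pm))
    return {"max_abs_error": max_err, "rescale_max_abs_error": rescale_err}


# ---------------------------------------------------------------------------
# spectral inversion identities


def spectral_inversion_study(n_waveforms: int = 100, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    max_double_err = 0.0
    max_energy_drift = 0.0
    for _ in range(n_waveforms):
        w = Waveform(rng.uniform(-1, 1, int(rng.integers(16, 4096))), 44100)
        twice = spectral_invert(spectral_invert(w))
        max_double_err = max(
            max_double_err, float(np.max(np.abs(twice.samples - w.samples)))
        )
        once = spectral_invert(w)
        e0, e1 = float(np.sum(w.samples**2)), float(np.sum(once.samples**2))
        max_energy_drift = max(max_energy_drift, abs(e1 - e0) / e0)
    t = np.arange(88200) / 44100.0
    tone = Waveform(0.5 * np.sin(2 * np.pi * 5000.0 * t), 44100)
    spec = np.abs(np.fft.rfft(spectral_invert(tone).samples))
    peak_hz = float(np.fft.rfftfreq(len(tone), d=1 / 44100.0)[np.argmax(spec)])
    return {
        "n_waveforms": n_waveforms,
        "max_double_inversion_error": max_double_err,
        "max_energy_rel_drift": max_energy_drift,
        "tone_5000hz_maps_to_hz": peak_hz,
    }


# ---------------------------------------------------------------------------
# confound-beta recovery (REML CI coverage + residualisation)


def _recovery_config(beta_loud: float) -> GeneratorConfig:
    base = null_config().to_dict()
    base.update(group_sizes={"control": 20}, beta_loudness=beta_loud)
    return GeneratorConfig.from_dict(base)


def confound_recovery_study(
    n_sims: int = 200, seed: int = 0, beta_loud: float = 0.02
) -> dict:
    """20 participants × 20 sounds × 2 repeats with a known loudness effect:
    CI coverage of the REML estimate and slope of adjusted responses on
    loudness (should be indistinguishable from zero)."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, n_sims)
    covered = 0
    betas = []
    slope_ok = 0
    slopes = []
    for s in sim_seeds:
        resp, parts, sounds, truth, _ = generate_responses(
            _recovery_config(beta_loud), int(s)
        )
        cov = pipeline.build_sound_covariates(resp, parts, sounds)
        fit = confound.fit_crossed_mixed_model(resp, cov)
        lo, hi = fit.conf_int("peak_db")
        covered += bool(lo <= beta_loud <= hi)
        betas.append(fit.betas["peak_db"])
        adjusted = confound.adjust_pupil_max(
            resp, confound.compute_sound_adjustments(fit, cov)
        )
        per_sound = (
            adjusted.groupby("sound_id")["pupil_max_adjusted"]
            .mean()
            .rename("y")
            .reset_index()
            .merge(cov[["sound_id", "peak_db"]], on="sound_id")
        )
        ols = smf.ols("y ~ peak_db", data=per_sound).fit()
        slopes.append(float(ols.params["peak_db"]))
        slope_ok += bool(abs(ols.params["peak_db"]) < 2 * ols.bse["peak_db"])
    slopes = np.asarray(slopes)
    return {
        "n_sims": n_sims,
        "true_beta": beta_loud,
        "ci_coverage": covered / n_sims,
        "mean_beta": float(np.mean(betas)),
        "mean_residual_slope": float(slopes.mean()),
        "residual_slope_se_of_mean": float(slopes.std(ddof=1) / np.sqrt(n_sims)),
        "mean_abs_residual_slope": float(np.mean(np.abs(slopes))),
        "residual_slope_within_2se_rate": slope_ok / n_sims,
    }


# ---------------------------------------------------------------------------
# differential-bias correction under the loudness imbalance


def bias_correction_study(n_sims: int = 200, seed: int = 0) -> dict:
    """Full-cohort records with M− sounds 6 dB louder and beta_loud > 0:
    adjusted group differentials should be unbiased, unadjusted ones not."""
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, n_sims)
    cfg = GeneratorConfig()  # defaults carry the 6 dB offset and beta_loud=0.02
    acc: dict[str, dict[str, list]] = {}
    for s in sim_seeds:
        resp, parts, sounds, truth, _ = generate_responses(cfg, int(s))
        cov = pipeline.build_sound_covariates(resp, parts, sounds)
        fit = confound.fit_crossed_mixed_model(resp, cov)
        adjusted = confound.adjust_pupil_max(
            resp, confound.compute_sound_adjustments(fit, cov)
        )
        summ_adj = groups.summarize_participants(adjusted, parts)
        summ_raw = groups.summarize_participants(
            adjusted, parts, value_col="pupil_max"
        )
        true_by_group = truth.participants.groupby("group")["true_differential"].mean()
        adj_by_group = summ_adj.groupby("group")["differential"].mean()
        raw_by_group = summ_raw.groupby("group")["differential"].mean()
        for g in true_by_group.index:
            d = acc.setdefault(g, {"true": [], "adj_err": [], "raw_err": []})
            d["true"].append(float(true_by_group[g]))
            d["adj_err"].append(float(adj_by_group[g] - true_by_group[g]))
            d["raw_err"].append(float(raw_by_group[g] - true_by_group[g]))
    out = {"n_sims": n_sims, "groups": {}}
    for g, d in acc.items():
        truth_mean = float(np.mean(d["true"]))
        out["groups"][g] = {
            "true_differential": truth_mean,
            "adjusted_mean_error": float(np.mean(d["adj_err"])),
            "unadjusted_mean_error": float(np.mean(d["raw_err"])),
            "adjusted_rel_error": float(abs(np.mean(d["adj_err"])) / abs(truth_mean)),
            "unadjusted_rel_error": float(
                abs(np.mean(d["raw_err"])) / abs(truth_mean)
            ),
        }
    rels = [v["adjusted_rel_error"] for v in out["groups"].values()]
    out["max_adjusted_rel_error"] = max(rels)
    out["min_unadjusted_rel_error"] = min(
        v["unadjusted_rel_error"] for v in out["groups"].values()
    )
    return out


# ---------------------------------------------------------------------------
# type-I error calibration


def type_one_error_study(n_sims: int = 1000, seed: int = 0) -> dict:
    """Null condition effects at study-scale group sizes: per-group paired
    t-tests and nuisance-adjusted group contrasts should reject at ~5%."""
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, n_sims)
    cfg = null_config()
    paired_rej = {g: 0 for g in cfg.group_sizes}
    contrast_rej: dict[str, int] = {}
    for s in sim_seeds:
        resp, parts, _, _, _ = generate_responses(cfg, int(s))
        summ = groups.summarize_participants(resp, parts, value_col="pupil_max")
        for g in paired_rej:
            paired_rej[g] += groups.paired_condition_test(summ, g)["p"] < 0.05
        contrasts = groups.group_differential_contrast(summ)
        for _, row in contrasts.iterrows():
            contrast_rej[row["group"]] = contrast_rej.get(row["group"], 0) + int(
                row["p"] < 0.05
            )
    return {
        "n_sims": n_sims,
        "paired_rejection_rate": {g: r / n_sims for g, r in paired_rej.items()},
        "contrast_rejection_rate": {g: r / n_sims for g, r in contrast_rej.items()},
    }


# ---------------------------------------------------------------------------
# qualitative structure recovery, end to end through traces


def structure_recovery_study(n_seeds: int = 100, seed: int = 0) -> dict:
    """Trace-level pipeline on default cohorts: does each seed reproduce the
    study's qualitative pattern?  (i) positive M+ − M− differentials in every
    patient group, (ii) larger differentials in SD and AD than controls,
    (iii) a negative score–differential slope across the patient cohort."""
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, n_seeds)
    cfg = GeneratorConfig()
    n_pass = 0
    comp = {"patient_differentials_positive": 0, "sd_ad_exceed_controls": 0,
            "semantic_slope_negative": 0}
    for s in sim_seeds:
        cohort = generate_cohort(cfg, int(s))
        responses = pipeline.preprocess_cohort(cohort.traces, cohort.trials)
        cov = pipeline.build_sound_covariates(
            cohort.trials, cohort.participants, cohort.sounds
        )
        result = pipeline.analyze_responses(responses, cohort.participants, cov)
        summ = result["summaries"]
        by_group = summ.loc[~summ["excluded"]].groupby("group")["differential"].mean()
        ok1 = all(by_group[g] > 0 for g in ("bvFTD", "SD", "PNFA", "AD"))
        contrasts = result["group_contrasts"].set_index("group")
        ok2 = contrasts.loc["SD", "contrast"] > 0 and contrasts.loc["AD", "contrast"] > 0
        ok3 = result["semantic_correlation"]["slope"] < 0
        comp["patient_differentials_positive"] += ok1
        comp["sd_ad_exceed_controls"] += ok2
        comp["semantic_slope_negative"] += ok3
        n_pass += ok1 and ok2 and ok3
    return {
        "n_seeds": n_seeds,
        "recovery_rate": n_pass / n_seeds,
        "component_rates": {k: v / n_seeds for k, v in comp.items()},
    }


# ---------------------------------------------------------------------------
# semantic-task scoring identities


def scoring_identity_study() -> dict:
    from .semantic import make_classification_key, score_classification, validate_key

    key = validate_key(make_classification_key())
    all_diff = pd.DataFrame(
        {"participant_id": "p", "pair_id": key["pair_id"], "response": "different"}
    )
    scores = score_classification(all_diff, key)
    rng = np.random.default_rng(0)
    partition_holds = True
    for i in range(50):
        resp = pd.DataFrame(
            {
                "participant_id": f"r{i}",
                "pair_id": key["pair_id"],
                "response": rng.choice(["same", "different"], len(key)),
            }
        )
        sc = score_classification(resp, key)
        merged = resp.merge(key, on="pair_id")
        correct = merged["response"] == merged["truth"]
        flagged = merged["contains_pupillometry_sound"].astype(bool)
        partition_holds &= (
            int(sc.loc[0, "total_score"])
            == int(sc.loc[0, "subset_score"]) + int(correct[~flagged].sum())
        )
    return {
        "n_pairs": len(key),
        "n_same": int((key["truth"] == "same").sum()),
        "n_different": int((key["truth"] == "different").sum()),
        "n_pupillometry_subset": int(key["contains_pupillometry_sound"].sum()),
        "all_different_responder_score": int(scores.loc[0, "total_score"]),
        "partition_identity_holds": bool(partition_holds),
    }
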