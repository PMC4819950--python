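"""Synthetic pupillometry experiments with known ground truth.

The study's patient data are not deposited, so every pipeline stage is
validated against cohorts generated here: five participant groups (healthy
controls and four dementia syndromes at the study's sizes 20/13/11/6/10), ten
meaningful and ten meaningless sounds with loudness/valence/arousal
covariates, per-participant 40-trial randomised playlists, per-trial pupil
traces with blinks, post-trial ratings, and semantic classification scores
coupled to the physiological ground truth.

The generative model lives natively on the pupil_max (log-ratio) scale.  The
systematic amplitude of trial *t* for participant *i*, sound *s* is

    R = alpha[group, condition] + u_i ± delta_i/2 + w_s
        + b_loud (L_s − L̄) + b_pleas (P_s − P̄) + b_arous (A_s − Ā)
        + habituation[group, condition] · (presentation_index − 1)

with u_i a participant intercept, delta_i the participant's deviation of the
M+ − M− differential (split ±half between conditions), w_s a sound intercept,
and the covariate terms the confound loadings the adjustment stage must
remove.  The observed trial amplitude adds N(0, residual_sd).  A trace is
rendered multiplicatively,

    area(t) = B · exp(R · g(t)) · (1 + eps(t)),

where B is the trial baseline (with a per-group linear drift over the
session), g a gamma-density kernel rising from sound onset (2000 ms) with its
grid maximum normalised to exactly 1, and eps Gaussian measurement noise —
so with eps = 0 and no blinks the preprocessing pipeline recovers pupil_max
= R to machine precision.  Semantic scores follow

    score_i = s0[group] − kappa · (true differential_i − group mean) ,

realised as binomially scored per-pair responses and clipped to [0, 60]:
worse semantic competence, larger excess response to meaningful sounds.

Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import main_trial_order
from .preprocess import PupilTrace, write_pupil_samples
from .semantic import make_classification_key

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticCohort",
    "null_config",
    "generate_responses",
    "generate_trace",
    "inject_blinks",
    "generate_cohort",
]

TRACE_TIMES_MS = np.arange(0, 11000, 4, dtype=np.int64)
SOUND_ONSET_MS = 2000


def _default_group_sizes():
    return {"control": 20, "bvFTD": 13, "SD": 11, "PNFA": 6, "AD": 10}


def _default_amplitudes():
    # (M+, M−) evoked log-ratio amplitudes per group: the semantic-salience
    # excess is largest in SD and AD, intermediate in bvFTD and PNFA, and a
    # trend-level 0.02 in controls
    return {
        "control": {"M+": 0.22, "M-": 0.20},
        "bvFTD": {"M+": 0.25, "M-": 0.20},
        "SD": {"M+": 0.32, "M-": 0.20},
        "PNFA": {"M+": 0.25, "M-": 0.20},
        "AD": {"M+": 0.32, "M-": 0.20},
    }


def _default_habituation():
    # controls habituate to meaningless sounds, the AD group to meaningful ones
    return {"control": {"M-": -0.001}, "AD": {"M+": -0.001}}


def _default_drift():
    # baseline pupil size rises over the session in the PNFA-like group only
    return {"PNFA": 2.0}


def _default_semantic_baseline():
    return {"control": 58.0, "bvFTD": 48.0, "SD": 50.0, "PNFA": 56.0, "AD": 51.0}


def _default_gender_counts():
    # m:f per group
    return {"control": (10, 10), "bvFTD": (11, 2), "SD": (7, 4), "PNFA": (1, 5),
            "AD": (5, 5)}


def _default_education():
    return {"control": 16.9, "bvFTD": 14.8, "SD": 14.7, "PNFA": 18.0, "AD": 15.2}


def _default_duration():
    return {"bvFTD": 7.5, "SD": 5.2, "PNFA": 5.7, "AD": 5.8}


def _default_span():
    return {"control": 5.5, "bvFTD": 4.5, "SD": 5.6, "PNFA": 4.2, "AD": 5.3}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic experiment (defaults are the study conditions)."""

    group_sizes: dict = field(default_factory=_default_group_sizes)
    n_sounds_per_condition: int = 10
    n_repeats: int = 2

    # trace construction
    baseline_mean: float = 1200.0  # device units
    baseline_sd: float = 150.0  # between participants
    baseline_trial_jitter_sd: float = 30.0  # trial-to-trial baseline wander
    kernel_shape: float = 2.0
    kernel_peak_ms: float = 930.0  # dilation peak latency after sound onset
    noise_sd: float = 0.02  # multiplicative per-sample measurement noise
    blink_rate: float = 1.5  # mean blinks per trial (Poisson)
    blink_duration_ms: tuple = (100.0, 300.0)  # uniform

    # pupil_max-scale effects
    condition_amplitudes: dict = field(default_factory=_default_amplitudes)
    participant_intercept_sd: float = 0.05
    participant_differential_sd: float = 0.03
    sound_intercept_sd: float = 0.02
    residual_sd: float = 0.08
    habituation_slopes: dict = field(default_factory=_default_habituation)
    baseline_drift: dict = field(default_factory=_default_drift)  # units / trial

    # confound structure
    beta_loudness: float = 0.02  # pupil_max units per dB peak level
    beta_pleasantness: float = 0.01  # per rating unit
    beta_arousal: float = 0.015  # per rating unit
    mplus_peak_db_mean: float = -14.0
    peak_db_sd: float = 3.0
    mminus_peak_db_offset: float = 6.0  # M− sounds are this much louder
    pleasantness_mplus_mean: float = 6.0
    pleasantness_mminus_mean: float = 4.5  # M− rated less pleasant
    arousal_mean: float = 5.0
    rating_sd_sounds: float = 1.0
    rating_noise_sd: float = 1.0
    rating_scale: tuple = (0.0, 10.0)

    # demographics (per-group means; Table-style conventions)
    gender_counts: dict = field(default_factory=_default_gender_counts)
    education_means: dict = field(default_factory=_default_education)
    duration_means: dict = field(default_factory=_default_duration)
    span_means: dict = field(default_factory=_default_span)

    # semantic task coupling
    semantic_baseline: dict = field(default_factory=_default_semantic_baseline)
    semantic_coupling: float = 160.0  # kappa: score points per unit differential

    def validate(self) -> "GeneratorConfig":
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for name in ("baseline_sd", "noise_sd", "residual_sd", "blink_rate",
                     "participant_intercept_sd", "sound_intercept_sd",
                     "participant_differential_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = set(self.group_sizes) - set(self.condition_amplitudes)
        if missing:
            raise ValueError(f"no condition amplitudes for groups {sorted(missing)}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()


def null_config(**overrides) -> GeneratorConfig:
    """Study-scale config with every structural effect switched off.

    Equal evoked amplitudes in both conditions for every group, no confound
    loadings, no sound intercepts, no habituation, no baseline drift, no
    semantic coupling — for type-I-error calibration of the group tests.
    Sound intercepts must be off for a clean null: with only ten sounds per
    condition, a realised imbalance of random sound effects between the M+
    and M− sets acts as a shared condition effect across participants.
    """
    amps = {g: {"M+": 0.2, "M-": 0.2} for g in _default_group_sizes()}
    cfg = GeneratorConfig(
        condition_amplitudes=amps,
        beta_loudness=0.0,
        beta_pleasantness=0.0,
        beta_arousal=0.0,
        sound_intercept_sd=0.0,
        habituation_slopes={},
        baseline_drift={},
        semantic_coupling=0.0,
        **overrides,
    )
    return cfg.validate()


@dataclass
class GroundTruth:
    """Realised generator state: what recovery tests compare against."""

    config: GeneratorConfig
    participants: pd.DataFrame  # u, delta, baseline, true_differential, target_score
    sounds: pd.DataFrame  # intercepts and true covariates
    trials: pd.DataFrame  # systematic amplitude, observed amplitude, true baseline
    blink_intervals: dict = field(default_factory=dict)  # trial_id -> [(s, e) ms]

    def to_json(self, path) -> None:
        payload = {
            "config": _jsonable(self.config.to_dict()),
            "participants": self.participants.to_dict(orient="list"),
            "sounds": self.sounds.to_dict(orient="list"),
            "trials": self.trials.to_dict(orient="list"),
            "blink_intervals": {k: [list(iv) for iv in v]
                                for k, v in self.blink_intervals.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# record-level generation


def _generate_sounds(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_sounds_per_condition
    ids = [f"m{i:02d}" for i in range(1, n + 1)] + [f"x{i:02d}" for i in range(1, n + 1)]
    cond = ["M+"] * n + ["M-"] * n
    is_minus = np.array([c == "M-" for c in cond])
    peak = (
        config.mplus_peak_db_mean
        + rng.normal(0.0, config.peak_db_sd, 2 * n)
        + np.where(is_minus, config.mminus_peak_db_offset, 0.0)
    )
    lo, hi = config.rating_scale
    pleas = np.clip(
        np.where(is_minus, config.pleasantness_mminus_mean, config.pleasantness_mplus_mean)
        + rng.normal(0.0, config.rating_sd_sounds, 2 * n),
        lo, hi,
    )
    arous = np.clip(
        config.arousal_mean + rng.normal(0.0, config.rating_sd_sounds, 2 * n), lo, hi
    )
    return pd.DataFrame(
        {
            "sound_id": ids,
            "condition": cond,
            "peak_db": peak,
            "true_pleasantness": pleas,
            "true_arousal": arous,
            "sound_intercept": rng.normal(0.0, config.sound_intercept_sd, 2 * n),
        }
    )


def _generate_participants(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for group, size in config.group_sizes.items():
        n_m, n_f = config.gender_counts.get(group, (size // 2, size - size // 2))
        genders = (["m"] * n_m + ["f"] * n_f)[:size]
        while len(genders) < size:
            genders.append("f")
        edu = np.clip(
            rng.normal(config.education_means.get(group, 16.0), 2.0, size), 11, 21
        )
        dur_mean = config.duration_means.get(group)
        dur = (
            np.clip(rng.normal(dur_mean, 2.0, size), 1.0, None)
            if dur_mean is not None
            else np.full(size, np.nan)
        )
        span = np.clip(rng.normal(config.span_means.get(group, 5.0), 1.0, size), 2, 9)
        for j in range(size):
            idx += 1
            rows.append(
                {
                    "participant_id": f"P{idx:03d}",
                    "group": group,
                    "gender": genders[j],
                    "education_y": float(edu[j]),
                    "symptom_duration_y": float(dur[j]),
                    "reverse_spatial_span": float(span[j]),
                    # all AD patients on cholinesterase inhibitors; a few
                    # antidepressant users scattered per the study's counts
                    "on_achei": int(group == "AD"),
                    "on_antidepressant": int(
                        (group == "SD" and j < 2)
                        or (group == "PNFA" and j < 1)
                        or (group == "AD" and j < 1)
                    ),
                }
            )
    df = pd.DataFrame(rows)
    df["baseline"] = np.clip(
        rng.normal(config.baseline_mean, config.baseline_sd, len(df)), 300.0, None
    )
    df["u"] = rng.normal(0.0, config.participant_intercept_sd, len(df))
    df["delta"] = rng.normal(0.0, config.participant_differential_sd, len(df))
    return df


def _generate_trials(
    config: GeneratorConfig,
    participants: pd.DataFrame,
    sounds: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-participant randomised playlists with systematic + observed amplitudes.

    Each participant's main-trial order is the same seeded uniform
    permutation of the 2×(10+10) (sound, repetition) slots that
    :func:`~pupilsem.audio.build_playlist` uses.
    """
    lo, hi = config.rating_scale
    n_slots = len(sounds) * config.n_repeats
    # per-slot sound attributes (each sound occupies n_repeats slots)
    slot_sound = np.repeat(np.arange(len(sounds)), config.n_repeats)
    sound_ids = sounds["sound_id"].to_numpy()
    cond_by_sound = sounds["condition"].to_numpy()
    confound_by_sound = (
        config.beta_loudness * (sounds["peak_db"] - sounds["peak_db"].mean())
        + config.beta_pleasantness
        * (sounds["true_pleasantness"] - sounds["true_pleasantness"].mean())
        + config.beta_arousal
        * (sounds["true_arousal"] - sounds["true_arousal"].mean())
    ).to_numpy()
    intercept_by_sound = sounds["sound_intercept"].to_numpy()
    pleas_by_sound = sounds["true_pleasantness"].to_numpy()
    arous_by_sound = sounds["true_arousal"].to_numpy()

    cols: dict[str, list] = {name: [] for name in (
        "trial_id", "participant_id", "group", "sound_id", "condition",
        "presentation_index", "pleasantness", "arousal", "intrinsic_amplitude",
        "confound_term", "systematic_amplitude", "true_pupil_max", "baseline_true",
    )}
    idx = np.arange(1, n_slots + 1, dtype=float)
    for prow in participants.itertuples():
        playlist_seed = int(rng.integers(0, 2**31 - 1))
        order = main_trial_order(n_slots, playlist_seed)
        s = slot_sound[order]
        g = prow.group
        amps = config.condition_amplitudes[g]
        hab = config.habituation_slopes.get(g, {})
        cond = cond_by_sound[s]
        is_plus = cond == "M+"
        amp = np.where(is_plus, amps["M+"], amps["M-"])
        hab_slope = np.where(is_plus, hab.get("M+", 0.0), hab.get("M-", 0.0))
        sign = np.where(is_plus, 0.5, -0.5)
        # intrinsic = what confound adjustment should leave intact
        intrinsic = (
            amp + prow.u + sign * prow.delta + intercept_by_sound[s]
            + hab_slope * (idx - 1.0)
        )
        confound = confound_by_sound[s]
        systematic = intrinsic + confound
        observed = systematic + rng.normal(0.0, config.residual_sd, n_slots)
        base = (
            prow.baseline
            + config.baseline_drift.get(g, 0.0) * (idx - 1.0)
            + rng.normal(0.0, config.baseline_trial_jitter_sd, n_slots)
        )
        pleas = np.clip(
            pleas_by_sound[s] + rng.normal(0.0, config.rating_noise_sd, n_slots),
            lo, hi,
        )
        arous = np.clip(
            arous_by_sound[s] + rng.normal(0.0, config.rating_noise_sd, n_slots),
            lo, hi,
        )
        cols["trial_id"].append(
            np.array([f"{prow.participant_id}_t{i:02d}" for i in range(1, n_slots + 1)])
        )
        cols["participant_id"].append(np.repeat(prow.participant_id, n_slots))
        cols["group"].append(np.repeat(g, n_slots))
        cols["sound_id"].append(sound_ids[s])
        cols["condition"].append(cond)
        cols["presentation_index"].append(idx.astype(int))
        cols["pleasantness"].append(pleas)
        cols["arousal"].append(arous)
        cols["intrinsic_amplitude"].append(intrinsic)
        cols["confound_term"].append(confound)
        cols["systematic_amplitude"].append(systematic)
        cols["true_pupil_max"].append(observed)
        cols["baseline_true"].append(base)
    return pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})


def _semantic_scores(
    config: GeneratorConfig,
    participants: pd.DataFrame,
    truth_trials: pd.DataFrame,
    rng: np.random.Generator,
):
    """Target scores coupled to the true differential, realised binomially."""
    per_part = (
        truth_trials.pivot_table(
            index="participant_id", columns="condition", values="intrinsic_amplitude"
        )
    )
    true_diff = (per_part["M+"] - per_part["M-"]).reindex(
        participants["participant_id"]
    )
    groups = participants.set_index("participant_id")["group"]
    group_mean = true_diff.groupby(groups).transform("mean")
    s0 = groups.map(config.semantic_baseline).astype(float)
    target = s0 - config.semantic_coupling * (true_diff - group_mean)
    p_correct = np.clip(target / 60.0, 0.02, 0.999)

    key = make_classification_key()
    n_pairs = len(key)
    n_part = len(participants)
    correct = rng.random((n_part, n_pairs)) < np.asarray(p_correct)[:, None]
    truths = key["truth"].to_numpy()
    flipped = np.where(truths == "same", "different", "same")
    responses = pd.DataFrame(
        {
            "participant_id": np.repeat(
                participants["participant_id"].to_numpy(), n_pairs
            ),
            "pair_id": np.tile(key["pair_id"].to_numpy(), n_part),
            "response": np.where(
                correct, np.tile(truths, (n_part, 1)), np.tile(flipped, (n_part, 1))
            ).ravel(),
        }
    )
    scores = correct.sum(axis=1).astype(int)
    return key, responses, scores, true_diff.to_numpy(), target.to_numpy()


def generate_responses(config: GeneratorConfig, seed: int):
    """Record-level synthetic experiment (no traces).

    Returns ``(responses, participants, sounds, truth)``: ``responses`` is a
    ResponseRecord-style table whose pupil_max is the observed trial
    amplitude (systematic + residual), i.e. what an ideal trace measurement
    would recover — the fast path for simulation studies of the adjustment
    and inference stages.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    r_sounds, r_parts, r_trials, r_task = [np.random.default_rng(s)
                                           for s in ss.spawn(4)]
    sounds = _generate_sounds(config, r_sounds)
    participants = _generate_participants(config, r_parts)
    trials = _generate_trials(config, participants, sounds, r_trials)
    key, task_responses, scores, true_diff, target = _semantic_scores(
        config, participants, trials, r_task
    )
    participants = participants.copy()
    participants["semantic_score"] = scores

    responses = trials[
        [
            "trial_id", "participant_id", "group", "sound_id", "condition",
            "presentation_index", "pleasantness", "arousal",
        ]
    ].copy()
    responses["baseline"] = trials["baseline_true"]
    responses["pupil_max"] = trials["true_pupil_max"]
    responses["artifact_fraction"] = 0.0
    responses["excluded"] = False

    truth_participants = participants[
        ["participant_id", "group", "baseline", "u", "delta"]
    ].copy()
    truth_participants["true_differential"] = true_diff
    truth_participants["target_score"] = target
    truth = GroundTruth(
        config=config,
        participants=truth_participants,
        sounds=sounds,
        trials=trials[
            [
                "trial_id", "intrinsic_amplitude", "confound_term",
                "systematic_amplitude", "true_pupil_max", "baseline_true",
            ]
        ],
    )
    public_participants = participants.drop(columns=["baseline", "u", "delta"])
    extras = {"key": key, "task_responses": task_responses}
    return responses, public_participants, sounds, truth, extras


# ---------------------------------------------------------------------------
# trace rendering


def response_kernel(
    times_ms: np.ndarray = TRACE_TIMES_MS,
    onset_ms: float = SOUND_ONSET_MS,
    shape: float = 2.0,
    peak_ms: float = 930.0,
) -> np.ndarray:
    """Gamma-density dilation kernel on the sample grid, grid-max exactly 1."""
    t = np.maximum(times_ms.astype(np.float64) - onset_ms, 0.0)
    scale = peak_ms / (shape - 1.0) if shape > 1.0 else peak_ms
    x = t / scale
    h = np.where(t > 0, x ** (shape - 1.0) * np.exp(-x), 0.0)
    return h / h.max()


def generate_trace(
    trial_id: str,
    baseline: float,
    amplitude: float,
    rng: np.random.Generator,
    noise_sd: float = 0.02,
    kernel: np.ndarray | None = None,
) -> PupilTrace:
    """Render one trial's pupil trace: area = B·exp(R·g(t))·(1 + eps)."""
    if kernel is None:
        kernel = response_kernel()
    area = baseline * np.exp(amplitude * kernel)
    if noise_sd > 0:
        area = area * (1.0 + rng.normal(0.0, noise_sd, area.size))
    if np.any(area <= 0):
        raise ValueError(f"trial {trial_id}: nonpositive pupil area generated")
    return PupilTrace(trial_id, TRACE_TIMES_MS.copy(), area,
                      np.ones(area.size, dtype=bool))


def inject_blinks(
    trace: PupilTrace,
    rate: float,
    duration_ms: tuple = (100.0, 300.0),
    rng: np.random.Generator | None = None,
) -> tuple[PupilTrace, list[tuple[int, int]]]:
    """Zero out Poisson(rate) blink events, each bracketed by 2-sample steep
    ramps (the characteristic blink trajectory); returns the injected
    zeroed intervals for ground-truth comparison."""
    if rate < 0:
        raise ValueError("blink rate must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    n_blinks = rng.poisson(rate)
    areas = trace.areas.copy()
    valid = trace.valid.copy()
    intervals: list[tuple[int, int]] = []
    step = trace.step_ms
    lo, hi = duration_ms
    for _ in range(n_blinks):
        dur = rng.uniform(lo, hi)
        start = rng.uniform(trace.times_ms[0], trace.times_ms[-1] + step - dur)
        i0 = int(np.searchsorted(trace.times_ms, start))
        i1 = int(np.searchsorted(trace.times_ms, start + dur))
        if i1 <= i0:
            continue
        areas[i0:i1] = 0.0
        valid[i0:i1] = False
        for off, frac in ((-2, 0.55), (-1, 0.2)):  # closing ramp
            j = i0 + off
            if 0 <= j < len(areas) and valid[j]:
                areas[j] *= frac
        for off, frac in ((0, 0.2), (1, 0.55)):  # reopening ramp
            j = i1 + off
            if 0 <= j < len(areas) and valid[j]:
                areas[j] *= frac
        intervals.append(
            (int(trace.times_ms[i0]), int(trace.times_ms[i1 - 1]) + step)
        )
    return (
        PupilTrace(trace.trial_id, trace.times_ms, areas, valid),
        sorted(intervals),
    )


@dataclass
class SyntheticCohort:
    """A complete synthetic experiment: every file dialect the pipeline consumes."""

    participants: pd.DataFrame
    sounds: pd.DataFrame
    trials: pd.DataFrame  # metadata only (no truth columns)
    traces: list  # PupilTrace, aligned with trials rows
    task_key: pd.DataFrame
    task_responses: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.sounds.drop(columns=["sound_intercept"]).to_csv(
            out / "sounds.csv", index=False
        )
        self.trials.to_csv(out / "trials.csv", index=False)
        write_pupil_samples(out / "samples.tsv", self.traces)
        self.task_key.to_csv(out / "task_key.csv", index=False)
        self.task_responses.to_csv(out / "task_responses.csv", index=False)
        self.truth.to_json(out / "ground_truth.json")


def generate_cohort(config: GeneratorConfig, seed: int) -> SyntheticCohort:
    """Generate the full experiment including rendered pupil traces.

    Record-level truth comes from :func:`generate_responses` with the same
    seed; traces are rendered so that, absent noise and blinks, the
    preprocessing pipeline recovers each trial's observed amplitude exactly.
    """
    responses, participants, sounds, truth, extras = generate_responses(config, seed)
    trials = responses.drop(columns=["baseline", "pupil_max",
                                     "artifact_fraction", "excluded"])
    kernel = response_kernel(
        shape=config.kernel_shape, peak_ms=config.kernel_peak_ms
    )
    trace_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])

    n = len(trials)
    base = truth.trials["baseline_true"].to_numpy()
    amp = truth.trials["true_pupil_max"].to_numpy()
    # vectorised rendering of all trials at once
    areas = base[:, None] * np.exp(amp[:, None] * kernel[None, :])
    if config.noise_sd > 0:
        areas = areas * (1.0 + trace_rng.normal(0.0, config.noise_sd, areas.shape))
    if np.any(areas <= 0):
        raise ValueError("nonpositive pupil area generated; check noise_sd")

    traces = []
    blink_intervals = {}
    ones = np.ones(areas.shape[1], dtype=bool)
    for i, trial_id in enumerate(trials["trial_id"]):
        tr = PupilTrace(trial_id, TRACE_TIMES_MS.copy(), areas[i], ones.copy())
        tr, injected = inject_blinks(
            tr, config.blink_rate, config.blink_duration_ms, trace_rng
        )
        traces.append(tr)
        blink_intervals[trial_id] = injected
    truth.blink_intervals = blink_intervals
    return SyntheticCohort(
        participants=participants,
        sounds=sounds,
        trials=trials,
        traces=traces,
        task_key=extras["key"],
        task_responses=extras["task_responses"],
        truth=truth,
    )
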