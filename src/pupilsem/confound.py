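"""Loudness/valence/arousal confound adjustment of pupil responses.

Peak loudness, pleasantness and arousal all drive pupil dilation on their
own, and the meaningless (M−) stimuli are systematically louder and less
pleasant than their meaningful (M+) counterparts, so the raw M+ − M−
differential is confounded.  This stage estimates the average per-unit effect
of each covariate on pupil_max with a linear mixed model — random intercepts
for participant and for sound, crossed, REML — and then removes a per-sound
constant

    adjustment_s = b_loud (L_s − L̄) + b_pleas (P_s − P̄) + b_arous (A_s − Ā)

from every crude response to that sound.  Covariates are sound-level:
measured peak level (dBFS) and the control group's mean ratings.  Because
they are centred at the stimulus-set mean, the adjustments sum to ~0 and the
grand-mean response is preserved; within-sound variance is untouched.

The fitted model also carries a sound-condition (M+/M−) fixed effect.
Without it the condition effect itself would load onto the covariate slopes
(condition and loudness are deliberately correlated in this design) and the
"adjustment" would cancel part of the real differential; with it the three
confound betas are estimated from within-condition covariate variation and
the correction leaves the semantic effect intact.  The condition coefficient
is never part of the adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedlm import RandomInterceptsFit, fit_random_intercepts

__all__ = [
    "ConfoundFit",
    "summarize_control_ratings",
    "fit_crossed_mixed_model",
    "compute_sound_adjustments",
    "adjust_pupil_max",
]

CONFOUND_COVARIATES = ("peak_db", "pleasantness_mean", "arousal_mean")


@dataclass
class ConfoundFit:
    """Fixed-effect confound estimates plus the variance decomposition."""

    betas: dict  # covariate -> estimate (pupil_max units per covariate unit)
    se: dict
    vcomp: dict  # 'participant'/'sound' -> random-intercept variance
    sigma2_resid: float
    loglik: float
    n_obs: int
    n_sounds: int
    n_fixed: int
    raw: RandomInterceptsFit = field(repr=False, default=None)

    def conf_int(self, covariate: str, alpha: float = 0.05) -> tuple[float, float]:
        """t interval for one confound beta.

        The confound covariates vary only between sounds, so the effective
        replication is the number of sounds: the t quantile uses
        ``n_sounds − n_fixed`` degrees of freedom, not the residual df.
        """
        ci = self.raw.conf_int(alpha=alpha, df=max(self.n_sounds - self.n_fixed, 1))
        return float(ci.loc[covariate, "lower"]), float(ci.loc[covariate, "upper"])

    def to_json(self, path) -> None:
        payload = {
            "betas": self.betas,
            "se": self.se,
            "variance_components": self.vcomp,
            "residual_variance": self.sigma2_resid,
            "reml_loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_sounds": self.n_sounds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def summarize_control_ratings(
    trials: pd.DataFrame, participants: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Per-sound mean pleasantness/arousal over control participants' ratings.

    Both presentations of a sound are pooled.  Patient ratings are collected
    but never used for adjustment.  Raises if any sound lacks control
    ratings (no imputation is attempted).
    """
    controls = set(participants.loc[participants["group"] == control_group, "participant_id"])
    if not controls:
        raise ValueError(f"no participants in group '{control_group}'")
    sub = trials[trials["participant_id"].isin(controls)]
    agg = (
        sub.groupby("sound_id")
        .agg(pleasantness_mean=("pleasantness", "mean"), arousal_mean=("arousal", "mean"))
        .reset_index()
    )
    uncovered = sorted(set(trials["sound_id"]) - set(agg["sound_id"]))
    if uncovered:
        raise ValueError(f"sounds with zero control ratings: {uncovered}")
    if agg[["pleasantness_mean", "arousal_mean"]].isna().any().any():
        bad = agg.loc[agg.isna().any(axis=1), "sound_id"].tolist()
        raise ValueError(f"sounds with zero control ratings: {bad}")
    return agg


def fit_crossed_mixed_model(
    responses: pd.DataFrame, covariates: pd.DataFrame
) -> ConfoundFit:
    """REML fit of pupil_max on the three sound-level confound covariates.

    ``responses`` needs columns pupil_max, participant_id, sound_id,
    condition (plus an optional ``excluded`` flag, honoured); ``covariates``
    is the per-sound table with peak_db, pleasantness_mean, arousal_mean.
    Participant and sound random intercepts are crossed.
    """
    df = responses
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    df = df.merge(
        covariates, on="sound_id", how="left", validate="many_to_one", suffixes=("", "_cov")
    )
    for col in CONFOUND_COVARIATES:
        if df[col].isna().any():
            missing = sorted(df.loc[df[col].isna(), "sound_id"].unique())
            raise ValueError(f"missing covariate {col} for sounds {missing}")
    if df["participant_id"].nunique() < 2 or df["sound_id"].nunique() < 2:
        raise ValueError("need >=2 participants and >=2 sounds")

    names = ["intercept", "condition_Mplus", *CONFOUND_COVARIATES]
    X = np.column_stack(
        [
            np.ones(len(df)),
            (df["condition"] == "M+").to_numpy(dtype=float),
            *(df[c].to_numpy(dtype=float) for c in CONFOUND_COVARIATES),
        ]
    )
    fit = fit_random_intercepts(
        df["pupil_max"].to_numpy(dtype=float),
        X,
        groups={"participant": df["participant_id"], "sound": df["sound_id"]},
        param_names=names,
    )
    return ConfoundFit(
        betas={c: float(fit.params[c]) for c in CONFOUND_COVARIATES},
        se={c: float(fit.bse[c]) for c in CONFOUND_COVARIATES},
        vcomp=fit.vcomp,
        sigma2_resid=fit.sigma2_resid,
        loglik=fit.loglik,
        n_obs=fit.n,
        n_sounds=int(df["sound_id"].nunique()),
        n_fixed=len(names),
        raw=fit,
    )


def compute_sound_adjustments(fit: ConfoundFit, covariates: pd.DataFrame) -> pd.Series:
    """Per-sound additive constant implied by the fitted confound betas.

    Each covariate is centred at its unweighted stimulus-set mean, so the
    adjustments sum to ~0 across sounds.
    """
    adj = np.zeros(len(covariates))
    for col in CONFOUND_COVARIATES:
        x = covariates[col].to_numpy(dtype=float)
        adj += fit.betas[col] * (x - x.mean())
    return pd.Series(adj, index=covariates["sound_id"].to_numpy(), name="adjustment")


def adjust_pupil_max(responses: pd.DataFrame, adjustments: pd.Series) -> pd.DataFrame:
    """Subtract each sound's confound constant from the crude responses.

    Adds ``adjustment`` and ``pupil_max_adjusted`` columns; all downstream
    analysis consumes the adjusted values.  Raises when a response's sound
    has no adjustment.
    """
    missing = sorted(set(responses["sound_id"]) - set(adjustments.index))
    if missing:
        raise ValueError(f"no adjustment available for sounds {missing}")
    out = responses.copy()
    out["adjustment"] = out["sound_id"].map(adjustments).astype(float)
    out["pupil_max_adjusted"] = out["pupil_max"] - out["adjustment"]
    return out
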