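"""Group-level inference on adjusted pupil responses.

Participant-level summaries (per-condition mean adjusted pupil_max and their
difference, the *differential response* — the study's headline physiological
signature), paired condition contrasts within groups, regression-adjusted
group comparisons against healthy controls, habituation and baseline-drift
trend tests, and the correlation between the differential response and
nonverbal auditory semantic performance.

Conventions mirror the study's analysis plan: all tests are two-sided with
p < .05 as the significance criterion, no multiplicity correction is applied
across the family of tests (raw p-values are reported so users can correct
post hoc), and group contrasts carry gender and education as nuisance
covariates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

KNOWN_GROUPS = ("control", "bvFTD", "SD", "PNFA", "AD")
PATIENT_GROUPS = ("bvFTD", "SD", "PNFA", "AD")

__all__ = [
    "KNOWN_GROUPS",
    "PATIENT_GROUPS",
    "summarize_participants",
    "paired_condition_test",
    "group_differential_contrast",
    "semantic_correlation",
    "ancillary_correlations",
    "habituation_test",
    "baseline_drift_test",
    "plot_differential_vs_score",
]

_SUMMARY_META = (
    "group",
    "gender",
    "education_y",
    "symptom_duration_y",
    "reverse_spatial_span",
    "on_achei",
    "on_antidepressant",
    "semantic_score",
)


def summarize_participants(
    adjusted: pd.DataFrame,
    participants: pd.DataFrame,
    value_col: str = "pupil_max_adjusted",
    allowed_groups: tuple = KNOWN_GROUPS,
) -> pd.DataFrame:
    """Collapse adjusted trial responses to one row per participant.

    Means are taken only over non-excluded trials.  Participants lacking a
    usable trial in either condition are flagged ``excluded`` with a reason
    (their condition means cannot be compared).  Unknown group labels raise.
    """
    unknown = sorted(set(participants["group"]) - set(allowed_groups))
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    df = adjusted
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    cond_means = (
        df.pivot_table(index="participant_id", columns="condition", values=value_col)
        .rename(columns={"M+": "mean_Mplus", "M-": "mean_Mminus"})
        .reindex(columns=["mean_Mplus", "mean_Mminus"])
    )
    meta_cols = [c for c in _SUMMARY_META if c in participants.columns]
    out = participants.set_index("participant_id")[meta_cols].join(cond_means)
    out["differential"] = out["mean_Mplus"] - out["mean_Mminus"]
    out["overall_reactivity"] = (out["mean_Mplus"] + out["mean_Mminus"]) / 2.0
    out["excluded"] = out["mean_Mplus"].isna() | out["mean_Mminus"].isna()
    out["exclusion_reason"] = np.where(
        out["excluded"], "missing a condition mean", ""
    )
    return out.reset_index()


def paired_condition_test(summaries: pd.DataFrame, group: str) -> dict:
    """Two-sided paired t-test of mean_Mplus vs mean_Mminus within one group."""
    sub = summaries.loc[
        (summaries["group"] == group) & ~summaries["excluded"],
        ["mean_Mplus", "mean_Mminus"],
    ].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"group {group}: need >=3 paired participants, have {n}")
    d = (sub["mean_Mplus"] - sub["mean_Mminus"]).to_numpy()
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(abs(d.mean()), 1.0):  # numerically zero variance
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            warnings.warn(
                f"group {group}: zero-variance nonzero differential; p reported as 0",
                stacklevel=2,
            )
            t, p = float(np.sign(d.mean()) * np.inf), 0.0
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * stats.t.sf(abs(t), n - 1))
    return {"group": group, "n": n, "mean_differential": float(d.mean()), "t": t,
            "df": n - 1, "p": p}


def _nuisance_formula(nuisance: tuple) -> str:
    terms = []
    for term in nuisance:
        terms.append(f"C({term})" if term == "gender" else term)
    return (" + " + " + ".join(terms)) if terms else ""


def _group_ols(
    data: pd.DataFrame,
    response: str,
    reference: str,
    nuisance: tuple,
):
    formula = (
        f"{response} ~ C(group, Treatment(reference='{reference}'))"
        + _nuisance_formula(nuisance)
    )
    fit = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design in group contrast")
    return fit


def group_differential_contrast(
    summaries: pd.DataFrame,
    nuisance: tuple = ("gender", "education_y"),
    response: str = "differential",
    reference: str = "control",
) -> pd.DataFrame:
    """Each patient group's differential response vs controls, nuisance-adjusted.

    Linear regression of the differential on group indicators plus the
    nuisance covariates (gender and education by default — the demographics
    that differed between groups).  Returns one row per non-reference group
    with the adjusted contrast, its SE, t and two-sided p.
    """
    data = summaries.loc[~summaries["excluded"]].dropna(subset=[response])
    if reference not in set(data["group"]):
        raise ValueError(f"reference group '{reference}' absent")
    if data["group"].nunique() < 2:
        raise ValueError("need >=2 groups for a contrast")
    fit = _group_ols(data, response, reference, nuisance)
    rows = []
    prefix = f"C(group, Treatment(reference='{reference}'))[T."
    for name, est in fit.params.items():
        if name.startswith(prefix):
            grp = name[len(prefix) : -1]
            rows.append(
                {
                    "group": grp,
                    "contrast": float(est),
                    "se": float(fit.bse[name]),
                    "t": float(fit.tvalues[name]),
                    "p": float(fit.pvalues[name]),
                    "significant": bool(fit.pvalues[name] < 0.05),
                }
            )
    return pd.DataFrame(rows)


def semantic_correlation(
    summaries: pd.DataFrame,
    scope: str = "patients",
    response: str = "differential",
) -> dict:
    """OLS of the differential response on the semantic classification score.

    ``scope`` is "patients" (combined patient cohort), "all", or one group
    name.  Under the semantic-salience hypothesis the slope is negative: the
    worse the semantic performance, the larger the excess response to
    meaningful sounds.  Returns slope, r², two-sided p and n.
    """
    data = summaries.loc[~summaries["excluded"]].dropna(
        subset=[response, "semantic_score"]
    )
    if scope == "patients":
        data = data[data["group"] != "control"]
    elif scope != "all":
        data = data[data["group"] == scope]
    n = len(data)
    if n < 4:
        raise ValueError(f"scope {scope}: need >=4 scored participants, have {n}")
    if data["semantic_score"].nunique() == 1:
        raise ValueError("semantic score has zero variance")
    fit = smf.ols(f"{response} ~ semantic_score", data=data).fit()
    return {
        "scope": scope,
        "n": n,
        "slope": float(fit.params["semantic_score"]),
        "se": float(fit.bse["semantic_score"]),
        "r2": float(fit.rsquared),
        "p": float(fit.pvalues["semantic_score"]),
    }


def ancillary_correlations(summaries: pd.DataFrame, scope: str = "patients") -> pd.DataFrame:
    """The control correlations the study reports as null.

    Pearson correlations, within the patient cohort by default, of the
    differential response and overall reactivity against disease-severity
    metrics and medication flags, and of overall / per-condition responses
    against the semantic score.
    """
    data = summaries.loc[~summaries["excluded"]]
    if scope == "patients":
        data = data[data["group"] != "control"]
    pairs = [
        ("differential", "symptom_duration_y"),
        ("differential", "reverse_spatial_span"),
        ("differential", "on_achei"),
        ("differential", "on_antidepressant"),
        ("overall_reactivity", "symptom_duration_y"),
        ("overall_reactivity", "reverse_spatial_span"),
        ("overall_reactivity", "on_achei"),
        ("overall_reactivity", "on_antidepressant"),
        ("overall_reactivity", "semantic_score"),
        ("mean_Mplus", "semantic_score"),
        ("mean_Mminus", "semantic_score"),
    ]
    rows = []
    for y, x in pairs:
        if x not in data.columns:
            continue
        sub = data[[y, x]].dropna().astype(float)
        if len(sub) < 4 or sub[x].nunique() < 2:
            continue
        r, p = stats.pearsonr(sub[y], sub[x])
        rows.append({"response": y, "covariate": x, "n": len(sub), "r": float(r),
                     "p": float(p)})
    return pd.DataFrame(rows)


def _within_participant_trend(df: pd.DataFrame, xcol: str, ycol: str) -> dict:
    """OLS slope of y on x with participant fixed effects (within estimator).

    Demeans x and y within participant; the t-test uses
    df = N − (number of participants) − 1, matching the dummy-variable fit.
    """
    if df[xcol].nunique() < 2:
        raise ValueError(f"need >=2 distinct values of {xcol}")
    g = df.groupby("participant_id")
    xd = df[xcol].astype(float) - g[xcol].transform("mean")
    yd = df[ycol].astype(float) - g[ycol].transform("mean")
    sxx = float(np.sum(xd**2))
    if sxx == 0.0:
        raise ValueError(f"no within-participant variation in {xcol}")
    slope = float(np.sum(xd * yd) / sxx)
    resid = yd - slope * xd
    dof = len(df) - df["participant_id"].nunique() - 1
    if dof <= 0:
        raise ValueError("not enough observations for the trend test")
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    t = slope / se if se > 0 else np.inf * np.sign(slope)
    p = float(2 * stats.t.sf(abs(t), dof))
    return {"slope": slope, "se": se, "t": float(t), "df": dof, "p": p,
            "n_obs": len(df)}


def habituation_test(
    adjusted: pd.DataFrame,
    group: str,
    condition: str,
    value_col: str = "pupil_max_adjusted",
) -> dict:
    """Linear trend of the adjusted response over presentation order.

    Per group × condition, regression of the response on presentation index
    (1..40) with participant fixed effects absorbing individual reactivity.
    A significantly negative slope is reported as habituation (attenuation of
    the evoked response over the session).
    """
    df = adjusted
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    df = df[(df["group"] == group) & (df["condition"] == condition)].dropna(
        subset=[value_col]
    )
    res = _within_participant_trend(df, "presentation_index", value_col)
    res.update(
        group=group,
        condition=condition,
        attenuation=bool(res["slope"] < 0 and res["p"] < 0.05),
    )
    return res


def baseline_drift_test(responses: pd.DataFrame, group: str) -> dict:
    """Linear trend of the per-trial baseline pupil area over the session.

    Per group, regression of baseline on presentation index with participant
    fixed effects; reports the signed slope (device units per trial) and p.
    """
    df = responses
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    df = df[df["group"] == group].dropna(subset=["baseline"])
    res = _within_participant_trend(df, "presentation_index", "baseline")
    res.update(group=group, drift=bool(res["p"] < 0.05))
    return res


def plot_differential_vs_score(summaries: pd.DataFrame, path=None):
    """Scatter of differential response vs semantic score across the patient
    cohort with the OLS fit and its 95% confidence band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = summaries.loc[
        ~summaries["excluded"] & (summaries["group"] != "control")
    ].dropna(subset=["differential", "semantic_score"])
    fit = smf.ols("differential ~ semantic_score", data=data).fit()
    xs = np.linspace(data["semantic_score"].min(), data["semantic_score"].max(), 100)
    pred = fit.get_prediction(pd.DataFrame({"semantic_score": xs})).summary_frame()

    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, marker in zip(PATIENT_GROUPS, "osD^"):
        sub = data[data["group"] == grp]
        ax.scatter(sub["semantic_score"], sub["differential"], marker=marker,
                   label=grp, alpha=0.8)
    ax.plot(xs, pred["mean"], color="k")
    ax.fill_between(xs, pred["mean_ci_lower"], pred["mean_ci_upper"],
                    color="k", alpha=0.15)
    ax.set_xlabel("auditory semantic classification score (/60)")
    ax.set_ylabel("differential pupil response (M+ − M−)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
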