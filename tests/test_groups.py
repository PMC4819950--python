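"""Participant summaries, condition contrasts, trend tests, correlations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats

from pupilsem.groups import (
    baseline_drift_test,
    group_differential_contrast,
    habituation_test,
    paired_condition_test,
    semantic_correlation,
    summarize_participants,
)
from pupilsem.simulate import GeneratorConfig, generate_responses, null_config


def toy_summaries(diffs_by_group, rng=None):
    """Participant summaries with given per-group differential arrays."""
    rng = rng or np.random.default_rng(0)
    rows = []
    i = 0
    for group, diffs in diffs_by_group.items():
        for d in diffs:
            i += 1
            base = rng.normal(0.2, 0.02)
            rows.append(
                {
                    "participant_id": f"P{i:03d}",
                    "group": group,
                    "gender": rng.choice(["m", "f"]),
                    "education_y": rng.uniform(12, 20),
                    "mean_Mplus": base + d / 2,
                    "mean_Mminus": base - d / 2,
                    "differential": d,
                    "overall_reactivity": base,
                    "semantic_score": np.nan,
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


class TestSummarize:
    def participants(self):
        return pd.DataFrame(
            {
                "participant_id": ["p1", "p2"],
                "group": ["control", "SD"],
                "gender": ["m", "f"],
                "education_y": [16.0, 14.0],
                "semantic_score": [58, 45],
            }
        )

    def test_condition_means_and_differential(self):
        adjusted = pd.DataFrame(
            {
                "participant_id": ["p1"] * 4 + ["p2"] * 2,
                "condition": ["M+", "M+", "M-", "M-", "M+", "M-"],
                "pupil_max_adjusted": [0.2, 0.4, 0.1, 0.1, 0.3, 0.2],
                "excluded": False,
            }
        )
        out = summarize_participants(adjusted, self.participants()).set_index(
            "participant_id"
        )
        assert out.loc["p1", "differential"] == pytest.approx(0.2)
        assert out.loc["p2", "differential"] == pytest.approx(0.1)
        assert not out["excluded"].any()

    def test_participant_missing_condition_flagged(self):
        adjusted = pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2"],
                "condition": ["M+", "M-", "M+"],  # p2 has no M- trial
                "pupil_max_adjusted": [0.2, 0.1, 0.3],
                "excluded": False,
            }
        )
        out = summarize_participants(adjusted, self.participants()).set_index(
            "participant_id"
        )
        assert not out.loc["p1", "excluded"]
        assert out.loc["p2", "excluded"]

    def test_unknown_group_label_rejected(self):
        parts = self.participants()
        parts.loc[1, "group"] = "mystery"
        adjusted = pd.DataFrame(
            {
                "participant_id": ["p1"],
                "condition": ["M+"],
                "pupil_max_adjusted": [0.2],
                "excluded": False,
            }
        )
        with pytest.raises(ValueError, match="mystery"):
            summarize_participants(adjusted, parts)

    def test_matches_groupby_oracle_on_simulated_records(self):
        resp, parts, _, _, _ = generate_responses(
            null_config(group_sizes={"control": 5, "SD": 4}), 3
        )
        out = summarize_participants(resp, parts, value_col="pupil_max").set_index(
            "participant_id"
        )
        oracle = resp.pivot_table(
            index="participant_id", columns="condition", values="pupil_max"
        )
        for pid in oracle.index:
            assert out.loc[pid, "differential"] == pytest.approx(
                oracle.loc[pid, "M+"] - oracle.loc[pid, "M-"]
            )


class TestPairedTest:
    def test_identical_means_give_t0_p1(self):
        s = toy_summaries({"control": np.zeros(8)})
        res = paired_condition_test(s, "control")
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_constant_nonzero_differential_warns_p_zero(self):
        s = toy_summaries({"control": np.full(5, 0.1)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = paired_condition_test(s, "control")
        assert res["p"] == 0.0

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(4)
        s = toy_summaries({"SD": rng.normal(0.05, 0.04, 11)}, rng)
        res = paired_condition_test(s, "SD")
        t, p = stats.ttest_rel(s["mean_Mplus"], s["mean_Mminus"])
        assert res["t"] == pytest.approx(t)
        assert res["p"] == pytest.approx(p)
        assert res["df"] == 10

    def test_too_few_participants_rejected(self):
        s = toy_summaries({"PNFA": [0.1, 0.2]})
        with pytest.raises(ValueError, match="PNFA"):
            paired_condition_test(s, "PNFA")


class TestGroupContrast:
    def test_covariate_orthogonal_contrast_equals_raw_mean_difference(self):
        rng = np.random.default_rng(6)
        s = toy_summaries(
            {"control": rng.normal(0.02, 0.03, 20), "SD": rng.normal(0.1, 0.03, 11)},
            rng,
        )
        # with no nuisance covariates the contrast is the raw mean difference
        out = group_differential_contrast(s, nuisance=()).set_index("group")
        raw = (
            s[s.group == "SD"]["differential"].mean()
            - s[s.group == "control"]["differential"].mean()
        )
        assert out.loc["SD", "contrast"] == pytest.approx(raw)

    def test_injected_excess_detected(self):
        rng = np.random.default_rng(7)
        s = toy_summaries(
            {
                "control": rng.normal(0.0, 0.02, 20),
                "SD": rng.normal(0.1, 0.02, 11),
                "AD": rng.normal(0.0, 0.02, 10),
            },
            rng,
        )
        out = group_differential_contrast(s).set_index("group")
        assert out.loc["SD", "contrast"] == pytest.approx(0.1, abs=0.03)
        assert out.loc["SD", "p"] < 0.05
        assert not out.loc["AD", "significant"]

    def test_rank_deficient_design_rejected(self):
        s = toy_summaries({"control": [0.1] * 5, "SD": [0.2] * 5})
        s["education_y"] = 16.0
        s["gender"] = "f"
        with pytest.raises(ValueError):
            group_differential_contrast(s, nuisance=("gender", "education_y"))

    def test_missing_reference_group_rejected(self):
        s = toy_summaries({"SD": [0.1] * 5, "AD": [0.2] * 5})
        with pytest.raises(ValueError, match="control"):
            group_differential_contrast(s)


class TestSemanticCorrelation:
    def test_exact_linear_relation_r2_one(self):
        s = toy_summaries({"SD": np.linspace(0.0, 0.2, 11)})
        s["semantic_score"] = 55 - 100 * s["differential"]
        res = semantic_correlation(s, scope="SD")
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(-0.01, rel=1e-9)

    def test_independent_score_r2_near_zero(self):
        rng = np.random.default_rng(9)
        s = toy_summaries({"SD": rng.normal(0.1, 0.05, 400)}, rng)
        s["semantic_score"] = rng.uniform(30, 60, len(s))
        res = semantic_correlation(s, scope="SD")
        assert res["r2"] < 0.02

    def test_zero_score_variance_rejected(self):
        s = toy_summaries({"SD": np.linspace(0, 0.2, 8)})
        s["semantic_score"] = 50.0
        with pytest.raises(ValueError, match="variance"):
            semantic_correlation(s, scope="SD")


def trend_records(slopes_by_group, rng, n_per_group=8, sd=0.02):
    """Adjusted-response records with a linear presentation-index trend."""
    rows = []
    i = 0
    for group, (slope_mplus, slope_mminus) in slopes_by_group.items():
        for _ in range(n_per_group):
            i += 1
            react = rng.normal(0.25, 0.05)
            for idx in range(1, 41):
                cond = "M+" if idx % 2 else "M-"
                slope = slope_mplus if cond == "M+" else slope_mminus
                rows.append(
                    {
                        "participant_id": f"P{i:03d}",
                        "group": group,
                        "condition": cond,
                        "presentation_index": idx,
                        "pupil_max_adjusted": react + slope * idx + rng.normal(0, sd),
                        "baseline": 1000.0,
                        "excluded": False,
                    }
                )
    return pd.DataFrame(rows)


class TestHabituation:
    def test_flat_responses_no_attenuation(self):
        rng = np.random.default_rng(10)
        rec = trend_records({"control": (0.0, 0.0)}, rng)
        res = habituation_test(rec, "control", "M+")
        assert abs(res["slope"]) < 3 * res["se"]
        assert not res["attenuation"]

    def test_minus_only_attenuation_detected(self):
        rng = np.random.default_rng(11)
        rec = trend_records({"control": (0.0, -0.005)}, rng)
        minus = habituation_test(rec, "control", "M-")
        plus = habituation_test(rec, "control", "M+")
        assert minus["attenuation"]
        assert minus["slope"] == pytest.approx(-0.005, abs=0.002)
        assert abs(plus["slope"]) < 0.0025  # less than half the injected slope

    def test_matches_dummy_variable_ols(self):
        rng = np.random.default_rng(12)
        rec = trend_records({"AD": (-0.003, 0.0)}, rng, n_per_group=5)
        res = habituation_test(rec, "AD", "M+")
        sub = rec[(rec.group == "AD") & (rec.condition == "M+")]
        ols = smf.ols(
            "pupil_max_adjusted ~ presentation_index + C(participant_id)", data=sub
        ).fit()
        assert res["slope"] == pytest.approx(ols.params["presentation_index"], rel=1e-9)
        assert res["se"] == pytest.approx(ols.bse["presentation_index"], rel=1e-9)
        assert res["p"] == pytest.approx(ols.pvalues["presentation_index"], rel=1e-9)

    def test_single_index_rejected(self):
        rng = np.random.default_rng(13)
        rec = trend_records({"SD": (0.0, 0.0)}, rng)
        rec["presentation_index"] = 1
        with pytest.raises(ValueError):
            habituation_test(rec, "SD", "M+")


class TestBaselineDrift:
    def test_constant_baselines_slope_zero(self):
        rng = np.random.default_rng(14)
        rec = trend_records({"control": (0.0, 0.0)}, rng)
        res = baseline_drift_test(rec, "control")
        assert res["slope"] == pytest.approx(0.0, abs=1e-9)
        assert not res["drift"]

    def test_group_specific_drift_detected(self):
        rng = np.random.default_rng(15)
        rec = trend_records({"PNFA": (0.0, 0.0), "control": (0.0, 0.0)}, rng)
        pnfa = rec["group"] == "PNFA"
        rec.loc[pnfa, "baseline"] = (
            1000.0
            + 2.0 * (rec.loc[pnfa, "presentation_index"] - 1)
            + rng.normal(0, 30, pnfa.sum())
        )
        rec.loc[~pnfa, "baseline"] = 1000.0 + rng.normal(0, 30, (~pnfa).sum())
        res_p = baseline_drift_test(rec, "PNFA")
        res_c = baseline_drift_test(rec, "control")
        assert res_p["drift"] and res_p["slope"] == pytest.approx(2.0, abs=0.6)
        assert abs(res_c["slope"]) < 1.0  # under half the injected drift

    def test_matches_dummy_variable_ols(self):
        rng = np.random.default_rng(16)
        rec = trend_records({"SD": (0.0, 0.0)}, rng, n_per_group=4)
        rec["baseline"] = 900.0 + rng.normal(0, 25, len(rec))
        res = baseline_drift_test(rec, "SD")
        ols = smf.ols(
            "baseline ~ presentation_index + C(participant_id)",
            data=rec[rec.group == "SD"],
        ).fit()
        assert res["slope"] == pytest.approx(ols.params["presentation_index"], rel=1e-9)
        assert res["p"] == pytest.approx(ols.pvalues["presentation_index"], rel=1e-9)
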