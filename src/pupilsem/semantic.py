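"""Scoring of the nonverbal auditory semantic classification task.

Sixty pairs of real sounds; the listener judges whether the two sounds in a
pair come from the same source (a goose honking / a goose's wings flapping)
or from different sources.  21 pairs are "same", 39 "different", and 14 pairs
contain one of the ten meaningful sounds used in the pupillometry session —
that subset links task performance directly to the pupillometric stimuli.

Scoring is forced-choice: one point per response matching the key, missing
responses count as incorrect.  Chance performance is 50% per trial (30/60);
this figure is documentation only and enters no inference.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "KEY_STRUCTURE",
    "validate_key",
    "score_classification",
    "compare_task_groups",
    "make_classification_key",
]

# canonical task structure: total pairs, same-source, different-source, pupillometry subset
KEY_STRUCTURE = {"n_pairs": 60, "n_same": 21, "n_different": 39, "n_subset": 14}


def validate_key(key: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Check a classification key against the canonical 60/21/39/14 structure.

    ``key`` has columns pair_id, sound_a, sound_b, truth ("same"/"different"),
    contains_pupillometry_sound (bool).  In strict mode a deviation raises
    with the observed counts; otherwise it warns and returns the key.
    """
    required = {"pair_id", "truth", "contains_pupillometry_sound"}
    missing = required - set(key.columns)
    if missing:
        raise ValueError(f"key missing columns: {sorted(missing)}")
    if key["pair_id"].duplicated().any():
        raise ValueError("key has duplicate pair_ids")
    bad_truth = set(key["truth"]) - {"same", "different"}
    if bad_truth:
        raise ValueError(f"invalid truth labels: {sorted(bad_truth)}")
    observed = {
        "n_pairs": len(key),
        "n_same": int((key["truth"] == "same").sum()),
        "n_different": int((key["truth"] == "different").sum()),
        "n_subset": int(key["contains_pupillometry_sound"].sum()),
    }
    if observed != KEY_STRUCTURE:
        msg = f"key structure {observed} != canonical {KEY_STRUCTURE}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return key


def score_classification(responses: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Score responses against a validated key, per participant.

    ``responses`` has columns participant_id, pair_id, response
    ("same"/"different"/missing).  Returns total correct (0–60), correct on
    the 14-pair pupillometry subset, and per-condition accuracy on "same"
    and "different" pairs.  A response to an unknown pair_id raises.
    """
    unknown = sorted(set(responses["pair_id"]) - set(key["pair_id"]))
    if unknown:
        raise ValueError(f"responses reference unknown pair_ids: {unknown}")
    if responses.duplicated(subset=["participant_id", "pair_id"]).any():
        raise ValueError("duplicate responses to the same pair")
    merged = responses.merge(key, on="pair_id", how="left")
    # unanswered pairs simply contribute no correct point (missing = incorrect)
    merged["correct"] = (merged["response"] == merged["truth"]).astype(int)
    merged["in_subset"] = merged["contains_pupillometry_sound"].astype(bool)
    merged["is_same"] = merged["truth"] == "same"

    g = merged.groupby("participant_id")
    total = g["correct"].sum()
    subset = (
        merged.loc[merged["in_subset"]]
        .groupby("participant_id")["correct"]
        .sum()
        .reindex(total.index, fill_value=0)
    )
    n_same = int((key["truth"] == "same").sum())
    n_diff = len(key) - n_same
    same_correct = (
        merged.loc[merged["is_same"]]
        .groupby("participant_id")["correct"]
        .sum()
        .reindex(total.index, fill_value=0)
    )
    diff_correct = total - same_correct
    return pd.DataFrame(
        {
            "participant_id": total.index,
            "total_score": total.to_numpy(dtype=int),
            "subset_score": subset.to_numpy(dtype=int),
            "same_accuracy": same_correct.to_numpy() / n_same,
            "different_accuracy": diff_correct.to_numpy() / n_diff,
        }
    ).reset_index(drop=True)


def compare_task_groups(
    scores: pd.DataFrame,
    participants: pd.DataFrame,
    nuisance: tuple = ("gender", "education_y"),
    score_col: str = "total_score",
) -> dict:
    """Group contrasts of classification scores, nuisance-adjusted.

    Regression of the score on group indicators plus gender and education;
    reports each group's contrast versus healthy controls and, because the
    study singles out the one unimpaired patient group, the patient groups
    versus PNFA.
    """
    from .groups import group_differential_contrast

    df = participants.merge(scores, on="participant_id", how="inner")
    df = df.rename(columns={score_col: "task_score"})
    df["excluded"] = df["task_score"].isna()
    vs_control = group_differential_contrast(
        df, nuisance=nuisance, response="task_score", reference="control"
    )
    vs_pnfa = group_differential_contrast(
        df, nuisance=nuisance, response="task_score", reference="PNFA"
    )
    vs_pnfa = vs_pnfa[vs_pnfa["group"] != "control"]
    return {"vs_control": vs_control, "vs_PNFA": vs_pnfa}


def make_classification_key(pupil_sound_ids: list[str] | None = None) -> pd.DataFrame:
    """Construct a synthetic 60-pair answer key with the canonical structure.

    The study's actual sound pairs are not deposited; this deterministic
    stand-in reproduces the task's combinatorial structure — 21 same-source
    and 39 different-source pairs, exactly 14 of which contain one of the ten
    pupillometry M+ sounds — so scoring and group comparisons can be
    exercised end to end.
    """
    if pupil_sound_ids is None:
        pupil_sound_ids = [f"m{i:02d}" for i in range(1, 11)]
    if len(pupil_sound_ids) != 10:
        raise ValueError("expected the 10 pupillometry M+ sound ids")
    extra = [f"e{i:02d}" for i in range(1, 86)]  # sounds unique to the task
    rows = []
    pid = 0

    def add(sound_a, sound_b, truth, flagged):
        nonlocal pid
        pid += 1
        rows.append(
            {
                "pair_id": f"p{pid:02d}",
                "sound_a": sound_a,
                "sound_b": sound_b,
                "truth": truth,
                "contains_pupillometry_sound": flagged,
            }
        )

    # 14 flagged pairs built on the pupillometry sounds: 5 same, 9 different
    for i in range(5):
        add(pupil_sound_ids[i], f"{pupil_sound_ids[i]}_alt", "same", True)
    for i in range(9):
        add(pupil_sound_ids[(5 + i) % 10], extra.pop(), "different", True)
    # remaining 16 same + 30 different pairs from task-only sounds
    for _ in range(16):
        a = extra.pop()
        add(a, f"{a}_alt", "same", False)
    for _ in range(30):
        add(extra.pop(), extra.pop(), "different", False)
    return validate_key(pd.DataFrame(rows))
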