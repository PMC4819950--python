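"""Artifact masking and per-trial pupil metrics for the synthetic cohort.

Regenerates the seed-7 cohort, masks blinks and losses (50 ms pre / 750 ms
post margins), computes per-trial baseline and pupil_max (log ratio of
maximal to baseline pupil area), and checks that artifact fractions are
balanced across groups and sounds.  Trial-level responses go to scratch/
(large, regenerable); the QC report goes to results/.

Run from the repository root:  python analysis/02_preprocess.py
"""

import json
from pathlib import Path

from pupilsem import pipeline, preprocess
from pupilsem.simulate import GeneratorConfig, generate_cohort

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort = generate_cohort(GeneratorConfig(), SEED)
    responses = pipeline.preprocess_cohort(cohort.traces, cohort.trials)
    qc = preprocess.qc_artifact_balance(responses)

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    responses.to_csv(scratch / "responses.csv", index=False)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    n_excluded = int(responses["excluded"].sum())
    report = {
        "seed": SEED,
        "n_trials": len(responses),
        "n_excluded": n_excluded,
        "mean_artifact_fraction": float(responses["artifact_fraction"].mean()),
        "artifact_balance": qc,
    }
    with open(results / "qc_report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    print(f"{len(responses)} trials; {n_excluded} excluded "
          f"({100 * n_excluded / len(responses):.1f}%)")
    print(f"mean artifact fraction {report['mean_artifact_fraction']:.3f}")
    print(f"artifact balance: group p={qc['group']['f_pvalue']:.2f}, "
          f"sound p={qc['sound']['f_pvalue']:.2f} "
          f"(imbalance flags: {qc['group']['imbalanced']}, {qc['sound']['imbalanced']})")
    print(f"responses -> {scratch/'responses.csv'}; QC -> {results/'qc_report.json'}")


if __name__ == "__main__":
    main()
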