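"""Group-level inference on the adjusted pupil responses.

Per-participant condition means and the M+ − M− differential response;
paired condition tests within each group; nuisance-adjusted (gender,
education) group contrasts against healthy controls; habituation and
baseline-drift trends; and the correlation between the differential
response and semantic classification score across the patient cohort
(with a figure analogous to a differential-vs-score scatter).

Run from the repository root:  python analysis/04_group_analysis.py
"""

import json
from pathlib import Path

from pupilsem import groups, pipeline
from pupilsem.groups import plot_differential_vs_score
from pupilsem.simulate import GeneratorConfig, generate_cohort

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort = generate_cohort(GeneratorConfig(), SEED)
    result = pipeline.run_full_analysis(cohort)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "group_analysis.json", "w") as fh:
        json.dump(pipeline.report_to_jsonable(result), fh, indent=2)
    result["summaries"].to_csv(results / "participant_summaries.csv", index=False)
    plot_differential_vs_score(
        result["summaries"], results / "differential_vs_score.png"
    )

    print("paired M+ vs M− tests (mean differential, p):")
    for g, t in result["paired_tests"].items():
        print(f"  {g:8s} {t['mean_differential']:+.3f}  p={t['p']:.4f}")
    print("group contrasts vs controls (adjusted differential):")
    for _, row in result["group_contrasts"].iterrows():
        star = "*" if row["significant"] else " "
        print(f"  {row['group']:8s} {row['contrast']:+.3f} p={row['p']:.4f}{star}")
    sem = result["semantic_correlation"]
    print(f"semantic score vs differential (patients, n={sem['n']}): "
          f"slope {sem['slope']:+.4f}, r2={sem['r2']:.2f}, p={sem['p']:.4f}")
    for h in result["habituation"]:
        if h["attenuation"]:
            print(f"habituation: {h['group']} {h['condition']} "
                  f"slope {h['slope']:+.5f}/trial, p={h['p']:.4f}")
    for d in result["baseline_drift"]:
        if d["drift"]:
            print(f"baseline drift: {d['group']} {d['slope']:+.2f} units/trial, "
                  f"p={d['p']:.4f}")
    print(f"report -> {results/'group_analysis.json'}")


if __name__ == "__main__":
    main()
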