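"""Confound adjustment of crude pupil responses.

Estimates the average effects of peak loudness and of control-rated
pleasantness and arousal on pupil_max with a crossed-random-effects REML
model (participant and sound intercepts), then subtracts the implied
per-sound constant from every crude response.  The M− sounds are ~6 dB
louder by construction, so the unadjusted M+ − M− differential is biased;
this stage removes that bias.

Run from the repository root:  python analysis/03_confound_adjust.py
"""

from pathlib import Path

from pupilsem import confound, pipeline
from pupilsem.simulate import GeneratorConfig, generate_cohort

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort = generate_cohort(GeneratorConfig(), SEED)
    responses = pipeline.preprocess_cohort(cohort.traces, cohort.trials)
    covariates = pipeline.build_sound_covariates(
        cohort.trials, cohort.participants, cohort.sounds
    )
    fit = confound.fit_crossed_mixed_model(responses, covariates)
    adjustments = confound.compute_sound_adjustments(fit, covariates)
    adjusted = confound.adjust_pupil_max(responses, adjustments)

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    adjusted.to_csv(scratch / "adjusted.csv", index=False)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    fit.to_json(results / "confound_fit.json")

    print("confound betas (pupil_max units):")
    for name, beta in fit.betas.items():
        print(f"  {name:20s} {beta:+.4f} (se {fit.se[name]:.4f})")
    print("variance components:", {k: round(v, 5) for k, v in fit.vcomp.items()},
          f"residual {fit.sigma2_resid:.5f}")
    print(f"adjustments span [{adjustments.min():+.3f}, {adjustments.max():+.3f}], "
          f"mean {adjustments.mean():+.1e}")
    print(f"adjusted responses -> {scratch/'adjusted.csv'}; "
          f"fit -> {results/'confound_fit.json'}")


if __name__ == "__main__":
    main()
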