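"""Artifact masking and per-trial pupil metrics."""

import io

import numpy as np
import pandas as pd
import pytest

from pupilsem.preprocess import (
    PupilTrace,
    TrialExcluded,
    apply_artifact_margins,
    artifact_fraction,
    compute_baseline,
    compute_pupil_max,
    detect_artifacts,
    mask_membership,
    qc_artifact_balance,
    read_pupil_samples,
    write_pupil_samples,
)
from pupilsem.simulate import generate_trace, inject_blinks

TIMES = np.arange(0, 11000, 4, dtype=np.int64)


def flat_trace(value=1000.0, trial_id="t1"):
    areas = np.full(TIMES.size, value)
    return PupilTrace(trial_id, TIMES, areas, np.ones(TIMES.size, dtype=bool))


def with_zero_run(start_ms, end_ms, value=1000.0):
    tr = flat_trace(value)
    sel = (TIMES >= start_ms) & (TIMES < end_ms)
    tr.areas[sel] = 0.0
    tr.valid[sel] = False
    return tr


class TestReadSamples:
    def test_toy_file_with_blank_area(self):
        tsv = "trial_id\ttime_ms\tpupil_area\na\t0\t1000\na\t4\t\na\t8\t1010\n"
        traces = read_pupil_samples(io.StringIO(tsv))
        assert len(traces) == 1
        tr = traces[0]
        assert len(tr) == 3
        assert list(tr.valid) == [True, False, True]

    def test_backwards_time_rejected(self):
        tsv = "trial_id\ttime_ms\tpupil_area\na\t8\t1000\na\t4\t1000\n"
        with pytest.raises(ValueError, match="backwards"):
            read_pupil_samples(io.StringIO(tsv))

    def test_duplicate_time_rejected(self):
        tsv = "trial_id\ttime_ms\tpupil_area\na\t4\t1000\na\t4\t1000\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_pupil_samples(io.StringIO(tsv))

    def test_round_trip(self, tmp_path):
        tr = with_zero_run(3000, 3200)
        path = tmp_path / "samples.tsv"
        write_pupil_samples(path, [tr])
        back = read_pupil_samples(path)[0]
        np.testing.assert_array_equal(back.times_ms, tr.times_ms)
        np.testing.assert_array_equal(back.valid, tr.valid)
        np.testing.assert_allclose(back.areas[back.valid], tr.areas[tr.valid])


class TestDetectArtifacts:
    def test_constant_trace_clean(self):
        assert detect_artifacts(flat_trace()) == []

    def test_zero_run_detected_exactly(self):
        assert detect_artifacts(with_zero_run(3000, 3200)) == [(3000, 3200)]

    def test_all_invalid_trace_fully_masked(self):
        tr = flat_trace()
        tr.valid[:] = False
        tr.areas[:] = 0.0
        assert detect_artifacts(tr) == [(0, 11000)]

    def test_smooth_evoked_response_not_flagged(self):
        tr = generate_trace("t", 1200.0, 1.0, np.random.default_rng(0), noise_sd=0.0)
        assert detect_artifacts(tr) == []

    def test_injected_blinks_recovered(self):
        """Synthetic blinks (steep drop/recover around a zero run) are
        detected: the detected mask overlaps the injected interval for at
        least 99% of simulated blinks."""
        rng = np.random.default_rng(7)
        hits = total = 0
        while total < 300:
            tr = generate_trace("t", 1200.0, 0.3, rng, noise_sd=0.02)
            tr, injected = inject_blinks(tr, rate=1.5, rng=rng)
            detected = detect_artifacts(tr)
            for s, e in injected:
                total += 1
                if any(ds < e and s < de for ds, de in detected):
                    hits += 1
        assert hits / total >= 0.99


class TestMargins:
    def test_margins_applied(self):
        assert apply_artifact_margins([(3000, 3100)]) == [(2950, 3850)]

    def test_overlapping_after_extension_merged(self):
        # interval-merge oracle: [50,950) and [550,1450) overlap -> one run
        assert apply_artifact_margins([(100, 200), (600, 700)]) == [(50, 1450)]

    def test_empty(self):
        assert apply_artifact_margins([]) == []

    def test_clipped_to_trial_bounds(self):
        assert apply_artifact_margins([(0, 100), (10800, 11000)]) == [
            (0, 850),
            (10750, 11000),
        ]

    def test_extending_margins_never_decreases_masked_fraction(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tr = flat_trace()
            n = rng.integers(1, 5)
            ivals = []
            for _ in range(n):
                s = int(rng.integers(0, 10500))
                ivals.append((s, s + int(rng.integers(4, 400))))
            prev = -1.0
            for post in (0, 200, 750, 2000):
                frac = artifact_fraction(
                    tr, apply_artifact_margins(sorted(ivals), post_ms=post)
                )
                assert frac >= prev
                prev = frac


class TestBaseline:
    def test_constant(self):
        assert compute_baseline(flat_trace(1000.0), []) == 1000.0

    def test_two_level_mean(self):
        tr = flat_trace(900.0)
        tr.areas[(TIMES >= 1000) & (TIMES < 2000)] = 1100.0
        assert compute_baseline(tr, []) == pytest.approx(1000.0)

    def test_fully_masked_baseline_excludes_trial(self):
        with pytest.raises(TrialExcluded):
            compute_baseline(flat_trace(), [(0, 2000)])


class TestPupilMax:
    def test_max_equal_baseline_gives_zero(self):
        assert compute_pupil_max(flat_trace(1000.0), 1000.0, []) == 0.0

    def test_log_identity(self):
        tr = flat_trace(1000.0)
        tr.areas[TIMES == 5000] = 1000.0 * np.e
        assert compute_pupil_max(tr, 1000.0, []) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_scan_on_sawtooth(self):
        tr = flat_trace(1000.0)
        tr.areas += 50 * (TIMES % 1000) / 1000.0
        masked = [(4000, 6000)]
        got = compute_pupil_max(tr, 1000.0, masked)
        best = max(  # exhaustive per-sample oracle
            a
            for t, a, v in zip(TIMES, tr.areas, tr.valid)
            if v and 2000 <= t < 11000 and not (4000 <= t < 6000)
        )
        assert got == pytest.approx(np.log(best / 1000.0), abs=1e-12)

    def test_empty_search_window_excludes_trial(self):
        with pytest.raises(TrialExcluded):
            compute_pupil_max(flat_trace(), 1000.0, [(2000, 11000)])

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        tr = generate_trace("t", 1500.0, 0.4, rng, noise_sd=0.02)
        masked = apply_artifact_margins(detect_artifacts(tr))
        b = compute_baseline(tr, masked)
        pm = compute_pupil_max(tr, b, masked)
        for c in (0.5, 3.7):
            scaled = PupilTrace("t", tr.times_ms, tr.areas * c, tr.valid)
            m2 = apply_artifact_margins(detect_artifacts(scaled))
            b2 = compute_baseline(scaled, m2)
            assert compute_pupil_max(scaled, b2, m2) == pytest.approx(pm, abs=1e-12)


class TestArtifactFraction:
    def test_none(self):
        assert artifact_fraction(flat_trace(), []) == 0.0

    def test_all(self):
        assert artifact_fraction(flat_trace(), [(0, 11000)]) == 1.0

    def test_partial_mask_direct_count(self):
        # samples at 2952..3848 inclusive fall in [2950, 3850): 225 of 2750
        assert artifact_fraction(flat_trace(), [(2950, 3850)]) == pytest.approx(
            225 / 2750
        )


def brute_force_kept(trace, k=8.0, rel_floor=0.01, pre=50, post=750):
    """Per-sample oracle for the whole masking pipeline: flag bad samples by
    the same rule, then test each sample against each bad sample's margin
    window directly (no run/merge logic)."""
    from pupilsem.preprocess import _bad_samples

    bad = _bad_samples(trace, k, rel_floor)
    step = trace.step_ms
    kept = []
    for i, t in enumerate(trace.times_ms):
        if not trace.valid[i]:
            continue
        removed = any(
            tb - pre <= t < tb + step + post
            for tb in trace.times_ms[bad]
        )
        if not removed:
            kept.append(int(t))
    return kept


def random_trace(rng):
    areas = 1000.0 + np.cumsum(rng.normal(0, 2.0, TIMES.size))
    valid = np.ones(TIMES.size, dtype=bool)
    for _ in range(rng.integers(0, 4)):
        s = rng.integers(0, TIMES.size - 30)
        ln = rng.integers(5, 120)
        areas[s : s + ln] = 0.0
        valid[s : s + ln] = False
    for _ in range(rng.integers(0, 3)):  # isolated spikes
        j = rng.integers(1, TIMES.size - 1)
        areas[j] += rng.choice([-1, 1]) * rng.uniform(300, 900)
    return PupilTrace("t", TIMES, np.maximum(areas, 0.0), valid & (areas > 0))


class TestMaskingPipelineOracle:
    def test_interval_pipeline_equals_per_sample_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            tr = random_trace(rng)
            masked = apply_artifact_margins(detect_artifacts(tr))
            kept = [
                int(t)
                for t, v, m in zip(
                    tr.times_ms, tr.valid, mask_membership(tr.times_ms, masked)
                )
                if v and not m
            ]
            assert kept == brute_force_kept(tr)


class TestQcBalance:
    def make_records(self, fractions, groups, sounds):
        return pd.DataFrame(
            {"artifact_fraction": fractions, "group": groups, "sound_id": sounds}
        )

    def test_identical_fractions_pass(self):
        rec = self.make_records([0.1] * 8, ["a"] * 4 + ["b"] * 4, ["s1", "s2"] * 4)
        out = qc_artifact_balance(rec)
        assert out["group"] == {"f_pvalue": 1.0, "imbalanced": False}

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(0)
        frac = np.concatenate([rng.uniform(0, 0.1, 40), rng.uniform(0, 0.1, 40) + 0.5])
        rec = self.make_records(
            frac, ["a"] * 40 + ["b"] * 40, ["s1", "s2", "s3", "s4"] * 20
        )
        out = qc_artifact_balance(rec)
        assert out["group"]["imbalanced"]
        assert not out["sound"]["imbalanced"]

    def test_null_rejection_rate_near_alpha(self):
        """Permuting group labels leaves ~5% spurious imbalance at alpha=.05."""
        rng = np.random.default_rng(1)
        frac = rng.uniform(0, 0.2, 60)
        sounds = [f"s{i % 5}" for i in range(60)]
        hits = 0
        n_perm = 400
        for _ in range(n_perm):
            groups = rng.permutation(["a"] * 30 + ["b"] * 30)
            out = qc_artifact_balance(self.make_records(frac, groups, sounds))
            hits += out["group"]["imbalanced"]
        assert 0.02 <= hits / n_perm <= 0.09

    def test_single_level_factor_rejected(self):
        rec = self.make_records([0.1, 0.2], ["a", "a"], ["s1", "s2"])
        with pytest.raises(ValueError):
            qc_artifact_balance(rec)
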