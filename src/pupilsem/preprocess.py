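"""Per-trial pupil preprocessing: artifact masking, baseline and response metrics.

A trial spans 11 s at 250 Hz: a 2 s silent baseline, the 2 s sound, and a 7 s
silent equilibration interval.  Blinks and signal-loss artifacts are masked
together with a safety margin (50 ms before, 750 ms after, the latter
covering the ensuing light reflex), and each trial is reduced to

* ``baseline`` — mean pupil area over the unmasked baseline samples, and
* ``pupil_max`` — the natural-log ratio of the maximal unmasked post-onset
  pupil area to baseline, the study's response metric.

Masked samples are discarded, never interpolated.  All intervals are
half-open ``[start_ms, end_ms)`` in 0-based trial time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRIAL_SPAN_MS = (0, 11000)
BASELINE_WINDOW_MS = (0, 2000)
RESPONSE_WINDOW_MS = (2000, 11000)
SAMPLE_STEP_MS = 4  # 250 Hz

__all__ = [
    "PupilTrace",
    "TrialExcluded",
    "read_pupil_samples",
    "write_pupil_samples",
    "detect_artifacts",
    "apply_artifact_margins",
    "compute_baseline",
    "compute_pupil_max",
    "artifact_fraction",
    "mask_membership",
    "process_trials",
    "qc_artifact_balance",
]


class TrialExcluded(Exception):
    """Raised when a trial cannot yield a metric (e.g. baseline fully masked)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class PupilTrace:
    """One trial's pupil-area time series.

    areas are in arbitrary device units (>0 when the pupil is tracked);
    ``valid`` marks samples where the signal was present.  Times are 0-based
    milliseconds from trial onset on a nominal 4 ms grid.
    """

    trial_id: str
    times_ms: np.ndarray
    areas: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=np.int64)
        self.areas = np.asarray(self.areas, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.times_ms.size
        if n == 0:
            raise ValueError(f"trial {self.trial_id}: empty trace")
        if self.areas.size != n or self.valid.size != n:
            raise ValueError(f"trial {self.trial_id}: mismatched array lengths")
        if n > 1:
            dt = np.diff(self.times_ms)
            if np.any(dt <= 0):
                raise ValueError(
                    f"trial {self.trial_id}: times not strictly increasing"
                )
            self._step_ms = int(np.median(dt))
        else:
            self._step_ms = SAMPLE_STEP_MS

    @property
    def step_ms(self) -> int:
        return self._step_ms

    def __len__(self) -> int:
        return self.times_ms.size


def read_pupil_samples(path) -> list[PupilTrace]:
    """Parse a long-format TSV (trial_id, time_ms, pupil_area) into traces.

    Blank or zero (or negative) areas mark lost samples.  Non-monotone
    timestamps or duplicate (trial, time) pairs are parse errors naming the
    offending trial.
    """
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str})
    required = {"trial_id", "time_ms", "pupil_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pupil sample file missing columns: {sorted(missing)}")
    traces = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        times = grp["time_ms"].to_numpy(dtype=np.int64)
        if np.any(np.diff(times) == 0):
            raise ValueError(f"trial {trial_id}: duplicate (trial, time) pair")
        if np.any(np.diff(times) < 0):
            raise ValueError(f"trial {trial_id}: time going backwards")
        areas = grp["pupil_area"].to_numpy(dtype=np.float64)
        valid = np.isfinite(areas) & (areas > 0)
        areas = np.where(valid, areas, 0.0)
        traces.append(PupilTrace(str(trial_id), times, areas, valid))
    return traces


def write_pupil_samples(path, traces: list[PupilTrace]) -> None:
    """Write traces back to the long TSV dialect (lost samples as blank)."""
    frames = []
    for tr in traces:
        areas = np.where(tr.valid, tr.areas, np.nan)
        frames.append(
            pd.DataFrame(
                {"trial_id": tr.trial_id, "time_ms": tr.times_ms, "pupil_area": areas}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


def _bad_samples(trace: PupilTrace, rate_threshold_k: float, rel_floor: float) -> np.ndarray:
    """Boolean mask of artifactual samples: signal loss plus rapid transients.

    A sample is artifactual when it is invalid/zero, or when it borders a
    first difference whose magnitude exceeds ``k`` robust scales.  The robust
    scale is the MAD of first differences over the trial, floored at
    ``rel_floor`` times the median valid area so that smooth physiological
    dilation (whose derivative sets the MAD on clean traces) is never flagged.
    """
    bad = ~trace.valid
    if bad.all() or len(trace) < 2:
        return bad
    diffs = np.diff(trace.areas)
    both_valid = trace.valid[:-1] & trace.valid[1:]
    scale = 0.0
    if both_valid.any():
        d = diffs[both_valid]
        scale = float(np.median(np.abs(d - np.median(d))))
    floor = rel_floor * float(np.median(trace.areas[trace.valid]))
    threshold = rate_threshold_k * max(scale, floor)
    # transitions into/out of signal loss are covered by the loss run itself
    # (and by the margins); the derivative rule targets valid-sample ramps
    steep = (np.abs(diffs) > threshold) & both_valid
    bad[:-1] |= steep
    bad[1:] |= steep
    return bad


def _runs_to_intervals(bad: np.ndarray, times: np.ndarray, step: int) -> list[tuple[int, int]]:
    """Convert maximal runs of flagged samples to half-open ms intervals."""
    if not bad.any():
        return []
    padded = np.concatenate(([False], bad, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    return [(int(times[i]), int(times[j]) + step) for i, j in zip(starts, ends)]


def detect_artifacts(
    trace: PupilTrace, rate_threshold_k: float = 8.0, rel_floor: float = 0.01
) -> list[tuple[int, int]]:
    """Detect blink/loss artifacts as disjoint, sorted half-open ms intervals.

    Blinks show a characteristic trajectory: the measured area collapses
    rapidly (often to zero) and recovers rapidly.  Flagged samples are the
    invalid/zero ones plus those adjacent to first differences exceeding
    ``rate_threshold_k`` robust scales (see ``_bad_samples``); maximal flagged
    runs become intervals.  An all-invalid trace yields one interval covering
    the whole trial.
    """
    bad = _bad_samples(trace, rate_threshold_k, rel_floor)
    return _runs_to_intervals(bad, trace.times_ms, trace.step_ms)


def apply_artifact_margins(
    intervals: list[tuple[int, int]],
    pre_ms: int = 50,
    post_ms: int = 750,
    trial_bounds: tuple[int, int] = TRIAL_SPAN_MS,
) -> list[tuple[int, int]]:
    """Extend each artifact by the safety margins and merge overlaps.

    Pupil data are discarded for ``pre_ms`` before and ``post_ms`` after each
    artifact (the post margin allows the ensuing light reflex to complete).
    Extended intervals are clipped to the trial bounds and merged.
    """
    lo, hi = trial_bounds
    extended = sorted(
        (max(lo, s - pre_ms), min(hi, e + post_ms)) for s, e in intervals
    )
    merged: list[tuple[int, int]] = []
    for s, e in extended:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mask_membership(times_ms: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Boolean mask: True where a sample time falls inside any interval."""
    masked = np.zeros(len(times_ms), dtype=bool)
    for s, e in intervals:
        masked |= (times_ms >= s) & (times_ms < e)
    return masked


def compute_baseline(
    trace: PupilTrace,
    masked: list[tuple[int, int]],
    window_ms: tuple[int, int] = BASELINE_WINDOW_MS,
    min_unmasked_frac: float = 0.25,
) -> float:
    """Mean pupil area over the valid, unmasked baseline-window samples.

    Raises :class:`TrialExcluded` when fewer than ``min_unmasked_frac`` of the
    baseline samples survive masking — too little signal for a stable anchor.
    """
    lo, hi = window_ms
    in_window = (trace.times_ms >= lo) & (trace.times_ms < hi)
    n_window = int(in_window.sum())
    if n_window == 0:
        raise TrialExcluded("no samples in baseline window")
    keep = in_window & trace.valid & ~mask_membership(trace.times_ms, masked)
    if keep.sum() < min_unmasked_frac * n_window:
        raise TrialExcluded("baseline window insufficiently sampled after masking")
    return float(np.mean(trace.areas[keep]))


def compute_pupil_max(
    trace: PupilTrace,
    baseline: float,
    masked: list[tuple[int, int]],
    window_ms: tuple[int, int] = RESPONSE_WINDOW_MS,
) -> float:
    """Natural-log ratio of maximal unmasked post-onset area to baseline."""
    if not baseline > 0:
        raise TrialExcluded("nonpositive baseline")
    lo, hi = window_ms
    keep = (
        (trace.times_ms >= lo)
        & (trace.times_ms < hi)
        & trace.valid
        & ~mask_membership(trace.times_ms, masked)
    )
    if not keep.any():
        raise TrialExcluded("response window fully masked")
    return float(np.log(np.max(trace.areas[keep]) / baseline))


def artifact_fraction(trace: PupilTrace, masked: list[tuple[int, int]]) -> float:
    """Proportion of the trial's samples that are invalid or inside the mask."""
    removed = ~trace.valid | mask_membership(trace.times_ms, masked)
    return float(removed.mean())


def process_trials(
    traces: list[PupilTrace],
    trial_meta: pd.DataFrame,
    rate_threshold_k: float = 8.0,
    pre_ms: int = 50,
    post_ms: int = 750,
) -> pd.DataFrame:
    """Run the full per-trial pipeline and join trial metadata.

    Returns one row per trace with baseline, pupil_max, artifact_fraction,
    and an ``excluded`` flag with a reason code for trials that fail the
    baseline or response-window requirements.
    """
    meta_cols = [
        c
        for c in (
            "participant_id",
            "sound_id",
            "condition",
            "presentation_index",
            "pleasantness",
            "arousal",
        )
        if c in trial_meta.columns
    ]
    meta = (
        trial_meta.assign(trial_id=trial_meta["trial_id"].astype(str))
        .set_index("trial_id")[meta_cols]
        .to_dict("index")
    )
    rows = []
    for trace in traces:
        intervals = detect_artifacts(trace, rate_threshold_k=rate_threshold_k)
        masked = apply_artifact_margins(intervals, pre_ms=pre_ms, post_ms=post_ms)
        frac = artifact_fraction(trace, masked)
        baseline = pupil_max = np.nan
        excluded, reason = False, ""
        try:
            baseline = compute_baseline(trace, masked)
            pupil_max = compute_pupil_max(trace, baseline, masked)
        except TrialExcluded as exc:
            excluded, reason = True, exc.reason
        row = {
            "trial_id": trace.trial_id,
            "baseline": baseline,
            "pupil_max": pupil_max,
            "artifact_fraction": frac,
            "excluded": excluded,
            "exclusion_reason": reason,
        }
        if trace.trial_id in meta:
            row.update(meta[trace.trial_id])
        rows.append(row)
    return pd.DataFrame(rows)


def qc_artifact_balance(records: pd.DataFrame) -> dict:
    """Check that artifact fractions are balanced across groups and sounds.

    Fits two simple linear regressions of artifact_fraction on group
    indicators and on sound indicators, and reports the F-test p-value of
    each; imbalance is flagged at p < .05.  ``records`` needs columns
    artifact_fraction, group, sound_id.
    """
    import statsmodels.formula.api as smf

    out = {}
    for factor, label in (("group", "group"), ("sound_id", "sound")):
        levels = records[factor].nunique()
        if levels < 2:
            raise ValueError(f"need >=2 levels of {factor} for the balance test")
        y = records["artifact_fraction"]
        if np.allclose(y, y.iloc[0]):
            out[label] = {"f_pvalue": 1.0, "imbalanced": False}
            continue
        fit = smf.ols(f"artifact_fraction ~ C({factor})", data=records).fit()
        p = float(fit.f_pvalue)
        out[label] = {"f_pvalue": p, "imbalanced": bool(p < 0.05)}
    return out
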