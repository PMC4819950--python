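"""Construction and validation of matched meaningful (M+) and meaningless (M−) sound stimuli.

The experiment contrasts real, recognisable nonverbal sounds (M+) with
synthetic control sounds (M−) obtained by spectral inversion: every frequency
component ``f`` is mapped to ``Nyquist − f``, which preserves spectrotemporal
complexity and energy while destroying semantic identity.  All stimuli are
fixed to a common duration and a common RMS intensity; peak level (dBFS) is
retained per sound as a loudness nuisance covariate for the downstream
confound adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "StimulusRecord",
    "fix_duration",
    "normalize_rms",
    "spectral_invert",
    "measure_peak_level",
    "rms",
    "pilot_exclusion_filter",
    "build_playlist",
    "prepare_stimulus",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: amplitude samples in [−1, 1] at a fixed sample rate (Hz)."""

    samples: np.ndarray
    sample_rate: int = 44100

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("waveform must be a non-empty 1-D signal")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class StimulusRecord:
    """Bookkeeping for one prepared stimulus."""

    sound_id: str
    condition: str  # "M+" or "M-"
    duration_s: float
    rms: float
    peak_db: float
    path: str = ""


def rms(w: Waveform) -> float:
    """Root-mean-square amplitude of the signal (linear scale)."""
    return float(np.sqrt(np.mean(np.square(w.samples))))


def fix_duration(w: Waveform, target_s: float) -> Waveform:
    """Force a waveform to ``target_s`` seconds.

    Short signals (naturally periodic sounds such as hiccoughs) are looped
    end-to-start until the target length; long signals are truncated.  No
    crossfade is applied at the loop seam.
    """
    if target_s <= 0:
        raise ValueError("target_s must be positive")
    n_target = round(target_s * w.sample_rate)
    if n_target <= 0:
        raise ValueError("target duration shorter than one sample")
    # np.resize repeats the input cyclically, which is exactly end-to-start looping
    return replace(w, samples=np.resize(w.samples, n_target))


def normalize_rms(w: Waveform, target_rms: float) -> Waveform:
    """Rescale a waveform to a target RMS (fixed mean overall intensity across the set)."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    current = rms(w)
    if current == 0.0:
        raise ValueError("cannot normalize an all-zero waveform (undefined gain)")
    return replace(w, samples=w.samples * (target_rms / current))


def spectral_invert(w: Waveform) -> Waveform:
    """Map every frequency component f to (sample_rate/2 − f).

    Implemented as sign alternation (sample n multiplied by (−1)^n), i.e. a
    ring modulation by the Nyquist frequency.  For real signals this reflects
    the whole spectrum about Nyquist/2, is exactly energy-preserving, and is
    an involution: applying it twice returns the input bit-exactly.
    """
    signs = np.ones(len(w))
    signs[1::2] = -1.0
    return replace(w, samples=w.samples * signs)


def measure_peak_level(w: Waveform) -> float:
    """Peak level in dBFS: 20·log10(max |sample|).  ≤ 0 for in-range signals.

    A digital stand-in for a physical peak sound-level-meter reading; the
    analysis treats peak level as an opaque per-sound loudness covariate.
    """
    peak = float(np.max(np.abs(w.samples)))
    if peak == 0.0:
        raise ValueError("all-zero waveform has no peak level")
    return 20.0 * np.log10(peak)


def pilot_exclusion_filter(
    identifications: pd.DataFrame, frac_threshold: float
) -> set[str]:
    """Retain sounds that pilot raters identified reliably.

    ``identifications`` has columns sound_id, n_raters, n_misidentified.  A
    sound is excluded when its misidentified fraction reaches the threshold
    (``n_misidentified / n_raters >= frac_threshold``): with 20 pilot raters
    and a 10% threshold, two or more misidentifications exclude a sound.
    """
    if not 0 < frac_threshold < 1:
        raise ValueError("frac_threshold must be in (0, 1)")
    required = {"sound_id", "n_raters", "n_misidentified"}
    missing = required - set(identifications.columns)
    if missing:
        raise ValueError(f"identifications table missing columns: {sorted(missing)}")
    n_raters = identifications["n_raters"].to_numpy(dtype=float)
    n_mis = identifications["n_misidentified"].to_numpy(dtype=float)
    if np.any(n_raters <= 0):
        raise ValueError("n_raters must be positive for every sound")
    if np.any(n_mis > n_raters) or np.any(n_mis < 0):
        raise ValueError("n_misidentified must be in [0, n_raters]")
    keep = (n_mis / n_raters) < frac_threshold
    return set(identifications.loc[keep, "sound_id"])


def build_playlist(
    stimuli: pd.DataFrame,
    familiarization: pd.DataFrame,
    seed: int,
    n_repeats: int = 2,
) -> pd.DataFrame:
    """Assemble the experiment playlist: familiarization trials, then the
    randomised main block.

    ``stimuli`` and ``familiarization`` are tables with columns sound_id and
    condition.  The main block presents each of 10 M+ and 10 M− sounds
    ``n_repeats`` times (40 trials by default) in a seeded uniform random
    order; the 2 M+ / 2 M− familiarization sounds come first, flagged, in the
    order given.  Returns a table with columns trial_index (1-based over the
    whole session), sound_id, condition, is_familiarization and
    presentation_index (1..40 for main trials, 0 for familiarization).
    """
    _check_condition_counts(stimuli, {"M+": 10, "M-": 10}, "main stimuli")
    _check_condition_counts(familiarization, {"M+": 2, "M-": 2}, "familiarization")

    slots = stimuli.loc[stimuli.index.repeat(n_repeats), ["sound_id", "condition"]]
    order = main_trial_order(len(slots), seed)
    main = slots.iloc[order].reset_index(drop=True)
    main["is_familiarization"] = False
    main["presentation_index"] = np.arange(1, len(main) + 1)

    fam = familiarization[["sound_id", "condition"]].copy()
    fam["is_familiarization"] = True
    fam["presentation_index"] = 0

    playlist = pd.concat([fam, main], ignore_index=True)
    playlist.insert(0, "trial_index", np.arange(1, len(playlist) + 1))
    return playlist


def main_trial_order(n_slots: int, seed: int) -> np.ndarray:
    """Seeded uniform permutation of the main-trial (sound, repetition) slots."""
    return np.random.default_rng(seed).permutation(n_slots)


def _check_condition_counts(df: pd.DataFrame, expected: dict, what: str) -> None:
    counts = df["condition"].value_counts().to_dict()
    if counts != expected:
        raise ValueError(f"{what}: expected condition counts {expected}, got {counts}")


def prepare_stimulus(
    w: Waveform,
    sound_id: str,
    condition: str,
    target_s: float = 2.0,
    target_rms: float = 0.1,
) -> tuple[Waveform, StimulusRecord]:
    """Duration-fix and RMS-normalize one stimulus; measure its peak level."""
    out = normalize_rms(fix_duration(w, target_s), target_rms)
    rec = StimulusRecord(
        sound_id=sound_id,
        condition=condition,
        duration_s=out.duration_s,
        rms=rms(out),
        peak_db=measure_peak_level(out),
    )
    return out, rec


def read_wav(path) -> Waveform:
    """Read a mono WAV file (float or 16-bit PCM) into a [−1, 1] waveform."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    return Waveform(samples=np.asarray(data, dtype=np.float64), sample_rate=int(sr))


def write_wav(path, w: Waveform, pcm16: bool = False) -> None:
    """Write a waveform as mono WAV (float32 by default, optionally 16-bit PCM)."""
    if pcm16:
        clipped = np.clip(w.samples, -1.0, 1.0)
        wavfile.write(path, w.sample_rate, (clipped * 32767).astype(np.int16))
    else:
        wavfile.write(path, w.sample_rate, w.samples.astype(np.float32))
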