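"""Monotone transforms from Hz to auditory perceptual scales.

Bark (Traunmüller), ERB-rate (Glasberg & Moore), Mel (Stevens & Volkmann),
semitones re a reference frequency (12 per octave), and the natural-log
scale used by log-mean normalization.  All transforms are strictly
increasing on (0, inf) and invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from . import data_model
from .data_model import Dataset, FREQUENCY_CUES, TIMEPOINTS, timepoint_column

SCALE_NAMES = ("Hz", "Bark", "ERB", "Mel", "ST", "log")

DEFAULT_ST_REFERENCE = 100.0


def _check_positive(f, what: str = "frequency"):
    arr = np.asarray(f, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{what} must be positive and finite")
    return arr


def hz_to_bark(f):
    """Traunmüller's critical-band rate: z = 26.81 f / (1960 + f) − 0.53."""
    arr = _check_positive(f)
    out = 26.81 * arr / (1960.0 + arr) - 0.53
    return float(out) if np.isscalar(f) else out


def bark_to_hz(z):
    arr = np.asarray(z, dtype=float)
    out = 1960.0 * (arr + 0.53) / (26.28 - arr)
    return float(out) if np.isscalar(z) else out


def hz_to_erb(f):
    """ERB-rate (Glasberg & Moore): 21.4 log10(1 + 0.00437 f)."""
    arr = _check_positive(f)
    out = 21.4 * np.log10(1.0 + 0.00437 * arr)
    return float(out) if np.isscalar(f) else out


def erb_to_hz(e):
    arr = np.asarray(e, dtype=float)
    out = (np.power(10.0, arr / 21.4) - 1.0) / 0.00437
    return float(out) if np.isscalar(e) else out


def hz_to_mel(f):
    """Mel scale (Stevens & Volkmann): 2595 log10(1 + f/700)."""
    arr = _check_positive(f)
    out = 2595.0 * np.log10(1.0 + arr / 700.0)
    return float(out) if np.isscalar(f) else out


def mel_to_hz(m):
    arr = np.asarray(m, dtype=float)
    out = 700.0 * (np.power(10.0, arr / 2595.0) - 1.0)
    return float(out) if np.isscalar(m) else out


def hz_to_semitones(f, reference: float = DEFAULT_ST_REFERENCE):
    """Semitones re ``reference`` Hz: 12 log2(f / reference).

    The reference maps to 0 and a doubling of frequency adds 12.
    """
    _check_positive(reference, "reference")
    arr = _check_positive(f)
    out = 12.0 * np.log2(arr / reference)
    return float(out) if np.isscalar(f) else out


def semitones_to_hz(s, reference: float = DEFAULT_ST_REFERENCE):
    _check_positive(reference, "reference")
    arr = np.asarray(s, dtype=float)
    out = reference * np.power(2.0, arr / 12.0)
    return float(out) if np.isscalar(s) else out


def hz_to_log(f):
    """Natural log of frequency (the scale of log-mean normalization)."""
    arr = _check_positive(f)
    out = np.log(arr)
    return float(out) if np.isscalar(f) else out


def log_to_hz(x):
    arr = np.asarray(x, dtype=float)
    out = np.exp(arr)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class Scale:
    """A named frequency scale with an invertible transform from Hz.

    ``reference`` only affects the semitone scale (default 100 Hz).
    """

    name: str
    reference: float = DEFAULT_ST_REFERENCE

    def __post_init__(self) -> None:
        if self.name not in SCALE_NAMES:
            raise ConfigError(f"unknown scale {self.name!r}; choose from {SCALE_NAMES}")
        if not self.reference > 0:
            raise ConfigError("semitone reference must be positive")

    def transform(self, f):
        if self.name == "Hz":
            return _check_positive(f) if not np.isscalar(f) else float(_check_positive(f))
        if self.name == "Bark":
            return hz_to_bark(f)
        if self.name == "ERB":
            return hz_to_erb(f)
        if self.name == "Mel":
            return hz_to_mel(f)
        if self.name == "ST":
            return hz_to_semitones(f, self.reference)
        return hz_to_log(f)

    def inverse(self, x):
        if self.name == "Hz":
            return x
        if self.name == "Bark":
            return bark_to_hz(x)
        if self.name == "ERB":
            return erb_to_hz(x)
        if self.name == "Mel":
            return mel_to_hz(x)
        if self.name == "ST":
            return semitones_to_hz(x, self.reference)
        return log_to_hz(x)


HZ = Scale("Hz")


def transform_dataset(data: Dataset, scale: Scale, cues=FREQUENCY_CUES) -> Dataset:
    """Replace the named frequency cues by their values on ``scale``.

    Duration is never transformed (it is not a frequency).  Timepoint
    columns of a requested formant are transformed along with its
    steady-state column.  Token count and row order are preserved and the
    result is tagged with the scale name.
    """
    cues = tuple(cues)
    bad = [c for c in cues if c not in FREQUENCY_CUES]
    if bad:
        raise ConfigError(f"only frequency cues {FREQUENCY_CUES} can be scale-transformed, got {bad}")
    if data.scale != "Hz":
        raise ConfigError(f"dataset is already on the {data.scale} scale; transforms start from Hz")
    df = data.df.copy()
    for cue in cues:
        targets = [cue] if cue in df.columns else []
        targets += [
            timepoint_column(cue, tp)
            for tp in TIMEPOINTS
            if cue in data_model.FORMANTS and timepoint_column(cue, tp) in df.columns
        ]
        for col in targets:
            df[col] = scale.transform(df[col].to_numpy())
    return data.with_frame(df, scale=scale.name)
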