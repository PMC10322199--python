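"""Synthetic vowel-production data with known ground truth.

The generator emulates the structure of a dense hVd vowel database: ~17-24
talkers x 21 vowel categories x 10 tokens, with the lack-of-invariance
problem built in explicitly.  Each talker carries a multiplicative formant
scale (a vocal-tract-length analog), an F0 baseline, a speaking-rate
multiplier for duration, and small idiosyncratic log-space offsets.  Token
cues are drawn log-normally around category prototypes:

    ln Fn  = ln(prototype_n,c) + ln(scale_t) + idio_t,n + eps,   eps ~ N(0, Sigma_c)
    ln F0  = ln(f0_base_t) + offset_c + noise
    dur    = rate_t * base_c * exp(noise)

Short categories are more centralized (prototypes shrunk toward the
inventory centroid in log space) and less variable than their long
counterparts, and are separated from them primarily by duration.  All
default numeric hyperparameters are invented, documented testing defaults:
they reproduce the qualitative structure the analysis assumes, not any
particular database's numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import Dataset
from .errors import ConfigError, SwevowelError

#: Long-vowel prototypes: label -> (F1, F2, F3 in Hz, intrinsic F0 offset in
#: log space).  Values are plausible for adult female Central-Swedish-like
#: monophthongs; they are testing defaults, not measurements.
_LONG_PROTOTYPES: dict[str, tuple[float, float, float]] = {
    "hid": (280.0, 2500.0, 3250.0),
    "hyd": (285.0, 2200.0, 2700.0),
    "hud": (320.0, 1800.0, 2300.0),
    "hed": (390.0, 2400.0, 3050.0),
    "häd": (520.0, 2300.0, 2950.0),
    "höd": (400.0, 1700.0, 2400.0),
    "had": (700.0, 1150.0, 2750.0),
    "håd": (430.0, 800.0, 2700.0),
    "hod": (330.0, 700.0, 2550.0),
    "härd": (650.0, 2100.0, 2900.0),
    "hörd": (560.0, 1600.0, 2550.0),
}

#: Long -> short counterpart (the long [ε:] "häd" has no short counterpart
#: in the 21-category analysis inventory).
_SHORT_OF = {
    "hid": "hidd",
    "hyd": "hydd",
    "hud": "hudd",
    "hed": "hedd",
    "höd": "hödd",
    "had": "hadd",
    "håd": "hådd",
    "hod": "hodd",
    "härd": "härr",
    "hörd": "hörr",
}

DEFAULT_LONG_DURATION = 220.0   # ms
DEFAULT_SHORT_DURATION = 120.0  # ms


def _intrinsic_f0_offset(f1: float) -> float:
    """Close vowels carry slightly higher intrinsic F0 than open vowels."""
    if f1 < 350.0:
        return 0.05
    if f1 > 600.0:
        return -0.04
    return 0.0


def default_prototypes(
    centralization: float = 0.85,
    formant_noise_sd: float = 0.05,
    short_noise_factor: float = 0.8,
    long_duration: float = DEFAULT_LONG_DURATION,
    short_duration: float = DEFAULT_SHORT_DURATION,
) -> pd.DataFrame:
    """Build the default 21-category prototype table.

    Short prototypes are the long ones shrunk toward the long-inventory
    centroid in log F1-F2-F3 space by ``centralization`` (1 = no shrink),
    with formant noise sd scaled by ``short_noise_factor``.
    """
    if not 0 < centralization <= 1:
        raise ConfigError("centralization must be in (0, 1]")
    long_logs = np.log([[f1, f2, f3] for f1, f2, f3 in _LONG_PROTOTYPES.values()])
    centroid = long_logs.mean(axis=0)
    rows = []
    for vowel, (f1, f2, f3) in _LONG_PROTOTYPES.items():
        rows.append(
            {
                "vowel": vowel,
                "quantity": "long",
                "F1": f1,
                "F2": f2,
                "F3": f3,
                "duration_base": long_duration,
                "f0_offset": _intrinsic_f0_offset(f1),
                "formant_noise_sd": formant_noise_sd,
            }
        )
        if vowel in _SHORT_OF:
            shrunk = np.exp(centroid + centralization * (np.log([f1, f2, f3]) - centroid))
            rows.append(
                {
                    "vowel": _SHORT_OF[vowel],
                    "quantity": "short",
                    "F1": float(shrunk[0]),
                    "F2": float(shrunk[1]),
                    "F3": float(shrunk[2]),
                    "duration_base": short_duration,
                    "f0_offset": _intrinsic_f0_offset(float(shrunk[0])),
                    "formant_noise_sd": formant_noise_sd * short_noise_factor,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TalkerProfile:
    """Ground-truth talker-level transformation parameters."""

    talker_id: str
    formant_scale: float
    f0_base: float
    rate: float
    idio_shift: Mapping[str, float]  # additive log-space offsets per formant

    def __post_init__(self) -> None:
        if not (self.formant_scale > 0 and self.f0_base > 0 and self.rate > 0):
            raise ConfigError("formant_scale, f0_base and rate must all be positive")


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic database.

    Defaults emulate the post-exclusion design of a dense single-variety
    hVd corpus: 17 talkers, 21 categories, 10 tokens per cell.
    """

    n_talkers: int = 17
    tokens_per_cell: int = 10
    prototypes: pd.DataFrame = field(default_factory=default_prototypes)
    formant_scale_sd: float = 0.06   # sd of ln(formant_scale) across talkers
    rate_sd: float = 0.12            # sd of ln(rate) across talkers
    f0_base_median: float = 200.0    # Hz, median talker F0 baseline
    f0_base_sd: float = 0.10         # sd of ln(f0_base)
    idio_sd: float = 0.02            # per-talker per-formant log offsets
    formant_corr: float = 0.3        # within-category correlation of adjacent formants
    f0_noise_sd: float = 0.08        # token-level sd of ln F0
    duration_noise_sd: float = 0.10  # token-level sd of ln duration
    seed: int = 0

    def validate(self) -> None:
        if self.n_talkers < 1 or self.tokens_per_cell < 1:
            raise ConfigError("n_talkers and tokens_per_cell must be positive")
        for name in ("formant_scale_sd", "rate_sd", "f0_base_sd", "idio_sd", "f0_noise_sd", "duration_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not -0.99 < self.formant_corr < 0.99:
            raise ConfigError("formant_corr must lie strictly within (-0.99, 0.99)")
        needed = {"vowel", "quantity", "F1", "F2", "F3", "duration_base", "f0_offset", "formant_noise_sd"}
        missing = needed - set(self.prototypes.columns)
        if missing:
            raise ConfigError(f"prototype table missing columns: {sorted(missing)}")
        proto = self.prototypes
        long_d = proto.loc[proto["quantity"] == "long", "duration_base"]
        short_d = proto.loc[proto["quantity"] == "short", "duration_base"]
        if len(long_d) and len(short_d) and not long_d.min() > short_d.max():
            raise ConfigError("long-category duration bases must exceed short-category bases")
        # positive definiteness of every category covariance (the zero-noise
        # limit is allowed: it degenerates to point prototypes)
        for _, row in proto.iterrows():
            sd = float(row["formant_noise_sd"])
            if sd > 0:
                np.linalg.cholesky(self.category_covariance(sd))

    def category_covariance(self, noise_sd: float) -> np.ndarray:
        """3x3 log-space formant covariance: equal sds, AR(1)-like correlation."""
        r = self.formant_corr
        corr = np.array([[1.0, r, r * r], [r, 1.0, r], [r * r, r, 1.0]])
        return (noise_sd**2) * corr

    @property
    def inventory(self) -> dict[str, str]:
        return dict(zip(self.prototypes["vowel"], self.prototypes["quantity"]))


def _as_rng(rng: np.random.Generator | int | None, seed: int) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(seed)
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def sample_talkers(config: SyntheticConfig, rng: np.random.Generator | int | None = None) -> list[TalkerProfile]:
    """Draw talker profiles: log-normal formant scale and rate, log-normal
    F0 baseline, small idiosyncratic formant offsets."""
    config.validate()
    rng = _as_rng(rng, config.seed)
    profiles = []
    for i in range(config.n_talkers):
        profiles.append(
            TalkerProfile(
                talker_id=f"T{i + 1:02d}",
                formant_scale=float(np.exp(rng.normal(0.0, config.formant_scale_sd))),
                f0_base=float(config.f0_base_median * np.exp(rng.normal(0.0, config.f0_base_sd))),
                rate=float(np.exp(rng.normal(0.0, config.rate_sd))),
                idio_shift={f: float(rng.normal(0.0, config.idio_sd)) for f in ("F1", "F2", "F3")},
            )
        )
    return profiles


def generate_dataset(
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 100,
) -> tuple[Dataset, list[TalkerProfile]]:
    """Generate a synthetic dataset plus its ground-truth talker profiles.

    Tokens violating the F1 < F2 < F3 ordering are rejected and resampled
    (up to ``max_retries`` per token; a failure raises).
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = _as_rng(rng, config.seed)
    profiles = sample_talkers(config, rng)

    records = []
    for profile in profiles:
        idio = np.array([profile.idio_shift[f] for f in ("F1", "F2", "F3")])
        log_scale = np.log(profile.formant_scale)
        for _, proto in config.prototypes.iterrows():
            mean_log = np.log([proto["F1"], proto["F2"], proto["F3"]]) + log_scale + idio
            cov = config.category_covariance(float(proto["formant_noise_sd"]))
            for i in range(config.tokens_per_cell):
                for attempt in range(max_retries):
                    formants = np.exp(rng.multivariate_normal(mean_log, cov))
                    if formants[0] < formants[1] < formants[2]:
                        break
                else:
                    raise SwevowelError(
                        f"could not sample ordered formants for {profile.talker_id}/{proto['vowel']}"
                    )
                f0 = profile.f0_base * np.exp(proto["f0_offset"] + rng.normal(0.0, config.f0_noise_sd))
                duration = profile.rate * proto["duration_base"] * np.exp(rng.normal(0.0, config.duration_noise_sd))
                records.append(
                    {
                        "talker": profile.talker_id,
                        "vowel": proto["vowel"],
                        "quantity": proto["quantity"],
                        "token_id": f"t{i + 1:02d}",
                        "F0": float(f0),
                        "F1": float(formants[0]),
                        "F2": float(formants[1]),
                        "F3": float(formants[2]),
                        "duration": float(duration),
                        "intended_vowel": pd.NA,
                    }
                )
    df = pd.DataFrame(records)
    dataset = Dataset(df=df, inventory=config.inventory, provenance="synthetic")
    return dataset, profiles


def profiles_frame(profiles: list[TalkerProfile]) -> pd.DataFrame:
    """Tidy frame of ground-truth talker parameters (for CSV export)."""
    return pd.DataFrame(
        {
            "talker": [p.talker_id for p in profiles],
            "formant_scale": [p.formant_scale for p in profiles],
            "f0_base": [p.f0_base for p in profiles],
            "rate": [p.rate for p in profiles],
            "idio_F1": [p.idio_shift["F1"] for p in profiles],
            "idio_F2": [p.idio_shift["F2"] for p in profiles],
            "idio_F3": [p.idio_shift["F3"] for p in profiles],
        }
    )
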