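"""The 15 vowel normalization accounts.

Accounts fall into four families:

* **transformations** — map Hz into a perceptual scale (Bark, ERB, Mel,
  semitones) without using any talker information;
* **intrinsic accounts** — re-express a token using only that token's own
  cues (Syrdal & Gopal's Bark-distance model; Miller's formant-ratio model,
  whose sensory reference is the one talker-level quantity, the geometric
  mean F0);
* **centering accounts** — subtract a talker-specific mean per cue
  (C-CuRE on any scale; Nearey's log-mean variants);
* **standardizing accounts** — additionally rescale by talker-specific
  spread (Lobanov z-scores) or range (Gerstman).

Parameter fitting (talker statistics) is strictly separated from
application: a fitted :class:`NormalizationModel` can be applied to held-out
tokens of the same talkers without ever reading their statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import CUES, Dataset, FORMANTS, FREQUENCY_CUES
from .errors import ConfigError, DegenerateStatsError, FitError, SwevowelError, ValidationError
from .scales import Scale, transform_dataset

DEFAULT_MILLER_K = 168.0   # Hz; Miller's (1989) published constant
GERSTMAN_SPAN = 999.0      # Gerstman's range-normalization multiplier

#: The full account roster, in presentation order.
ACCOUNT_ROSTER = (
    "raw-Hz",
    "Bark",
    "ERB",
    "Mel",
    "ST",
    "SyrdalGopal",
    "Miller",
    "CCuRE-Hz",
    "CCuRE-Bark",
    "CCuRE-ERB",
    "CCuRE-Mel",
    "Nearey1",
    "Nearey2",
    "Gerstman",
    "Lobanov",
)

TRANSFORM_ACCOUNTS = ("raw-Hz", "Bark", "ERB", "Mel", "ST")
INTRINSIC_ACCOUNTS = ("SyrdalGopal", "Miller")
CENTERING_ACCOUNTS = ("CCuRE-Hz", "CCuRE-Bark", "CCuRE-ERB", "CCuRE-Mel", "Nearey1", "Nearey2")
STANDARDIZING_ACCOUNTS = ("Gerstman", "Lobanov")
#: Accounts whose parameters are talker statistics over other tokens.
EXTRINSIC_ACCOUNTS = CENTERING_ACCOUNTS + STANDARDIZING_ACCOUNTS

_CCURE_SCALE = {"CCuRE-Hz": "Hz", "CCuRE-Bark": "Bark", "CCuRE-ERB": "ERB", "CCuRE-Mel": "Mel"}
_TRANSFORM_SCALE = {"raw-Hz": "Hz", "Bark": "Bark", "ERB": "ERB", "Mel": "Mel", "ST": "ST"}


def account_kind(account: str) -> str:
    if account in TRANSFORM_ACCOUNTS:
        return "transform"
    if account in INTRINSIC_ACCOUNTS:
        return "intrinsic"
    if account in CENTERING_ACCOUNTS:
        return "centering"
    if account in STANDARDIZING_ACCOUNTS:
        return "standardizing"
    raise ConfigError(f"unknown account {account!r}; choose from {ACCOUNT_ROSTER}")


# ---------------------------------------------------------------------------
# Talker statistics
# ---------------------------------------------------------------------------

@dataclass
class TalkerStats:
    """Per-talker, per-cue summary statistics fitted on training tokens.

    ``table`` is indexed by (talker, cue) with columns mean, sd (n−1), min,
    max, and log_mean (mean of natural-log values; NaN when any value is
    non-positive on the fitted scale).  ``grand_log_mean`` pools natural-log
    values over ``nearey2_formants``; ``gm_f0`` is the geometric mean F0 of
    each talker's training tokens.  ``scale`` records the scale of the data
    the statistics were computed on.
    """

    table: pd.DataFrame
    grand_log_mean: pd.Series
    gm_f0: pd.Series
    cues: tuple[str, ...]
    nearey2_formants: tuple[str, ...]
    scale: str = "Hz"

    @property
    def talkers(self) -> tuple[str, ...]:
        return tuple(self.table.index.get_level_values("talker").unique())

    def get(self, talker: str, cue: str, stat: str) -> float:
        return float(self.table.loc[(talker, cue), stat])

    def per_row(self, talkers: pd.Series, cue: str, stat: str) -> np.ndarray:
        """Align the statistic ``stat`` of cue ``cue`` to a talker column."""
        lookup = self.table.xs(cue, level="cue")[stat]
        vals = talkers.map(lookup)
        if vals.isna().any():
            unseen = sorted(set(talkers[vals.isna()]))
            raise SwevowelError(
                f"no fitted {stat}({cue}) for talker(s) {unseen}; "
                "statistics are fitted on training data only and never refit silently"
            )
        return vals.to_numpy(dtype=float)

    def per_row_series(self, talkers: pd.Series, series: pd.Series, what: str) -> np.ndarray:
        vals = talkers.map(series)
        if vals.isna().any():
            unseen = sorted(set(talkers[vals.isna()]))
            raise SwevowelError(f"no fitted {what} for talker(s) {unseen}")
        return vals.to_numpy(dtype=float)


def fit_talker_stats(
    training: Dataset,
    cues: Sequence[str],
    nearey2_formants: Sequence[str] | None = None,
) -> TalkerStats:
    """Fit per-talker summary statistics, pooled over all vowel categories.

    Requires every talker to contribute at least two training tokens (the
    sample sd is otherwise undefined).
    """
    cues = tuple(cues)
    missing = [c for c in cues if c not in training.df.columns]
    if missing:
        raise ConfigError(f"cues absent from dataset: {missing}")
    if nearey2_formants is None:
        nearey2_formants = tuple(c for c in FORMANTS if c in cues)
    nearey2_formants = tuple(nearey2_formants)

    df = training.df
    sizes = df.groupby("talker").size()
    too_few = sizes.index[sizes < 2].tolist()
    if too_few:
        raise FitError(f"talker(s) with fewer than 2 training tokens: {too_few}")
    if training.scale == "Hz":
        for cue in cues:
            if (df[cue] <= 0).any():
                raise ValidationError(f"non-positive {cue} value in training data")

    rows = []
    for talker, group in df.groupby("talker", sort=True):
        for cue in cues:
            v = group[cue].to_numpy(dtype=float)
            log_mean = float(np.mean(np.log(v))) if np.all(v > 0) else np.nan
            rows.append(
                {
                    "talker": talker,
                    "cue": cue,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)),
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                    "log_mean": log_mean,
                }
            )
    table = pd.DataFrame(rows).set_index(["talker", "cue"])

    glm = {}
    gm_f0 = {}
    for talker, group in df.groupby("talker", sort=True):
        if nearey2_formants:
            pooled = np.concatenate([group[c].to_numpy(dtype=float) for c in nearey2_formants])
            glm[talker] = float(np.mean(np.log(pooled))) if np.all(pooled > 0) else np.nan
        if "F0" in df.columns:
            f0 = group["F0"].to_numpy(dtype=float)
            gm_f0[talker] = float(np.exp(np.mean(np.log(f0)))) if np.all(f0 > 0) else np.nan
    return TalkerStats(
        table=table,
        grand_log_mean=pd.Series(glm, dtype=float),
        gm_f0=pd.Series(gm_f0, dtype=float),
        cues=cues,
        nearey2_formants=nearey2_formants,
        scale=training.scale,
    )


# ---------------------------------------------------------------------------
# Account application (training statistics in, normalized cues out)
# ---------------------------------------------------------------------------

def apply_ccure(
    data: Dataset,
    stats: TalkerStats,
    scale: Scale | None = None,
    include_duration: bool = True,
    cues: Sequence[str] | None = None,
) -> Dataset:
    """C-CuRE: subtract each talker's training mean from each cue.

    ``data`` must already be on the scale the statistics were fitted on.
    Duration is centered to the talker's mean duration iff
    ``include_duration`` (C-CuRE is the one account that applies to any
    cue, including temporal ones).
    """
    if scale is not None and scale.name != stats.scale:
        raise ConfigError(f"statistics fitted on {stats.scale} but scale {scale.name} requested")
    if data.scale != stats.scale:
        raise ConfigError(f"data on {data.scale} scale but statistics fitted on {stats.scale}")
    if cues is None:
        cues = [c for c in stats.cues if c != "duration"]
    df = data.df.copy()
    for cue in cues:
        df[cue] = df[cue].to_numpy(dtype=float) - stats.per_row(df["talker"], cue, "mean")
    if include_duration and "duration" in data.df.columns and "duration" in stats.cues:
        df["duration"] = df["duration"].to_numpy(dtype=float) - stats.per_row(df["talker"], "duration", "mean")
    return data.with_frame(df)


def apply_nearey1(data: Dataset, stats: TalkerStats, cues: Sequence[str] | None = None) -> Dataset:
    """Nearey's log-mean model: ln(F) minus the talker's per-cue log mean."""
    if cues is None:
        cues = [c for c in stats.cues if c in FREQUENCY_CUES]
    df = data.df.copy()
    for cue in cues:
        log_mean = stats.per_row(df["talker"], cue, "log_mean")
        if np.isnan(log_mean).any():
            raise DegenerateStatsError(f"log mean of {cue} undefined (non-positive training values)")
        df[cue] = np.log(df[cue].to_numpy(dtype=float)) - log_mean
    return data.with_frame(df)


def apply_nearey2(
    data: Dataset,
    stats: TalkerStats,
    formants: Sequence[str] | None = None,
    normalize_f0: bool = False,
) -> Dataset:
    """Nearey's single log-mean model: ln(F) minus one grand log mean per
    talker, pooled over the active formant set.

    F0, when normalized alongside the formants (five-cue conditions), is
    centered by its own log mean rather than the formant-pooled one.
    """
    if formants is None:
        formants = stats.nearey2_formants
    df = data.df.copy()
    glm = stats.per_row_series(df["talker"], stats.grand_log_mean, "grand log mean")
    if np.isnan(glm).any():
        raise DegenerateStatsError("grand log mean undefined (non-positive training values)")
    for cue in formants:
        df[cue] = np.log(df[cue].to_numpy(dtype=float)) - glm
    if normalize_f0:
        if "F0" not in df.columns:
            raise ConfigError("normalize_f0 requested but dataset has no F0 column")
        df["F0"] = np.log(df["F0"].to_numpy(dtype=float)) - stats.per_row(df["talker"], "F0", "log_mean")
    return data.with_frame(df)


def apply_gerstman(
    data: Dataset,
    stats: TalkerStats,
    cues: Sequence[str] | None = None,
    span: float = GERSTMAN_SPAN,
) -> Dataset:
    """Gerstman range normalization: affine map sending each talker's
    training minimum to 0 and maximum to ``span`` (999).

    Test values outside the training range are passed through un-clipped.
    """
    if cues is None:
        cues = [c for c in stats.cues if c in FREQUENCY_CUES]
    df = data.df.copy()
    for cue in cues:
        lo = stats.per_row(df["talker"], cue, "min")
        hi = stats.per_row(df["talker"], cue, "max")
        if np.any(hi <= lo):
            bad = sorted(set(df["talker"].to_numpy()[hi <= lo]))
            raise DegenerateStatsError(f"degenerate training range for cue {cue} of talker(s) {bad}")
        df[cue] = span * (df[cue].to_numpy(dtype=float) - lo) / (hi - lo)
    return data.with_frame(df)


def apply_lobanov(data: Dataset, stats: TalkerStats, cues: Sequence[str] | None = None) -> Dataset:
    """Lobanov normalization: per-talker, per-cue z-scores with training
    mean and sample sd."""
    if cues is None:
        cues = [c for c in stats.cues if c in FREQUENCY_CUES]
    df = data.df.copy()
    for cue in cues:
        mean = stats.per_row(df["talker"], cue, "mean")
        sd = stats.per_row(df["talker"], cue, "sd")
        if np.any(sd <= 0):
            bad = sorted(set(df["talker"].to_numpy()[sd <= 0]))
            raise DegenerateStatsError(f"zero training variance for cue {cue} of talker(s) {bad}")
        df[cue] = (df[cue].to_numpy(dtype=float) - mean) / sd
    return data.with_frame(df)


def apply_syrdal_gopal(data: Dataset) -> Dataset:
    """Syrdal & Gopal's Bark-distance model: height as F1−F0 and backness
    as F2−F1, both in Bark.  Intrinsic — no talker statistics.

    The output space is exactly two-dimensional; the F0 and F3 columns are
    consumed/dropped, duration (if present) is carried through untouched.
    """
    from .scales import hz_to_bark

    for needed in ("F0", "F1", "F2"):
        if needed not in data.df.columns:
            raise ConfigError(f"Syrdal-Gopal requires cue {needed}; account inapplicable")
    if data.scale != "Hz":
        raise ConfigError("Syrdal-Gopal starts from Hz (it applies its own Bark transform)")
    df = data.df.copy()
    f0b = hz_to_bark(df["F0"].to_numpy(dtype=float))
    f1b = hz_to_bark(df["F1"].to_numpy(dtype=float))
    f2b = hz_to_bark(df["F2"].to_numpy(dtype=float))
    df["F1"] = f1b - f0b
    df["F2"] = f2b - f1b
    df = df.drop(columns=[c for c in ("F0", "F3") if c in df.columns])
    return data.with_frame(df)


def apply_miller(
    data: Dataset,
    stats: TalkerStats,
    k: float = DEFAULT_MILLER_K,
    formants: Sequence[str] = FORMANTS,
    include_f0: bool = False,
) -> Dataset:
    """Miller's formant-ratio model.

    The talker's sensory reference is SR = k (GMf0 / k)^(1/3), where GMf0
    is the geometric mean F0 over the talker's training tokens.  Dimensions
    are log10 ratios: F1/SR, F2/F1 and — in the three-formant variant —
    F3/F2.  With ``include_f0`` the F0 column becomes log10(F0/SR).
    """
    if not k > 0:
        raise ConfigError("Miller's k must be positive")
    formants = tuple(formants)
    if "F1" not in formants or "F2" not in formants:
        raise ConfigError("Miller requires at least F1 and F2")
    missing = [c for c in formants if c not in data.df.columns]
    if missing:
        raise ConfigError(f"Miller formant cue(s) missing from dataset: {missing}")
    df = data.df.copy()
    sr = stats.per_row_series(df["talker"], stats.gm_f0, "geometric-mean F0")
    if np.isnan(sr).any():
        raise DegenerateStatsError("geometric-mean F0 undefined for some talker")
    sr = k * np.power(sr / k, 1.0 / 3.0)
    f1 = df["F1"].to_numpy(dtype=float)
    f2 = df["F2"].to_numpy(dtype=float)
    df["F1"] = np.log10(f1 / sr)
    df["F2"] = np.log10(f2 / f1)
    if "F3" in formants:
        df["F3"] = np.log10(df["F3"].to_numpy(dtype=float) / f2)
    if include_f0:
        df["F0"] = np.log10(df["F0"].to_numpy(dtype=float) / sr)
    return data.with_frame(df)


# ---------------------------------------------------------------------------
# Fitted models and dispatch
# ---------------------------------------------------------------------------

@dataclass
class NormalizationModel:
    """A fitted normalization account, applicable to new tokens.

    ``cues`` is the active cue set; ``output_cues`` describes the dimensions
    of the normalized space (the output frame keeps canonical column slots
    so that downstream cue selection is uniform across accounts).
    """

    account: str
    cues: tuple[str, ...]
    scale: Scale
    stats: TalkerStats | None
    output_cues: tuple[str, ...]
    constants: dict = field(default_factory=dict)

    @property
    def observer_cues(self) -> tuple[str, ...]:
        """Column names the ideal observer should read after normalization."""
        if self.account == "SyrdalGopal":
            return tuple(c for c in self.cues if c in ("F1", "F2", "duration"))
        return self.cues


def check_compatibility(account: str, cues: Sequence[str]) -> None:
    """Raise ConfigError for account/cue-set combinations that are undefined."""
    account_kind(account)  # validates the name
    cues = tuple(cues)
    unknown = [c for c in cues if c not in CUES]
    if unknown:
        raise ConfigError(f"unknown cue(s) {unknown}; cues are drawn from {CUES}")
    if account == "SyrdalGopal" and tuple(c for c in cues if c != "duration") != ("F1", "F2"):
        raise ConfigError(
            "Syrdal-Gopal is defined on exactly the F1/F2 comparison "
            "(F0 is consumed as the normalizer, not a category cue)"
        )
    if account == "Miller" and not {"F1", "F2"} <= set(cues):
        raise ConfigError("Miller requires F1 and F2 in the cue set")


def fit_normalization(
    training: Dataset,
    account: str,
    cues: Sequence[str],
    miller_k: float = DEFAULT_MILLER_K,
    st_reference: float = 100.0,
    nearey2_formants: Sequence[str] | None = None,
) -> NormalizationModel:
    """Fit a normalization account on training data for the given cue set.

    Transform-only and Syrdal-Gopal accounts have no fitted parameters;
    Miller fits only each talker's geometric-mean F0; extrinsic accounts fit
    the talker statistics they need, on the scale they operate on.
    """
    check_compatibility(account, cues)
    cues = tuple(cues)
    freq_cues = tuple(c for c in cues if c in FREQUENCY_CUES)
    formant_cues = tuple(c for c in cues if c in FORMANTS)
    kind = account_kind(account)
    constants: dict = {}
    stats: TalkerStats | None = None

    if account in TRANSFORM_ACCOUNTS:
        scale = Scale(_TRANSFORM_SCALE[account], reference=st_reference)
    elif account == "SyrdalGopal":
        scale = Scale("Bark")
    elif account == "Miller":
        scale = Scale("log")
        constants["k"] = float(miller_k)
        if not miller_k > 0:
            raise ConfigError("Miller's k must be positive")
        stats = fit_talker_stats(training, cues=("F0",))
    elif account in _CCURE_SCALE:
        scale = Scale(_CCURE_SCALE[account])
        on_scale = training if scale.name == "Hz" else transform_dataset(training, scale, cues=freq_cues)
        stats = fit_talker_stats(on_scale, cues=cues)
    elif account in ("Nearey1", "Nearey2"):
        scale = Scale("log")
        nf = tuple(nearey2_formants) if nearey2_formants is not None else formant_cues
        stats = fit_talker_stats(training, cues=freq_cues, nearey2_formants=nf)
    else:  # Gerstman, Lobanov
        scale = Scale("Hz")
        constants["span"] = GERSTMAN_SPAN
        stats = fit_talker_stats(training, cues=freq_cues)

    output_cues = _output_cue_names(account, cues, scale)
    return NormalizationModel(
        account=account, cues=cues, scale=scale, stats=stats,
        output_cues=output_cues, constants=constants,
    )


def _output_cue_names(account: str, cues: tuple[str, ...], scale: Scale) -> tuple[str, ...]:
    if account == "SyrdalGopal":
        named = ("F1-F0 [Bark]", "F2-F1 [Bark]")
        return named + (("duration [ms]",) if "duration" in cues else ())
    if account == "Miller":
        names = []
        for c in cues:
            if c == "F0":
                names.append("log10(F0/SR)")
            elif c == "F1":
                names.append("log10(F1/SR)")
            elif c == "F2":
                names.append("log10(F2/F1)")
            elif c == "F3":
                names.append("log10(F3/F2)")
            else:
                names.append("duration [ms]")
        return tuple(names)
    suffix = {
        "transform": f" [{scale.name}]",
        "centering": f" − talker mean [{scale.name}]",
        "standardizing": " (talker-standardized)",
    }[account_kind(account)] if account != "raw-Hz" else " [Hz]"
    out = []
    for c in cues:
        if c == "duration":
            out.append("duration − talker mean [ms]" if account.startswith("CCuRE") else "duration [ms]")
        else:
            out.append(c + suffix)
    return tuple(out)


def normalize(data: Dataset, model: NormalizationModel) -> Dataset:
    """Apply a fitted account to a dataset on the Hz scale.

    The returned dataset carries only the identifier columns and the active
    cue columns, tagged with the account and scale for provenance.
    Deterministic; never reads statistics from ``data``.
    """
    if data.scale != "Hz":
        raise ConfigError(f"normalize expects raw Hz data, got scale {data.scale}")
    for cue in model.cues:
        if cue not in data.df.columns:
            raise ConfigError(
                f"cue {cue} missing from dataset; average timepoints first if only "
                "per-timepoint formant columns are present"
            )
    account = model.account
    freq_cues = tuple(c for c in model.cues if c in FREQUENCY_CUES)
    formant_cues = tuple(c for c in model.cues if c in FORMANTS)

    if account == "raw-Hz":
        out = data.with_frame(data.df)
    elif account in TRANSFORM_ACCOUNTS:
        out = transform_dataset(data, model.scale, cues=freq_cues)
    elif account == "SyrdalGopal":
        out = apply_syrdal_gopal(data)
    elif account == "Miller":
        out = apply_miller(
            data, model.stats, k=model.constants["k"],
            formants=formant_cues, include_f0="F0" in model.cues,
        )
    elif account in _CCURE_SCALE:
        on_scale = data if model.scale.name == "Hz" else transform_dataset(data, model.scale, cues=freq_cues)
        out = apply_ccure(on_scale, model.stats, include_duration="duration" in model.cues, cues=freq_cues)
    elif account == "Nearey1":
        out = apply_nearey1(data, model.stats, cues=freq_cues)
    elif account == "Nearey2":
        out = apply_nearey2(
            data, model.stats, formants=model.stats.nearey2_formants,
            normalize_f0="F0" in model.cues,
        )
    elif account == "Gerstman":
        out = apply_gerstman(data, model.stats, cues=freq_cues, span=model.constants["span"])
    else:  # Lobanov
        out = apply_lobanov(data, model.stats, cues=freq_cues)

    keep = ["talker", "vowel", "quantity", "token_id", "intended_vowel"]
    keep += [c for c in model.observer_cues if c in out.df.columns]
    out = out.with_frame(out.df[keep], account=account, scale=model.scale.name)
    return out
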