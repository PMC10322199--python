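"""Domain types and table I/O for vowel-production data.

A dataset is one row per recorded vowel token: a talker identifier, the
produced vowel category, the vowel's quantity class (long/short), and the
acoustic cues F0, F1-F3 (Hz) and duration (ms).  Formants may be measured
either as a single steady-state value or at several named timepoints into
the vowel (20/35/50/65/80 %), in which case the steady state is obtained by
averaging the mid-vowel measurements.

Units are fixed: Hz for frequencies, ms for duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError, SchemaError, SwevowelError, ValidationError

logger = logging.getLogger("swevowel")

#: Acoustic cue columns, in canonical order.
CUES = ("F0", "F1", "F2", "F3", "duration")
#: Formant cues (subject to timepoint measurement and scale transforms).
FORMANTS = ("F1", "F2", "F3")
#: Frequency cues (transformable to perceptual scales).
FREQUENCY_CUES = ("F0", "F1", "F2", "F3")
#: Valid within-vowel measurement points (% into the vowel).
TIMEPOINTS = (20, 35, 50, 65, 80)
#: Mid-vowel timepoints used for the steady-state average.
DEFAULT_TIMEPOINT_SELECTION = (35, 50, 65)

ID_COLUMNS = ("talker", "vowel", "token_id")
CANONICAL_COLUMNS = ID_COLUMNS + ("quantity",) + CUES + ("intended_vowel",)

#: Category conventionally dropped from analyses (elicits the same short
#: vowel as "hedd").
DEFAULT_DROP_CATEGORIES = ("hädd",)


def load_inventory(path: str | Path | None = None) -> dict[str, str]:
    """Load a vowel inventory mapping category label -> quantity class.

    With no argument, returns the bundled 22-word Central Swedish hVd
    inventory (21 analysis categories plus the conventionally dropped
    ``hädd``).
    """
    if path is None:
        text = resources.files("swevowel.data").joinpath("central_swedish.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    inventory = yaml.safe_load(text)
    if not isinstance(inventory, dict):
        raise SchemaError("inventory file must be a mapping vowel -> quantity")
    for vowel, quantity in inventory.items():
        if quantity not in ("long", "short"):
            raise SchemaError(f"inventory quantity for {vowel!r} must be 'long' or 'short', got {quantity!r}")
    return dict(inventory)


def timepoint_column(cue: str, timepoint: int) -> str:
    return f"{cue}_{timepoint}"


@dataclass(frozen=True)
class VowelToken:
    """One vowel production.

    ``F1``--``F3`` are either a single steady-state value in Hz or a mapping
    timepoint (% into the vowel) -> Hz.
    """

    talker: str
    vowel: str
    quantity: str
    token_id: str
    F0: float
    F1: float | Mapping[int, float]
    F2: float | Mapping[int, float]
    F3: float | Mapping[int, float]
    duration: float
    intended_vowel: str | None = None

    def __post_init__(self) -> None:
        if self.quantity not in ("long", "short"):
            raise ValidationError(f"token {self.talker}/{self.vowel}/{self.token_id}: bad quantity {self.quantity!r}")
        for name in ("F0", "duration"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(f"token {self.talker}/{self.vowel}/{self.token_id}: {name} must be positive")
        for tp in self.formant_timepoints() or [None]:
            f1, f2, f3 = (self.formant(n, tp) for n in FORMANTS)
            where = f" at timepoint {tp}%" if tp is not None else ""
            if any(not np.isfinite(v) or v <= 0 for v in (f1, f2, f3)):
                raise ValidationError(
                    f"token {self.talker}/{self.vowel}/{self.token_id}: formants must be positive{where}"
                )
            if not (f1 < f2 < f3):
                raise ValidationError(
                    f"token {self.talker}/{self.vowel}/{self.token_id}: requires F1 < F2 < F3{where}"
                )

    def formant_timepoints(self) -> tuple[int, ...]:
        """Timepoints at which formants were measured (empty if steady-state)."""
        if isinstance(self.F1, Mapping):
            return tuple(sorted(self.F1))
        return ()

    def formant(self, name: str, timepoint: int | None = None) -> float:
        value = getattr(self, name)
        if isinstance(value, Mapping):
            if timepoint is None:
                raise SwevowelError(f"{name} of token {self.token_id} is a timepoint vector; specify a timepoint")
            if timepoint not in value:
                raise SwevowelError(
                    f"token {self.talker}/{self.vowel}/{self.token_id}: timepoint {timepoint}% missing for {name}"
                )
            return float(value[timepoint])
        return float(value)


@dataclass
class Dataset:
    """A collection of vowel tokens backed by a tidy :class:`pandas.DataFrame`.

    Columns: talker, vowel, quantity, token_id, F0, F1, F2, F3, duration,
    intended_vowel, plus optional timepoint columns ``<formant>_<pct>``.
    ``scale`` and ``account`` tag the provenance of the cue values (raw data
    is on the Hz scale under the raw-Hz account).
    """

    df: pd.DataFrame
    inventory: dict[str, str]
    provenance: str = ""
    scale: str = "Hz"
    account: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS + ("quantity",) if c not in self.df.columns]
        if missing:
            raise SchemaError(f"dataset frame missing required columns: {missing}")
        if "intended_vowel" not in self.df.columns:
            self.df = self.df.assign(intended_vowel=pd.Series(pd.NA, index=self.df.index, dtype="object"))
        else:
            # canonical missing marker: object dtype with pd.NA (CSV round trips
            # would otherwise flip an all-missing column to float NaN)
            col = self.df["intended_vowel"].astype("object")
            self.df = self.df.assign(intended_vowel=col.where(col.notna(), pd.NA))
        dupes = self.df.duplicated(subset=list(ID_COLUMNS))
        if dupes.any():
            rows = self.df.index[dupes].tolist()[:10]
            raise ValidationError(f"duplicate (talker, vowel, token_id) triples at rows {rows}")
        unknown = set(self.df["vowel"]) - set(self.inventory)
        if unknown:
            raise ValidationError(f"vowel labels not in inventory: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def talkers(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["talker"].unique()))

    @property
    def vowels(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["vowel"].unique()))

    def timepoint_columns(self) -> tuple[str, ...]:
        return tuple(
            timepoint_column(cue, tp)
            for cue in FORMANTS
            for tp in TIMEPOINTS
            if timepoint_column(cue, tp) in self.df.columns
        )

    @property
    def tokens(self) -> Iterator[VowelToken]:
        tp_cols = {
            cue: [(tp, timepoint_column(cue, tp)) for tp in TIMEPOINTS if timepoint_column(cue, tp) in self.df.columns]
            for cue in FORMANTS
        }
        for _, row in self.df.iterrows():
            formants = {}
            for cue in FORMANTS:
                if tp_cols[cue]:
                    formants[cue] = {tp: float(row[col]) for tp, col in tp_cols[cue]}
                else:
                    formants[cue] = float(row[cue])
            intended = row.get("intended_vowel")
            yield VowelToken(
                talker=str(row["talker"]),
                vowel=str(row["vowel"]),
                quantity=str(row["quantity"]),
                token_id=str(row["token_id"]),
                F0=float(row["F0"]),
                duration=float(row["duration"]),
                intended_vowel=None if pd.isna(intended) else str(intended),
                **formants,
            )

    def with_frame(self, df: pd.DataFrame, **tags) -> "Dataset":
        """Return a copy of this dataset around a replacement frame."""
        out = replace(self, df=df.copy())
        for key, value in tags.items():
            setattr(out, key, value)
        return out

    def subset_quantity(self, which: str) -> "Dataset":
        """Restrict to 'long' or 'short' vowels ('all' is a no-op)."""
        if which == "all":
            return self.with_frame(self.df)
        if which not in ("long", "short"):
            raise ConfigError(f"vowel subset must be 'long', 'short' or 'all', got {which!r}")
        return self.with_frame(self.df[self.df["quantity"] == which])

    def equals(self, other: "Dataset") -> bool:
        if self.inventory != other.inventory or self.scale != other.scale:
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if sorted(a.columns) != sorted(b.columns):
            return False
        return a[sorted(a.columns)].equals(b[sorted(b.columns)])


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _resolve_schema(schema: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    """Return mapping canonical name -> file column name."""
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        loaded = yaml.safe_load(Path(schema).read_text("utf-8"))
        if not isinstance(loaded, dict):
            raise SchemaError("schema file must be a mapping canonical -> file column")
        return {str(k): str(v) for k, v in loaded.items()}
    return dict(schema)


def _invariant_violations(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Row-addressed positivity / formant-order violations."""
    problems: list[tuple[int, str]] = []
    cue_cols = [c for c in CUES if c in df.columns]
    tp_cols = [
        (cue, tp, timepoint_column(cue, tp))
        for cue in FORMANTS
        for tp in TIMEPOINTS
        if timepoint_column(cue, tp) in df.columns
    ]
    for col in cue_cols + [c for _, _, c in tp_cols]:
        bad = df.index[~(df[col] > 0) | ~np.isfinite(df[col])]
        problems.extend((int(i), f"{col} must be positive") for i in bad)
    # formant ordering, steady state
    if all(c in df.columns for c in FORMANTS):
        bad = df.index[~((df["F1"] < df["F2"]) & (df["F2"] < df["F3"]))]
        problems.extend((int(i), "requires F1 < F2 < F3") for i in bad)
    # formant ordering per timepoint
    for tp in TIMEPOINTS:
        cols = [timepoint_column(cue, tp) for cue in FORMANTS]
        if all(c in df.columns for c in cols):
            f1, f2, f3 = (df[c] for c in cols)
            bad = df.index[~((f1 < f2) & (f2 < f3))]
            problems.extend((int(i), f"requires F1 < F2 < F3 at timepoint {tp}%") for i in bad)
    return sorted(set(problems))


def read_token_table(
    path: str | Path,
    schema: Mapping[str, str] | str | Path | None = None,
    inventory: Mapping[str, str] | str | Path | None = None,
    on_invalid: str = "drop",
    provenance: str | None = None,
) -> Dataset:
    """Read a vowel-token table from CSV into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file (RFC-4180, UTF-8, header row, decimal point ".").
    schema
        Optional remapping of canonical column names to the file's column
        names (dict or YAML file path).
    inventory
        Vowel inventory (mapping or YAML path); defaults to the bundled
        Central Swedish inventory.
    on_invalid
        ``"drop"`` rejects rows violating positivity/ordering invariants and
        reports them in a warning; ``"raise"`` raises ``ValidationError``.
    """
    path = Path(path)
    if not path.exists():
        raise SwevowelError(f"no such file: {path}")
    if on_invalid not in ("drop", "raise"):
        raise ConfigError("on_invalid must be 'drop' or 'raise'")
    try:
        raw = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SwevowelError(f"empty input file: {path}") from None
    if raw.empty:
        raise SwevowelError(f"input file has a header but no rows: {path}")

    mapping = _resolve_schema(schema)
    rename = {file_col: canon for canon, file_col in mapping.items() if file_col in raw.columns}
    missing_mapped = [file_col for file_col in mapping.values() if file_col not in raw.columns]
    if missing_mapped:
        raise SchemaError(f"schema names columns absent from the file: {missing_mapped}")
    df = raw.rename(columns=rename)

    for col in ID_COLUMNS + ("F0", "duration"):
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col!r}")
    for cue in FORMANTS:
        has_tp = any(timepoint_column(cue, tp) in df.columns for tp in TIMEPOINTS)
        if cue not in df.columns and not has_tp:
            raise SchemaError(f"required column missing: {cue!r} (no steady-state or timepoint columns)")

    numeric_cols = [c for c in CUES if c in df.columns] + [
        timepoint_column(cue, tp)
        for cue in FORMANTS
        for tp in TIMEPOINTS
        if timepoint_column(cue, tp) in df.columns
    ]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"non-numeric value in column {col!r} at row(s) {bad.tolist()[:10]}")
        if coerced.isna().any():
            raise ParseError(f"missing value in column {col!r} at row(s) {df.index[coerced.isna()].tolist()[:10]}")
        df[col] = coerced.astype(float)

    for col in ID_COLUMNS:
        df[col] = df[col].astype(str)

    inv = inventory if isinstance(inventory, Mapping) else load_inventory(inventory)
    inv = dict(inv)
    unknown = set(df["vowel"]) - set(inv)
    if unknown:
        raise ValidationError(f"vowel labels not in inventory: {sorted(unknown)}")
    expected_quantity = df["vowel"].map(inv)
    if "quantity" in df.columns:
        mismatch = df.index[df["quantity"].astype(str) != expected_quantity]
        if len(mismatch):
            raise ValidationError(
                f"quantity column disagrees with the inventory at row(s) {mismatch.tolist()[:10]}"
            )
    df["quantity"] = expected_quantity
    if "intended_vowel" in df.columns:
        df["intended_vowel"] = df["intended_vowel"].where(df["intended_vowel"].notna(), pd.NA).astype("object")

    problems = _invariant_violations(df)
    if problems:
        diagnostics = "; ".join(f"row {i}: {msg}" for i, msg in problems[:20])
        if on_invalid == "raise":
            raise ValidationError(f"{len(problems)} invariant violation(s): {diagnostics}")
        warnings.warn(f"rejected {len(set(i for i, _ in problems))} row(s): {diagnostics}", stacklevel=2)
        df = df.drop(index=sorted(set(i for i, _ in problems)))
        if df.empty:
            raise SwevowelError("all rows rejected by invariant checks")

    keep = [c for c in CANONICAL_COLUMNS if c in df.columns]
    keep += [c for c in df.columns if c not in keep and any(c == timepoint_column(f, t) for f in FORMANTS for t in TIMEPOINTS)]
    df = df[keep].reset_index(drop=True)
    return Dataset(df=df, inventory=inv, provenance=provenance or str(path))


def write_token_table(data: Dataset, path: str | Path) -> None:
    """Write a dataset back to canonical CSV (UTF-8, '.' decimal)."""
    cols = [c for c in CANONICAL_COLUMNS if c in data.df.columns] + list(data.timepoint_columns())
    out = data.df[cols].copy()
    if data.account is not None:
        out["account"] = data.account
        out["scale"] = data.scale
    # %.17g guarantees bit-exact float round trips through text
    out.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


# ---------------------------------------------------------------------------
# Timepoint averaging
# ---------------------------------------------------------------------------

def average_formant_timepoints(
    token: VowelToken, selection: Iterable[int] = DEFAULT_TIMEPOINT_SELECTION
) -> VowelToken:
    """Replace a token's formant vectors by their mean over ``selection``.

    F0 and duration are unchanged.  The default selection is the three
    mid-vowel measurement points (35, 50, 65 % into the vowel).
    """
    selection = tuple(sorted(selection))
    if not selection:
        raise ConfigError("timepoint selection must be non-empty")
    means = {}
    for cue in FORMANTS:
        means[cue] = float(np.mean([token.formant(cue, tp) for tp in selection]))
    return replace(token, **means)


def average_timepoints(
    data: Dataset, selection: Iterable[int] = DEFAULT_TIMEPOINT_SELECTION
) -> Dataset:
    """Dataset-level timepoint averaging: collapse ``<formant>_<pct>`` columns
    into steady-state formant columns."""
    selection = tuple(sorted(selection))
    if not selection:
        raise ConfigError("timepoint selection must be non-empty")
    df = data.df.copy()
    for cue in FORMANTS:
        cols = [timepoint_column(cue, tp) for tp in selection]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SwevowelError(f"selected timepoint column(s) missing for {cue}: {missing}")
        df[cue] = df[cols].mean(axis=1)
    df = df.drop(columns=list(data.timepoint_columns()))
    return data.with_frame(df)


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionReport:
    """Token/talker counts removed by each exclusion rule, in application
    order: produced/intended mismatches, then talkers below the per-vowel
    token minimum, then dropped categories."""

    mismatched_tokens: int
    talkers_dropped: int
    dropped_talkers: tuple[str, ...]
    talker_rule_tokens: int
    category_tokens: int
    dropped_categories: tuple[str, ...] = field(default=())

    @property
    def total_tokens_removed(self) -> int:
        return self.mismatched_tokens + self.talker_rule_tokens + self.category_tokens


def apply_exclusions(
    data: Dataset,
    min_tokens: int = 5,
    drop_mismatched: bool = True,
    drop_categories: Sequence[str] = DEFAULT_DROP_CATEGORIES,
) -> tuple[Dataset, ExclusionReport]:
    """Apply the standard exclusion filters, in order.

    1. Remove tokens whose produced vowel differs from the intended one
       (where ``intended_vowel`` is recorded).
    2. Remove entire talkers that have fewer than ``min_tokens`` remaining
       tokens for any vowel occurring in the (post-step-1) dataset.
    3. Remove all tokens of ``drop_categories``.
    """
    if min_tokens < 1:
        raise ConfigError("min_tokens must be >= 1")
    df = data.df

    if drop_mismatched and "intended_vowel" in df.columns:
        intended = df["intended_vowel"]
        mismatch = intended.notna() & (intended.astype("object") != df["vowel"])
    else:
        mismatch = pd.Series(False, index=df.index)
    n_mismatch = int(mismatch.sum())
    df = df[~mismatch]

    vowels_present = sorted(df["vowel"].unique())
    counts = df.groupby(["talker", "vowel"], sort=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=vowels_present, fill_value=0)
    bad_talkers = tuple(sorted(counts.index[(counts < min_tokens).any(axis=1)]))
    talker_mask = df["talker"].isin(bad_talkers)
    n_talker_tokens = int(talker_mask.sum())
    df = df[~talker_mask]

    drop_categories = tuple(drop_categories)
    cat_mask = df["vowel"].isin(drop_categories)
    n_cat = int(cat_mask.sum())
    df = df[~cat_mask]

    if df.empty:
        warnings.warn("dataset is empty after exclusions", stacklevel=2)

    report = ExclusionReport(
        mismatched_tokens=n_mismatch,
        talkers_dropped=len(bad_talkers),
        dropped_talkers=bad_talkers,
        talker_rule_tokens=n_talker_tokens,
        category_tokens=n_cat,
        dropped_categories=drop_categories,
    )
    logger.info("exclusions: %s", report)
    return data.with_frame(df.reset_index(drop=True)), report
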