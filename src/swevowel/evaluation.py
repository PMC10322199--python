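"""Stratified cross-validated evaluation of normalization accounts.

The experiment grid crosses the 15 accounts with three cue sets (F1-F2;
F1-F3; F0-F3 plus duration) and three vowel subsets (long, short, all).
For each compatible cell, tokens are split per talker-by-vowel into k
(default 5) even folds; on each fold the normalization parameters and the
ideal-observer category parameters are fitted on the other k−1 folds and
accuracy is measured on the held-out fold, with a percentile-bootstrap 95%
confidence interval per fold (endpoint-averaged across folds in the
summary).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset
from .errors import ConfigError, SwevowelError
from .ideal_observer import confusion_table, evaluate_accuracy, fit_observer
from .normalization import (
    ACCOUNT_ROSTER,
    DEFAULT_MILLER_K,
    check_compatibility,
    fit_normalization,
    normalize,
)

logger = logging.getLogger("swevowel")

#: The three cue-set conditions, keyed by short name.
CUE_SETS: dict[str, tuple[str, ...]] = {
    "F1-F2": ("F1", "F2"),
    "F1-F3": ("F1", "F2", "F3"),
    "F0-F3+dur": ("F0", "F1", "F2", "F3", "duration"),
}

VOWEL_SUBSETS = ("long", "short", "all")


@dataclass(frozen=True)
class FoldAssignment:
    """A deterministic token -> fold mapping, stratified by talker x vowel.

    Within every talker-by-vowel cell, fold sizes differ by at most one.
    """

    assignment: pd.Series  # index aligned with the dataset frame, values 1..k
    k: int
    seed: int

    def train_test(self, data: Dataset, fold: int) -> tuple[Dataset, Dataset]:
        if fold not in range(1, self.k + 1):
            raise ConfigError(f"fold must be in 1..{self.k}")
        mask = self.assignment.reindex(data.df.index)
        if mask.isna().any():
            raise SwevowelError("fold assignment does not cover the dataset (was the data re-indexed?)")
        test = data.with_frame(data.df[mask == fold])
        train = data.with_frame(data.df[mask != fold])
        return train, test


def make_folds(data: Dataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Split tokens of every talker-by-vowel cell into k near-even folds.

    Each cell is shuffled under the seed and dealt round-robin, so cell
    fold sizes differ by at most one.  Cells smaller than k are allowed
    with a warning (some folds then miss that cell).
    """
    if k < 2:
        raise ConfigError("fold count k must be at least 2")
    rng = np.random.default_rng(seed)
    assignment = pd.Series(0, index=data.df.index, dtype=int)
    small_cells = []
    for (talker, vowel), group in data.df.groupby(["talker", "vowel"], sort=True):
        n = len(group)
        if n < k:
            small_cells.append((talker, vowel, n))
        order = rng.permutation(n)
        folds = (np.arange(n) % k) + 1
        assignment.loc[group.index[order]] = folds
    if small_cells:
        warnings.warn(
            f"{len(small_cells)} talker-by-vowel cell(s) have fewer than {k} tokens "
            f"(e.g. {small_cells[:3]}); folds will be uneven for those cells",
            stacklevel=2,
        )
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def bootstrap_ci(
    outcomes: Sequence[float] | np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of a binary outcome vector."""
    outcomes = np.asarray(outcomes, dtype=float)
    if outcomes.size == 0:
        raise ConfigError("outcomes must be non-empty")
    if B < 2:
        raise ConfigError("bootstrap replicate count B must be at least 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, outcomes.size, size=(B, outcomes.size))
    means = outcomes[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


@dataclass
class ConditionResult:
    """Cross-validated accuracy for one account x cue set x vowel subset."""

    account: str
    cue_set: str
    vowel_subset: str
    fold_accuracies: list[float]
    mean_accuracy: float
    ci: tuple[float, float]            # endpoint-averaged across folds
    fold_cis: list[tuple[float, float]]
    mean_p_intended: float
    confusions: list[pd.DataFrame] = field(repr=False, default_factory=list)
    n_test: int = 0
    ci_method: str = "percentile bootstrap per fold, endpoints averaged across folds"

    def to_rows(self) -> pd.DataFrame:
        """Tidy one-row-per-fold frame."""
        return pd.DataFrame(
            {
                "account": self.account,
                "cue_set": self.cue_set,
                "vowel_subset": self.vowel_subset,
                "fold": np.arange(1, len(self.fold_accuracies) + 1),
                "accuracy": self.fold_accuracies,
                "ci_lower": [c[0] for c in self.fold_cis],
                "ci_upper": [c[1] for c in self.fold_cis],
                "mean_accuracy": self.mean_accuracy,
            }
        )


def run_condition(
    data: Dataset,
    account: str,
    cue_set: str | Sequence[str],
    vowel_subset: str,
    folds: FoldAssignment,
    rule: str = "criterion",
    n_boot: int = 1000,
    miller_k: float = DEFAULT_MILLER_K,
    rng: np.random.Generator | None = None,
) -> ConditionResult:
    """Evaluate one account under one cue set and vowel subset.

    Per fold: fit the normalization on the training folds, normalize train
    and test, fit the observer (uniform priors) on normalized training
    tokens, and score the held-out fold.  No statistic is ever computed on
    test tokens.
    """
    cue_name = cue_set if isinstance(cue_set, str) else None
    cues = CUE_SETS[cue_set] if isinstance(cue_set, str) else tuple(cue_set)
    if cue_name is None:
        cue_name = "+".join(cues)
    check_compatibility(account, cues)
    subset = data.subset_quantity(vowel_subset)
    if rule == "luce" and rng is None:
        raise ConfigError("Luce's choice rule requires a random generator")

    seeds = np.random.SeedSequence(entropy=(folds.seed, 7)).generate_state(folds.k)
    fold_acc: list[float] = []
    fold_cis: list[tuple[float, float]] = []
    confusions = []
    p_intended = []
    n_test = 0
    for fold in range(1, folds.k + 1):
        train, test = folds.train_test(subset, fold)
        if len(test) == 0:
            raise SwevowelError(f"fold {fold} has no test tokens for subset {vowel_subset!r}")
        model = fit_normalization(train, account, cues, miller_k=miller_k)
        norm_train = normalize(train, model)
        norm_test = normalize(test, model)
        observer = fit_observer(norm_train, cue_names=model.observer_cues, priors="uniform")
        acc, record = evaluate_accuracy(observer, norm_test, rule=rule, rng=rng)
        fold_acc.append(acc)
        fold_cis.append(bootstrap_ci(record["correct"].to_numpy(), B=n_boot, seed=int(seeds[fold - 1]) % (2**31)))
        confusions.append(confusion_table(record))
        p_intended.append(float(record["p_intended"].mean()))
        n_test += len(record)
    mean_ci = (float(np.mean([c[0] for c in fold_cis])), float(np.mean([c[1] for c in fold_cis])))
    result = ConditionResult(
        account=account,
        cue_set=cue_name,
        vowel_subset=vowel_subset,
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        ci=mean_ci,
        fold_cis=fold_cis,
        mean_p_intended=float(np.mean(p_intended)),
        confusions=confusions,
        n_test=n_test,
    )
    logger.info(
        "condition %s / %s / %s: accuracy %.3f [%.3f, %.3f]",
        account, cue_name, vowel_subset, result.mean_accuracy, *result.ci,
    )
    return result


def run_grid(
    data: Dataset,
    accounts: Iterable[str] = ACCOUNT_ROSTER,
    cue_sets: Iterable[str] = tuple(CUE_SETS),
    subsets: Iterable[str] = VOWEL_SUBSETS,
    folds: FoldAssignment | None = None,
    k: int = 5,
    seed: int = 0,
    rule: str = "criterion",
    n_boot: int = 1000,
    miller_k: float = DEFAULT_MILLER_K,
) -> tuple[pd.DataFrame, list[ConditionResult], list[dict]]:
    """Run the full account x cue-set x vowel-subset grid.

    Incompatible cells (Syrdal-Gopal outside the F1-F2 comparison) are
    recorded as skipped with the reason, not silently absent.  Returns a
    tidy per-fold results frame, the full condition results, and the
    skipped-cell records.
    """
    accounts = tuple(accounts)
    if not accounts:
        raise ConfigError("account roster must be non-empty")
    if folds is None:
        folds = make_folds(data, k=k, seed=seed)
    results: list[ConditionResult] = []
    skipped: list[dict] = []
    rows = []
    for account in accounts:
        for cue_set in cue_sets:
            cues = CUE_SETS[cue_set] if isinstance(cue_set, str) else tuple(cue_set)
            try:
                check_compatibility(account, cues)
            except ConfigError as exc:
                for subset in subsets:
                    skipped.append(
                        {"account": account, "cue_set": cue_set, "vowel_subset": subset, "reason": str(exc)}
                    )
                continue
            for subset in subsets:
                try:
                    res = run_condition(
                        data, account, cue_set, subset, folds,
                        rule=rule, n_boot=n_boot, miller_k=miller_k,
                    )
                except SwevowelError as exc:
                    skipped.append(
                        {"account": account, "cue_set": cue_set, "vowel_subset": subset, "reason": str(exc)}
                    )
                    continue
                results.append(res)
                rows.append(res.to_rows())
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return table, results, skipped


def shuffle_labels(data: Dataset, seed: int = 0) -> Dataset:
    """Permute vowel labels across tokens (within nothing) as a chance-level
    diagnostic: any pipeline evaluated on shuffled labels should score near
    1/K, which guards against information leakage bugs."""
    rng = np.random.default_rng(seed)
    df = data.df.copy()
    perm = rng.permutation(len(df))
    df["vowel"] = df["vowel"].to_numpy()[perm]
    df["quantity"] = df["quantity"].to_numpy()[perm]
    df["intended_vowel"] = pd.NA
    df["token_id"] = [f"s{i}" for i in range(len(df))]  # keep triples unique
    return data.with_frame(df)
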