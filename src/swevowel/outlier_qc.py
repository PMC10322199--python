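"""Measurement-error screening via per-cell Mahalanobis distances.

For each talker-by-vowel cell, a multivariate Gaussian is fitted over the
five raw cues (F0, F1-F3, duration).  Under Gaussianity the squared
Mahalanobis distance from the cell mean is chi-square distributed with dim
degrees of freedom, so the 0.5th-99.5th quantile band of the distribution
maps to the chi-square quantiles at the two bounds.  Tokens falling outside
that central band are flagged: above the upper bound as conventional
outliers, below the lower bound as suspiciously hyper-central points (e.g.
duplicated or imputed measurements).  At the default band 1% of clean
Gaussian data is flagged.

QC only flags: it never drops or corrects tokens (correction is a manual,
signal-level step outside this package's scope).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .data_model import CUES, Dataset
from .errors import ConfigError

logger = logging.getLogger("swevowel")

DEFAULT_BOUNDS = (0.005, 0.995)


@dataclass(frozen=True)
class OutlierFlag:
    """One token's distance from its talker-by-vowel cell distribution."""

    talker: str
    vowel: str
    token_id: str
    distance_sq: float
    lower_threshold: float
    threshold: float
    flagged: bool


def flag_outliers(
    data: Dataset,
    cues: Sequence[str] = CUES,
    central_mass_bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Flag outlier candidates per talker-by-vowel cell.

    Returns a frame sorted by descending squared distance with columns
    talker, vowel, token_id, distance_sq, lower_threshold, threshold,
    flagged (flagged is True outside the [lower, upper] chi-square band).
    Cells with fewer than dim+2 tokens, or with singular covariance, are
    skipped with a warning.
    """
    cues = tuple(cues)
    missing = [c for c in cues if c not in data.df.columns]
    if missing:
        raise ConfigError(f"cue column(s) missing: {missing}")
    lo, hi = central_mass_bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ConfigError("central_mass_bounds must satisfy 0 <= lower < upper <= 1")
    dim = len(cues)
    upper = float(chi2.ppf(hi, df=dim))
    lower = float(chi2.ppf(lo, df=dim)) if lo > 0 else 0.0

    rows = []
    skipped = []
    for (talker, vowel), group in data.df.groupby(["talker", "vowel"], sort=True):
        X = group[list(cues)].to_numpy(dtype=float)
        if len(X) < dim + 2:
            skipped.append((talker, vowel, f"only {len(X)} tokens (< dim+2 = {dim + 2})"))
            continue
        mu = X.mean(axis=0)
        sigma = np.cov(X, rowvar=False, ddof=1)
        try:
            L = linalg.cholesky(sigma, lower=True)
        except linalg.LinAlgError:
            skipped.append((talker, vowel, "singular cell covariance"))
            continue
        z = linalg.solve_triangular(L, (X - mu).T, lower=True)
        md2 = np.einsum("ij,ij->j", z, z)
        for token_id, d2 in zip(group["token_id"], md2):
            rows.append(
                {
                    "talker": talker,
                    "vowel": vowel,
                    "token_id": token_id,
                    "distance_sq": float(d2),
                    "lower_threshold": lower,
                    "threshold": upper,
                    "flagged": bool(d2 > upper or d2 < lower),
                }
            )
    if skipped:
        warnings.warn(f"skipped {len(skipped)} cell(s): {skipped[:5]}", stacklevel=2)
    out = pd.DataFrame(
        rows,
        columns=["talker", "vowel", "token_id", "distance_sq", "lower_threshold", "threshold", "flagged"],
    )
    out = out.sort_values("distance_sq", ascending=False).reset_index(drop=True)
    logger.info("flagged %d of %d tokens", int(out["flagged"].sum()), len(out))
    return out
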