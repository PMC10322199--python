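"""Multivariate-Gaussian Bayesian ideal observer for vowel categorization.

Each vowel category is modeled by a multivariate normal likelihood over the
active cue space; the posterior of category c given cue vector x is

    p(c | x) = N(x | mu_c, Sigma_c) p(c) / sum_k N(x | mu_k, Sigma_k) p(k).

Categorization uses either the accuracy-maximizing criterion rule (argmax
posterior, ties broken by roster order) or Luce's choice rule (sample a
category in proportion to its posterior).  Posteriors are computed from
log densities with max-subtraction so that crowded, high-dimensional
spaces do not underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

from .data_model import Dataset
from .errors import ConfigError, FitError, SwevowelError

PRIOR_TOL = 1e-12


@dataclass
class GaussianCategory:
    """One vowel category: mean vector, covariance matrix, training count."""

    label: str
    mu: np.ndarray
    sigma: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = self.mu.shape[0]
        if self.sigma.shape != (d, d):
            raise FitError(f"category {self.label}: covariance shape {self.sigma.shape} != ({d},{d})")
        if not np.allclose(self.sigma, self.sigma.T):
            raise FitError(f"category {self.label}: covariance not symmetric")


@dataclass
class IdealObserver:
    """An ordered set of Gaussian categories plus a prior vector."""

    categories: list[GaussianCategory]
    priors: np.ndarray
    cue_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if len(self.priors) != len(self.categories):
            raise ConfigError("one prior per category required")
        if np.any(self.priors <= 0):
            raise ConfigError("all category priors must be positive")
        if abs(self.priors.sum() - 1.0) > PRIOR_TOL:
            raise ConfigError(f"priors must sum to 1, got {self.priors.sum()!r}")
        # Cholesky factors, computed once; failure means a singular fit.
        self._chol = []
        for cat in self.categories:
            try:
                self._chol.append(linalg.cholesky(cat.sigma, lower=True))
            except linalg.LinAlgError as exc:
                raise FitError(f"category {cat.label}: covariance not positive definite") from exc

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.categories)

    @property
    def dim(self) -> int:
        return len(self.cue_names)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cue_names": list(self.cue_names),
            "priors": self.priors.tolist(),
            "categories": [
                {"label": c.label, "mu": c.mu.tolist(), "sigma": c.sigma.tolist(), "n_train": c.n_train}
                for c in self.categories
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "IdealObserver":
        cats = [
            GaussianCategory(label=c["label"], mu=np.array(c["mu"]), sigma=np.array(c["sigma"]), n_train=c["n_train"])
            for c in payload["categories"]
        ]
        return cls(categories=cats, priors=np.array(payload["priors"]), cue_names=tuple(payload["cue_names"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "IdealObserver":
        return cls.from_dict(json.loads(Path(path).read_text("utf-8")))


def uniform_priors(n_categories: int) -> np.ndarray:
    """Uniform prior over an n-alternatives-forced-choice task."""
    if n_categories < 1:
        raise ConfigError("need at least one category")
    return np.full(n_categories, 1.0 / n_categories)


def fit_observer(
    training: Dataset,
    cue_names: Sequence[str],
    priors: Sequence[float] | str = "uniform",
    ridge: float = 0.0,
) -> IdealObserver:
    """Fit one Gaussian per vowel category on (normalized) training tokens.

    Category means are sample means and covariances sample covariances
    (n−1), pooled across talkers within category.  Category order is the
    sorted label order (this is also the deterministic tie-break order).
    ``ridge`` adds epsilon*I to every covariance; it defaults to 0 and is
    logged when used (a rescue for singular fits, not a default smoother).
    """
    cue_names = tuple(cue_names)
    missing = [c for c in cue_names if c not in training.df.columns]
    if missing:
        raise ConfigError(f"cue column(s) missing from training data: {missing}")
    dim = len(cue_names)
    categories = []
    for label, group in training.df.groupby("vowel", sort=True):
        X = group[list(cue_names)].to_numpy(dtype=float)
        if len(X) < dim + 1:
            raise FitError(
                f"category {label}: {len(X)} training tokens < dim+1 = {dim + 1}; covariance would be singular"
            )
        mu = X.mean(axis=0)
        sigma = np.cov(X, rowvar=False, ddof=1).reshape(dim, dim)
        if ridge:
            import logging

            logging.getLogger("swevowel").warning("ridge %g applied to category %s", ridge, label)
            sigma = sigma + ridge * np.eye(dim)
        categories.append(GaussianCategory(label=str(label), mu=mu, sigma=sigma, n_train=len(X)))
    if not categories:
        raise FitError("no categories in training data")
    if isinstance(priors, str):
        if priors != "uniform":
            raise ConfigError("priors must be 'uniform' or an explicit vector")
        prior_vec = uniform_priors(len(categories))
    else:
        prior_vec = np.asarray(priors, dtype=float)
    try:
        return IdealObserver(categories=categories, priors=prior_vec, cue_names=cue_names)
    except FitError as exc:
        raise FitError(f"{exc}; consider a small ridge or more training tokens") from exc


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _log_density(observer: IdealObserver, X: np.ndarray) -> np.ndarray:
    """Log N(x | mu_c, Sigma_c) for every row of X and category c -> (n, K)."""
    n, d = X.shape
    out = np.empty((n, len(observer.categories)))
    const = -0.5 * d * np.log(2.0 * np.pi)
    for j, (cat, L) in enumerate(zip(observer.categories, observer._chol)):
        z = linalg.solve_triangular(L, (X - cat.mu).T, lower=True)
        maha = np.einsum("ij,ij->j", z, z)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, j] = const - 0.5 * (logdet + maha)
    return out


def log_posterior_matrix(observer: IdealObserver, X: np.ndarray) -> np.ndarray:
    """Normalized log posteriors for a batch of cue vectors -> (n, K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != observer.dim:
        raise ConfigError(f"cue vector dimension {X.shape[1]} != observer dimension {observer.dim}")
    if not np.all(np.isfinite(X)):
        raise SwevowelError("non-finite cue values passed to the observer")
    logp = _log_density(observer, X) + np.log(observer.priors)
    return logp - logsumexp(logp, axis=1, keepdims=True)


def posterior(observer: IdealObserver, x: Sequence[float]) -> np.ndarray:
    """Posterior probability vector over categories for one cue vector.

    Sums to 1 (within floating tolerance) by construction.
    """
    return np.exp(log_posterior_matrix(observer, np.asarray(x, dtype=float).reshape(1, -1))[0])


def classify(
    observer: IdealObserver,
    x: Sequence[float],
    rule: str = "criterion",
    rng: np.random.Generator | None = None,
) -> str:
    """Classify one cue vector.

    ``criterion``: accuracy-maximizing argmax of the posterior, ties broken
    by category (roster) order.  ``luce``: sample a category with
    probability equal to its posterior (requires a seeded ``rng``).
    """
    post = posterior(observer, x)
    if rule == "criterion":
        return observer.labels[int(np.argmax(post))]
    if rule == "luce":
        if rng is None:
            raise ConfigError("Luce's choice rule requires a random generator")
        return observer.labels[int(rng.choice(len(post), p=post / post.sum()))]
    raise ConfigError(f"unknown decision rule {rule!r}; use 'criterion' or 'luce'")


def classify_batch(
    observer: IdealObserver,
    X: np.ndarray,
    rule: str = "criterion",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized :func:`classify` over rows of X -> array of labels."""
    logpost = log_posterior_matrix(observer, X)
    labels = np.asarray(observer.labels, dtype=object)
    if rule == "criterion":
        return labels[np.argmax(logpost, axis=1)]
    if rule == "luce":
        if rng is None:
            raise ConfigError("Luce's choice rule requires a random generator")
        post = np.exp(logpost)
        post = post / post.sum(axis=1, keepdims=True)
        cum = np.cumsum(post, axis=1)
        u = rng.random(len(post))
        idx = (u[:, None] > cum).sum(axis=1)
        return labels[np.minimum(idx, len(labels) - 1)]
    raise ConfigError(f"unknown decision rule {rule!r}")


def evaluate_accuracy(
    observer: IdealObserver,
    test: Dataset,
    rule: str = "criterion",
    rng: np.random.Generator | None = None,
) -> tuple[float, pd.DataFrame]:
    """Score the observer on held-out tokens.

    Accuracy is the fraction of test tokens whose predicted label equals
    the produced (intended) vowel.  The per-token record retains the
    posterior assigned to the intended category and the predicted label,
    for diagnostics and confusion tabulation.  If all categories share one
    distribution (indistinguishable inventory) a warning is attached via
    the ``degenerate`` flag on the record frame attrs.
    """
    if len(test) == 0:
        raise SwevowelError("empty test set")
    X = test.df[list(observer.cue_names)].to_numpy(dtype=float)
    logpost = log_posterior_matrix(observer, X)
    labels = np.asarray(observer.labels, dtype=object)
    if rule == "criterion":
        predicted = labels[np.argmax(logpost, axis=1)]
    else:
        predicted = classify_batch(observer, X, rule=rule, rng=rng)
    intended = test.df["vowel"].to_numpy(dtype=object)
    label_index = {lab: j for j, lab in enumerate(observer.labels)}
    p_intended = np.array(
        [np.exp(logpost[i, label_index[v]]) if v in label_index else np.nan for i, v in enumerate(intended)]
    )
    correct = predicted == intended
    record = pd.DataFrame(
        {
            "talker": test.df["talker"].to_numpy(),
            "vowel": intended,
            "token_id": test.df["token_id"].to_numpy(),
            "predicted": predicted,
            "p_intended": p_intended,
            "correct": correct,
        }
    )
    mus = np.array([c.mu for c in observer.categories])
    record.attrs["degenerate"] = bool(len(mus) > 1 and np.allclose(mus, mus[0]))
    return float(correct.mean()), record


def confusion_table(record: pd.DataFrame) -> pd.DataFrame:
    """Intended-by-predicted count table from an evaluation record."""
    return pd.crosstab(record["vowel"], record["predicted"], dropna=False)
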