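import numpy as np
import pandas as pd
import pytest

import swevowel as sv


@pytest.fixture(scope="session")
def synth():
    """Default-design synthetic dataset (17 talkers x 21 vowels x 10 tokens)
    with its ground-truth talker profiles."""
    data, profiles = sv.generate_dataset(sv.SyntheticConfig(seed=1))
    return data, profiles


@pytest.fixture(scope="session")
def small_synth():
    """A small, fast dataset for unit tests (5 talkers, full inventory)."""
    cfg = sv.SyntheticConfig(n_talkers=5, tokens_per_cell=8, seed=7)
    data, profiles = sv.generate_dataset(cfg)
    return data, profiles


def make_dataset(rows, inventory=None):
    """Build a Dataset from plain dicts; fills defaults for brevity."""
    records = []
    for row in rows:
        rec = {
            "talker": "T1",
            "vowel": "hid",
            "token_id": f"t{len(records) + 1}",
            "F0": 200.0,
            "F1": 300.0,
            "F2": 2000.0,
            "F3": 3000.0,
            "duration": 150.0,
            "intended_vowel": pd.NA,
        }
        rec.update(row)
        records.append(rec)
    df = pd.DataFrame(records)
    if inventory is None:
        inventory = sv.load_inventory()
    df["quantity"] = df["vowel"].map(inventory)
    return sv.Dataset(df=df, inventory=dict(inventory))


def naive_posterior(mus, sigmas, priors, x):
    """Independent brute-force posterior: explicit densities, no log tricks."""
    x = np.asarray(x, dtype=float)
    dens = []
    for mu, sigma, prior in zip(mus, sigmas, priors):
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        d = len(mu)
        diff = x - mu
        norm = np.sqrt((2.0 * np.pi) ** d * np.linalg.det(sigma))
        dens.append(prior * np.exp(-0.5 * diff @ np.linalg.inv(sigma) @ diff) / norm)
    dens = np.asarray(dens)
    return dens / dens.sum()
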