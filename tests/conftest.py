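"""Shared fixtures and the independent brute-force likelihood oracle.

The oracle enumerates every hidden presence path explicitly and never calls
the forward recursion, so it can certify the recursion's correctness.
"""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import occuchain as oc


def brute_force_markov_likelihood(psi, theta, theta_prime, theta0, p, history):
    """Site likelihood by exhaustive enumeration of all 2^K hidden presence
    sequences (tractable for K <= ~12)."""
    h = np.asarray(history, dtype=float)
    K = h.size
    total = 0.0
    for z in product((0, 1), repeat=K):
        prob = theta0 if z[0] else 1.0 - theta0
        for j in range(1, K):
            if z[j - 1]:
                prob *= theta_prime if z[j] else 1.0 - theta_prime
            else:
                prob *= theta if z[j] else 1.0 - theta
        for j in range(K):
            if np.isnan(h[j]):
                continue
            if z[j]:
                prob *= p if h[j] == 1.0 else 1.0 - p
            elif h[j] == 1.0:
                prob = 0.0
                break
        total += prob
    like = psi * total
    observed = h[~np.isnan(h)]
    if not (observed == 1.0).any():
        like += 1.0 - psi
    return like


@pytest.fixture(scope="session")
def toy_dataset():
    """Two hand-built sites with known histories and covariates."""
    det = pd.DataFrame(
        {
            "site_id": ["A", "A", "A", "B", "B", "B"],
            "replicate_index": [1, 2, 3, 1, 2, 3],
            "detection": [1, 0, 1, 0, 0, 0],
        }
    )
    cov = pd.DataFrame(
        {
            "site_id": ["A", "B"],
            "propfor": [0.8, 0.4],
            "lvs": [0.5, 0.1],
            "meanrain_mm": [1000.0, 3000.0],
            "meanndvi": [0.4, 0.7],
            "cvndvi": [0.2, 0.3],
            "forest_km2": [150.0, 75.0],
        }
    )
    return oc.load_survey(det, cov)


@pytest.fixture(scope="session")
def sim_dataset_and_fit():
    """One simulated survey at the reference truth with its top-model fit,
    shared by the landscape tests (session-scoped: fitting is the slow part)."""
    truth = oc.reference_truth(n_sites=300)
    ds = oc.simulate_dataset(truth, seed=11)
    fit = oc.fit_model(truth.spec(), ds, oc.FitOptions(n_starts=1))
    return truth, ds, fit
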