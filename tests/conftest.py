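"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import allelescan as al
from allelescan.preprocess import Histogram


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset with planted AI, shared across tests."""
    cfg = al.SimConfig(
        chrom_length=8_000_000, n_individuals=8, n_ai_regions=4
    )
    sites, matrix, truth = al.simulate_dataset(cfg, seed=11)
    return cfg, sites, matrix, truth


@pytest.fixture
def tiny_sites():
    """Hand-built 3-site table on two chromosomes."""
    return al.SiteTable(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "pos": [100, 5000, 250],
                "snp_id": ["rs1", "rs2", "rs3"],
                "alleleA": ["A", "C", "G"],
                "alleleB": ["G", "T", "A"],
                "genic": [True, False, True],
            }
        )
    ).validate()


def normal_histogram(mean, sd, lo=-4.0, hi=7.0, n_bins=120) -> Histogram:
    """Discretized normal used as a fixture emission distribution."""
    edges = np.linspace(lo, hi, n_bins + 1)
    from scipy.stats import norm

    mass = np.diff(norm.cdf(edges, mean, sd))
    return Histogram(edges, mass / mass.sum())


@pytest.fixture(scope="session")
def fixture_model():
    """A small trained-looking 8-state model with known parameters."""
    h_expr = normal_histogram(2.5, 0.9)
    h_non = normal_histogram(0.0, 0.7)
    model = al.make_initial_model(3, h_expr, h_non, D=4000.0)
    # sharpen into a plausibly trained configuration
    model.mu = np.array([0.0, -2.0, -1.0, -0.4, 0.0, 0.4, 1.0, 2.0])
    model.sigma = np.array([2.0, 0.35, 0.35, 0.35, 0.35, 0.35, 0.35, 0.35])
    S = 8
    T = np.full((S, S), 0.07 / (S - 1))
    np.fill_diagonal(T, 0.93)
    model.T = T
    model.pi = np.full(S, 1.0 / S)
    return model.validate()


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force)
# ---------------------------------------------------------------------------


def enumerate_paths(pi, A_per_gap, L):
    """Exhaustive path enumeration oracle for small HMM instances.

    ``A_per_gap`` is a list of (S, S) transition matrices, one per gap;
    ``L`` the (n, S) emission log-likelihoods.  Returns (gamma, xi,
    loglik, best_path, best_logp).
    """
    n, S = L.shape
    log_pi = np.log(pi)
    logA = [np.log(np.maximum(a, 1e-300)) for a in A_per_gap]
    logps = []
    paths = list(itertools.product(range(S), repeat=n))
    for path in paths:
        lp = log_pi[path[0]] + L[0, path[0]]
        for t in range(1, n):
            lp += logA[t - 1][path[t - 1], path[t]] + L[t, path[t]]
        logps.append(lp)
    logps = np.array(logps)
    mx = logps.max()
    w = np.exp(logps - mx)
    tot = w.sum()
    loglik = mx + np.log(tot)
    gamma = np.zeros((n, S))
    xi = np.zeros((n - 1, S, S))
    for p, wt in zip(paths, w):
        for t, s in enumerate(p):
            gamma[t, s] += wt
        for t in range(n - 1):
            xi[t, p[t], p[t + 1]] += wt
    gamma /= tot
    xi /= tot
    best = int(np.argmax(logps))
    return gamma, xi, loglik, np.array(paths[best]), float(logps[best])


def greedy_oracle(z, w_max):
    """Re-enumerating reference for the greedy window assignment."""
    z = np.asarray(z, dtype=float)
    n = len(z)
    out = np.full(n, np.nan)
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        best = None
        for start in range(n):
            for length in range(1, w_max + 1):
                if start + length > n:
                    break
                if assigned[start : start + length].any():
                    continue
                Z = z[start : start + length].sum() / np.sqrt(length)
                key = (-abs(Z), start, length)
                if best is None or key < best[0]:
                    best = (key, start, length, Z)
        _, start, length, Z = best
        out[start : start + length] = Z
        assigned[start : start + length] = True
    return out


def random_stochastic_matrix(rng, S, diag_weight=8.0):
    """Random self-loop-heavy stochastic matrix (positive spectrum).

    Transition matrices at SNP scale are strongly diagonal; the diagonal
    dominance keeps the spectrum real and positive so fractional powers
    are well defined.
    """
    M = rng.uniform(0.1, 1.0, size=(S, S))
    M[np.diag_indices(S)] += diag_weight * S
    return M / M.sum(axis=1, keepdims=True)
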