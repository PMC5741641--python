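"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.signal import correlate

from mppeep import BandSpec, Dictionary, SnippetSet, make_atoms


# ---------------------------------------------------------------------------
# Oracles (kept independent of the library paths they check)
# ---------------------------------------------------------------------------

def lag_order(S: int) -> list[int]:
    """Tie-break lag ordering: 0, -1, +1, -2, +2, ..."""
    order = [0]
    for s in range(1, S + 1):
        order.extend([-s, s])
    return order


def brute_force_assign(X: np.ndarray, atoms: np.ndarray, S: int):
    """Reference assignment: explicit loop over every atom and lag.

    Correlation at lag s is sum_n x[n] * d[n - s] with the atom zero-padded;
    the winner maximises |corr| with ties to smallest atom index, then the
    lag order 0, -1, +1, ...
    """
    n, M = X.shape
    K = atoms.shape[0]
    omega = np.zeros(n, dtype=int)
    alpha = np.zeros(n)
    shift = np.zeros(n, dtype=int)
    for i in range(n):
        best = None
        for k in range(K):
            for s in lag_order(S):
                c = 0.0
                for t in range(M):
                    m = t - s
                    if 0 <= m < M:
                        c += X[i, t] * atoms[k, m]
                if best is None or abs(c) > abs(best[0]):
                    best = (c, k, s)
        alpha[i], omega[i], shift[i] = best
    return omega, alpha, shift


def shiftmax_abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Max |cross-correlation| between two unit-norm vectors over all lags."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    return float(np.max(np.abs(correlate(a, b, mode="full"))))


def bipartite_match_corr(learned: np.ndarray, truth: np.ndarray) -> float:
    """Min |corr| over the best one-to-one matching of learned to true atoms."""
    K = truth.shape[0]
    C = np.array([[shiftmax_abs_corr(learned[i], truth[j]) for j in range(K)]
                  for i in range(learned.shape[0])])
    rows, cols = linear_sum_assignment(-C)
    return float(np.min(C[rows, cols]))


def event_f1(true_taus: np.ndarray, rec_taus: np.ndarray, tol: int) -> float:
    """F1 of recovered event times against truth with a τ tolerance."""
    true_taus = np.asarray(true_taus)
    rec_taus = np.asarray(rec_taus)
    if true_taus.size == 0 and rec_taus.size == 0:
        return 1.0
    if true_taus.size == 0 or rec_taus.size == 0:
        return 0.0
    used = np.zeros(rec_taus.size, dtype=bool)
    tp = 0
    for t in true_taus:
        dist = np.abs(rec_taus - t)
        dist[used] = tol + 1
        j = int(np.argmin(dist))
        if dist[j] <= tol:
            used[j] = True
            tp += 1
    precision = tp / rec_taus.size
    recall = tp / true_taus.size
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def sigma_band() -> BandSpec:
    return BandSpec(name="sigma", f_lo=11.0, f_hi=16.0)


@pytest.fixture
def gabor_atoms(sigma_band) -> Dictionary:
    """Three well-separated sigma-band atoms at the test scale (fs=100, M=50)."""
    return make_atoms(K=3, M=50, band=sigma_band, fs=100.0, rng_seed=7)


def snippets_from_matrix(X: np.ndarray) -> SnippetSet:
    X = np.atleast_2d(X)
    return SnippetSet(M=X.shape[1], vectors=X,
                      origins=np.zeros(X.shape[0], dtype=int),
                      method=["tiling"] * X.shape[0])
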