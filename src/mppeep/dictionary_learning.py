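"""Shift-invariant dictionary learning with correntropy-robust atom updates.

Each frequency band is modelled by K unit-norm, M-sample FIR atoms learned
from the event snippets of that band by a shift-invariant variant of
k-means:

* assignment ("phasic event decomposition"): every snippet is matched, via
  FFT cross-correlation, to the single (atom, lag) pair with the largest
  absolute correlation — exactly one atom per snippet, so the sparsity of
  the decomposition is fixed at one;
* update: the members of each cluster are lag-aligned, stacked into a
  matrix, and the atom is re-estimated as the first principal direction
  under a correntropy (Gaussian-kernel) cost. The half-quadratic solver
  turns this into iteratively re-weighted rank-1 SVDs whose weights
  exponentially suppress rows with large residuals, so outlier snippet
  shapes cannot bias the template. The kernel width is set from the
  residuals by Silverman's rule at every half-quadratic step.

Learning restarts from several random seed dictionaries; the result with
the lowest mutual coherence (most diverse atoms) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import DEFAULTS
from .preprocess import SnippetSet


@dataclass
class Dictionary:
    """K unit-norm M-sample FIR atoms for one band."""

    atoms: np.ndarray  # (K, M)
    band: str = ""
    fs: float = 0.0
    provenance: str = "learned"
    init_id: int = 0

    def __post_init__(self):
        self.atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        if not np.all(np.isfinite(self.atoms)):
            raise ValueError("atoms must be finite")
        norms = np.linalg.norm(self.atoms, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("atoms must be unit-norm")

    @property
    def K(self) -> int:
        return self.atoms.shape[0]

    @property
    def M(self) -> int:
        return self.atoms.shape[1]


@dataclass
class AssignmentSet:
    """One (atom, amplitude, lag) assignment per snippet."""

    omega: np.ndarray  # (n,) atom indices
    alpha: np.ndarray  # (n,) signed projection amplitudes
    shift: np.ndarray  # (n,) integer lags in [-S, S]

    def __len__(self) -> int:
        return self.omega.size


@dataclass
class TrainLog:
    """Per-iteration and per-initialisation training diagnostics."""

    iterations: list = field(default_factory=list)
    init_coherence: dict = field(default_factory=dict)
    best_init: int = -1


def _fix_sign(atom: np.ndarray) -> np.ndarray:
    """Resolve the SVD sign ambiguity: largest-magnitude entry positive."""
    if atom[np.argmax(np.abs(atom))] < 0:
        return -atom
    return atom


def mutual_coherence(dictionary: Dictionary) -> float:
    """Maximum absolute inner product between distinct unit-norm atoms."""
    if dictionary.K < 2:
        raise ValueError("mutual coherence needs at least two atoms")
    gram = dictionary.atoms @ dictionary.atoms.T
    np.fill_diagonal(gram, 0.0)
    return float(np.max(np.abs(gram)))


def seed_dictionary(events: SnippetSet, K: int, rng_seed: int,
                    norm_percentile: float = DEFAULTS.seed_norm_percentile,
                    band: str = "", fs: float = 0.0) -> Dictionary:
    """Draw a seed dictionary from the largest-norm event snippets.

    Candidates are the snippets at or above the ``norm_percentile`` of the
    norm distribution. The first atom is drawn at random; each subsequent
    atom is the candidate that minimises the running mutual coherence with
    the atoms already chosen, so the initial filters are as different from
    each other as the pool allows.
    """
    if len(events) == 0:
        raise ValueError("empty event set")
    norms = np.linalg.norm(events.vectors, axis=1)
    cutoff = np.percentile(norms, norm_percentile)
    pool = np.flatnonzero(norms >= cutoff)
    pool = pool[norms[pool] > 0]
    if pool.size < K:
        raise ValueError(
            f"only {pool.size} snippets at/above the {norm_percentile}th norm "
            f"percentile; cannot seed K={K} atoms"
        )
    candidates = events.vectors[pool] / norms[pool, None]

    rng = np.random.default_rng(rng_seed)
    chosen = [int(rng.integers(pool.size))]
    remaining = [i for i in range(pool.size) if i != chosen[0]]
    while len(chosen) < K:
        sel = candidates[chosen]
        # coherence each remaining candidate would add
        worst = np.max(np.abs(candidates[remaining] @ sel.T), axis=1)
        pick = remaining[int(np.argmin(worst))]
        chosen.append(pick)
        remaining.remove(pick)

    atoms = np.stack([_fix_sign(candidates[i]) for i in chosen])
    return Dictionary(atoms=atoms, band=band or events.band, fs=fs,
                      provenance="seed", init_id=rng_seed)


def _lag_order(S: int) -> np.ndarray:
    """Lag values ordered for tie-breaking: 0, -1, +1, -2, +2, ..."""
    order = [0]
    for s in range(1, S + 1):
        order.extend([-s, s])
    return np.array(order, dtype=int)


def assign_snippets(snippets: SnippetSet, dictionary: Dictionary,
                    max_shift: int | None = None) -> AssignmentSet:
    """Assign every snippet to its best (atom, lag) by FFT cross-correlation.

    The correlation at lag ``s`` is ``sum_n x[n] * d[n - s]`` with the atom
    zero-padded outside its support; lags range over ``[-S, S]``. The winner
    maximises ``|correlation|``; ties break to the smallest atom index, then
    the smallest ``|lag|``, then the negative lag.
    """
    M = snippets.M
    if dictionary.M != M:
        raise ValueError(f"dictionary M={dictionary.M} != snippet M={M}")
    S = int(np.floor(M * DEFAULTS.shift_fraction)) if max_shift is None else int(max_shift)
    if S >= M / 2:
        raise ValueError(f"max_shift={S} must be < M/2={M / 2}")
    if len(snippets) == 0:
        return AssignmentSet(np.empty(0, int), np.empty(0), np.empty(0, int))

    X = snippets.vectors  # (n, M)
    D = dictionary.atoms  # (K, M)
    # full cross-correlation: index k corresponds to lag s = k - (M - 1)
    corr = sps.fftconvolve(X[:, None, :], D[None, :, ::-1], mode="full", axes=2)
    lag_order = _lag_order(S)
    corr = corr[:, :, (M - 1) + lag_order]  # (n, K, 2S+1) in tie-break lag order

    n, K, L = corr.shape
    flat = corr.reshape(n, K * L)
    best = np.argmax(np.abs(flat), axis=1)  # first occurrence wins ties
    omega = best // L
    alpha = flat[np.arange(n), best]
    shift = lag_order[best % L]
    return AssignmentSet(omega=omega.astype(int), alpha=alpha,
                         shift=shift.astype(int))


def correntropy_rank1(X: np.ndarray, max_hq_iter: int = 50,
                      w_tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Robust first principal direction of the rows of ``X``.

    Half-quadratic optimisation of a correntropy cost: starting from the
    ordinary first right singular vector, each step (i) measures per-row
    reconstruction residuals, (ii) sets the Gaussian kernel width by
    Silverman's rule on those residuals, (iii) converts residuals to weights
    ``w_k = exp(-e_k^2 / 2 sigma^2)``, and (iv) recomputes the principal
    direction of the ``sqrt(w)``-row-scaled matrix. Iteration stops when the
    largest weight change drops below ``w_tol``.

    The kernel width is floored at the residual root-mean-square (``rms/√2``):
    Silverman's bandwidth tracks the residual *spread*, which for homogeneous
    (outlier-free) rows is far smaller than the residual scale itself; below
    the floor the Gaussian kernel saturates and the estimate would collapse
    onto the few smallest-residual rows instead of reducing to ordinary SVD
    in the clean limit. Outlier rows inflate both terms, so the floor never
    blunts the down-weighting that provides robustness.

    Returns the unit-norm direction (largest-magnitude entry positive) and
    the final row weights in (0, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not np.any(X):
        raise ValueError("all-zero matrix has no principal direction")

    def principal(mat: np.ndarray) -> np.ndarray:
        _, _, vt = np.linalg.svd(mat, full_matrices=False)
        return vt[0]

    d = principal(X)
    w = np.ones(n)
    for _ in range(max_hq_iter):
        resid = X - np.outer(X @ d, d)
        e = np.linalg.norm(resid, axis=1)
        spread = np.std(e, ddof=1) if n > 1 else 0.0
        sigma = max(1.06 * spread * n ** (-1 / 5),
                    np.sqrt(np.mean(e**2) / 2))
        if not (sigma > 0):
            # zero residual spread: nothing to down-weight
            return _fix_sign(d), np.ones(n)
        w_new = np.exp(-(e**2) / (2 * sigma**2))
        d = principal(X * np.sqrt(w_new)[:, None])
        if np.max(np.abs(w_new - w)) < w_tol:
            w = w_new
            break
        w = w_new
    return _fix_sign(d), w


def _align(vec: np.ndarray, shift: int) -> np.ndarray:
    """Undo an assigned lag: shift content left by ``shift`` with zero fill."""
    M = vec.size
    out = np.zeros(M)
    if shift >= 0:
        out[:M - shift] = vec[shift:]
    else:
        out[-shift:] = vec[:M + shift]
    return out


def update_dictionary(assignments: AssignmentSet, snippets: SnippetSet,
                      dictionary: Dictionary) -> Dictionary:
    """Re-estimate every atom from its lag-aligned cluster members.

    Clusters with no members keep their previous atom unchanged.
    """
    if len(assignments) != len(snippets):
        raise ValueError("assignments do not align with snippets")
    atoms = dictionary.atoms.copy()
    for k in range(dictionary.K):
        members = np.flatnonzero(assignments.omega == k)
        if members.size == 0:
            continue
        stacked = np.stack([
            _align(snippets.vectors[i], int(assignments.shift[i]))
            for i in members
        ])
        atom, _ = correntropy_rank1(stacked)
        atoms[k] = atom
    return Dictionary(atoms=atoms, band=dictionary.band, fs=dictionary.fs,
                      provenance="learned", init_id=dictionary.init_id)


def learn_dictionary(events: SnippetSet, K: int,
                     n_init: int = DEFAULTS.n_init,
                     max_iter: int = DEFAULTS.max_iter,
                     tol: float = DEFAULTS.tol,
                     rng_seed: int = 0,
                     max_shift: int | None = None,
                     band: str = "", fs: float = 0.0) -> tuple[Dictionary, TrainLog]:
    """Learn K atoms by alternating assignment and robust update.

    Each of ``n_init`` initialisations seeds a dictionary from high-norm
    snippets and iterates until the Frobenius norm of the dictionary change
    drops below ``tol`` or ``max_iter`` iterations; across initialisations
    the dictionary with the lowest mutual coherence wins.
    """
    if len(events) == 0:
        raise ValueError("no event snippets to learn from")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")

    seeds = np.random.SeedSequence(rng_seed).generate_state(n_init) % (2**31)
    log = TrainLog()
    best: tuple[float, Dictionary] | None = None
    for init_id, seed in enumerate(seeds):
        dictionary = seed_dictionary(events, K, int(seed), band=band, fs=fs)
        dictionary.init_id = init_id
        for it in range(max_iter):
            assignments = assign_snippets(events, dictionary, max_shift)
            updated = update_dictionary(assignments, events, dictionary)
            change = float(np.linalg.norm(updated.atoms - dictionary.atoms))
            sizes = np.bincount(assignments.omega, minlength=K).tolist()
            log.iterations.append({
                "init": init_id, "iter": it,
                "atom_change": change, "cluster_sizes": sizes,
            })
            dictionary = updated
            if change < tol:
                break
        coherence = mutual_coherence(dictionary) if K >= 2 else 0.0
        log.init_coherence[init_id] = coherence
        if best is None or coherence < best[0]:
            best = (coherence, dictionary)
    log.best_init = best[1].init_id
    return best[1], log
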