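"""Kurtosis-calibrated separation of background snippets from phasic events.

Within one band, the Euclidean norms of M-sample snippets of pure background
activity follow a chi-like distribution whose main lobe is close to Gaussian
for large M (central limit theorem), while genuine neuromodulations populate
a heavy right tail. The threshold γ between the two regimes is found without
labels: sort the norms, then trim the largest values one by one until the
excess kurtosis of the retained sub-population falls to the Gaussian value
(within a tolerance). Only a heavy right tail raises excess kurtosis, and
removing the largest norms can only lower it, so the stopping rule is
one-sided: trimming ends as soon as kurtosis ≤ +tol. γ is the largest
retained norm; snippets with norm strictly above γ are treated as bona fide
phasic events.

The test presumes the phasic events are temporally sparse (a small fraction
of the snippets): a large event fraction turns the norm density bimodal,
whose kurtosis is low before any trimming, and the threshold degenerates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULTS
from .preprocess import SnippetSet

#: Minimum number of norms for the Gaussian (CLT) approximation to be
#: trustworthy.
MIN_NORMS = 200


@dataclass
class NoiseModel:
    """Per-band norm threshold γ with the trimming path that produced it.

    ``kurtosis_trace`` records ``(retained_fraction, excess_kurtosis)`` at
    every trimming step so the convergence of the Gaussianity test can be
    audited after the fact.
    """

    gamma: float
    M: int
    kurtosis_trace: list
    n_snippets: int

    def __post_init__(self):
        # estimated models always have gamma > 0; a zero threshold is legal
        # only for hand-built models (it classifies everything as event)
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


def snippet_norms(snippets: SnippetSet) -> np.ndarray:
    """Euclidean norm of every snippet, order preserved."""
    if len(snippets) == 0:
        raise ValueError("empty snippet set")
    return np.linalg.norm(snippets.vectors, axis=1)


def _prefix_excess_kurtosis(sorted_norms: np.ndarray) -> np.ndarray:
    """Bias-corrected sample excess kurtosis of every prefix of length >= 4.

    Computed from cumulative power sums so the whole trimming path costs
    O(n). Entry ``j`` is the kurtosis of ``sorted_norms[:j+1]``; entries for
    prefixes shorter than 4 (where the corrected estimator is undefined) are
    NaN.
    """
    x = sorted_norms.astype(float)
    n = np.arange(1, x.size + 1, dtype=float)
    s1 = np.cumsum(x)
    mean = s1 / n
    # Central moments via shifted cumulants would lose precision; use the
    # binomial expansion around the running mean with raw power sums.
    s2 = np.cumsum(x**2)
    s3 = np.cumsum(x**3)
    s4 = np.cumsum(x**4)
    m2 = s2 / n - mean**2
    m3 = s3 / n - 3 * mean * s2 / n + 2 * mean**3
    m4 = s4 / n - 4 * mean * s3 / n + 6 * mean**2 * s2 / n - 3 * mean**4
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = m4 / m2**2 - 3.0
        # bias correction (Fisher): valid for n >= 4
        G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
    G2[:3] = np.nan
    _ = m3  # skewness not needed; kept for clarity of the moment ladder
    return G2


def estimate_gamma(norms, tol: float = DEFAULTS.kurtosis_tol,
                   min_frac: float = DEFAULTS.min_frac,
                   M: int | None = None) -> NoiseModel:
    """Estimate the background/event norm threshold γ.

    Parameters
    ----------
    norms:
        Snippet Euclidean norms (length >= 200).
    tol:
        Excess-kurtosis tolerance; trimming stops once kurtosis ≤ +tol.
    min_frac:
        Floor on the retained fraction; trimming never removes more than
        ``1 - min_frac`` of the norms.
    M:
        Embedding dimension recorded in the model (optional, for audit).

    Returns
    -------
    NoiseModel
        With ``gamma`` set to the largest retained norm at convergence and
        the full trimming path in ``kurtosis_trace``.
    """
    norms = np.asarray(norms, dtype=float)
    if norms.size < MIN_NORMS:
        raise ValueError(
            f"need at least {MIN_NORMS} norms for the Gaussian-limit test, "
            f"got {norms.size}"
        )
    if np.any(norms < 0):
        raise ValueError("norms must be non-negative")
    if np.std(norms) == 0:
        raise ValueError("degenerate input: all norms identical")

    sorted_norms = np.sort(norms)
    n = sorted_norms.size
    kurt = _prefix_excess_kurtosis(sorted_norms)

    k_floor = max(4, int(np.ceil(min_frac * n)))
    trace: list[tuple[float, float]] = []
    chosen = k_floor
    for k in range(n, k_floor - 1, -1):
        trace.append((k / n, float(kurt[k - 1])))
        if np.isfinite(kurt[k - 1]) and kurt[k - 1] <= tol:
            chosen = k
            break
    else:
        chosen = k_floor

    gamma = float(sorted_norms[chosen - 1])
    if gamma <= 0:
        raise ValueError("degenerate input: converged threshold is not positive")
    return NoiseModel(gamma=gamma, M=int(M) if M is not None else -1,
                      kurtosis_trace=trace, n_snippets=n)


def partition_snippets(snippets: SnippetSet,
                       model: NoiseModel) -> tuple[SnippetSet, SnippetSet]:
    """Split a snippet set into phasic events (norm > γ) and background."""
    if model.M not in (-1, snippets.M):
        raise ValueError(f"model built for M={model.M}, set has M={snippets.M}")
    norms = snippet_norms(snippets)
    is_event = norms > model.gamma
    return snippets.subset(is_event), snippets.subset(~is_event)
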