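"""Point-process analytics on decoded event trains.

Three complementary read-outs of an MPP train: a kernel-smoothed event rate
(events per sample, comparable in timescale to behavioural signals), the
normalized cross-correlation and lag between that rate and a reference
signal (with a causal-only option for brain-to-muscle delays), and a
trigger-locked event density, the point-process intensity analogue of a
peristimulus time histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULTS
from .mpp_decode import MPPTrain
from .signal_io import RawTrace


@dataclass
class RateSeries:
    """Kernel-smoothed event rate in events per sample."""

    values: np.ndarray
    fs: float
    kernel_sigma: float
    kernel_support: int

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DensityEstimate:
    """Trigger-locked event density (events per second per trigger)."""

    bin_edges: np.ndarray  # seconds relative to trigger
    counts: np.ndarray
    density: np.ndarray


def _truncated_gaussian(sigma: float, support: int) -> np.ndarray:
    """Unit-mass Gaussian kernel truncated to ``±support/2`` samples."""
    half = support // 2
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-(offsets**2) / (2 * sigma**2))
    return kernel / kernel.sum()


def smooth_rate(train: MPPTrain,
                kernel_sigma: float = DEFAULTS.kernel_sigma,
                kernel_support: int = DEFAULTS.kernel_support) -> RateSeries:
    """Smooth an event train into a rate with a truncated Gaussian kernel.

    Every event contributes one unit of mass (the kernel is renormalized
    after truncation) centered on the event's waveform peak, so away from
    the trace edges the series integrates to the event count.
    """
    if kernel_support > 4 * kernel_sigma:
        raise ValueError("kernel_support must not exceed 4 * kernel_sigma")
    n = train.n_samples
    if n < 1:
        raise ValueError("train has no trace length")
    deltas = np.zeros(n)
    for ev in train.events:
        deltas[ev.time_sample] += 1.0
    kernel = _truncated_gaussian(kernel_sigma, kernel_support)
    values = np.convolve(deltas, kernel, mode="same")
    return RateSeries(values=values, fs=train.fs,
                      kernel_sigma=kernel_sigma, kernel_support=kernel_support)


def xcorr_delay(rate, reference, max_lag: int,
                causal_only: bool = True) -> tuple[float, int]:
    """Best normalized cross-correlation between a rate and a reference.

    The correlation at lag ``L`` is the Pearson coefficient of the
    overlapping segments of the two series with the rate advanced by ``L``
    samples; a positive lag means the rate (the neural events) leads the
    reference. With ``causal_only`` only non-negative lags compete. Returns
    ``(corr, lag)`` at the maximising lag; ties break to the smallest
    ``|lag|``, preferring the positive one.
    """
    r = rate.values if isinstance(rate, RateSeries) else np.asarray(rate, float)
    y = reference.samples if isinstance(reference, RawTrace) else np.asarray(reference, float)
    if r.size != y.size:
        raise ValueError("rate and reference must have equal length")
    n = r.size
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    if np.std(r) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")

    lags = [0]
    for s in range(1, max_lag + 1):
        lags.append(s)
        if not causal_only:
            lags.append(-s)

    best_corr, best_lag = -np.inf, 0
    for L in lags:
        if L >= 0:
            a, b = r[:n - L] if L else r, y[L:]
        else:
            a, b = r[-L:], y[:n + L]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        c = float(np.corrcoef(a, b)[0, 1])
        if c > best_corr + 1e-12:
            best_corr, best_lag = c, L
    return best_corr, best_lag


def event_density(train: MPPTrain, triggers, window: tuple[float, float],
                  bin_width: float) -> DensityEstimate:
    """Trigger-locked event density over ``[-pre, +post)`` seconds.

    Events are tallied by their time relative to each trigger; counts are
    normalized by the number of triggers and the bin width, yielding an
    intensity in events per second per trigger.
    """
    triggers = np.asarray(triggers, dtype=float)
    if triggers.size == 0:
        raise ValueError("no triggers")
    pre, post = window
    span = pre + post
    n_bins = int(round(span / bin_width))
    if n_bins < 1:
        raise ValueError("window spans less than one bin")
    edges = -pre + bin_width * np.arange(n_bins + 1)

    times = np.array([ev.time_sample for ev in train.events], dtype=float) / train.fs
    rel = (times[None, :] - triggers[:, None] / train.fs).ravel()
    counts, _ = np.histogram(rel, bins=edges)
    density = counts / (triggers.size * bin_width)
    return DensityEstimate(bin_edges=edges, counts=counts, density=density)
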