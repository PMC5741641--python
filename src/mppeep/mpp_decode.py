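"""Decoding a band-passed trace into a marked point process.

At test time the learned dictionary acts as a matched-filter bank: the trace
is cross-correlated with every unit-norm atom, candidate locations are
scanned in descending combined correlation magnitude, and a candidate
becomes an event only if its projection amplitude exceeds the band's noise
threshold γ and it keeps a minimum separation from every already accepted
event (one event per window — the decomposition sparsity is one). Each
event carries the mark triple (τ window start, α signed amplitude, ω atom
index) plus the sample of the fitted waveform's largest absolute peak, so
event timing can be referenced either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dictionary_learning import Dictionary
from .noise_model import NoiseModel
from .signal_io import RawTrace


@dataclass
class MPPEvent:
    """One marked event: window start τ, amplitude α, atom index ω."""

    tau: int
    alpha: float
    omega: int
    peak_sample: int | None = None

    @property
    def time_sample(self) -> int:
        """Event timing: the waveform peak if recorded, else τ."""
        return self.tau if self.peak_sample is None else self.peak_sample


@dataclass
class MPPTrain:
    """An ordered train of marked events for one channel and band."""

    events: list
    band: str = ""
    channel: str = ""
    fs: float = 1.0
    n_samples: int = 0
    gamma: float = 0.0

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda ev: ev.tau)

    def __len__(self) -> int:
        return len(self.events)

    def taus(self) -> np.ndarray:
        return np.array([ev.tau for ev in self.events], dtype=int)

    def alphas(self) -> np.ndarray:
        return np.array([ev.alpha for ev in self.events], dtype=float)

    def omegas(self) -> np.ndarray:
        return np.array([ev.omega for ev in self.events], dtype=int)


def deconvolve(trace: RawTrace, dictionary: Dictionary,
               model: NoiseModel | None = None, gamma: float | None = None,
               min_separation: int | None = None) -> MPPTrain:
    """Decode a band-passed trace into an MPP train.

    Parameters
    ----------
    trace:
        Band-passed single-channel trace.
    dictionary:
        Learned (or known) unit-norm atoms for the band.
    model, gamma:
        Noise threshold; pass either a :class:`NoiseModel` or a raw γ.
    min_separation:
        Minimum distance in samples between accepted event starts; defaults
        to M (non-overlapping events) and may be lowered to M/2.
    """
    M = dictionary.M
    n = len(trace)
    if n < M:
        raise ValueError(f"trace length {n} shorter than atom length {M}")
    if dictionary.K < 1:
        raise ValueError("empty dictionary")
    if gamma is None:
        if model is None:
            raise ValueError("either a noise model or gamma is required")
        gamma = model.gamma
    if min_separation is None:
        min_separation = M
    if min_separation < M // 2:
        raise ValueError(f"min_separation={min_separation} below M/2={M // 2}")

    x = trace.samples
    # valid cross-correlation: corr[k, t] = sum_m x[t+m] d_k[m]
    corr = np.stack([sps.fftconvolve(x, d[::-1], mode="valid")
                     for d in dictionary.atoms])
    combined = np.max(np.abs(corr), axis=0)

    candidates = np.flatnonzero(combined > gamma)
    # descending magnitude, ties to the earlier window
    order = np.lexsort((candidates, -combined[candidates]))
    candidates = candidates[order]

    accepted: list[int] = []
    events: list[MPPEvent] = []
    taken = np.array([], dtype=int)
    for t in candidates:
        if taken.size and np.min(np.abs(taken - t)) < min_separation:
            continue
        k = int(np.argmax(np.abs(corr[:, t])))
        alpha = float(corr[k, t])
        peak = int(t + np.argmax(np.abs(dictionary.atoms[k])))
        events.append(MPPEvent(tau=int(t), alpha=alpha, omega=k, peak_sample=peak))
        accepted.append(int(t))
        taken = np.asarray(accepted)

    return MPPTrain(events=events, band=dictionary.band, channel=trace.channel,
                    fs=trace.fs, n_samples=n, gamma=float(gamma))


def reconstruct(train: MPPTrain, dictionary: Dictionary) -> RawTrace:
    """Model-based reconstruction: sum of α-scaled atoms placed at their τ."""
    M = dictionary.M
    n = train.n_samples
    out = np.zeros(n)
    for ev in train.events:
        if ev.tau < 0 or ev.tau + M > n:
            raise ValueError(f"event at tau={ev.tau} exceeds trace bounds")
        if not (0 <= ev.omega < dictionary.K):
            raise ValueError(f"event atom index {ev.omega} out of range")
        out[ev.tau:ev.tau + M] += ev.alpha * dictionary.atoms[ev.omega]
    return RawTrace(samples=out, fs=train.fs, channel=train.channel)
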