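"""Ground-truth generator for the transient EEP model.

Emits traces with the exact statistical structure the pipeline assumes: a
1/f^a Gaussian background plus sparse, amplitude-scaled, band-limited
M-sample transients at known times, so that every stage — embedding, noise
thresholding, dictionary learning, deconvolution — can be tested against a
known answer without external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULTS
from .dictionary_learning import Dictionary, mutual_coherence
from .mpp_decode import MPPEvent, MPPTrain, reconstruct
from .preprocess import BandSpec
from .signal_io import RawTrace


@dataclass
class GroundTruth:
    """True events, atoms and noise behind a synthetic trace."""

    events: MPPTrain
    atoms: Dictionary
    noise: np.ndarray
    noise_exponent: float
    snr_db: float | None
    rng_seed: int


def make_atoms(K: int, M: int, band: BandSpec, fs: float, rng_seed: int,
               phases=None, coherence_bound: float = 0.95) -> Dictionary:
    """K unit-norm Gabor-like atoms spanning a band.

    Each atom is a Hann-windowed sinusoid; frequencies are spread uniformly
    across ``[f_lo, f_hi]`` and phases are drawn at random (or given).
    Phase draws are repeated until the pairwise mutual coherence is below
    ``coherence_bound`` (at most 100 draws).
    """
    if band.f_hi >= fs / 2:
        raise ValueError("band must lie below Nyquist")
    freqs = (np.array([band.center]) if K == 1
             else np.linspace(band.f_lo, band.f_hi, K))
    t = np.arange(M) / fs
    window = np.hanning(M)
    rng = np.random.default_rng(rng_seed)

    for _ in range(100):
        phi = (np.asarray(phases, dtype=float) if phases is not None
               else rng.uniform(0, 2 * np.pi, size=K))
        atoms = window * np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phi[:, None])
        atoms /= np.linalg.norm(atoms, axis=1, keepdims=True)
        d = Dictionary(atoms=atoms, band=band.name, fs=fs, provenance="seed",
                       init_id=rng_seed)
        if K < 2 or mutual_coherence(d) < coherence_bound:
            return d
        if phases is not None:
            break
    raise ValueError(
        f"could not draw K={K} atoms with coherence < {coherence_bound} "
        f"in band {band.name} at M={M}"
    )


def make_colored_noise(n: int, exponent: float, fs: float,
                       rng_seed: int) -> RawTrace:
    """Unit-variance Gaussian noise with power spectral density ∝ 1/f^exponent."""
    if n < 256:
        raise ValueError("need at least 256 samples")
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    rng = np.random.default_rng(rng_seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2)
    x = np.fft.irfft(spectrum * shaping, n=n)
    x /= np.std(x)
    return RawTrace(samples=x, fs=fs, channel="synthetic")


def _draw_event_times(n: int, M: int, rate: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson times thinned to a hard-core separation of M.

    The candidate rate is inflated by the dead-time correction
    ``rate / (1 - rate * M / fs)`` so that the thinned output rate matches
    the requested one in expectation.
    """
    duty = rate * M / fs
    candidate_rate = rate / (1.0 - duty)
    T = n / fs
    n_cand = rng.poisson(candidate_rate * T)
    cand = np.sort(rng.integers(0, n - M + 1, size=n_cand))
    kept: list[int] = []
    last = -np.inf
    for t in cand:
        if t - last >= M:
            kept.append(int(t))
            last = t
    return np.array(kept, dtype=int)


def make_eep(atoms: Dictionary, n: int,
             event_rate: float = DEFAULTS.event_rate,
             amp_range: tuple[float, float] = DEFAULTS.amp_range,
             snr_db: float | None = DEFAULTS.snr_db,
             noise_exponent: float = DEFAULTS.noise_exponent,
             rng_seed: int = 0) -> tuple[RawTrace, GroundTruth]:
    """Synthesize a trace of sparse transients in 1/f background.

    Event times follow a hard-core-thinned Poisson process (separation >= M),
    amplitudes are uniform on ``amp_range``, atom indices uniform over the
    dictionary. The background is colored noise scaled so the event-to-noise
    power ratio *on the event-bearing support* equals ``snr_db``;
    ``snr_db=None`` omits the background entirely (noiseless trace), and a
    trace with no events keeps the background at unit variance.
    """
    if atoms.K < 1:
        raise ValueError("empty dictionary")
    M = atoms.M
    fs = atoms.fs
    if not (fs > 0):
        raise ValueError("dictionary must carry a sampling frequency")
    if event_rate < 0 or event_rate * M / fs >= 0.5:
        raise ValueError(
            f"event_rate={event_rate}/s infeasible for M={M} at fs={fs} "
            "(duty cycle must stay below 0.5)"
        )

    rng = np.random.default_rng(rng_seed)
    taus = (_draw_event_times(n, M, event_rate, fs, rng)
            if event_rate > 0 else np.array([], dtype=int))
    alphas = rng.uniform(*amp_range, size=taus.size)
    omegas = rng.integers(0, atoms.K, size=taus.size)
    peak_offsets = np.argmax(np.abs(atoms.atoms), axis=1)
    events = [
        MPPEvent(tau=int(t), alpha=float(a), omega=int(w),
                 peak_sample=int(t + peak_offsets[w]))
        for t, a, w in zip(taus, alphas, omegas)
    ]
    train = MPPTrain(events=events, band=atoms.band, channel="synthetic",
                     fs=fs, n_samples=n)

    clean = reconstruct(train, atoms).samples if events else np.zeros(n)
    if snr_db is None:
        noise = np.zeros(n)
    else:
        noise = make_colored_noise(n, noise_exponent, fs,
                                   rng_seed=int(rng.integers(2**31))).samples
        if events:
            support = np.zeros(n, dtype=bool)
            for ev in events:
                support[ev.tau:ev.tau + M] = True
            p_signal = np.mean(clean[support] ** 2)
            p_noise = np.mean(noise[support] ** 2)
            scale = np.sqrt(p_signal / (p_noise * 10 ** (snr_db / 10)))
            noise = noise * scale
        # with no events the SNR is undefined; the background keeps its
        # natural unit variance

    samples = clean + noise
    # store the noise as the exact float difference so the additive
    # decomposition trace == reconstruct(events) + noise holds bitwise
    noise = samples - clean
    trace = RawTrace(samples=samples, fs=fs, channel="synthetic")
    truth = GroundTruth(events=train, atoms=atoms, noise=noise,
                        noise_exponent=noise_exponent, snr_db=snr_db,
                        rng_seed=rng_seed)
    return trace, truth
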