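"""Package-wide default parameters.

Every tunable default of the pipeline lives here so that scripts, the CLI
and tests can introspect one object instead of chasing keyword defaults
through the call graph.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml


@dataclass(frozen=True)
class Defaults:
    """Default hyper-parameters of the transient-model pipeline.

    Attributes
    ----------
    q_target:
        Target quality factor (center frequency / -3 dB bandwidth) of the
        band-pass pre-filter.
    filter_mode:
        Phase behaviour of the pre-filter; ``zero-phase`` (forward-backward)
        for off-line analysis, ``causal`` for on-line use.
    envelope_percentile:
        Percentile of the Hilbert envelope above which a local maximum
        qualifies as a modulated-pattern (snippet) candidate.
    kurtosis_tol:
        Half-width of the excess-kurtosis band around 0 (the Gaussian value)
        that terminates the noise-threshold trimming.
    min_frac:
        Floor on the fraction of snippet norms retained while trimming.
    seed_norm_percentile:
        Norm percentile defining the pool of snippets eligible to seed the
        dictionary.
    n_init:
        Number of random initialisations of the dictionary learner.
    max_iter:
        Maximum alternating iterations per initialisation.
    tol:
        Frobenius-norm change of the dictionary below which learning stops.
    init_selection:
        Rule that picks the winner among initialisations.
    shift_fraction:
        Lag search half-range of the shift-invariant assignment, as a
        fraction of the snippet length M.
    kernel_sigma:
        Standard deviation, in samples, of the Gaussian kernel used to
        smooth event trains into rates.
    kernel_support:
        Total finite support, in samples, of the truncated smoothing kernel.
    noise_exponent:
        Spectral exponent of the synthetic 1/f^a background.
    event_rate:
        Synthetic event rate in events per second; the default keeps events
        temporally sparse (duty cycle ~5% at the test scale), matching the
        sparsity the detection model assumes and the density of phenomena
        like sleep spindles (a few per minute).
    amp_range:
        Uniform amplitude range of synthetic event marks.
    snr_db:
        Synthetic event-to-background signal-to-noise ratio in dB, measured
        on the event-bearing support.
    """

    q_target: float = 2.0
    filter_mode: str = "zero-phase"
    envelope_percentile: float = 75.0
    kurtosis_tol: float = 0.1
    min_frac: float = 0.5
    seed_norm_percentile: float = 90.0
    n_init: int = 5
    max_iter: int = 20
    tol: float = 1e-2
    init_selection: str = "min_mutual_coherence"
    shift_fraction: float = 0.25
    kernel_sigma: float = 100.0
    kernel_support: int = 200
    noise_exponent: float = 1.0
    event_rate: float = 0.1
    amp_range: tuple[float, float] = (1.0, 3.0)
    snr_db: float = 10.0


DEFAULTS = Defaults()


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict.

    Unknown keys are preserved; known keys override :data:`DEFAULTS` when the
    caller merges them via :func:`merge_defaults`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def merge_defaults(overrides: dict | None = None) -> dict:
    """Return the defaults as a dict, updated with ``overrides``."""
    merged = asdict(DEFAULTS)
    if overrides:
        merged.update(overrides)
    return merged
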