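"""Trace, event-table and model I/O.

Traces are single-channel, uniformly sampled series. Two on-disk formats are
supported: EDF (European Data Format), read through :mod:`mne`, and a plain
comma-separated text format where metadata rides in ``#``-prefixed header
lines. Event tables, dictionaries and noise models round-trip through
CSV/JSON so every artifact of a run is a small text file.

Conventions: sample indexing is 0-based everywhere; times appear in seconds
only at the I/O boundary (``tau_seconds = tau_sample / fs``); amplitudes are
unitless and propagate the input scale (for EDF the physical dimension of
the channel, typically µV).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mppeep")

_EVENT_COLUMNS = ["tau_sample", "tau_seconds", "alpha", "omega", "band", "channel"]


@dataclass
class RawTrace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples:
        Signal values (µV or arbitrary units); stored as float64.
    fs:
        Sampling frequency in Hz, > 0.
    channel:
        Channel label.
    t0:
        Start offset in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs


# ---------------------------------------------------------------------------
# Delimited trace format
# ---------------------------------------------------------------------------

def write_trace_csv(trace: RawTrace, path) -> None:
    """Write a trace as one sample per line with ``#`` metadata headers."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={float(trace.fs)!r}\n")
        fh.write(f"# channel={trace.channel}\n")
        fh.write(f"# t0={float(trace.t0)!r}\n")
        for v in trace.samples:
            fh.write(f"{float(v)!r}\n")  # repr round-trips float64 exactly


def _read_trace_csv(path, channel: str | None, fs: float | None) -> RawTrace:
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            try:
                values.append(float(line.split(",")[0]))
            except ValueError as exc:
                raise ValueError(f"non-numeric content in {path}: {line!r}") from exc
    if fs is None:
        if "fs" not in meta:
            raise ValueError(f"{path} has no fs header and no fs was supplied")
        fs = float(meta["fs"])
    return RawTrace(
        samples=np.array(values),
        fs=fs,
        channel=channel or meta.get("channel", ""),
        t0=float(meta.get("t0", 0.0)),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_trace_edf(path, channel: str) -> RawTrace:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise KeyError(f"channel {channel!r} not in {raw.ch_names}")
    data = raw.get_data(picks=[channel])[0]
    # MNE rescales EDF channels with a known physical dimension (µV) to
    # volts; undo that so values match the stored physical scale.
    return RawTrace(samples=data * 1e6, fs=float(raw.info["sfreq"]), channel=channel)


def read_trace(path, format: str, channel: str | None = None,
               fs: float | None = None) -> RawTrace:
    """Read a single-channel trace.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"edf"`` or ``"delimited"``.
    channel:
        Channel label; required for EDF.
    fs:
        Sampling frequency override for delimited files without an
        ``# fs=`` header line.
    """
    if format == "edf":
        if channel is None:
            raise ValueError("EDF reading requires a channel label")
        return _read_trace_edf(path, channel)
    if format == "delimited":
        return _read_trace_csv(path, channel, fs)
    raise ValueError(f"unknown format {format!r}")


def write_edf(path, traces: list[RawTrace], physical_dim: str = "uV") -> None:
    """Write channels to a minimal EDF file (one data record).

    All traces must share length and sampling frequency. Samples are
    quantised to the 16-bit EDF grid over a symmetric physical range per
    channel, so the round-trip error is bounded by half a quantisation step.
    """
    if not traces:
        raise ValueError("no traces to write")
    n = len(traces[0])
    fs = traces[0].fs
    for t in traces:
        if len(t) != n or t.fs != fs:
            raise ValueError("all traces must share length and fs")

    def pad(text, width):
        s = str(text)[:width]
        return s + " " * (width - len(s))

    ns = len(traces)
    header_bytes = 256 + ns * 256
    duration = n / fs

    header = b"".join(pad(x, w).encode("ascii") for x, w in [
        ("0", 8), ("X", 80), ("X", 80), ("01.01.00", 8), ("00.00.00", 8),
        (header_bytes, 8), ("", 44), (1, 8), (f"{duration:.6g}", 8), (ns, 4),
    ])
    pmaxs = []
    for t in traces:
        pmax = float(np.max(np.abs(t.samples)))
        pmaxs.append(pmax if pmax > 0 else 1.0)
    for fld, width in [("channel", 16), ("transducer", 80), ("dim", 8),
                       ("pmin", 8), ("pmax", 8), ("dmin", 8), ("dmax", 8),
                       ("prefilter", 80), ("nr", 8), ("reserved", 32)]:
        for t, pmax in zip(traces, pmaxs):
            value = {
                "channel": t.channel, "transducer": "", "dim": physical_dim,
                "pmin": f"{-pmax:.6g}", "pmax": f"{pmax:.6g}",
                "dmin": -32767, "dmax": 32767, "prefilter": "",
                "nr": n, "reserved": "",
            }[fld]
            header += pad(value, width).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(header)
        for t, pmax in zip(traces, pmaxs):
            digital = np.round(t.samples / pmax * 32767).astype("<i2")
            fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def events_to_frame(train, fs: float) -> pd.DataFrame:
    """Flatten an event train into the canonical event table."""
    rows = [
        {
            "tau_sample": int(ev.tau),
            "tau_seconds": ev.tau / fs,
            "alpha": float(ev.alpha),
            "omega": int(ev.omega),
            "band": train.band,
            "channel": train.channel,
        }
        for ev in train.events
    ]
    frame = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return frame.sort_values("tau_sample", kind="stable").reset_index(drop=True)


def write_events(train, fs: float, path) -> None:
    """Write an event train as a CSV event table with a fixed column order."""
    events_to_frame(train, fs).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read a CSV event table back into a DataFrame."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event table {path} missing columns {missing}")
    return frame[_EVENT_COLUMNS]


# ---------------------------------------------------------------------------
# Dictionary / noise-model archives (JSON)
# ---------------------------------------------------------------------------

def save_dictionary(dictionary, path) -> None:
    """Serialize a dictionary (metadata + K×M atom table) to JSON."""
    payload = {
        "band": dictionary.band,
        "fs": dictionary.fs,
        "M": int(dictionary.atoms.shape[1]),
        "K": int(dictionary.atoms.shape[0]),
        "provenance": dictionary.provenance,
        "init_id": dictionary.init_id,
        "atoms": [list(map(float, row)) for row in dictionary.atoms],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_dictionary(path):
    from .dictionary_learning import Dictionary

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return Dictionary(
        atoms=np.array(payload["atoms"], dtype=float),
        band=payload["band"],
        fs=payload["fs"],
        provenance=payload.get("provenance", "learned"),
        init_id=payload.get("init_id", 0),
    )


def save_noise_model(model, path) -> None:
    """Serialize a noise model, including its kurtosis trace, to JSON."""
    payload = {
        "gamma": float(model.gamma),
        "M": int(model.M),
        "n_snippets": int(model.n_snippets),
        "kurtosis_trace": [[float(f), float(k)] for f, k in model.kurtosis_trace],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_noise_model(path):
    from .noise_model import NoiseModel

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return NoiseModel(
        gamma=payload["gamma"],
        M=payload["M"],
        kurtosis_trace=[tuple(pair) for pair in payload["kurtosis_trace"]],
        n_snippets=payload["n_snippets"],
    )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
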