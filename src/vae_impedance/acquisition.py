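"""Impedance acquisition: voltage-divider conversion, trace I/O and replay.

The measurement front end is a simple voltage divider driven by a constant
AC source: a known reference resistor ``R`` in series with the chest load.
With ``v_lead1`` the source-side RMS voltage and ``v_lead2`` the RMS voltage
across the reference resistor, the load impedance is

    Z = (v_lead1 - v_lead2) * R / v_lead2

The instrument emulated here oversamples the RMS voltages and reports one
block-averaged value per tick (by default 32 raw readings averaged every
10 ms, i.e. a 100 Hz impedance stream).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "OpenCircuitError",
    "InvalidConfigurationError",
    "TraceParseError",
    "ImpedanceTrace",
    "compute_impedance",
    "emulate_block_averaging",
    "read_trace",
    "write_trace",
    "replay",
]

#: Uniform-spacing check: relative tolerance on timestamp increments.
_SPACING_RTOL = 1e-6

#: Metadata keys recognised in the trace file header.
_META_KEYS = ("rate_hz", "resistor_ohm", "source", "note")

_HEADER = "time_s,impedance_ohm"


class OpenCircuitError(ValueError):
    """No voltage drop across the reference resistor (division guard)."""


class InvalidConfigurationError(ValueError):
    """A physically impossible configuration value (e.g. R <= 0)."""


class TraceParseError(ValueError):
    """A trace file that does not follow the CSV dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class ImpedanceTrace:
    """A uniformly sampled impedance series in ohms.

    Attributes
    ----------
    t : np.ndarray
        Sample times, seconds from recording start, strictly increasing and
        uniformly spaced to within ``1e-6`` relative tolerance.
    z : np.ndarray
        Impedance samples, ohms.
    rate_hz : float
        Sampling rate (samples per second).
    meta : dict
        Free-form provenance (source, reference resistor value, notes).
        Negative computed impedances are not rejected but flagged here
        under ``"negative_flagged"`` so downstream quality checks can see
        evidence of lead faults.
    """

    t: np.ndarray
    z: np.ndarray
    rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "z", z)
        if t.shape != z.shape or t.ndim != 1:
            raise ValueError("t and z must be 1-D arrays of equal length")
        if self.rate_hz <= 0:
            raise InvalidConfigurationError("rate_hz must be positive")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            step = 1.0 / self.rate_hz
            if np.any(np.abs(dt - step) > _SPACING_RTOL * step + 1e-12):
                raise ValueError("timestamps must be uniformly spaced")
        if not np.all(np.isfinite(z)):
            raise ValueError("impedance samples must be finite")

    def __len__(self) -> int:
        return int(self.z.size)

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, including the final sample period."""
        return len(self) / self.rate_hz

    @property
    def t_start(self) -> float:
        return float(self.t[0]) if len(self) else 0.0

    def slice(self, t0: float, t1: float) -> "ImpedanceTrace":
        """Samples with ``t0 <= t < t1`` (empty slice allowed)."""
        i0, i1 = np.searchsorted(self.t, [t0, t1], side="left")
        return ImpedanceTrace(self.t[i0:i1], self.z[i0:i1], self.rate_hz, dict(self.meta))


def compute_impedance(v_lead1: float, v_lead2: float, r: float) -> float:
    """Load impedance from the two scope voltages and the reference resistor.

    Parameters
    ----------
    v_lead1, v_lead2 : float
        RMS voltages of scope leads 1 and 2 against ground (volts).  The
        load drop is their difference; the reference-resistor drop is
        ``v_lead2`` itself.
    r : float
        Reference resistor, ohms; must be positive.

    Returns
    -------
    float
        ``(v_lead1 - v_lead2) * r / v_lead2`` in ohms.
    """
    if r <= 0:
        raise InvalidConfigurationError(f"reference resistor must be positive, got {r}")
    if v_lead2 == 0:
        raise OpenCircuitError("no drop across reference resistor (open circuit?)")
    return (v_lead1 - v_lead2) * r / v_lead2


def emulate_block_averaging(
    raw: Iterable[float],
    block: int = 32,
    tick: float = 0.01,
    meta: dict | None = None,
) -> ImpedanceTrace:
    """Block-average a raw oversampled stream into an impedance trace.

    Each output sample is the arithmetic mean of one consecutive block of
    ``block`` raw readings; one averaged sample is emitted per ``tick``
    seconds, so the output rate is ``1/tick`` (100 Hz at the defaults).
    A trailing partial block is dropped rather than padded, to avoid a
    biased mean at the end of the stream.
    """
    if block < 1:
        raise InvalidConfigurationError("block must be >= 1")
    if tick <= 0:
        raise InvalidConfigurationError("tick must be positive")
    values = np.asarray(list(raw) if not isinstance(raw, np.ndarray) else raw, dtype=float)
    n_out = values.size // block
    z = values[: n_out * block].reshape(n_out, block).mean(axis=1)
    rate = 1.0 / tick
    m = dict(meta or {})
    m.setdefault("source", "block-averaged stream")
    m["block"] = block
    return ImpedanceTrace(np.arange(n_out) * tick, z, rate, m)


def _format_float(x: float) -> str:
    """Shortest decimal form that round-trips the float exactly."""
    return repr(float(x))


def write_trace(trace: ImpedanceTrace, path) -> None:
    """Write a trace in the CSV dialect (``# key=value`` header, then rows)."""
    with open(path, "w", encoding="utf-8") as fh:
        _write_trace_stream(trace, fh)


def _write_trace_stream(trace: ImpedanceTrace, fh: io.TextIOBase) -> None:
    fh.write(f"# rate_hz={_format_float(trace.rate_hz)}\n")
    for key in _META_KEYS:
        if key == "rate_hz":
            continue
        if key in trace.meta:
            fh.write(f"# {key}={trace.meta[key]}\n")
    fh.write(_HEADER + "\n")
    for t, z in zip(trace.t, trace.z):
        fh.write(f"{_format_float(t)},{_format_float(z)}\n")


def read_trace(path) -> ImpedanceTrace:
    """Read a trace file; raises :class:`TraceParseError` with a line number."""
    meta: dict = {}
    times: list[float] = []
    values: list[float] = []
    rate: float | None = None
    seen_header = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.strip()
            if not line:
                continue
            if line.startswith("#"):
                if seen_header:
                    raise TraceParseError("metadata after header row", lineno)
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise TraceParseError(f"malformed metadata {body!r}", lineno)
                key, _, val = body.partition("=")
                key = key.strip()
                val = val.strip()
                if key == "rate_hz":
                    try:
                        rate = float(val)
                    except ValueError:
                        raise TraceParseError(f"non-numeric rate_hz {val!r}", lineno) from None
                else:
                    meta[key] = val
                continue
            if not seen_header:
                if line != _HEADER:
                    raise TraceParseError(
                        f"expected header {_HEADER!r}, got {line!r}", lineno
                    )
                seen_header = True
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise TraceParseError(f"expected 2 cells, got {len(cells)}", lineno)
            try:
                t = float(cells[0])
                z = float(cells[1])
            except ValueError:
                raise TraceParseError(f"non-numeric cell in {line!r}", lineno) from None
            if not (math.isfinite(t) and math.isfinite(z)):
                raise TraceParseError("non-finite value", lineno)
            if times and t <= times[-1]:
                raise TraceParseError("timestamps not strictly increasing", lineno)
            times.append(t)
            values.append(z)
    if not seen_header:
        raise TraceParseError("missing header row", None)
    if rate is None:
        if len(times) >= 2:
            rate = 1.0 / (times[1] - times[0])
        else:
            rate = 100.0
    try:
        return ImpedanceTrace(np.array(times), np.array(values), rate, meta)
    except ValueError as exc:
        raise TraceParseError(str(exc), None) from exc


def replay(trace: ImpedanceTrace, chunk_seconds: float) -> Iterator[ImpedanceTrace]:
    """Yield consecutive, non-overlapping chunks covering the trace exactly.

    The concatenation of the emitted chunks reproduces the input trace
    sample-for-sample, so streamed and batch analyses of the same recording
    see identical data.
    """
    if chunk_seconds <= 0:
        raise InvalidConfigurationError("chunk_seconds must be positive")
    n = len(trace)
    step = max(1, int(round(chunk_seconds * trace.rate_hz)))
    for i0 in range(0, n, step):
        i1 = min(n, i0 + step)
        yield ImpedanceTrace(trace.t[i0:i1], trace.z[i0:i1], trace.rate_hz, dict(trace.meta))
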