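"""Breath waveform container and delimited-text I/O.

A :class:`BreathWaveform` holds one ventilator cycle sampled on a uniform
time grid: time (s), flow at the Y-piece (L/s, inspiratory positive), airway
pressure (cmH2O) and delivered volume (mL, the running trapezoidal integral
of the sampled flow).  Metadata (sampling rate, settings, provenance of the
simulated system) travels in a plain ``meta`` dictionary.

The on-disk format is a CSV file with ``#``-prefixed ``key=value`` header
lines followed by the column header ``t_s,flow_lps,paw_cmh2o,volume_ml``.
Values are written with 6 significant digits, which round-trips losslessly
at that precision.  Both LF and CRLF dialects are accepted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["BreathWaveform", "read_waveform", "write_waveform"]

_COLUMNS = ("t_s", "flow_lps", "paw_cmh2o", "volume_ml")

#: grid jitter tolerated before a time vector is declared non-uniform, s
_GRID_TOL = 1e-9


@dataclass
class BreathWaveform:
    """Uniformly sampled time/flow/pressure/volume record of one cycle."""

    t: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    volume: np.ndarray
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("waveform needs at least 2 samples")
        if not (self.flow.size == self.paw.size == self.volume.size == n):
            raise ValueError("t, flow, paw and volume must have equal length")
        dt = np.diff(self.t)
        if dt.size and (np.abs(dt - dt[0]) > _GRID_TOL).any():
            raise ValueError("time grid is not uniform")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def fs(self) -> float:
        """Sampling rate, Hz (from the grid; ``meta['fs']`` takes priority)."""
        if "fs" in self.meta:
            return float(self.meta["fs"])
        return 1.0 / float(self.t[1] - self.t[0])

    @classmethod
    def from_samples(cls, t, flow, paw, meta=None) -> "BreathWaveform":
        """Build a waveform, deriving the volume column from the flow trace.

        The volume column is the cumulative trapezoidal integral of the
        sampled flow (L/s over s, scaled to mL), i.e. exactly what a bedside
        data logger would compute from the same samples.
        """
        t = np.asarray(t, dtype=float)
        flow = np.asarray(flow, dtype=float)
        volume = cumulative_trapezoid(flow, t, initial=0.0) * 1000.0
        return cls(t=t, flow=flow, paw=np.asarray(paw, dtype=float),
                   volume=volume, meta=dict(meta or {}))


def _format_meta_value(v: Any) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_waveform(w: BreathWaveform, path: Union[str, "io.TextIOBase"]) -> None:
    """Write a waveform as headered CSV (see module docstring for layout)."""
    lines = []
    for key in sorted(w.meta):
        lines.append(f"# {key}={_format_meta_value(w.meta[key])}")
    lines.append(",".join(_COLUMNS))
    for row in zip(w.t, w.flow, w.paw, w.volume):
        lines.append(",".join(f"{x:.6g}" for x in row))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", newline="") as fh:
            fh.write(text)


def _parse_meta_value(s: str) -> Any:
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    if s == "None":
        return None
    return s


def read_waveform(path: Union[str, "io.TextIOBase"]) -> BreathWaveform:
    """Read a waveform CSV, raising informative errors with line numbers."""
    if hasattr(path, "read"):
        raw = path.read()
    else:
        with open(path, "r", newline="") as fh:
            raw = fh.read()
    meta: Dict[str, Any] = {}
    header_seen = False
    cols: Dict[str, list] = {c: [] for c in _COLUMNS}
    for lineno, line in enumerate(raw.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise ValueError(f"line {lineno}: malformed metadata line {line!r}")
            key, _, value = body.partition("=")
            meta[key.strip()] = _parse_meta_value(value.strip())
            continue
        fields = [f.strip() for f in line.split(",")]
        if not header_seen:
            missing = [c for c in _COLUMNS if c not in fields]
            if missing:
                raise ValueError(
                    f"line {lineno}: missing column(s) {missing} in header {fields}"
                )
            order = [fields.index(c) for c in _COLUMNS]
            header_seen = True
            continue
        if len(fields) < len(_COLUMNS):
            raise ValueError(f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}")
        try:
            values = [float(fields[i]) for i in order]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
        for c, v in zip(_COLUMNS, values):
            cols[c].append(v)
    if not header_seen:
        raise ValueError("no column header found")
    t = np.asarray(cols["t_s"])
    if t.size >= 2:
        dt = np.diff(t)
        dt_ref = float(np.median(dt))
        # 6-significant-digit timestamps carry harmless rounding jitter;
        # snap those back onto the exact grid, reject real irregularity.
        bad = np.nonzero(np.abs(dt - dt_ref) > 0.01 * abs(dt_ref))[0]
        if bad.size:
            # +2: one for the column-header line, one for 1-based numbering
            raise ValueError(
                f"non-uniform time grid at data row {bad[0] + 2} "
                f"(dt {dt[bad[0]]:g} vs {dt_ref:g})"
            )
        t = t[0] + dt_ref * np.arange(t.size)
    return BreathWaveform(
        t=t,
        flow=np.asarray(cols["flow_lps"]),
        paw=np.asarray(cols["paw_cmh2o"]),
        volume=np.asarray(cols["volume_ml"]),
        meta=meta,
    )
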