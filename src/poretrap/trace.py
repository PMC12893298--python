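"""Core trace data model, file IO and the analysis low-pass stage.

Package-wide unit conventions: current in nA, voltage in mV, time in s,
frequency in Hz, PSD in nA^2/Hz, conductivity in S/m, lengths in nm.
Sample indexing is 0-based with half-open spans ``[start, end)``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
from scipy import signal

SCHEMA_VERSION = "1"

#: Columns required in columnar (CSV/TSV) trace files.
COLUMNAR_COLUMNS = ("time_s", "current_nA", "voltage_mV")


class TraceLoadError(ValueError):
    """Raised when a trace file is malformed or violates the Trace contract."""


@dataclass
class TraceMeta:
    """Recording metadata.

    Parameters
    ----------
    device_id : str
        Identifier of the nanopore device/chip.
    conductivity : float, optional
        Electrolyte conductivity in S/m (1 M KCl is ~11.2 S/m at 25 degC).
    temperature : float, optional
        Bath temperature in degC.
    pore_length : float, optional
        Effective pore (membrane channel) length L in nm.
    hardware_filter_hz : float, optional
        Analog anti-alias cutoff of the acquisition chain, Hz.
    analysis_filter_hz : float, optional
        Digital low-pass cutoff applied for analysis, Hz.
    """

    device_id: str = ""
    conductivity: Optional[float] = None
    temperature: Optional[float] = None
    pore_length: Optional[float] = None
    hardware_filter_hz: Optional[float] = None
    analysis_filter_hz: Optional[float] = None

    def validate(self, fs: Optional[float] = None) -> None:
        hw, an = self.hardware_filter_hz, self.analysis_filter_hz
        if hw is not None and an is not None and an > hw:
            raise ValueError(
                f"analysis_filter_hz ({an}) must not exceed hardware_filter_hz ({hw})"
            )
        if fs is not None and hw is not None and hw > fs / 2 + 1e-9:
            raise ValueError(f"hardware_filter_hz ({hw}) exceeds Nyquist ({fs / 2})")


@dataclass
class VoltageProtocol:
    """Ordered trap-release voltage phases, repeated ``n_cycles`` times.

    ``phases`` is a list of ``(level_mV, duration_s)``. A valid cycle contains
    at least one positive-bias (trap) phase and one opposite-polarity
    (release) phase.
    """

    phases: Sequence[tuple[float, float]]
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        levels = [lv for lv, _ in self.phases]
        durations = [du for _, du in self.phases]
        if any(d <= 0 for d in durations):
            raise ValueError("every phase duration must be > 0")
        if not any(lv > 0 for lv in levels) or not any(lv < 0 for lv in levels):
            raise ValueError(
                "a trap-release cycle needs a positive (trap) and a "
                "negative (release) phase"
            )

    @property
    def cycle_duration(self) -> float:
        return float(sum(d for _, d in self.phases))

    @property
    def total_duration(self) -> float:
        return self.cycle_duration * self.n_cycles

    @property
    def trap_phase_index(self) -> int:
        """Index of the first positive-bias phase (the trap phase)."""
        for i, (lv, _) in enumerate(self.phases):
            if lv > 0:
                return i
        raise ValueError("protocol has no positive-bias phase")

    def phase_spans(self, fs: float, cycle: int = 0) -> list[tuple[int, int]]:
        """Half-open sample spans of each phase of one cycle, absolute indices."""
        t0 = cycle * self.cycle_duration
        spans = []
        t = t0
        for _, du in self.phases:
            spans.append((int(round(t * fs)), int(round((t + du) * fs))))
            t += du
        return spans

    def voltage_at(self, n: int, fs: float) -> np.ndarray:
        """Render the per-sample voltage (mV) for ``n`` samples."""
        out = np.zeros(n)
        edges = np.cumsum([0.0] + [du for _, du in self.phases])
        for c in range(self.n_cycles):
            base = c * self.cycle_duration
            for (lv, _), a, b in zip(self.phases, edges[:-1], edges[1:]):
                i0 = min(n, int(round((base + a) * fs)))
                i1 = min(n, int(round((base + b) * fs)))
                out[i0:i1] = lv
        return out


@dataclass
class Trace:
    """A sampled ionic-current record.

    ``samples`` holds current in nA; ``voltage`` is either a per-sample array
    in mV (same length as ``samples``) or a :class:`VoltageProtocol`
    describing the applied bias symbolically.
    """

    samples: np.ndarray
    fs: float
    voltage: Union[np.ndarray, VoltageProtocol, None] = None
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise TraceLoadError(f"non-finite current sample at record {bad}")
        if isinstance(self.voltage, (list, tuple, np.ndarray)):
            self.voltage = np.asarray(self.voltage, dtype=np.float64)
            if self.voltage.shape != self.samples.shape:
                raise ValueError("per-sample voltage must match samples in length")
        self.meta.validate(self.fs)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def voltage_array(self) -> np.ndarray:
        """Per-sample applied bias in mV, rendering the protocol if needed."""
        if self.voltage is None:
            raise ValueError("trace has no voltage information")
        if isinstance(self.voltage, VoltageProtocol):
            return self.voltage.voltage_at(len(self), self.fs)
        return self.voltage

    def slice(self, start: int, end: int) -> "Trace":
        """Sub-trace over the half-open sample span [start, end)."""
        v = self.voltage
        if isinstance(v, np.ndarray):
            v = v[start:end]
        elif isinstance(v, VoltageProtocol):
            v = v.voltage_at(len(self), self.fs)[start:end]
        return Trace(self.samples[start:end], self.fs, v, dataclasses.replace(self.meta))


def _meta_to_dict(meta: TraceMeta) -> dict:
    return {k: v for k, v in dataclasses.asdict(meta).items() if v is not None}


def _infer_format(path: Union[str, Path]) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        return "columnar"
    if suffix in (".h5", ".hdf5"):
        return "container"
    raise ValueError(f"cannot infer trace format from suffix {suffix!r}")


def read_trace(path: Union[str, Path], format: Optional[str] = None) -> Trace:
    """Read a trace from a columnar (CSV/TSV) or HDF5 container file.

    Columnar files must carry a header row with columns ``time_s``,
    ``current_nA`` and optionally ``voltage_mV``; the sampling rate is
    recovered as 1/median(dt). Containers hold one group per recording with
    datasets ``current`` (nA) and optionally ``voltage`` (mV), and attributes
    ``fs_hz`` plus the TraceMeta fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "columnar":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        missing = [c for c in ("time_s", "current_nA") if c not in df.columns]
        if missing:
            raise TraceLoadError(f"columnar trace missing columns {missing}")
        cur = df["current_nA"].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(cur)):
            bad = int(np.flatnonzero(~np.isfinite(cur))[0])
            raise TraceLoadError(f"non-finite current sample at record {bad}")
        t = df["time_s"].to_numpy(dtype=np.float64)
        if len(t) < 2:
            raise TraceLoadError("columnar trace needs at least 2 records")
        dt = np.median(np.diff(t))
        if dt <= 0 or not np.isfinite(dt):
            raise TraceLoadError("time_s column is not strictly increasing")
        fs = 1.0 / dt
        volt = (
            df["voltage_mV"].to_numpy(dtype=np.float64)
            if "voltage_mV" in df.columns
            else None
        )
        return Trace(cur, fs, volt)
    if fmt == "container":
        with h5py.File(path, "r") as f:
            groups = [k for k in f.keys() if isinstance(f[k], h5py.Group)]
            if not groups:
                raise TraceLoadError("container holds no recording group")
            g = f[groups[0]]
            if "current" not in g:
                raise TraceLoadError("recording group lacks a 'current' dataset")
            cur = np.asarray(g["current"], dtype=np.float64)
            volt = np.asarray(g["voltage"], dtype=np.float64) if "voltage" in g else None
            fs = float(g.attrs["fs_hz"])
            meta_kwargs = {}
            for fld in dataclasses.fields(TraceMeta):
                if fld.name in g.attrs:
                    v = g.attrs[fld.name]
                    meta_kwargs[fld.name] = str(v) if fld.name == "device_id" else float(v)
            if not np.all(np.isfinite(cur)):
                bad = int(np.flatnonzero(~np.isfinite(cur))[0])
                raise TraceLoadError(f"non-finite current sample at record {bad}")
            return Trace(cur, fs, volt, TraceMeta(**meta_kwargs))
    raise ValueError(f"unknown trace format {fmt!r}")


def write_trace(trace: Trace, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a trace so that ``read_trace`` round-trips samples to <=1e-9 nA."""
    if not isinstance(trace, Trace):
        raise TypeError("write_trace expects a Trace")
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "columnar":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        cols = {"time_s": trace.times, "current_nA": trace.samples}
        if trace.voltage is not None:
            cols["voltage_mV"] = trace.voltage_array()
        pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
        return
    if fmt == "container":
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            g = f.create_group("recording")
            g.create_dataset("current", data=trace.samples)
            if trace.voltage is not None:
                g.create_dataset("voltage", data=trace.voltage_array())
            g.attrs["fs_hz"] = trace.fs
            g.attrs["schema_version"] = SCHEMA_VERSION
            for k, v in _meta_to_dict(trace.meta).items():
                g.attrs[k] = v
        return
    raise ValueError(f"unknown trace format {fmt!r}")


def bessel_sos(cutoff_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the analysis Bessel low-pass (-3 dB at cutoff)."""
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff_hz} at fs {fs}")
    return signal.bessel(order, cutoff_hz, btype="low", fs=fs, output="sos", norm="mag")


def lowpass_filter(trace: Trace, cutoff_hz: float) -> Trace:
    """Zero-phase 4-pole Bessel low-pass; returns a new Trace.

    Applied forward-backward (``sosfiltfilt``) so event boundaries are not
    shifted; the effective magnitude response is the square of the one-pass
    Bessel magnitude. Sample count, fs and voltage are unchanged;
    ``meta.analysis_filter_hz`` is set to ``cutoff_hz``.
    """
    sos = bessel_sos(cutoff_hz, trace.fs)
    filtered = signal.sosfiltfilt(sos, trace.samples)
    meta = dataclasses.replace(trace.meta, analysis_filter_hz=float(cutoff_hz))
    return Trace(filtered, trace.fs, trace.voltage, meta)


def filter_gain(cutoff_hz: float, fs: float, freq_hz: float) -> float:
    """Amplitude gain of the zero-phase analysis filter at ``freq_hz``."""
    sos = bessel_sos(cutoff_hz, fs)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)  # forward-backward pass squares |H|


def filter_noise_bandwidth_factor(cutoff_hz: float, fs: float, worn: int = 8192) -> float:
    """Fraction of white-noise variance passed by the zero-phase filter.

    Integrates the effective squared magnitude (|H|^4 of the one-pass stage)
    over [0, fs/2]; multiplying an input white-noise variance by this factor
    predicts the output variance.
    """
    sos = bessel_sos(cutoff_hz, fs)
    w, h = signal.sosfreqz(sos, worN=worn, fs=fs)
    return float(np.trapezoid(np.abs(h) ** 4, w) / (fs / 2))
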