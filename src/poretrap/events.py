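"""Trap-release cycle splitting, 3-sigma event segmentation and baseline QC.

Each trap-release cycle holds one candidate gating event. Within the trap
phase, the open-pore mean I0 and RMS noise sigma_open are estimated on the
leading baseline window; samples whose current magnitude falls below
I0 - threshold_sigma * sigma_open for at least a minimum run are the gated
segment. QC rejects events whose open baseline is multi-component (drift or
missed gating) or deviates from a blank-recording reference, and normalizes
relative currents so that the open-segment mean is exactly 1.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trace import Trace, VoltageProtocol

logger = logging.getLogger(__name__)

#: Leading portion of the trap phase used for I0 / sigma_open (s).
OPEN_WINDOW_S = 0.1
#: Minimum contiguous sub-threshold duration that counts as gating (s).
MIN_GATED_RUN_S = 1e-3
#: Relative deviation of the open mean from the blank reference tolerated by QC.
DRIFT_TOLERANCE = 0.05


class RejectReason(str, enum.Enum):
    NONE = "none"
    BASELINE_DRIFT = "baseline_drift"
    MULTI_COMPONENT_BASELINE = "multi_component_baseline"
    NO_GATING = "no_gating"
    TOO_SHORT = "too_short"


@dataclass
class SegmentStats:
    """Mean/RMS summary of one segment; ``mean_relative`` is on the I/I0 scale."""

    mean: float
    rms_noise: float
    n: int
    mean_relative: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("segment needs at least one sample")
        if self.rms_noise < 0:
            raise ValueError("rms_noise must be >= 0")


@dataclass
class GatingEvent:
    """One trap-release cycle split into open and gated regions.

    Spans are half-open sample intervals relative to the cycle start;
    ``trap_samples`` holds the current magnitude (nA) of the trap phase.
    Relative currents are corrected by ``correction_factor`` (set by QC) so
    the open-segment mean is 1.
    """

    cycle_index: int
    trap_span: tuple[int, int]
    open_span: Optional[tuple[int, int]]
    gated_span: Optional[tuple[int, int]]
    i0: float
    sigma_open: float
    open_stats: Optional[SegmentStats]
    gated_stats: Optional[SegmentStats]
    fs: float
    trap_samples: np.ndarray = field(repr=False)
    correction_factor: float = 1.0
    valid: bool = False
    reject_reason: RejectReason = RejectReason.NONE
    qc_done: bool = False
    poor_fit: bool = False

    def _rel(self, span: tuple[int, int]) -> np.ndarray:
        a, b = span
        off = self.trap_span[0]
        return self.trap_samples[a - off:b - off] / self.i0 * self.correction_factor

    def open_rel(self) -> np.ndarray:
        """Corrected relative current of the open segment."""
        if self.open_span is None:
            raise ValueError("event has no open segment")
        return self._rel(self.open_span)

    def gated_rel(self) -> np.ndarray:
        """Corrected relative current of the gated segment."""
        if self.gated_span is None:
            raise ValueError("event has no gated segment")
        return self._rel(self.gated_span)

    def gated_nA(self) -> np.ndarray:
        if self.gated_span is None:
            raise ValueError("event has no gated segment")
        a, b = self.gated_span
        off = self.trap_span[0]
        return self.trap_samples[a - off:b - off]

    @property
    def depth(self) -> Optional[float]:
        """Mean fractional blockade 1 - <I_gated>/I0 (corrected scale)."""
        if self.gated_stats is None:
            return None
        return 1.0 - self.gated_stats.mean_relative


def split_cycles(trace: Trace, protocol: VoltageProtocol) -> list[tuple[int, int]]:
    """Half-open sample intervals of each trap-release cycle.

    The intervals tile the protocol span without overlap. A shortfall beyond
    one sample per phase boundary raises.
    """
    n_needed = int(round(protocol.total_duration * trace.fs))
    slack = len(protocol.phases) * protocol.n_cycles  # 1 sample per boundary
    if len(trace) + slack < n_needed:
        raise ValueError(
            f"protocol spans {n_needed} samples but trace has only "
            f"{len(trace)} (shortfall {n_needed - len(trace)})"
        )
    bounds = [
        min(int(round(c * protocol.cycle_duration * trace.fs)), len(trace))
        for c in range(protocol.n_cycles + 1)
    ]
    return [(bounds[i], bounds[i + 1]) for i in range(protocol.n_cycles)]


def _runs_below(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean mask."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _trap_span_from_voltage(cycle: Trace, protocol: Optional[VoltageProtocol]) -> tuple[int, int]:
    if protocol is not None:
        spans = protocol.phase_spans(cycle.fs, cycle=0)
        return spans[protocol.trap_phase_index]
    if cycle.voltage is not None:
        v = cycle.voltage_array()
        pos = _runs_below(v > 0)
        if pos:
            return max(pos, key=lambda ab: ab[1] - ab[0])
    return (0, len(cycle))


def segment_event(cycle: Trace, protocol: Optional[VoltageProtocol] = None,
                  cycle_index: int = 0, threshold_sigma: float = 3.0,
                  open_window_s: float = OPEN_WINDOW_S,
                  min_gated_run_s: float = MIN_GATED_RUN_S) -> GatingEvent:
    """Segment one cycle into open and gated regions by the 3-sigma rule.

    The trap phase is located from ``protocol`` (or the cycle's per-sample
    voltage; else the whole cycle is used). I0 and sigma_open come from the
    first ``open_window_s`` of the trap phase; the gated span is the longest
    run of at least ``min_gated_run_s`` below I0 - threshold_sigma*sigma_open
    on the current magnitude.
    """
    fs = cycle.fs
    a, b = _trap_span_from_voltage(cycle, protocol)
    x = np.abs(cycle.samples[a:b])
    n_open = int(round(open_window_s * fs))
    min_run = max(2, int(round(min_gated_run_s * fs)))

    def _reject(reason: RejectReason) -> GatingEvent:
        stats = None
        i0 = sigma = np.nan
        if x.size >= n_open and n_open >= 2:
            i0 = float(x[:n_open].mean())
            sigma = float(x[:n_open].std())
            stats = SegmentStats(i0, sigma, n_open, 1.0)
        return GatingEvent(cycle_index, (a, b), (a, a + min(n_open, x.size)) if stats else None,
                           None, i0, sigma, stats, None, fs, x,
                           valid=False, reject_reason=reason)

    if x.size < n_open + min_run or n_open < 2:
        return _reject(RejectReason.TOO_SHORT)

    i0 = float(x[:n_open].mean())
    sigma_open = float(x[:n_open].std())
    if i0 <= 0 or sigma_open > 0.1 * i0:
        # baseline window is contaminated (e.g. gating started inside it)
        return _reject(RejectReason.TOO_SHORT)
    threshold = i0 - threshold_sigma * sigma_open
    runs = [(s, e) for s, e in _runs_below(x < threshold) if e - s >= min_run]
    if not runs:
        return _reject(RejectReason.NO_GATING)
    g0, g1 = max(runs, key=lambda ab: ab[1] - ab[0])
    if g0 < n_open:
        # gating begins before a full baseline window is available
        return _reject(RejectReason.TOO_SHORT)

    open_x = x[:g0]
    gated_x = x[g0:g1]
    open_stats = SegmentStats(float(open_x.mean()), float(open_x.std()),
                              open_x.size, float(open_x.mean() / i0))
    gated_stats = SegmentStats(float(gated_x.mean()), float(gated_x.std()),
                               gated_x.size, float(gated_x.mean() / i0))
    return GatingEvent(cycle_index, (a, b), (a, a + g0), (a + g0, a + g1),
                       i0, sigma_open, open_stats, gated_stats, fs, x,
                       valid=True, reject_reason=RejectReason.NONE)


def qc_and_normalize(event: GatingEvent,
                     reference_baseline: Optional[SegmentStats] = None,
                     drift_tolerance: float = DRIFT_TOLERANCE,
                     k_max_open: int = 3) -> GatingEvent:
    """Baseline QC and open-mean normalization (in place; returns the event).

    A sub-level mixture is fitted to the open segment: more than one selected
    component marks the event ``multi_component_baseline``. If a blank
    reference is given, an open mean deviating beyond ``drift_tolerance``
    marks ``baseline_drift``. Otherwise the correction factor
    1/(open mean on the relative scale) is applied so the corrected open mean
    is exactly 1. Idempotent.
    """
    from .sublevels import fit_gmm_candidates, select_sublevel_model

    if event.open_stats is None or event.open_span is None:
        raise ValueError("event has no open segment; cannot QC")
    if not event.valid and event.reject_reason is not RejectReason.NONE and not event.qc_done:
        return event  # segmentation already rejected it

    open_rel = event.open_rel()
    candidates = fit_gmm_candidates(open_rel, k_max=k_max_open,
                                    seed=event.cycle_index)
    selected = select_sublevel_model(candidates)
    if selected.k != 1:
        event.valid = False
        event.reject_reason = RejectReason.MULTI_COMPONENT_BASELINE
        event.qc_done = True
        return event

    if reference_baseline is not None:
        dev = abs(event.open_stats.mean - reference_baseline.mean)
        if dev > drift_tolerance * abs(reference_baseline.mean):
            event.valid = False
            event.reject_reason = RejectReason.BASELINE_DRIFT
            event.qc_done = True
            return event
    else:
        logger.info("event %d: no blank reference; drift check disabled",
                    event.cycle_index)

    cf = 1.0 / float(open_rel.mean())
    event.correction_factor *= cf
    for stats in (event.open_stats, event.gated_stats):
        if stats is not None:
            stats.mean_relative *= cf
    event.valid = True
    event.reject_reason = RejectReason.NONE
    event.qc_done = True
    return event


def events_table(events: Sequence[GatingEvent]) -> pd.DataFrame:
    """One row per event: spans, I0, sigma_open, depth, QC status."""
    rows = []
    for ev in events:
        rows.append({
            "cycle_index": ev.cycle_index,
            "open_start": ev.open_span[0] if ev.open_span else -1,
            "open_end": ev.open_span[1] if ev.open_span else -1,
            "gated_start": ev.gated_span[0] if ev.gated_span else -1,
            "gated_end": ev.gated_span[1] if ev.gated_span else -1,
            "i0_nA": ev.i0,
            "sigma_open_nA": ev.sigma_open,
            "depth": ev.depth if ev.depth is not None else np.nan,
            "correction_factor": ev.correction_factor,
            "valid": ev.valid,
            "reject_reason": ev.reject_reason.value,
        })
    return pd.DataFrame(rows)
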