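"""Per-event metrics and per-species radar fingerprints.

Each valid trapping event contributes up to six metric axes: mean fractional
blockade depth, GMM sub-level count, low-frequency 1/f exponent alpha, and
the three band noise-increase factors. A species fingerprint is the per-axis
arithmetic mean and population standard deviation over its events; spectral
axes may aggregate fewer events than depth/sublevels when some segments were
too short for PSD estimation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .events import GatingEvent
from .spectral import NIFSet, OneOverFFit
from .sublevels import SubLevelModel

AXES = ("depth", "sublevels", "alpha", "nif_low", "nif_mid", "nif_high")


@dataclass
class EventMetrics:
    """Fingerprint contributions of one valid event; spectral fields optional."""

    depth: float
    k: int
    alpha: Optional[float] = None
    nifs: Optional[NIFSet] = None

    def __post_init__(self) -> None:
        if not 0 < self.depth < 1:
            raise ValueError(f"depth must lie in (0, 1); got {self.depth}")
        if self.k < 1:
            raise ValueError("sub-level count must be >= 1")

    def axis_values(self) -> dict[str, float]:
        out = {"depth": self.depth, "sublevels": float(self.k)}
        if self.alpha is not None:
            out["alpha"] = self.alpha
        if self.nifs is not None:
            out["nif_low"], out["nif_mid"], out["nif_high"] = self.nifs.as_tuple()
        return out


@dataclass
class Fingerprint:
    """Mean +- SD (population) per axis over a species' events."""

    axes: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    n_events: np.ndarray

    def as_dict(self) -> dict:
        return {
            "axes": list(self.axes),
            "means": [None if np.isnan(v) else float(v) for v in self.means],
            "sds": [None if np.isnan(v) else float(v) for v in self.sds],
            "n_events": [int(v) for v in self.n_events],
        }


def event_metrics(event: GatingEvent, sublevel: SubLevelModel,
                  one_over_f: Optional[OneOverFFit] = None,
                  nifs: Optional[NIFSet] = None) -> EventMetrics:
    """Collapse one event's analyses into its metric vector.

    Refuses invalid events and events whose corrected gated mean implies a
    non-positive blockade (those cannot have passed the 3-sigma rule).
    """
    if not event.valid:
        raise ValueError("refusing metrics for an invalid event")
    depth = event.depth
    if depth is None or depth <= 0:
        raise ValueError("event has no positive blockade depth; not a gated event")
    alpha = one_over_f.alpha if one_over_f is not None else None
    return EventMetrics(depth=float(depth), k=sublevel.k, alpha=alpha, nifs=nifs)


def aggregate_fingerprint(metrics: Sequence[EventMetrics]) -> Fingerprint:
    """Per-axis mean and population SD over the events providing each axis."""
    if not metrics:
        raise ValueError("cannot aggregate an empty event list")
    means, sds, counts = [], [], []
    per_axis = {ax: [] for ax in AXES}
    for m in metrics:
        for ax, v in m.axis_values().items():
            per_axis[ax].append(v)
    for ax in AXES:
        vals = np.asarray(per_axis[ax], dtype=float)
        if vals.size:
            means.append(vals.mean())
            sds.append(vals.std())  # population SD (ddof=0)
            counts.append(vals.size)
        else:
            means.append(np.nan)
            sds.append(np.nan)
            counts.append(0)
    return Fingerprint(AXES, np.array(means), np.array(sds),
                       np.array(counts, dtype=int))


@dataclass
class FingerprintComparison:
    axes: tuple[str, ...]
    standardized_diff: np.ndarray  # (mean_a - mean_b) / pooled SD; nan if undefined
    distance: float


def compare_fingerprints(a: Fingerprint, b: Fingerprint) -> FingerprintComparison:
    """Per-axis standardized mean difference and their Euclidean norm.

    Axes with zero pooled SD (or missing on either side) are reported as NaN
    and excluded from the distance.
    """
    if a.axes != b.axes:
        raise ValueError("fingerprints have different axis sets")
    pooled = np.sqrt((a.sds ** 2 + b.sds ** 2) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = (a.means - b.means) / pooled
    diff = np.where(pooled > 0, diff, np.nan)
    finite = np.isfinite(diff)
    distance = float(np.sqrt(np.nansum(diff[finite] ** 2))) if finite.any() else 0.0
    return FingerprintComparison(a.axes, diff, distance)


def export_radar(fp: Fingerprint, path: Union[str, Path],
                 provenance: Optional[dict] = None,
                 plot_path: Optional[Union[str, Path]] = None) -> None:
    """Write the fingerprint as JSON and (optionally) a radar plot.

    The JSON preserves raw values in the fixed axis order; the plot min-max
    normalizes each axis and draws the mean line with a +-1 SD band.
    """
    path = Path(path)
    payload = fp.as_dict()
    payload["provenance"] = provenance or {}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if plot_path is not None:
        plot_radar({"fingerprint": fp}, plot_path)


def read_fingerprint(path: Union[str, Path]) -> Fingerprint:
    d = json.loads(Path(path).read_text())
    to_arr = lambda xs: np.array([np.nan if v is None else v for v in xs], dtype=float)
    return Fingerprint(tuple(d["axes"]), to_arr(d["means"]), to_arr(d["sds"]),
                       np.array(d["n_events"], dtype=int))


def plot_radar(fingerprints: dict[str, Fingerprint],
               path: Union[str, Path]) -> None:
    """Radar plot of one or more fingerprints, axes min-max co-normalized."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axes = next(iter(fingerprints.values())).axes
    n_ax = len(axes)
    lo = np.full(n_ax, np.inf)
    hi = np.full(n_ax, -np.inf)
    for fp in fingerprints.values():
        lo = np.fmin(lo, fp.means - fp.sds)
        hi = np.fmax(hi, fp.means + fp.sds)
    span = np.where(hi > lo, hi - lo, 1.0)

    theta = np.linspace(0, 2 * np.pi, n_ax, endpoint=False)
    theta_closed = np.concatenate([theta, theta[:1]])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    for name, fp in fingerprints.items():
        mean_n = (fp.means - lo) / span
        lo_n = (fp.means - fp.sds - lo) / span
        hi_n = (fp.means + fp.sds - lo) / span
        close = lambda v: np.concatenate([v, v[:1]])
        line, = ax.plot(theta_closed, close(mean_n), label=name)
        ax.fill_between(theta_closed, close(np.clip(lo_n, 0, None)),
                        close(hi_n), alpha=0.25, color=line.get_color())
    ax.set_xticks(theta)
    ax.set_xticklabels(axes)
    ax.set_yticklabels([])
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
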