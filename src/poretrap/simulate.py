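"""Seeded synthetic trap-release recordings with ground-truth annotations.

The generator is phenomenological: the open-pore baseline follows the
channel+access conductance model at the protocol bias; open-pore noise is
white plus 1/f^alpha flicker (FFT spectral shaping); a capture occurs after
an exponential waiting time in each trap phase; the gated current is
I0 * (1 - depth(t)) where depth(t) is a telegraph chain over the preset's
discrete blockade levels (exponential dwells), optionally blurred by an
Ornstein-Uhlenbeck wander; gated segments carry their own preset-specific
noise (elevated white floor and flicker) so that gated/open band-power
ratios exceed 1. Presets emulate the surface-coating phenotypes: a stable
shallow single level (amine/APTES), discrete deeper metastable levels
(biotin), broad multi-level flickering (Tween-20), and streptavidin
titration stages with progressively rarer, less stable trapping.
"""
from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .conductance import PoreSpec, pore_conductance
from .trace import Trace, TraceMeta, VoltageProtocol, bessel_sos
from scipy import signal as _signal

REGISTRY_VERSION = "1"


@dataclass
class NoiseSpec:
    """Open-pore noise model: white floor plus 1/f^alpha flicker.

    ``white_sd`` is the RMS (nA) of the raw white component at the full
    sampling bandwidth; its one-sided PSD is 2*white_sd^2/fs. ``flicker_amp``
    is the one-sided flicker PSD at 1 Hz (nA^2*Hz^(alpha-1)).
    """

    white_sd: float = 0.08
    flicker_alpha: float = 1.0
    flicker_amp: float = 2e-4

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.flicker_amp < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0 <= self.flicker_alpha <= 3:
            raise ValueError("flicker_alpha must lie in [0, 3]")


@dataclass
class GatedNoise:
    """Extra noise inside gated segments.

    ``white_mult`` scales the open white RMS; flicker parameters are
    absolute (same units as :class:`NoiseSpec`). These control the
    noise-increase factors of each preset.
    """

    white_mult: float = 1.0
    flicker_amp: float = 0.0
    flicker_alpha: float = 1.0


@dataclass
class OUWander:
    """Ornstein-Uhlenbeck wander of the blockade depth (relative units).

    ``relaxation_hz`` is the corner frequency of the resulting Lorentzian;
    ``sd`` its stationary standard deviation.
    """

    relaxation_hz: float
    sd: float


@dataclass
class SimPreset:
    """Generative parameters of one surface-coating phenotype."""

    name: str
    depth_levels: Sequence[float]
    level_weights: Sequence[float]
    switch_rate: float  # level-to-level telegraph rate, Hz
    capture_rate: float  # 1/s within the trap phase
    capture_delay_s: float = 0.3
    event_stability: str = "persistent"  # persistent|intermittent|flickering|none
    wander: Optional[OUWander] = None
    #: Optional second, fast configuration wander (high-corner Lorentzian).
    wander_fast: Optional[OUWander] = None
    gated_noise: GatedNoise = field(default_factory=GatedNoise)
    gated_dwell_s: float = 0.8  # mean gated dwell for intermittent/flickering
    released_dwell_s: float = 0.3
    #: Slew limit on docking-configuration changes: the depth trajectory is
    #: low-passed here (Hz) so level transitions take a finite re-seating
    #: time instead of being instantaneous steps.
    level_lowpass_hz: Optional[float] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_levels, dtype=float)
        w = np.asarray(self.level_weights, dtype=float)
        if d.size != w.size or d.size == 0:
            raise ValueError("depth_levels and level_weights must match and be non-empty")
        if np.any((d <= 0) | (d >= 1)):
            raise ValueError("all depths must lie in (0, 1)")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("level weights must sum to 1")
        if self.capture_rate < 0:
            raise ValueError("capture_rate must be >= 0")
        if self.event_stability not in ("persistent", "intermittent", "flickering", "none"):
            raise ValueError(f"unknown event_stability {self.event_stability!r}")


@dataclass
class GroundTruth:
    """Sample-exact annotation of a simulated recording."""

    fs: float
    seed: int
    preset_name: str
    cycle_spans: list[tuple[int, int]]
    capture_index: list[Optional[int]]  # absolute sample of first capture, per cycle
    gated_spans: list[list[tuple[int, int]]]  # absolute, per cycle
    level_pieces: list[list[tuple[int, int, float]]]  # (start, end, depth) per cycle
    preset_params: dict = field(default_factory=dict)
    registry_version: str = REGISTRY_VERSION

    @property
    def n_captured(self) -> int:
        return sum(ci is not None for ci in self.capture_index)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# preset registry: numeric values are fixed design choices expressing the
# phenotypes (shallow/stable, discrete/metastable, broad/flickering) and the
# streptavidin titration trend; see docs/methods.md for the rationale.
_PRESETS: dict[str, SimPreset] = {}


def _register(p: SimPreset) -> None:
    _PRESETS[p.name] = p


# APTES amine coating: shallow (~10%) stable single-level blockade.
_register(SimPreset(
    name="amine", depth_levels=[0.10], level_weights=[1.0], switch_rate=0.0,
    capture_rate=20.0, event_stability="persistent",
    gated_noise=GatedNoise(white_mult=1.4, flicker_amp=8e-4, flicker_alpha=1.0)))
# PEG4-biotin coating: deeper blockade with a few discrete metastable
# docking configurations, slow (~Hz) transitions between them.
_register(SimPreset(
    name="biotin", depth_levels=[0.30, 0.45, 0.60],
    level_weights=[0.10, 0.80, 0.10], switch_rate=70.0, capture_rate=20.0,
    event_stability="persistent",
    gated_noise=GatedNoise(white_mult=1.6, flicker_amp=1e-3, flicker_alpha=1.2)))
# Tween-20, discrete variant: four resolvable levels (used for sub-level
# count recovery).
_register(SimPreset(
    name="tween", depth_levels=[0.20, 0.35, 0.45, 0.60], level_weights=[0.25] * 4,
    switch_rate=7.0, capture_rate=20.0, event_stability="persistent",
    gated_noise=GatedNoise(white_mult=1.8, flicker_amp=1e-3, flicker_alpha=1.3)))
# Tween-20, smeared variant: broad continuous blockade distribution with a
# slow large-amplitude configuration wander and the strongest interaction
# noise (used for phenotype/fingerprint contrasts).
_register(SimPreset(
    name="tween_smeared", depth_levels=[0.40], level_weights=[1.0],
    switch_rate=0.0, capture_rate=20.0, event_stability="persistent",
    wander=OUWander(relaxation_hz=0.3, sd=0.15),
    wander_fast=OUWander(relaxation_hz=300.0, sd=0.029),
    gated_noise=GatedNoise(white_mult=2.0, flicker_amp=6e-2, flicker_alpha=1.5)))
# Tween-coated biotinylated particles: biotin-like levels with tween-like
# wander and noise.
_register(SimPreset(
    name="biotin_tween", depth_levels=[0.25, 0.45, 0.65], level_weights=[1 / 3] * 3,
    switch_rate=6.0, capture_rate=20.0, event_stability="persistent",
    level_lowpass_hz=100.0, wander=OUWander(relaxation_hz=2.0, sd=0.05),
    gated_noise=GatedNoise(white_mult=1.8, flicker_amp=2e-2, flicker_alpha=1.4)))
# Streptavidin titration stages: progressively rarer and less stable
# trapping with more configurational states.
_register(SimPreset(
    name="sa_1to1", depth_levels=[0.20, 0.35, 0.50, 0.65], level_weights=[0.25] * 4,
    switch_rate=10.0, capture_rate=6.0, event_stability="intermittent",
    level_lowpass_hz=100.0, wander=OUWander(relaxation_hz=2.0, sd=0.04),
    gated_dwell_s=0.8,
    gated_noise=GatedNoise(white_mult=2.0, flicker_amp=2.5e-2, flicker_alpha=1.5)))
_register(SimPreset(
    name="sa_1to10", depth_levels=[0.15, 0.30, 0.45, 0.60], level_weights=[0.25] * 4,
    switch_rate=14.0, capture_rate=1.0, event_stability="flickering",
    level_lowpass_hz=100.0, wander=OUWander(relaxation_hz=2.0, sd=0.05),
    gated_dwell_s=0.05, released_dwell_s=0.05,
    gated_noise=GatedNoise(white_mult=2.2, flicker_amp=3e-2, flicker_alpha=1.6)))
_register(SimPreset(
    name="sa_excess", depth_levels=[0.15], level_weights=[1.0], switch_rate=0.0,
    capture_rate=0.0, event_stability="none"))


def get_preset(name: str) -> SimPreset:
    """Return a deep copy of a registry preset; unknown names list the registry."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; known presets: {sorted(_PRESETS)}")
    return copy.deepcopy(_PRESETS[name])


def preset_names() -> list[str]:
    return sorted(_PRESETS)


# ---------------------------------------------------------------------------


def synth_colored_noise(n: int, fs: float, spec: NoiseSpec,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None) -> np.ndarray:
    """Zero-mean noise with ensemble one-sided PSD 2*white_sd^2/fs + A/f^alpha.

    The white part is drawn in the time domain (exact variance in
    expectation); the flicker part is synthesized by FFT spectral shaping of
    seeded Gaussian noise, exact in expectation on the Fourier grid.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.zeros(n)
    if spec.white_sd > 0:
        out += rng.standard_normal(n) * spec.white_sd
    if spec.flicker_amp > 0:
        f = np.fft.rfftfreq(n, 1.0 / fs)
        s = np.zeros_like(f)
        s[1:] = spec.flicker_amp / f[1:] ** spec.flicker_alpha
        nf = f.size
        g = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
        z = np.sqrt(n * fs * s / 2.0) * g / np.sqrt(2.0)
        z[0] = 0.0
        if n % 2 == 0:
            z[-1] = np.sqrt(n * fs * s[-1]) * rng.standard_normal()
        out += np.fft.irfft(z, n)
    return out


def _telegraph_depths(n: int, fs: float, preset: SimPreset,
                      rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Per-sample depth following the preset's telegraph chain; returns pieces."""
    levels = np.asarray(preset.depth_levels, dtype=float)
    weights = np.asarray(preset.level_weights, dtype=float)
    depths = np.empty(n)
    pieces = []
    i = 0
    while i < n:
        lv = float(rng.choice(levels, p=weights))
        if preset.switch_rate > 0 and levels.size > 1:
            dwell = max(1, int(round(rng.exponential(1.0 / preset.switch_rate) * fs)))
        else:
            dwell = n - i
        j = min(n, i + dwell)
        depths[i:j] = lv
        pieces.append((i, j, lv))
        i = j
    if preset.level_lowpass_hz is not None and n > 100:
        sos = _signal.butter(2, preset.level_lowpass_hz, btype="low", fs=fs,
                             output="sos")
        depths = _signal.sosfiltfilt(sos, depths)
    for wander in (preset.wander, preset.wander_fast):
        if wander is None:
            continue
        theta = 2 * np.pi * wander.relaxation_hz
        a = np.exp(-theta / fs)
        innov_sd = wander.sd * np.sqrt(1 - a * a)
        w = rng.standard_normal(n) * innov_sd
        # exact OU discretization x[k] = a x[k-1] + w[k], started stationary
        w[0] += a * rng.standard_normal() * wander.sd
        depths = depths + _signal.lfilter([1.0], [1.0, -a], w)
    return np.clip(depths, 0.05, 0.95), pieces


def _gated_intervals(start: int, end: int, fs: float, preset: SimPreset,
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    """Gated sample intervals within [start, end) given the stability class."""
    if preset.event_stability == "persistent":
        return [(start, end)]
    spans = []
    i = start
    gated = True
    while i < end:
        mean = preset.gated_dwell_s if gated else preset.released_dwell_s
        dwell = max(1, int(round(rng.exponential(mean) * fs)))
        j = min(end, i + dwell)
        if gated:
            spans.append((i, j))
        i = j
        gated = not gated
    return spans


def simulate_recording(protocol: VoltageProtocol, pore: PoreSpec,
                       preset: SimPreset, noise: Optional[NoiseSpec] = None,
                       seed: int = 0, fs: float = 200_000.0,
                       capture_delay_s: Optional[float] = None,
                       hardware_filter_hz: float = 100_000.0,
                       ) -> tuple[Trace, GroundTruth]:
    """Render a full trap-release recording plus its ground truth.

    Per cycle: the baseline sits at G*V/1000 nA for each phase polarity; a
    capture occurs in the trap phase after ``capture_delay_s`` plus an
    exponential waiting time of rate ``preset.capture_rate``; the gated
    current is I0*(1 - depth(t)); gated segments get the preset's own noise.
    A digital stand-in for the acquisition anti-alias stage is applied only
    when ``hardware_filter_hz`` < 0.45*fs (above that it would sit at the
    Nyquist limit and is recorded in metadata only).
    """
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(seed)
    delay = preset.capture_delay_s if capture_delay_s is None else capture_delay_s
    g = pore_conductance(pore)
    n = int(round(protocol.total_duration * fs))
    x = np.empty(n)

    # open-pore noise over the whole record (gated intervals overwritten below)
    x[:] = synth_colored_noise(n, fs, noise, rng) if (
        noise.white_sd > 0 or noise.flicker_amp > 0) else 0.0

    trap_idx = protocol.trap_phase_index
    cycle_spans, capture_index, gated_spans_all, pieces_all = [], [], [], []
    gn = preset.gated_noise
    gated_noise_spec = NoiseSpec(white_sd=noise.white_sd * gn.white_mult,
                                 flicker_alpha=gn.flicker_alpha,
                                 flicker_amp=gn.flicker_amp)

    for c in range(protocol.n_cycles):
        spans = protocol.phase_spans(fs, cycle=c)
        c0, c1 = spans[0][0], spans[-1][1]
        cycle_spans.append((min(c0, n), min(c1, n)))
        cap_idx = None
        cycle_gated: list[tuple[int, int]] = []
        cycle_pieces: list[tuple[int, int, float]] = []
        for p, ((lv, _du), (a, b)) in enumerate(zip(protocol.phases, spans)):
            a, b = min(a, n), min(b, n)
            if a >= b:
                continue
            i_base = g * lv / 1000.0
            x[a:b] += i_base
            if (p == trap_idx and preset.capture_rate > 0
                    and preset.event_stability != "none"):
                wait = delay + rng.exponential(1.0 / preset.capture_rate)
                start = a + int(round(wait * fs))
                if start < b - 1:
                    cap_idx = start
                    for s0, s1 in _gated_intervals(start, b, fs, preset, rng):
                        m = s1 - s0
                        if m < 2:
                            continue
                        depths, pieces = _telegraph_depths(m, fs, preset, rng)
                        # replace baseline+open-noise with gated level + gated noise
                        gseg = i_base * (1.0 - depths)
                        if gated_noise_spec.white_sd > 0 or gated_noise_spec.flicker_amp > 0:
                            gseg = gseg + synth_colored_noise(m, fs, gated_noise_spec, rng)
                        x[s0:s1] = gseg
                        cycle_gated.append((s0, s1))
                        cycle_pieces.extend((s0 + i, s0 + j, d) for i, j, d in pieces)
        capture_index.append(cap_idx)
        gated_spans_all.append(cycle_gated)
        pieces_all.append(cycle_pieces)

    if hardware_filter_hz < 0.45 * fs:
        sos = bessel_sos(hardware_filter_hz, fs)
        x = _signal.sosfiltfilt(sos, x)

    meta = TraceMeta(device_id=f"sim-{preset.name}-{seed}",
                     conductivity=pore.sigma, pore_length=pore.l,
                     hardware_filter_hz=min(hardware_filter_hz, fs / 2))
    trace = Trace(x, fs, protocol, meta)
    truth = GroundTruth(
        fs=fs, seed=seed, preset_name=preset.name, cycle_spans=cycle_spans,
        capture_index=capture_index, gated_spans=gated_spans_all,
        level_pieces=pieces_all, preset_params=dataclasses.asdict(preset))
    return trace, truth


def default_protocol(n_cycles: int = 5, trap_s: float = 6.0,
                     release_s: float = 1.0, bias_mv: float = 300.0) -> VoltageProtocol:
    """The standard +bias trap / -bias release cycling protocol."""
    return VoltageProtocol(phases=[(bias_mv, trap_s), (-bias_mv, release_s)],
                           n_cycles=n_cycles)
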