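"""Frequency-domain signatures: Welch PSD, 1/f fit, band powers and NIFs.

The low-frequency flicker component of an ionic-current spectrum is modelled
as S(f) = A / f^alpha + C over 1-100 Hz, where A lumps the Hooge-type
magnitude (Hooge constant x I^2 / carrier number; the factors are not
separately identifiable from one spectrum) and C is the white floor. Band
powers are trapezoidal integrals of the one-sided PSD over half-open bands,
and the noise-increase factor (NIF) of a band is the ratio of gated- to
open-segment band power.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal


class SpectralUnavailableError(ValueError):
    """Segment too short for the requested spectral estimate."""


@dataclass
class Band:
    """Half-open frequency band [f1, f2), Hz."""

    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError(f"need 0 < f1 < f2, got [{self.f1}, {self.f2})")


#: The three fingerprint bands: low (1/f-dominated), mid, high.
DEFAULT_BANDS: tuple[Band, Band, Band] = (Band(1.0, 100.0), Band(100.0, 1000.0),
                                          Band(1000.0, 10_000.0))


@dataclass
class PSDEstimate:
    """One-sided Welch PSD (nA^2/Hz) of a current segment."""

    freqs: np.ndarray
    s: np.ndarray
    fs: float
    window_len: int
    overlap: float
    n_segments: int
    sample_variance: float = 0.0

    def total_power(self) -> float:
        """Trapezoidal integral of the PSD over (0, fs/2]."""
        return float(np.trapezoid(self.s[1:], self.freqs[1:]))

    def parseval_ratio(self) -> float:
        """total_power / sample variance; ~1 when Parseval holds."""
        if self.sample_variance <= 0:
            return np.nan
        return self.total_power() / self.sample_variance


@dataclass
class OneOverFFit:
    """Fitted S(f) = A f^-alpha + C over ``band``.

    ``fit_ok`` is False when the 1/f term carries <10% of the in-band power
    (the exponent is then not meaningful).
    """

    amplitude_a: float
    alpha: float
    c: float
    fit_ok: bool
    band: Band = field(default_factory=lambda: Band(1.0, 100.0))

    def model(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return self.amplitude_a * f ** (-self.alpha) + self.c


@dataclass
class NIFSet:
    """Noise-increase factors for the low/mid/high bands."""

    nif_low: float
    nif_mid: float
    nif_high: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.nif_low, self.nif_mid, self.nif_high)


def welch_psd(segment: np.ndarray, fs: float, window_len: Optional[int] = None,
              overlap: float = 0.5) -> PSDEstimate:
    """Welch PSD with Hann windows and mean averaging.

    ``window_len`` defaults to min(len(segment), round(fs)) — 1-s windows,
    giving 1 Hz resolution as required by the 1-100 Hz band.
    """
    x = np.asarray(segment, dtype=np.float64)
    if window_len is None:
        window_len = int(min(x.size, round(fs)))
    if x.size < window_len or window_len < 8:
        raise SpectralUnavailableError(
            f"segment of {x.size} samples is shorter than one window "
            f"({window_len}); flag event spectral-unavailable"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    noverlap = int(window_len * overlap)
    freqs, s = signal.welch(x, fs=fs, window="hann", nperseg=window_len,
                            noverlap=noverlap, detrend="constant",
                            average="mean")
    hop = window_len - noverlap
    n_segments = 1 + (x.size - window_len) // hop
    return PSDEstimate(freqs, s, fs, window_len, overlap, n_segments,
                       sample_variance=float(x.var()))


def band_power(psd: PSDEstimate, band: Band) -> float:
    """Trapezoidal integral of the PSD over [f1, f2), nA^2.

    The PSD is linearly interpolated at the band edges so that adjacent
    bands tile exactly: power(a,b) + power(b,c) == power(a,c).
    """
    f, s = psd.freqs, psd.s
    if band.f2 > f[-1] + 1e-9:
        raise ValueError(
            f"band [{band.f1}, {band.f2}) exceeds the PSD range (max {f[-1]} Hz)"
        )
    inside = (f > band.f1) & (f < band.f2)
    grid = np.concatenate(([band.f1], f[inside], [band.f2]))
    vals = np.interp(grid, f, s)
    return float(np.trapezoid(vals, grid))


def fit_one_over_f(psd: PSDEstimate, band: Optional[Band] = None) -> OneOverFFit:
    """Robust log-space fit of A f^-alpha + C over the (default 1-100 Hz) band.

    Least squares on log10 PSD with a soft-L1 loss; bounds alpha in [0, 3],
    A >= 0, C >= 0. Initialization: alpha = 1, C = median in-band PSD, A from
    the lowest-frequency intercept.
    """
    band = band or Band(1.0, 100.0)
    f, s = psd.freqs, psd.s
    mask = (f >= band.f1) & (f <= band.f2) & (f > 0) & (s > 0)
    if mask.sum() < 10:
        raise SpectralUnavailableError(
            f"only {int(mask.sum())} PSD bins in [{band.f1}, {band.f2}) Hz; "
            "need >= 10 for the 1/f fit"
        )
    fb, sb = f[mask], s[mask]
    log_s = np.log10(sb)
    c0 = float(np.median(sb))
    a0 = max((sb[0] - c0) * fb[0], 1e-3 * c0 * fb[0])

    def resid(p):
        a, alpha, c = p
        return np.log10(a * fb ** (-alpha) + c + 1e-300) - log_s

    res = optimize.least_squares(
        resid, x0=[a0, 1.0, c0], bounds=([0.0, 0.0, 0.0], [np.inf, 3.0, np.inf]),
        loss="soft_l1", f_scale=0.3, max_nfev=2000)
    a, alpha, c = res.x
    # fraction of in-band power carried by the 1/f term
    flicker = np.trapezoid(a * fb ** (-alpha), fb)
    total = np.trapezoid(a * fb ** (-alpha) + c, fb)
    fit_ok = bool(total > 0 and flicker / total >= 0.10)
    return OneOverFFit(float(a), float(alpha), float(c), fit_ok, band)


def compute_nif(gated_psd: PSDEstimate, open_psd: PSDEstimate,
                bands: Sequence[Band] = DEFAULT_BANDS) -> NIFSet:
    """Band-power ratios gated/open in fixed low/mid/high order."""
    if len(bands) != 3:
        raise ValueError("compute_nif expects exactly three bands (low, mid, high)")
    ratios = []
    for band in bands:
        p_open = band_power(open_psd, band)
        if p_open <= 0:
            raise ValueError(
                f"open-segment power is zero in [{band.f1}, {band.f2}) Hz; "
                "degenerate open segment"
            )
        ratios.append(band_power(gated_psd, band) / p_open)
    return NIFSet(*ratios)
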