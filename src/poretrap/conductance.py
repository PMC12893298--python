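"""Nanopore conductance model: channel plus access resistance.

For a cylindrical pore of diameter d (nm) and effective length l (nm) in an
electrolyte of conductivity sigma (S/m),

    G = sigma * [ 4 l / (pi d^2) + 1 / d ]^(-1)

with G in nS (1 S/m == 1 nS/nm makes the unit bookkeeping exact). The second
term is the access resistance of the two pore mouths. Inverting the model for
d at measured G is a quadratic with a single positive root, used for pore
sizing from the current-voltage characteristic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: Conductivity of 1 M KCl at 25 degC, S/m (overridable wherever used).
DEFAULT_CONDUCTIVITY_S_PER_M = 11.2


@dataclass
class PoreSpec:
    """Pore geometry and measurement condition.

    d, l in nm; sigma in S/m; v is the applied bias in mV.
    """

    d: float
    l: float = 8.7
    sigma: float = DEFAULT_CONDUCTIVITY_S_PER_M
    v: float = 300.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("pore diameter must be > 0")
        if self.l < 0:
            raise ValueError("pore length must be >= 0")
        if self.sigma <= 0:
            raise ValueError("conductivity must be > 0")


def pore_conductance(spec: PoreSpec) -> float:
    """Open-pore conductance in nS."""
    d, l = spec.d, spec.l
    return spec.sigma / (4.0 * l / (np.pi * d * d) + 1.0 / d)


def open_pore_current(spec: PoreSpec) -> float:
    """Predicted open-pore current in nA at bias ``spec.v`` (mV)."""
    return pore_conductance(spec) * spec.v / 1000.0


def estimate_diameter(g: float, l: float = 8.7,
                      sigma: float = DEFAULT_CONDUCTIVITY_S_PER_M) -> float:
    """Pore diameter (nm) from measured conductance g (nS).

    Solves sigma d^2 - g d - 4 g l / pi = 0 for its positive root; the round
    trip with :func:`pore_conductance` is the identity.
    """
    if g <= 0:
        raise ValueError("conductance must be > 0")
    if l < 0 or sigma <= 0:
        raise ValueError("non-physical pore length or conductivity")
    disc = g * g + 16.0 * sigma * g * l / np.pi
    return (g + np.sqrt(disc)) / (2.0 * sigma)


def diameter_from_iv(current_na: float, voltage_mv: float, l: float = 8.7,
                     sigma: float = DEFAULT_CONDUCTIVITY_S_PER_M) -> float:
    """Pore diameter (nm) from an open-pore current/voltage pair."""
    if voltage_mv == 0:
        raise ValueError("voltage must be nonzero")
    g = abs(current_na) / abs(voltage_mv) * 1000.0
    return estimate_diameter(g, l, sigma)
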