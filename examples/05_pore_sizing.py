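"""Pore sizing from an open-pore current-voltage pair.

The conductance model G = sigma*[4L/(pi d^2) + 1/d]^-1 is inverted for the
diameter; 13.7 nA at 300 mV with L = 8.7 nm in 1 M KCl gives ~9 nm.
"""
from poretrap import PoreSpec, diameter_from_iv, pore_conductance

d = diameter_from_iv(13.7, 300.0, l=8.7, sigma=11.2)
g = pore_conductance(PoreSpec(d=d, l=8.7, sigma=11.2))
print(f"G = {13.7/0.3:.1f} nS  ->  d = {d:.2f} nm (round-trip G = {g:.1f} nS)")
# the residual vs the 8.7 nm TEM reference is set by the assumed conductivity
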