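import numpy as np
import pytest

from poretrap import (PoreSpec, Trace, TraceMeta, VoltageProtocol,
                      open_pore_current)
from poretrap.pipeline import pore_for_current


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def reference_pore():
    """Pore whose open current at +300 mV is exactly 13.7 nA."""
    return pore_for_current(13.7, 300.0, l=8.7, sigma=11.2)


@pytest.fixture
def short_protocol():
    """2-s trap / 0.5-s release cycling."""
    return VoltageProtocol(phases=[(300.0, 2.0), (-300.0, 0.5)], n_cycles=5)


def make_step_cycle(fs: float = 50_000.0, baseline: float = 13.7,
                    gated_level: float = 3.0, open_s: float = 1.0,
                    gated_s: float = 1.0, tail_s: float = 0.0,
                    noise_sd: float = 0.05, seed: int = 0) -> Trace:
    """Baseline -> step to ``gated_level`` -> optional tail back at baseline."""
    rng = np.random.default_rng(seed)
    n_open = int(open_s * fs)
    n_gated = int(gated_s * fs)
    n_tail = int(tail_s * fs)
    x = np.concatenate([
        np.full(n_open, baseline),
        np.full(n_gated, gated_level),
        np.full(n_tail, baseline),
    ])
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, x.size)
    v = np.full(x.size, 300.0)
    return Trace(x, fs, v, TraceMeta(device_id="synthetic-step"))
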