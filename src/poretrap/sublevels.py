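"""Gaussian-mixture sub-level statistics of segment current histograms.

The number of discrete conductance sub-levels inside a gated segment is
estimated by fitting 1-D Gaussian mixtures with k = 1..k_max components to
the relative-current samples and selecting k by BIC, after pruning
candidates with vanishing component weights or unresolvably close means.
R^2 of the mixture density against a Freedman-Diaconis histogram is recorded
as an advisory goodness-of-fit flag.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

K_MAX_DEFAULT = 6
#: Components lighter than this weight mark a candidate as overfitted.
MIN_COMPONENT_WEIGHT = 0.02
#: Adjacent means closer than this multiple of the larger sigma are unresolved.
MIN_SEPARATION_SIGMA = 1.5
#: Segments longer than this are uniformly decimated before fitting.
MAX_FIT_SAMPLES = 50_000
N_RESTARTS = 5
MIN_SEGMENT_SAMPLES = 500
#: Advisory histogram-fit quality floor; below it the event is "poor-fit".
R2_ADVISORY_FLOOR = 0.9


@dataclass
class SubLevelModel:
    """One fitted mixture: k components with weights/means/sigmas sorted by mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    bic: float
    r2: float
    n_fit: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be > 0")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = self.weights / (self.sigmas * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - self.means) / self.sigmas) ** 2)
        return comp.sum(axis=-1)


def _fit_seed(seed: Optional[int], k: int, n: int) -> int:
    """Deterministic restart seed derived from event identity and k."""
    key = f"{seed}:{k}:{n}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _histogram_r2(x: np.ndarray, model: SubLevelModel) -> float:
    """R^2 of the mixture density vs a Freedman-Diaconis density histogram."""
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        bins = 50
    else:
        width = 2 * iqr / x.size ** (1 / 3)
        bins = max(10, min(500, int(np.ceil((x.max() - x.min()) / width))))
    dens, edges = np.histogram(x, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pred = model.pdf(centers)
    ss_res = float(np.sum((dens - pred) ** 2))
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_gmm_candidates(segment: np.ndarray, k_max: int = K_MAX_DEFAULT,
                       seed: Optional[int] = None) -> list[SubLevelModel]:
    """Fit mixtures with k = 1..k_max to relative-current samples.

    Segments longer than ``MAX_FIT_SAMPLES`` are uniformly decimated first.
    Each k uses ``N_RESTARTS`` k-means-initialized EM restarts with a seed
    derived deterministically from ``seed`` (event identity), keeping the
    best likelihood.
    """
    x = np.asarray(segment, dtype=np.float64).ravel()
    if x.size < MIN_SEGMENT_SAMPLES:
        raise ValueError(
            f"segment of {x.size} samples is below the {MIN_SEGMENT_SAMPLES}-"
            "sample floor; mark the event too_short"
        )
    if x.size > MAX_FIT_SAMPLES:
        stride = int(np.ceil(x.size / MAX_FIT_SAMPLES))
        x = x[::stride]
    X = x[:, None]
    out = []
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=N_RESTARTS,
            random_state=_fit_seed(seed, k, x.size), reg_covar=1e-10,
            max_iter=300)
        gm.fit(X)
        order = np.argsort(gm.means_.ravel())
        weights = gm.weights_.ravel()[order]
        weights = weights / weights.sum()
        model = SubLevelModel(
            k=k,
            weights=weights,
            means=gm.means_.ravel()[order],
            sigmas=np.sqrt(gm.covariances_.ravel()[order]),
            bic=float(gm.bic(X)),
            r2=np.nan,
            n_fit=x.size,
        )
        model.r2 = _histogram_r2(x, model)
        out.append(model)
    return out


def _is_resolved(model: SubLevelModel) -> bool:
    if np.any(model.weights < MIN_COMPONENT_WEIGHT):
        return False
    for i in range(model.k - 1):
        sep = model.means[i + 1] - model.means[i]
        if sep < MIN_SEPARATION_SIGMA * max(model.sigmas[i], model.sigmas[i + 1]):
            return False
    return True


def select_sublevel_model(candidates: Sequence[SubLevelModel]) -> SubLevelModel:
    """Minimum-BIC candidate among resolvable mixtures.

    Candidates with any component weight below 2% or adjacent means closer
    than 1.5x the larger sigma are pruned as overfitted. If everything is
    pruned the k = 1 candidate is returned with a warning.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    survivors = [m for m in candidates if _is_resolved(m)]
    if not survivors:
        logger.warning("all mixture candidates pruned; falling back to k=1")
        k1 = [m for m in candidates if m.k == 1]
        return k1[0] if k1 else min(candidates, key=lambda m: m.k)
    return min(survivors, key=lambda m: m.bic)


def sublevel_count(segment: np.ndarray, k_max: int = K_MAX_DEFAULT,
                   seed: Optional[int] = None) -> SubLevelModel:
    """Convenience: fit candidates and select in one call."""
    return select_sublevel_model(fit_gmm_candidates(segment, k_max, seed))


def sublevel_table(models: Sequence[SubLevelModel]) -> "np.ndarray":
    import pandas as pd

    rows = []
    for i, m in enumerate(models):
        rows.append({
            "event": i, "k": m.k, "bic": m.bic, "r2": m.r2, "n_fit": m.n_fit,
            "means": ";".join(f"{v:.6g}" for v in m.means),
            "weights": ";".join(f"{v:.6g}" for v in m.weights),
            "sigmas": ";".join(f"{v:.6g}" for v in m.sigmas),
        })
    return pd.DataFrame(rows)
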