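"""Discrete worm-like-chain sampling with exact tangent-correlation calibration.

Chains are built as equal-length segment walks whose per-step tangent
correlation is ``<t_i . t_{i+1}> = exp(-step/P)``, so the tangent correlation
decays as ``exp(-s/P)`` along the contour and the ensemble obeys the
three-dimensional end-to-end relation ``<R^2> = 2PL(1 - (P/L)(1 - e^(-L/P)))``
(surface parameter 1) up to the discretization correction.

In 2D the per-step turning angle is Gaussian; since ``<cos theta> =
exp(-sigma^2/2)`` exactly for a Gaussian angle, the calibration
``sigma^2 = 2 * step / P`` is closed-form (``BEND_VARIANCE_FACTOR``).  In 3D
the step direction is drawn from a von Mises-Fisher distribution about the
previous tangent with concentration solved so the mean cosine matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "WLCParams",
    "FilamentGroundTruth",
    "sample_wlc_chain",
    "sample_wlc_ensemble",
    "discrete_wlc_mean_square_r",
    "BEND_VARIANCE_FACTOR",
]

#: 2D turning-angle variance is BEND_VARIANCE_FACTOR * step / P (exact
#: Gaussian calibration of <cos theta> = exp(-step/P)).
BEND_VARIANCE_FACTOR = 2.0


@dataclass(frozen=True)
class LognormalLength:
    """Lognormal contour-length model parameterized by target mean/s.d.
    (moment matching), truncated from below."""

    mean_nm: float
    sd_nm: float
    truncation_min_nm: float = 0.0

    def __post_init__(self):
        if self.mean_nm <= 0 or self.sd_nm <= 0:
            raise ValueError("lognormal mean and sd must be positive")
        if self.truncation_min_nm < 0:
            raise ValueError("truncation_min_nm must be >= 0")

    @property
    def mu_sigma(self) -> tuple[float, float]:
        var = self.sd_nm**2
        sigma2 = np.log1p(var / self.mean_nm**2)
        mu = np.log(self.mean_nm) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        mu, sigma = self.mu_sigma
        n = 1 if size is None else size
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.lognormal(mu, sigma, size=n - filled)
            ok = draw >= self.truncation_min_nm
            k = int(ok.sum())
            out[filled : filled + k] = draw[ok]
            filled += k
        return out[0] if size is None else out


@dataclass(frozen=True)
class WLCParams:
    """Parameters of the discrete WLC sampler.

    ``persistence_length_nm`` may be ``inf`` to switch off bending (straight
    chains).  ``contour_length_nm`` fixes the length; alternatively
    ``length_model`` draws it per chain.
    """

    persistence_length_nm: float
    step_nm: float = 5.0
    contour_length_nm: float | None = None
    length_model: LognormalLength | None = None
    dimension: Literal[2, 3] = 2

    def __post_init__(self):
        if self.persistence_length_nm <= 0:
            raise ValueError("persistence length must be positive")
        if self.step_nm <= 0:
            raise ValueError("step must be positive")
        if (self.contour_length_nm is None) == (self.length_model is None):
            raise ValueError("give exactly one of contour_length_nm / length_model")
        if self.contour_length_nm is not None and self.contour_length_nm < self.step_nm:
            raise ValueError(
                f"contour length {self.contour_length_nm} nm shorter than one "
                f"step ({self.step_nm} nm)"
            )
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")


@dataclass(frozen=True)
class FilamentGroundTruth:
    """A sampled chain with its generating parameters."""

    id: int
    ordered_points_nm: np.ndarray = field(repr=False)
    P_true_nm: float
    L_true_nm: float

    @property
    def end_to_end_nm(self) -> float:
        return float(np.linalg.norm(self.ordered_points_nm[-1] - self.ordered_points_nm[0]))

    @property
    def n_points(self) -> int:
        return self.ordered_points_nm.shape[0]


def _n_segments(L: float, step: float) -> int:
    # L = n * step up to float fuzz; otherwise floor (sampled lognormal L)
    n = int(round(L / step))
    if abs(n * step - L) > 1e-6 * max(L, 1.0):
        n = int(L / step)
    if n < 1:
        raise ValueError(f"contour length {L} nm shorter than one step ({step} nm)")
    return n


def _vmf_kappa(mean_cos: float) -> float:
    """Concentration of a von Mises-Fisher distribution on S^2 with the given
    mean resultant cosine (coth k - 1/k = mean_cos)."""
    if mean_cos >= 1.0 - 1e-12:
        return np.inf

    def f(k):
        return 1.0 / np.tanh(k) - 1.0 / k - mean_cos

    lo, hi = 1e-8, 4.0 / max(1.0 - mean_cos, 1e-12)
    while f(hi) < 0:
        hi *= 2
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)


def _sample_vmf_cos(kappa: float, rng: np.random.Generator, size) -> np.ndarray:
    """Cosine of the polar angle of vMF(kappa) samples (inverse-CDF form)."""
    u = rng.random(size)
    if np.isinf(kappa):
        return np.ones(size)
    # w = 1 + log(u + (1-u) e^{-2k}) / k, numerically stable for large kappa
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def sample_wlc_ensemble(
    params: WLCParams, n_chains: int, seed: int
) -> list[FilamentGroundTruth]:
    """Sample ``n_chains`` independent chains (vectorized across chains).

    Deterministic for a given (params, seed).  Chains start at the origin with
    initial tangent along +x.
    """
    rng = np.random.default_rng(seed)
    step = params.step_nm
    if params.contour_length_nm is not None:
        lengths = np.full(n_chains, params.contour_length_nm)
    else:
        lengths = params.length_model.sample(rng, size=n_chains)
    nsegs = np.array([_n_segments(L, step) for L in lengths])
    nmax = int(nsegs.max())

    if params.dimension == 2:
        pts = _walk_2d(params, rng, n_chains, nmax, step)
    else:
        pts = _walk_3d(params, rng, n_chains, nmax, step)

    out = []
    for i in range(n_chains):
        n = nsegs[i]
        out.append(
            FilamentGroundTruth(
                id=i,
                ordered_points_nm=pts[i, : n + 1].copy(),
                P_true_nm=params.persistence_length_nm,
                L_true_nm=n * step,
            )
        )
    return out


def _walk_2d(params, rng, n_chains, nmax, step):
    P = params.persistence_length_nm
    sigma = 0.0 if np.isinf(P) else np.sqrt(BEND_VARIANCE_FACTOR * step / P)
    turns = rng.normal(0.0, sigma, size=(n_chains, nmax)) if sigma > 0 else np.zeros((n_chains, nmax))
    turns[:, 0] = 0.0  # initial tangent along +x
    headings = np.cumsum(turns, axis=1)
    steps = np.stack([np.cos(headings), np.sin(headings)], axis=-1) * step
    pts = np.zeros((n_chains, nmax + 1, 2))
    np.cumsum(steps, axis=1, out=pts[:, 1:])
    return pts


def _walk_3d(params, rng, n_chains, nmax, step):
    P = params.persistence_length_nm
    mean_cos = 0.0 if np.isinf(P) else float(np.exp(-step / P))
    kappa = np.inf if np.isinf(P) else _vmf_kappa(mean_cos)
    tang = np.zeros((n_chains, 3))
    tang[:, 0] = 1.0
    pts = np.zeros((n_chains, nmax + 1, 3))
    for k in range(nmax):
        if k > 0 and not np.isinf(kappa):
            w = _sample_vmf_cos(kappa, rng, n_chains)
            phi = rng.uniform(0.0, 2.0 * np.pi, n_chains)
            # orthonormal frame perpendicular to the current tangent
            ref = np.where(
                (np.abs(tang[:, 0]) < 0.9)[:, None],
                np.array([1.0, 0.0, 0.0]),
                np.array([0.0, 1.0, 0.0]),
            )
            e1 = np.cross(tang, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(tang, e1)
            sin_t = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
            tang = (
                w[:, None] * tang
                + (sin_t * np.cos(phi))[:, None] * e1
                + (sin_t * np.sin(phi))[:, None] * e2
            )
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        pts[:, k + 1] = pts[:, k] + step * tang
    return pts


def sample_wlc_chain(params: WLCParams, seed: int) -> FilamentGroundTruth:
    """Sample one chain (see :func:`sample_wlc_ensemble`)."""
    return sample_wlc_ensemble(params, 1, seed)[0]


def discrete_wlc_mean_square_r(n_segments: int, step: float, P: float) -> float:
    """Exact <R^2> of the discrete chain with per-step correlation
    a = exp(-step/P):  N d^2 [ (1+a)/(1-a) - 2a(1-a^N) / (N (1-a)^2) ]."""
    if np.isinf(P):
        return (n_segments * step) ** 2
    a = np.exp(-step / P)
    N = n_segments
    return step**2 * (
        N * (1 + a) / (1 - a) - 2 * a * (1 - a**N) / (1 - a) ** 2
    )
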