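"""Worm-like-chain persistence-length inference.

Filament stiffness is summarized by the persistence length ``P`` of the
worm-like chain (WLC) model, inferred from the relation between the mean
squared end-to-end distance and the contour length,

    <R^2> = 2 s P L (1 - (s P / L) (1 - exp(-L / (s P)))),

where ``L`` is the contour length and ``s`` is a surface parameter fixed at 1
for surface-equilibrated filaments.  A cloud of (L, R^2) records — one per
traced filament, or one per layer pair of a simulated nanotube frame — is fit
by nonlinear least squares for ``P``.

The module follows a model/results split: :class:`WormLikeChainModel` holds
the records, ``fit()`` returns a :class:`WLCResults` carrying the estimate,
its standard error, residual diagnostics and the outlier mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


__all__ = [
    "FilamentRecord",
    "WormLikeChainModel",
    "WLCResults",
    "wlc_mean_square_r",
    "filter_records",
    "fit_wlc",
    "mask_and_refit",
    "per_frame_persistence",
    "select_final_fraction",
    "flexibility_ratio",
]


MIN_LENGTH_NM = 200.0  # detections shorter than this are unreliable at AFM resolution


def wlc_mean_square_r(L, P, s: float = 1.0):
    """Expected squared end-to-end distance of a WLC.

    Evaluates ``2 s P L (1 - (sP/L)(1 - exp(-L/sP)))`` stably via ``expm1``;
    equals ``L**2`` in the stiff limit ``L << sP`` and ``2 s P L`` in the
    flexible limit ``L >> sP``.
    """
    L = np.asarray(L, dtype=float)
    sp = s * P
    return 2.0 * sp * L + 2.0 * sp * sp * np.expm1(-L / sp)


@dataclass(frozen=True)
class FilamentRecord:
    """A single (contour length, squared end-to-end distance) observation."""

    L_nm: float
    R2_nm2: float
    source: str = "afm"

    def __post_init__(self):
        if self.L_nm <= 0:
            raise ValueError(f"contour length must be positive, got {self.L_nm}")
        if not (0.0 <= self.R2_nm2 <= self.L_nm**2 * (1 + 1e-9)):
            raise ValueError(
                f"R2={self.R2_nm2} outside [0, L^2]={self.L_nm ** 2} (L={self.L_nm})"
            )


class WLCFitError(RuntimeError):
    """Raised when the records cannot support a WLC fit."""


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["L_nm"].to_numpy(float), records["R2_nm2"].to_numpy(float)
    recs = list(records)
    if recs and isinstance(recs[0], FilamentRecord):
        return (
            np.array([r.L_nm for r in recs]),
            np.array([r.R2_nm2 for r in recs]),
        )
    arr = np.asarray(recs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("records must be FilamentRecords, (L, R2) pairs or a DataFrame")
    return arr[:, 0], arr[:, 1]


def filter_records(records, min_length_nm: float = MIN_LENGTH_NM):
    """Drop detections below the minimum contour length (threshold inclusive:
    L == min_length_nm is kept)."""
    L, R2 = _as_arrays(records)
    keep = L >= min_length_nm
    return [FilamentRecord(l, r) for l, r in zip(L[keep], R2[keep])]


class WormLikeChainModel:
    """WLC model for a set of filament records.

    Parameters
    ----------
    records : sequence of FilamentRecord, (L, R2) array, or DataFrame
        Observations.  Lengths in nm, squared distances in nm^2 (any
        consistent unit works; the fitted ``P`` comes out in the length unit).
    s : float
        Surface parameter; fixed at 1 by default.
    """

    #: fit bounds and convergence tolerance
    XTOL = 1e-10

    def __init__(self, records, s: float = 1.0):
        self.L, self.R2 = _as_arrays(records)
        if np.any(self.L <= 0):
            raise ValueError("contour lengths must be positive")
        self.s = float(s)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, s: float = 1.0) -> "WormLikeChainModel":
        return cls(df, s=s)

    @property
    def nobs(self) -> int:
        return self.L.size

    def predict(self, P: float, L=None):
        return wlc_mean_square_r(self.L if L is None else L, P, self.s)

    def fit(
        self,
        fix_s: bool = True,
        mask_residuals: bool = False,
        mask_iterations: int = 1,
        P0: float | None = None,
    ) -> "WLCResults":
        """Nonlinear least-squares fit of P (and optionally s).

        With ``mask_residuals=True`` the fit is repeated after removing
        records whose residual magnitude exceeds one residual standard
        deviation (a single pass by default).
        """
        keep = np.ones(self.nobs, dtype=bool)
        res = self._fit_once(keep, fix_s=fix_s, P0=P0)
        for _ in range(mask_iterations if mask_residuals else 0):
            resid = self.R2 - wlc_mean_square_r(self.L, res.P_nm, res.s)
            sd = float(np.std(resid[keep]))
            if sd == 0:
                break
            new_keep = keep & (np.abs(resid) <= sd)
            if not new_keep.any():
                raise WLCFitError("residual masking removed every record")
            if new_keep.sum() == keep.sum():
                res = res._replace_mask(keep)
                break
            keep = new_keep
            res = self._fit_once(keep, fix_s=fix_s, P0=res.P_nm)
        return res

    def _fit_once(self, keep: np.ndarray, fix_s: bool, P0: float | None) -> "WLCResults":
        L, R2 = self.L[keep], self.R2[keep]
        if L.size < 5:
            raise WLCFitError(f"need >= 5 records for a WLC fit, got {L.size}")
        if np.unique(L).size < 2:
            raise WLCFitError("records must span more than one distinct contour length")
        Lmax = float(L.max())
        p0 = float(P0) if P0 is not None else Lmax / 4.0
        upper = 10.0 * Lmax
        p0 = min(max(p0, 1e-6), upper * 0.999)

        if fix_s:
            def model(l, P):
                return wlc_mean_square_r(l, P, self.s)

            popt, pcov = curve_fit(
                model, L, R2, p0=[p0], bounds=([1e-9], [upper]), xtol=self.XTOL
            )
            P_hat, s_hat = float(popt[0]), self.s
            stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
        else:
            def model(l, P, s):
                return wlc_mean_square_r(l, P, s)

            popt, pcov = curve_fit(
                model, L, R2, p0=[p0, self.s],
                bounds=([1e-9, 1e-3], [upper, 10.0]), xtol=self.XTOL,
            )
            P_hat, s_hat = float(popt[0]), float(popt[1])
            stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf

        resid = R2 - wlc_mean_square_r(L, P_hat, s_hat)
        stiff = P_hat >= 0.99 * upper
        return WLCResults(
            model=self,
            P_nm=P_hat,
            stderr_nm=stderr,
            s=s_hat,
            mask=keep.copy(),
            residual_sd=float(np.std(resid)),
            stiff_limit=stiff,
        )


@dataclass
class WLCResults:
    """Fit results: persistence length, its standard error, and diagnostics."""

    model: WormLikeChainModel
    P_nm: float
    stderr_nm: float
    s: float
    mask: np.ndarray = field(repr=False)
    residual_sd: float
    stiff_limit: bool = False

    @property
    def n_used(self) -> int:
        return int(self.mask.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.mask).sum())

    def predict(self, L):
        return wlc_mean_square_r(L, self.P_nm, self.s)

    def _replace_mask(self, mask: np.ndarray) -> "WLCResults":
        out = WLCResults(
            model=self.model, P_nm=self.P_nm, stderr_nm=self.stderr_nm, s=self.s,
            mask=mask.copy(), residual_sd=self.residual_sd, stiff_limit=self.stiff_limit,
        )
        return out

    def summary(self) -> str:
        lines = [
            "Worm-like chain fit",
            "===================",
            f"persistence length P : {self.P_nm:12.4g} nm",
            f"s.e. of fit          : {self.stderr_nm:12.4g} nm",
            f"surface parameter s  : {self.s:12.4g} (fixed)" if True else "",
            f"records used         : {self.n_used} of {self.mask.size}"
            f" ({self.n_removed} masked)",
            f"residual s.d.        : {self.residual_sd:12.4g} nm^2",
        ]
        if self.stiff_limit:
            lines.append("flag                 : stiff-limit (P at bound; R^2 ~ L^2)")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Scatter the (L, R^2) records (masked ones hollow) with the fitted
        curve overlaid; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        L, R2 = self.model.L, self.model.R2
        ax.scatter(L[self.mask], R2[self.mask], s=12, label="records")
        if (~self.mask).any():
            ax.scatter(L[~self.mask], R2[~self.mask], s=12, facecolors="none",
                       edgecolors="tab:red", label="masked")
        grid = np.linspace(L.min(), L.max(), 200)
        ax.plot(grid, self.predict(grid), color="k",
                label=f"WLC fit, P = {self.P_nm:.3g} nm")
        ax.set_xlabel("contour length L (nm)")
        ax.set_ylabel(r"squared end-to-end distance $R^2$ (nm$^2$)")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "P_nm": self.P_nm,
            "stderr_nm": self.stderr_nm,
            "s": self.s,
            "n_used": self.n_used,
            "n_removed": self.n_removed,
            "residual_sd": self.residual_sd,
            "stiff_limit": self.stiff_limit,
        }


def fit_wlc(records, s: float = 1.0, fix_s: bool = True) -> WLCResults:
    """Convenience wrapper: one-shot WLC fit without residual masking."""
    return WormLikeChainModel(records, s=s).fit(fix_s=fix_s)


def mask_and_refit(records, fit: WLCResults | None = None, s: float = 1.0) -> WLCResults:
    """Remove records with |residual| > 1 residual s.d. of an initial fit and
    refit once."""
    model = fit.model if fit is not None else WormLikeChainModel(records, s=s)
    return model.fit(mask_residuals=True, mask_iterations=1)


def middle_fraction_slice(n: int, fraction: float = 0.8) -> slice:
    """Index slice keeping the middle ``fraction`` of ``n`` ordered layers,
    dropping ``ceil((1-fraction)/2 * n)`` at each end (100 layers -> 11..90)."""
    drop = math.ceil((1.0 - fraction) / 2.0 * n)
    return slice(drop, n - drop)


def _pair_records(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All layer-pair (L, R2) records of one frame: L is the summed
    consecutive centroid-to-centroid distance, R2 the squared chord."""
    steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    n = centroids.shape[0]
    i, j = np.triu_indices(n, k=1)
    L = cum[j] - cum[i]
    R2 = np.sum((centroids[j] - centroids[i]) ** 2, axis=1)
    return L, R2


def per_frame_persistence(
    frames_centroids: Sequence[np.ndarray],
    middle_fraction: float = 0.8,
    min_length_nm: float | None = None,
    s: float = 1.0,
) -> list[WLCResults]:
    """Per-frame WLC fits from nanotube layer centroids.

    For each frame the centroid chain is restricted to its middle
    ``middle_fraction`` of layers (overhang exclusion); every layer pair
    contributes one (L, R^2) record; the frame is fit with residual masking.
    No minimum-length filter is applied to simulated layer pairs unless
    ``min_length_nm`` is given.
    """
    results: list[WLCResults] = []
    for k, cents in enumerate(frames_centroids):
        cents = np.asarray(cents, dtype=float)
        if cents.shape[0] < 10:
            warnings.warn(f"frame {k}: fewer than 10 layers, skipped")
            continue
        cents = cents[middle_fraction_slice(cents.shape[0], middle_fraction)]
        if cents.shape[0] < 2:
            warnings.warn(f"frame {k}: fewer than 2 usable layers, skipped")
            continue
        L, R2 = _pair_records(cents)
        if min_length_nm is not None:
            keep = L >= min_length_nm
            L, R2 = L[keep], R2[keep]
        R2 = np.minimum(R2, L**2)  # guard against rounding pushing R2 above L^2
        model = WormLikeChainModel(np.column_stack([L, R2]), s=s)
        results.append(model.fit(mask_residuals=True))
    return results


def select_final_fraction(
    frames, fraction: float = 0.1, total_steps: float = 1e9, key=None
):
    """Keep frames from the final ``fraction`` of the run: step index
    >= (1 - fraction) * total_steps, inclusive."""
    cutoff = (1.0 - fraction) * total_steps
    get = key if key is not None else (lambda f: f.t if hasattr(f, "t") else f)
    return [f for f in frames if get(f) >= cutoff - 1e-9]


def flexibility_ratio(P_um: float, mean_L_nm: float, sig_figs: int = 2) -> float:
    """Persistence length over mean contour length, rounded to ``sig_figs``
    significant figures (e.g. P = 3.4 um, <L> = 970.9 nm -> 3.5)."""
    ratio = (P_um * 1000.0) / mean_L_nm
    if ratio == 0:
        return 0.0
    ndigits = sig_figs - 1 - math.floor(math.log10(abs(ratio)))
    return round(ratio, ndigits)
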