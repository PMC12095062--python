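"""Structural statistics from coarse-grained nanotube trajectories.

Covers the post-processing half of a coarse-grained MD study: rigid-body
alignment and mean structure, per-nucleotide RMSF, designed-bond occupancy,
the inter-duplex angle beta, kissing-loop quality filtering of runs, layer
centroids for persistence-length analysis, and reduced-unit time conversion.

The bond call is a distance criterion (designed partners closer than a
cutoff), an engine-independent proxy for energy-based base-pair calls; the
default cutoff is chosen so that generator-bonded pairs (placed ~1 nm apart)
are called bonded in noiseless frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .oxdna import SIM_UNIT_NM, Configuration

__all__ = [
    "UnitsSpec",
    "align_and_mean",
    "compute_rmsf",
    "bond_occupancy",
    "duplex_angle_beta",
    "kl_quality_filter",
    "convert_time",
    "layer_centroids",
    "BOND_CUTOFF_NM",
]

#: designed-pair distance below which a bond is called formed (nm)
BOND_CUTOFF_NM = 2.5

#: one oxDNA reduced time unit in picoseconds
TIME_UNIT_PS = 3.03


@dataclass(frozen=True)
class UnitsSpec:
    """Reduced-unit time bookkeeping (dt in simulation units)."""

    dt_sim_units: float = 0.003
    time_unit_ps: float = TIME_UNIT_PS
    steps: int = 1_000_000_000

    def __post_init__(self):
        if self.dt_sim_units <= 0:
            raise ValueError("dt must be positive")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")


def convert_time(units: UnitsSpec) -> tuple[float, float]:
    """(timestep in fs, total simulated time in us) by direct unit
    conversion: dt = 0.003 -> 9.09 fs; 1e9 steps -> 9.09 us."""
    timestep_fs = units.dt_sim_units * units.time_unit_ps * 1000.0
    total_time_us = units.steps * timestep_fs * 1e-9
    return timestep_fs, total_time_us


def _positions(frame) -> np.ndarray:
    return frame.positions if isinstance(frame, Configuration) else np.asarray(frame, float)


def align_and_mean(frames: Sequence, reference: int = 0):
    """Rigid-body superposition of every frame onto a reference frame.

    Returns ``(mean_structure, aligned, rotations, centroid_index)`` where
    ``aligned`` is an (n_frames, N, 3) array, ``rotations`` the per-frame
    rotation matrices, and ``centroid_index`` the frame closest (RMSD) to the
    mean structure.
    """
    if len(frames) < 2:
        raise ValueError("alignment needs at least 2 frames")
    ref = _positions(frames[reference])
    ref_c = ref - ref.mean(axis=0)
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        warnings.warn("reference structure is (nearly) collinear; alignment is degenerate")
    aligned = np.empty((len(frames), ref.shape[0], 3))
    rotations = np.empty((len(frames), 3, 3))
    for k, frame in enumerate(frames):
        pos = _positions(frame)
        pos_c = pos - pos.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, pos_c)
        aligned[k] = rot.apply(pos_c) + ref.mean(axis=0)
        rotations[k] = rot.as_matrix()
    mean = aligned.mean(axis=0)
    rmsd = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=1))
    return mean, aligned, rotations, int(np.argmin(rmsd))


def compute_rmsf(aligned: np.ndarray, mean: np.ndarray | None = None) -> np.ndarray:
    """Per-nucleotide RMSF: sqrt(mean_frames |x_i - mean_i|^2)."""
    aligned = np.asarray(aligned)
    if aligned.ndim != 3 or aligned.shape[0] < 2:
        raise ValueError("RMSF needs an aligned (n_frames >= 2, N, 3) stack")
    if mean is None:
        mean = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))


def _region_pairs(registry: pd.DataFrame, region: str | None) -> pd.DataFrame:
    sel = registry if region is None else registry[registry["region"] == region]
    if sel.empty:
        raise ValueError(f"region {region!r} not present in the bond registry")
    return sel


def bond_occupancy(
    frames: Sequence,
    registry: pd.DataFrame,
    region: str | None = None,
    distance_cutoff_nm: float = BOND_CUTOFF_NM,
    positions_in_nm: bool = False,
) -> float:
    """Fraction of (frame x designed pair) combinations with the partners
    closer than the cutoff.  Frame order does not matter; the result is
    linear in the number of bonded (frame, pair) combinations."""
    pairs = _region_pairs(registry, region)
    i = pairs["i"].to_numpy(int)
    j = pairs["j"].to_numpy(int)
    formed = 0
    total = 0
    for frame in frames:
        pos = _positions(frame)
        if not positions_in_nm and isinstance(frame, Configuration):
            pos = pos * SIM_UNIT_NM
        d = np.linalg.norm(pos[i] - pos[j], axis=1)
        formed += int((d < distance_cutoff_nm).sum())
        total += d.size
    return formed / total


def duplex_angle_beta(frame, duplex_a: Sequence[int], duplex_b: Sequence[int]) -> float:
    """Angle beta (degrees, in [0, 180]) between two duplex axes.

    Each axis is the principal direction of the duplex's nucleotide
    positions, oriented 5'->3' (first to last nucleotide id) so that
    parallel duplexes give 0 degrees.  Symmetric in its arguments.
    """
    pos = _positions(frame)
    axes = []
    for ids in (duplex_a, duplex_b):
        ids = np.asarray(ids, int)
        if ids.size < 4:
            raise ValueError("each duplex needs >= 4 nucleotides")
        pts = pos[ids]
        centered = pts - pts.mean(axis=0)
        _, sv, vt = np.linalg.svd(centered, full_matrices=False)
        if sv[0] < 1e-12:
            raise ValueError("degenerate duplex point cloud")
        axis = vt[0]
        if np.dot(axis, pts[-1] - pts[0]) < 0:
            axis = -axis
        axes.append(axis)
    cosang = float(np.clip(np.dot(axes[0], axes[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def kl_quality_filter(
    runs: Sequence[tuple[Sequence, pd.DataFrame]] | Sequence[Sequence],
    registry: pd.DataFrame | None = None,
    min_mean_bonds: float = 11.0,
    designed: int = 12,
    distance_cutoff_nm: float = BOND_CUTOFF_NM,
    positions_in_nm: bool = False,
) -> list[int]:
    """Indices (input order) of runs whose every internal kissing loop keeps
    a mean formed-bond count >= ``min_mean_bonds`` out of ``designed``.

    ``runs`` is a sequence of frame sequences sharing one ``registry`` (or a
    sequence of (frames, registry) tuples).
    """
    accepted = []
    for idx, run in enumerate(runs):
        frames, reg = (run if registry is None else (run, registry))
        kls = reg[reg["category"] == "internal_KL"]
        if kls.empty:
            raise ValueError("bond registry has no internal_KL pairs")
        ok = True
        for region, grp in kls.groupby("region"):
            if len(grp) != designed:
                warnings.warn(
                    f"run {idx}: region {region} has {len(grp)} designed bonds, "
                    f"expected {designed}"
                )
            occ = bond_occupancy(
                frames, grp, None, distance_cutoff_nm, positions_in_nm
            )
            if occ * len(grp) < min_mean_bonds:
                ok = False
                break
        if ok:
            accepted.append(idx)
    return accepted


def layer_centroids(frame, layer_of_nt: np.ndarray, in_nm: bool = True) -> np.ndarray:
    """Per-layer centroid positions, ordered by layer index.

    Invariant under permutation of nucleotides within a layer; raises on
    empty layers.
    """
    pos = _positions(frame)
    if isinstance(frame, Configuration) and in_nm:
        pos = pos * SIM_UNIT_NM
    layer_of_nt = np.asarray(layer_of_nt, int)
    if layer_of_nt.size != pos.shape[0]:
        raise ValueError("layer map does not cover all nucleotides")
    n_layers = int(layer_of_nt.max()) + 1
    counts = np.bincount(layer_of_nt, minlength=n_layers)
    if (counts == 0).any():
        raise ValueError(f"empty layer(s): {np.nonzero(counts == 0)[0].tolist()}")
    cents = np.empty((n_layers, 3))
    for d in range(3):
        cents[:, d] = np.bincount(layer_of_nt, weights=pos[:, d], minlength=n_layers) / counts
    return cents
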