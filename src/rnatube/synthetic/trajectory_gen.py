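"""Synthetic coarse-grained nanotube trajectories in the oxDNA dialect.

Each frame bends the tube axis as a fresh discrete worm-like chain of layer
centroids with a prescribed bending persistence length; nucleotides decorate
each layer rigidly via parallel-transported frames.  Designed bonds can be
broken stochastically (partners displaced apart) at a configurable rate, and
isotropic per-nucleotide jitter can be added.  Frame headers carry the step
index at the configured save cadence; positions are written in simulation
units (1 unit = 0.8518 nm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..oxdna import SIM_UNIT_NM, Configuration, write_topology, write_trajectory
from .assembly import Assembly
from .wlc_chain import WLCParams, sample_wlc_ensemble

__all__ = ["TrajectoryConfig", "generate_nanotube_trajectory", "frame_steps"]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Trajectory cadence and disorder parameters.

    Defaults mirror the production-run bookkeeping being emulated: 1e9 steps
    saved every 5e5 -> 2,000 frames.
    """

    n_frames: int = 2000
    save_every_steps: int = 500_000
    bend_P_nm: float = 2000.0
    frozen: bool = False  # zero-temperature switch: identical frames
    bond_break_rate: float = 0.0  # per designed pair per frame
    jitter_sd_nm: float = 0.0
    box_nm: float = 4000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.bond_break_rate <= 1.0):
            raise ValueError("bond_break_rate must be in [0, 1]")


def frame_steps(config: TrajectoryConfig) -> np.ndarray:
    """Step indices of the saved frames: save_every, 2*save_every, ..."""
    return np.arange(1, config.n_frames + 1, dtype=np.int64) * config.save_every_steps


def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transport an orthonormal frame (e1, e2) along unit tangents."""
    n = tangents.shape[0]
    e1 = np.empty((n, 3))
    e2 = np.empty((n, 3))
    ref = np.array([0.0, 0.0, 1.0])
    t0 = tangents[0]
    v = ref - np.dot(ref, t0) * t0
    if np.linalg.norm(v) < 1e-8:
        v = np.array([1.0, 0.0, 0.0]) - t0[0] * t0
    e1[0] = v / np.linalg.norm(v)
    e2[0] = np.cross(t0, e1[0])
    for k in range(1, n):
        a, b = tangents[k - 1], tangents[k]
        c = np.cross(a, b)
        s2 = np.dot(c, c)
        if s2 < 1e-16:
            e1[k], e2[k] = e1[k - 1], e2[k - 1]
            continue
        cos = np.dot(a, b)
        # Rodrigues rotation taking a to b
        def rot(u):
            return (
                u * cos
                + np.cross(c, u)
                + c * np.dot(c, u) * (1 - cos) / s2
            )
        e1[k] = rot(e1[k - 1])
        e1[k] -= np.dot(e1[k], b) * b
        e1[k] /= np.linalg.norm(e1[k])
        e2[k] = np.cross(b, e1[k])
    return e1, e2


def generate_nanotube_trajectory(
    assembly: Assembly,
    config: TrajectoryConfig,
    out_prefix=None,
):
    """Generate a trajectory for an assembly.

    Returns ``(topology, frames, truth)`` where ``truth`` maps frame index to
    the ground-truth layer centroids (nm) and the set of broken bond rows.
    With ``out_prefix`` set, writes ``<prefix>.top`` / ``<prefix>.dat`` and a
    bond registry CSV ``<prefix>_bonds.csv``.
    """
    spec = assembly.spec
    rng = np.random.default_rng(config.seed)
    n_layers = spec.n_layers
    rise = spec.layer_rise_nm

    # local (in-layer) coordinates of each nucleotide relative to its layer
    # centroid, in the straight reference assembly (axis = +z)
    cents0 = assembly.layer_centroids()
    local = assembly.positions_nm - cents0[assembly.layer_of_nt]
    steps = frame_steps(config)

    if config.frozen:
        axes = None
    else:
        params = WLCParams(
            persistence_length_nm=config.bend_P_nm,
            step_nm=rise,
            contour_length_nm=(n_layers - 1) * rise if n_layers > 1 else rise,
            dimension=3,
        )

    frames = []
    truth_centroids = []
    truth_broken = []
    box = np.full(3, config.box_nm / SIM_UNIT_NM)
    bonds = assembly.bonds
    for fi, t in enumerate(steps):
        if config.frozen or n_layers == 1:
            centroids = cents0.copy()
            tangents = np.tile([0.0, 0.0, 1.0], (n_layers, 1))
        else:
            chain = sample_wlc_ensemble(params, 1, int(rng.integers(2**31)))[0]
            centroids = chain.ordered_points_nm[:n_layers]
            # chain runs along +x; tangents per layer
            diffs = np.diff(centroids, axis=0)
            diffs /= np.linalg.norm(diffs, axis=1, keepdims=True)
            tangents = np.vstack([diffs[:1], 0.5 * (diffs[:-1] + diffs[1:]), diffs[-1:]])
            tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        e1, e2 = _transport_frames(tangents)

        pos = np.empty_like(assembly.positions_nm)
        bvec = np.empty_like(pos)
        nvec = np.empty_like(pos)
        for l in range(n_layers):
            sel = assembly.layer_of_nt == l
            loc = local[sel]
            pos[sel] = (
                centroids[l]
                + loc[:, 0:1] * e1[l]
                + loc[:, 1:2] * e2[l]
                + loc[:, 2:3] * tangents[l]
            )
            radial = loc[:, 0:1] * e1[l] + loc[:, 1:2] * e2[l]
            nrm = np.linalg.norm(radial, axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            bvec[sel] = -radial / nrm  # base vectors point inward
            nvec[sel] = tangents[l]

        if config.jitter_sd_nm > 0 and not config.frozen:
            pos = pos + rng.normal(0.0, config.jitter_sd_nm, pos.shape)

        broken_idx = np.array([], dtype=int)
        if config.bond_break_rate > 0 and not config.frozen:
            broken = rng.random(len(bonds)) < config.bond_break_rate
            broken_idx = np.nonzero(broken)[0]
            for bi in broken_idx:
                j = int(bonds.iloc[bi]["j"])
                # displace the partner well beyond the bonded distance
                direction = pos[j] - pos[int(bonds.iloc[bi]["i"])]
                nrm = np.linalg.norm(direction)
                direction = direction / nrm if nrm > 0 else np.array([1.0, 0, 0])
                pos[j] = pos[j] + direction * 5.0  # nm, well beyond any bond cutoff

        frames.append(
            Configuration(
                t=int(t),
                box=box.copy(),
                positions=pos / SIM_UNIT_NM,
                base_vectors=bvec,
                normal_vectors=nvec,
            )
        )
        truth_centroids.append(centroids)
        truth_broken.append(broken_idx)

    truth = {"layer_centroids_nm": truth_centroids, "broken_bonds": truth_broken}
    if out_prefix is not None:
        prefix = Path(out_prefix)
        write_topology(prefix.with_suffix(".top"), assembly.topology)
        write_trajectory(prefix.with_suffix(".dat"), frames)
        bonds.to_csv(prefix.parent / (prefix.name + "_bonds.csv"), index=False)
    return assembly.topology, frames, truth
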