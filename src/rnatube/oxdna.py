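"""Reader/writer for classic oxDNA-style topology and configuration files.

Topology: header ``N_nucleotides N_strands``, then one line per nucleotide
``strand_id base three_prime five_prime`` (−1 for chain ends).  Configuration
frames: three header lines ``t = <step>``, ``b = bx by bz``, ``E = 0 0 0``
followed by one line per nucleotide with position, base vector, normal
vector and (zeroed) velocities.  The trajectory reader streams one frame at
a time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Topology",
    "Configuration",
    "FormatError",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_configurations",
]

#: one oxDNA simulation length unit in nm
SIM_UNIT_NM = 0.8518


class FormatError(ValueError):
    """Malformed topology/configuration input."""


@dataclass
class Topology:
    strand_id: np.ndarray  # 1-based strand ids, contiguous
    base: np.ndarray  # base letters
    neighbor_3p: np.ndarray  # index of 3' neighbour, -1 at ends
    neighbor_5p: np.ndarray

    @property
    def n_nucleotides(self) -> int:
        return self.strand_id.size

    @property
    def n_strands(self) -> int:
        return int(self.strand_id.max()) if self.strand_id.size else 0

    def validate(self) -> None:
        for i, j in enumerate(self.neighbor_3p):
            if j >= 0 and self.neighbor_5p[j] != i:
                raise FormatError(f"neighbour links inconsistent at nucleotide {i}")
        ids = np.unique(self.strand_id)
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise FormatError("strand ids must be contiguous starting at 1")


@dataclass
class Configuration:
    t: int
    box: np.ndarray
    positions: np.ndarray  # (N, 3) simulation units
    base_vectors: np.ndarray = field(default=None)
    normal_vectors: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.positions.shape[0]
        if self.base_vectors is None:
            self.base_vectors = np.tile([1.0, 0.0, 0.0], (n, 1))
        if self.normal_vectors is None:
            self.normal_vectors = np.tile([0.0, 0.0, 1.0], (n, 1))


def read_topology(path) -> Topology:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError("empty topology file")
    try:
        n_nt, n_strands = map(int, lines[0].split())
    except ValueError as e:
        raise FormatError(f"bad topology header: {lines[0]!r}") from e
    if len(lines) < n_nt + 1:
        raise FormatError(f"topology declares {n_nt} nucleotides, file has {len(lines) - 1}")
    strand = np.empty(n_nt, dtype=int)
    base = np.empty(n_nt, dtype="U1")
    n3 = np.empty(n_nt, dtype=int)
    n5 = np.empty(n_nt, dtype=int)
    for i in range(n_nt):
        parts = lines[i + 1].split()
        if len(parts) != 4:
            raise FormatError(f"topology line {i + 2}: expected 4 fields, got {len(parts)}")
        strand[i], base[i], n3[i], n5[i] = int(parts[0]), parts[1], int(parts[2]), int(parts[3])
    topo = Topology(strand, base, n3, n5)
    if topo.n_strands != n_strands:
        raise FormatError(
            f"topology header declares {n_strands} strands, found {topo.n_strands}"
        )
    topo.validate()
    return topo


def write_topology(path, topo: Topology) -> None:
    with open(path, "w") as fh:
        fh.write(f"{topo.n_nucleotides} {topo.n_strands}\n")
        for s, b, a3, a5 in zip(topo.strand_id, topo.base, topo.neighbor_3p, topo.neighbor_5p):
            fh.write(f"{s} {b} {a3} {a5}\n")


def _read_frame(fh: io.TextIOBase, n_nt: int, frame_index: int) -> Configuration | None:
    header = fh.readline()
    if not header:
        return None
    try:
        if not header.startswith("t"):
            raise FormatError("missing 't =' line")
        t = int(float(header.split("=")[1]))
        box = np.array([float(x) for x in fh.readline().split("=")[1].split()])
        fh.readline()  # energy line
        rows = np.empty((n_nt, 9))
        for i in range(n_nt):
            line = fh.readline()
            if not line or line.startswith("t"):
                raise FormatError("truncated frame")
            rows[i] = [float(x) for x in line.split()[:9]]
    except (FormatError, ValueError, IndexError) as e:
        raise FormatError(f"frame {frame_index}: {e}") from e
    return Configuration(
        t=t,
        box=box,
        positions=rows[:, 0:3],
        base_vectors=rows[:, 3:6],
        normal_vectors=rows[:, 6:9],
    )


def read_trajectory(path, topo: Topology) -> Iterator[Configuration]:
    """Stream configurations one frame at a time (constant memory)."""
    n_nt = topo.n_nucleotides
    with open(path) as fh:
        k = 0
        while True:
            frame = _read_frame(fh, n_nt, k)
            if frame is None:
                return
            unit = np.linalg.norm(frame.base_vectors, axis=1)
            if frame.positions.shape[0] != n_nt or np.any(np.abs(unit - 1) > 1e-3):
                raise FormatError(f"frame {k}: orientation vectors not unit-norm")
            yield frame
            k += 1


def read_configurations(path, topo: Topology) -> list[Configuration]:
    return list(read_trajectory(path, topo))


def write_trajectory(path, frames, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for frame in frames:
            fh.write(f"t = {frame.t}\n")
            fh.write("b = " + " ".join(f"{x:.6f}" for x in frame.box) + "\n")
            fh.write("E = 0 0 0\n")
            for p, bv, nv in zip(frame.positions, frame.base_vectors, frame.normal_vectors):
                fh.write(
                    " ".join(f"{x:.8f}" for x in (*p, *bv, *nv))
                    + " 0 0 0 0 0 0\n"
                )
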