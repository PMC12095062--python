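"""Cylindrical-lattice assembly of RNA origami tiles into a nanotube.

A tile spans three duplexes with 120 deg intrinsic curvature, so three tiles
close one 360 deg layer; layers stack along the tube axis with a fixed rise
and connect corner-to-corner through external kissing loops (a of one tile
pairs with a' of the tile above it, b with b').  The builder places
nucleotides on the cylinder, assigns a single strand per tile (RNA origami
is one-stranded), and records a designed-bond registry with categories
``stem``, ``internal_KL`` (12 base pairs per loop) and ``external_KL``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..oxdna import Topology

__all__ = ["TileGeometry", "AssemblySpec", "Assembly", "build_tile_assembly",
           "BOND_CATEGORIES", "INTERNAL_KL_BONDS"]

BOND_CATEGORIES = ("stem", "internal_KL", "external_KL")
#: designed base pairs per internal kissing loop
INTERNAL_KL_BONDS = 12


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class TileGeometry:
    n_duplexes: int = 3
    intrinsic_curvature_deg: float = 120.0
    tile_dims_nm: tuple[float, float, float] = (11.0, 5.0, 2.5)
    connectors: tuple[str, ...] = ("a", "b", "a'", "b'")


@dataclass(frozen=True)
class AssemblySpec:
    n_layers: int
    tiles_per_layer: int = 3
    nt_per_tile: int = 300
    layer_rise_nm: float = 10.0
    outer_diameter_nm: float = 11.0
    internal_kls_per_tile: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.tiles_per_layer < 1:
            raise ValueError("n_layers and tiles_per_layer must be >= 1")
        if self.nt_per_tile < 48:
            raise ValueError("nt_per_tile must fit stems and kissing loops (>= 48)")

    @property
    def n_tiles(self) -> int:
        return self.n_layers * self.tiles_per_layer

    @property
    def n_nucleotides(self) -> int:
        return self.n_tiles * self.nt_per_tile


@dataclass
class Assembly:
    """Nucleotide positions (nm, tube axis along +z), topology, registries."""

    spec: AssemblySpec
    geometry: TileGeometry
    positions_nm: np.ndarray = field(repr=False)
    topology: Topology = field(repr=False)
    layer_of_nt: np.ndarray = field(repr=False)
    tile_of_nt: np.ndarray = field(repr=False)
    bonds: pd.DataFrame = field(repr=False)  # columns i, j, category, region

    @property
    def n_layers(self) -> int:
        return self.spec.n_layers

    def layer_indices(self, layer: int) -> np.ndarray:
        return np.nonzero(self.layer_of_nt == layer)[0]

    def layer_centroids(self) -> np.ndarray:
        cents = np.empty((self.spec.n_layers, 3))
        for l in range(self.spec.n_layers):
            cents[l] = self.positions_nm[self.layer_of_nt == l].mean(axis=0)
        return cents

    def external_kl_count(self) -> int:
        return int((self.bonds["category"] == "external_KL").sum())


def build_tile_assembly(spec: AssemblySpec, geom: TileGeometry | None = None) -> Assembly:
    """Build the assembly on a cylindrical lattice.

    Raises :class:`GeometryError` unless tiles_per_layer x curvature = 360
    deg.  Total tiles = n_layers x tiles_per_layer; external kissing loops
    connect consecutive layers (2 per tile per interface).
    """
    geom = geom or TileGeometry()
    if abs(spec.tiles_per_layer * geom.intrinsic_curvature_deg - 360.0) > 1e-6:
        raise GeometryError(
            f"{spec.tiles_per_layer} tiles of {geom.intrinsic_curvature_deg} deg "
            "curvature do not close a 360 deg layer"
        )
    radius = spec.outer_diameter_nm / 2.0
    arc = 2.0 * np.pi / spec.tiles_per_layer
    n_nt = spec.n_nucleotides
    positions = np.empty((n_nt, 3))
    strand = np.empty(n_nt, dtype=int)
    layer_of = np.empty(n_nt, dtype=int)
    tile_of = np.empty(n_nt, dtype=int)
    n3 = np.full(n_nt, -1, dtype=int)
    n5 = np.full(n_nt, -1, dtype=int)
    bases = np.array(list("ACGU"))
    rng = np.random.default_rng(spec.seed)
    base = bases[rng.integers(0, 4, n_nt)]

    per_duplex = spec.nt_per_tile // geom.n_duplexes
    duplex_dr = geom.tile_dims_nm[2] / 2.0  # radial stagger between duplexes
    duplex_dz = geom.tile_dims_nm[1] / (geom.n_duplexes + 1)

    idx = 0
    for layer in range(spec.n_layers):
        z0 = layer * spec.layer_rise_nm
        for t in range(spec.tiles_per_layer):
            tile_id = layer * spec.tiles_per_layer + t
            theta0 = t * arc
            for k in range(spec.nt_per_tile):
                d = min(k // per_duplex, geom.n_duplexes - 1)
                kk = k % per_duplex
                half = per_duplex // 2
                # each duplex is a folded hairpin: outbound strand at radius
                # r, return strand paired 0.7 nm inward, so designed stem
                # partners (kk, per_duplex-1-kk) sit side by side
                if kk < half:
                    frac = kk / max(half - 1, 1)
                    r = radius - duplex_dr * (d % 2)
                else:
                    frac = (per_duplex - 1 - kk) / max(half - 1, 1)
                    r = radius - duplex_dr * (d % 2) - 0.7
                theta = theta0 + 0.05 * arc + 0.9 * arc * min(frac, 1.0)
                positions[idx] = (
                    r * np.cos(theta),
                    r * np.sin(theta),
                    z0 + duplex_dz * (d - (geom.n_duplexes - 1) / 2.0),
                )
                strand[idx] = tile_id + 1
                layer_of[idx] = layer
                tile_of[idx] = tile_id
                if k > 0:
                    n3[idx - 1] = idx
                    n5[idx] = idx - 1
                idx += 1

    topo = Topology(strand, base, n3, n5)
    bonds = _designed_bonds(spec, geom, per_duplex)
    _place_kissing_loops(positions, bonds, spec)
    return Assembly(
        spec=spec,
        geometry=geom,
        positions_nm=positions,
        topology=topo,
        layer_of_nt=layer_of,
        tile_of_nt=tile_of,
        bonds=bonds,
    )


def _designed_bonds(spec: AssemblySpec, geom: TileGeometry, per_duplex: int) -> pd.DataFrame:
    rows = []
    npt = spec.nt_per_tile

    def nt(tile_id, k):
        return tile_id * npt + k

    n_stem = max(2, per_duplex // 4)
    for layer in range(spec.n_layers):
        for t in range(spec.tiles_per_layer):
            tile_id = layer * spec.tiles_per_layer + t
            region_tile = f"L{layer}T{t}"
            # stems: antiparallel pairing of each duplex's first/last quarter
            for d in range(geom.n_duplexes):
                lo = d * per_duplex
                for k in range(n_stem):
                    rows.append(
                        (nt(tile_id, lo + k), nt(tile_id, lo + per_duplex - 1 - k),
                         "stem", f"{region_tile}/stem{d}")
                    )
            # internal kissing loops: 12 designed pairs each, loops of
            # adjacent duplexes reaching toward one another near the hairpin
            # turn (outbound side of the lower duplex, return side of the
            # upper duplex)
            # anchored at the quarter position so the loop indices avoid the
            # tile corners (external connectors) and the stem quarters
            anchor = per_duplex // 4
            for m in range(spec.internal_kls_per_tile):
                d_a = m % (geom.n_duplexes - 1)
                d_b = d_a + 1
                for k in range(INTERNAL_KL_BONDS):
                    ia = d_a * per_duplex + (anchor + k) % per_duplex
                    ib = d_b * per_duplex + (anchor + k) % per_duplex
                    rows.append(
                        (nt(tile_id, ia), nt(tile_id, ib),
                         "internal_KL", f"{region_tile}/iKL{m}")
                    )
            # external kissing loops to the layer above, corner-to-corner
            # (a-a' and b-b'); one representative designed pair per connector
            if layer + 1 < spec.n_layers:
                upper = (layer + 1) * spec.tiles_per_layer + t
                corner_a, corner_b = 0, npt - 1
                corner_ap, corner_bp = per_duplex - 1, npt - per_duplex
                rows.append(
                    (nt(tile_id, corner_a), nt(upper, corner_ap),
                     "external_KL", f"L{layer}-L{layer + 1}/T{t}/a-a'")
                )
                rows.append(
                    (nt(tile_id, corner_b), nt(upper, corner_bp),
                     "external_KL", f"L{layer}-L{layer + 1}/T{t}/b-b'")
                )
    df = pd.DataFrame(rows, columns=["i", "j", "category", "region"])
    if df.duplicated(subset=["i", "j"]).any():
        raise GeometryError("designed-bond registry contains duplicate pairs")
    return df


#: bonded partners are placed this far apart in the straight assembly (nm)
BONDED_DISTANCE_NM = 1.0


def _place_kissing_loops(positions: np.ndarray, bonds: pd.DataFrame,
                         spec: AssemblySpec) -> None:
    """Place kissing-loop partner nucleotides in contact.

    Internal loops: the partner reaches to 1 nm radially inward of its mate.
    External loops: both corner nucleotides move to the shared layer
    boundary, 1 nm apart along the tube axis.
    """
    for row in bonds.itertuples():
        i, j = int(row.i), int(row.j)
        if row.category == "internal_KL":
            p = positions[i]
            inward = -np.array([p[0], p[1], 0.0])
            nrm = np.linalg.norm(inward)
            inward = inward / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
            positions[j] = p + BONDED_DISTANCE_NM * inward
        elif row.category == "external_KL":
            lower_layer = i // (spec.nt_per_tile * spec.tiles_per_layer)
            z_boundary = (lower_layer + 0.5) * spec.layer_rise_nm
            xy = 0.5 * (positions[i][:2] + positions[j][:2])
            positions[i] = (*xy, z_boundary - BONDED_DISTANCE_NM / 2.0)
            positions[j] = (*xy, z_boundary + BONDED_DISTANCE_NM / 2.0)
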