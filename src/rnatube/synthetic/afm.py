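"""AFM-like rendering of filament chains.

A chain is rasterized onto a pixel grid, dilated with a disc that combines
the geometric tube radius with the scanning-tip radius (morphological tip
convolution), and assigned a constant apparent height above a flat
background.  Gaussian height noise is optional.  The output is a height map
in nm, a binary mask of filament pixels, and a ground-truth table linking
every filament to its generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .wlc_chain import FilamentGroundTruth

__all__ = ["AFMSceneConfig", "render_afm_scene", "render_filament_image", "PlacementError"]


class PlacementError(ValueError):
    """A chain does not fit inside the field of view."""


@dataclass(frozen=True)
class AFMSceneConfig:
    """Rendering parameters for an AFM-like scene.

    ``tube_height_nm`` defaults to the apparent height of a surface-collapsed
    RNA nanotube (~6 nm); ``tube_radius_nm`` to half the 11 nm design
    diameter; ``tip_radius_nm`` broadens the apparent width.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 4.0
    tube_height_nm: float = 6.0
    tube_radius_nm: float = 5.5
    tip_radius_nm: float = 2.0
    background_height_nm: float = 0.0
    noise_sd_nm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")

    @property
    def footprint_radius_px(self) -> int:
        return max(1, int(round((self.tube_radius_nm + self.tip_radius_nm) / self.pixel_size_nm)))


def _rasterize_path(points_px: np.ndarray, shape) -> np.ndarray:
    """Union of Bresenham segments between consecutive (row, col) points."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.rint(points_px).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    mask[pts[-1, 0], pts[-1, 1]] = True
    return mask


def chain_to_pixels(chain: FilamentGroundTruth, pixel_size_nm: float,
                    offset_px=(0.0, 0.0)) -> np.ndarray:
    """Chain coordinates (x, y in nm) to image (row, col) pixel coordinates.

    Image convention: 0-based (row, col), y-down; only the first two chain
    coordinates are used (3D chains are projected onto the surface plane).
    """
    xy = np.asarray(chain.ordered_points_nm)[:, :2] / pixel_size_nm
    rc = np.stack([xy[:, 1] + offset_px[0], xy[:, 0] + offset_px[1]], axis=1)
    return rc


def render_afm_scene(config: AFMSceneConfig, chains: list[FilamentGroundTruth],
                     offsets_px: list[tuple[float, float]] | None = None):
    """Render chains into one scene.

    Returns ``(height_image_nm, mask, ground_truth)`` where the table holds
    one row per filament (id, P_true_nm, L_true_nm, offset) and the mask is
    exactly the tip-dilated union of the chain rasterizations.
    """
    shape = tuple(config.image_size_px)
    margin = config.footprint_radius_px + 1
    if offsets_px is None:
        offsets_px = _auto_offsets(config, chains, margin)

    mask = np.zeros(shape, dtype=bool)
    rows = []
    paths = []
    for chain, off in zip(chains, offsets_px):
        rc = chain_to_pixels(chain, config.pixel_size_nm, off)
        if (rc.min(axis=0) < margin).any() or (rc[:, 0].max() >= shape[0] - margin) or (
            rc[:, 1].max() >= shape[1] - margin
        ):
            raise PlacementError(
                f"filament {chain.id} extends outside the field of view "
                f"(margin {margin} px)"
            )
        mask |= _rasterize_path(rc, shape)
        paths.append(rc)
        rows.append(
            {
                "id": chain.id,
                "P_true_nm": chain.P_true_nm,
                "L_true_nm": chain.L_true_nm,
                "offset_row_px": off[0],
                "offset_col_px": off[1],
            }
        )
    if chains:
        mask = dilation(mask, disk(config.footprint_radius_px))

    image = np.full(shape, config.background_height_nm, dtype=float)
    image[mask] += config.tube_height_nm
    if config.noise_sd_nm > 0:
        rng = np.random.default_rng(config.seed)
        image += rng.normal(0.0, config.noise_sd_nm, size=shape)

    truth = pd.DataFrame(rows, columns=["id", "P_true_nm", "L_true_nm",
                                        "offset_row_px", "offset_col_px"])
    return image, mask, truth, paths


def _auto_offsets(config, chains, margin):
    """Greedy random placement keeping chain bounding boxes disjoint."""
    rng = np.random.default_rng(config.seed + 1)
    shape = config.image_size_px
    placed: list[tuple[float, float, float, float]] = []
    offsets = []
    for chain in chains:
        rc0 = chain_to_pixels(chain, config.pixel_size_nm)
        lo, hi = rc0.min(axis=0), rc0.max(axis=0)
        h, w = hi - lo
        pad = 2 * margin
        if h + 2 * pad >= shape[0] or w + 2 * pad >= shape[1]:
            raise PlacementError(f"filament {chain.id} larger than the field of view")
        for _ in range(200):
            r = rng.uniform(pad - lo[0], shape[0] - pad - hi[0])
            c = rng.uniform(pad - lo[1], shape[1] - pad - hi[1])
            box = (lo[0] + r - pad, lo[1] + c - pad, hi[0] + r + pad, hi[1] + c + pad)
            if all(
                box[2] < b[0] or b[2] < box[0] or box[3] < b[1] or b[3] < box[1]
                for b in placed
            ):
                placed.append(box)
                offsets.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place filament {chain.id} without overlap; "
                "use a larger image or fewer filaments"
            )
    return offsets


def render_filament_image(chain: FilamentGroundTruth, config: AFMSceneConfig):
    """Render one chain in a tight auto-sized field of view.

    Convenience for per-filament processing pipelines; returns
    ``(height_image_nm, mask, path_px)``.
    """
    margin = config.footprint_radius_px + 2
    rc = chain_to_pixels(chain, config.pixel_size_nm)
    lo = rc.min(axis=0)
    rc = rc - lo + margin
    hi = rc.max(axis=0)
    shape = (int(np.ceil(hi[0])) + margin + 1, int(np.ceil(hi[1])) + margin + 1)
    mask = _rasterize_path(rc, shape)
    mask = dilation(mask, disk(config.footprint_radius_px))
    image = np.full(shape, config.background_height_nm, dtype=float)
    image[mask] += config.tube_height_nm
    if config.noise_sd_nm > 0:
        rng = np.random.default_rng(config.seed + chain.id)
        image += rng.normal(0.0, config.noise_sd_nm, size=shape)
    return image, mask, rc
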