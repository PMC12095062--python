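"""End-to-end persistence-length recovery: sample -> render -> trace -> fit.

Chains are sampled from a WLC preset, rendered one per tight field of view
as AFM-like height images, traced back through skeletonization and
longest-path extraction, filtered at the 200 nm detection floor, and fit
with the surface-parameter-1 WLC relation including one pass of +/-1 s.d.
residual masking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic.afm import render_filament_image
from .synthetic.presets import AFMPreset
from .synthetic.wlc_chain import sample_wlc_ensemble
from .tracing import trace_mask
from .wlc import MIN_LENGTH_NM, WLCResults, WormLikeChainModel, filter_records

__all__ = ["trace_preset_scene", "recover_persistence_length", "median_recovery"]


def trace_preset_scene(preset: AFMPreset, n_filaments: int, seed: int) -> pd.DataFrame:
    """Sample and render ``n_filaments`` chains and trace each one.

    Each chain gets its own field of view (non-interacting filaments), as for
    well-separated tubes picked individually from a scan.  Returns the tidy
    per-filament trace table with ground truth columns appended.
    """
    chains = sample_wlc_ensemble(preset.wlc, n_filaments, seed)
    rows = []
    for chain in chains:
        _, mask, _ = render_filament_image(chain, preset.scene)
        df = trace_mask(mask, preset.scene.pixel_size_nm)
        if len(df) != 1:  # fragmented or self-occluded trace: keep the longest
            if df.empty:
                continue
            df = df.sort_values("contour_nm", ascending=False).head(1)
        row = df.iloc[0].to_dict()
        row.update(id=chain.id, P_true_nm=chain.P_true_nm, L_true_nm=chain.L_true_nm)
        rows.append(row)
    return pd.DataFrame(rows)


def recover_persistence_length(
    preset: AFMPreset,
    n_filaments: int = 300,
    seed: int = 0,
    min_length_nm: float = MIN_LENGTH_NM,
) -> WLCResults:
    """Full single-seed recovery: returns the masked-refit WLC result."""
    traces = trace_preset_scene(preset, n_filaments, seed)
    records = np.column_stack(
        [traces["contour_nm"].to_numpy(), traces["end_to_end_nm"].to_numpy() ** 2]
    )
    records = records[records[:, 0] >= min_length_nm]
    records[:, 1] = np.minimum(records[:, 1], records[:, 0] ** 2)
    model = WormLikeChainModel(records)
    return model.fit(mask_residuals=True)


def median_recovery(
    preset: AFMPreset, n_filaments: int = 300, seeds=range(5)
) -> tuple[float, list[WLCResults]]:
    """Median fitted persistence length (nm) over independent seeds."""
    fits = [recover_persistence_length(preset, n_filaments, s) for s in seeds]
    return float(np.median([f.P_nm for f in fits])), fits
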