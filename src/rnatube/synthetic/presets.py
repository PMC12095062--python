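"""Benchmark presets emulating the study conditions of the AFM experiments.

Two surface-deposited nanotube populations are emulated:

* ``WT_AFM`` — wild-type tubes: persistence length 3.4 um, contour lengths
  lognormal with mean 970.9 nm and s.d. 735.1 nm;
* ``DSOV_AFM`` — tubes carrying a double-stranded loop-out: persistence
  length 0.8 um, contour lengths lognormal with mean 706.1 nm and
  s.d. 563.8 nm.

Both truncate contour lengths at the 200 nm detection floor and render at
4 nm/px, within the 2-10 nm/px range of the AFM scans being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .afm import AFMSceneConfig
from .wlc_chain import LognormalLength, WLCParams

__all__ = ["AFMPreset", "WT_AFM", "DSOV_AFM", "PRESETS"]


@dataclass(frozen=True)
class AFMPreset:
    name: str
    wlc: WLCParams
    scene: AFMSceneConfig

    @property
    def P_true_nm(self) -> float:
        return self.wlc.persistence_length_nm


def _preset(name: str, P_nm: float, mean_nm: float, sd_nm: float) -> AFMPreset:
    return AFMPreset(
        name=name,
        wlc=WLCParams(
            persistence_length_nm=P_nm,
            step_nm=5.0,
            length_model=LognormalLength(mean_nm=mean_nm, sd_nm=sd_nm,
                                         truncation_min_nm=200.0),
            dimension=2,
        ),
        scene=AFMSceneConfig(pixel_size_nm=4.0, tube_height_nm=6.0,
                             tube_radius_nm=5.5, tip_radius_nm=2.0,
                             noise_sd_nm=0.0),
    )


WT_AFM = _preset("WT_AFM", 3400.0, 970.9, 735.1)
DSOV_AFM = _preset("DSOV_AFM", 800.0, 706.1, 563.8)

#: well-conditioned recovery benchmark (L/P near 1.5, where the fit is most
#: informative); not tied to either experimental population
CALIBRATION = _preset("CALIBRATION", 1000.0, 1500.0, 600.0)

PRESETS = {p.name: p for p in (WT_AFM, DSOV_AFM, CALIBRATION)}
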