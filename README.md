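# rnatube

Quantitative analysis of RNA origami nanotube cytoskeletons: worm-like-chain
persistence-length inference from AFM-like filament images, structural
statistics from coarse-grained nanotube trajectories, and morphometrics of
giant unilamellar vesicles (GUVs) expressing an RNA cytoskeleton. A
synthetic-data generator reproduces every input the pipeline consumes — WLC
filaments, AFM-like height images, two-channel GUV scenes, oxDNA-style
trajectories — with complete ground truth, so each analysis stage can be
benchmarked by parameter recovery.

Intended users: people building or analyzing nucleic-acid nanostructures and
synthetic cells who need reproducible, testable versions of the standard
image- and trajectory-analysis steps (skeleton tracing, WLC fitting, Hough
vesicle detection, radial profiles, circularity, bond occupancy).

## The model at the core

A semiflexible filament of contour length *L* and persistence length *P*
obeys the worm-like-chain relation for the mean squared end-to-end distance

    ⟨R²⟩ = 2sPL (1 − (sP/L)(1 − e^(−L/sP))),   s = 1,

which reduces to L² for stiff filaments (L ≪ P) and 2PL for flexible ones
(L ≫ P). `WormLikeChainModel` holds a cloud of per-filament (L, R²) records
and `fit()` returns a `WLCResults` with the estimate, its standard error,
residual diagnostics, the outlier mask (±1 s.d. residual masking) and a
`summary()`. Records come either from traced filament masks (AFM branch) or
from the layer centroids of simulated nanotubes, fitted per frame.

## Worked example

```python
import numpy as np
from rnatube.pipeline import trace_preset_scene
from rnatube.synthetic.presets import DSOV_AFM
from rnatube.wlc import WormLikeChainModel, flexibility_ratio

# sample 1,500 flexible-variant filaments, render AFM-like images, trace them
traces = trace_preset_scene(DSOV_AFM, n_filaments=1500, seed=1)
records = np.column_stack([traces["contour_nm"], traces["end_to_end_nm"] ** 2])
records = records[records[:, 0] >= 200.0]          # drop sub-200 nm detections
records[:, 1] = np.minimum(records[:, 1], records[:, 0] ** 2)

fit = WormLikeChainModel(records).fit(mask_residuals=True)
print(fit.summary())
print("P/<L> =", flexibility_ratio(fit.P_nm / 1000, traces["L_true_nm"].mean()))
```

prints

```
Worm-like chain fit
===================
persistence length P :        898.5 nm
s.e. of fit          :        8.538 nm
surface parameter s  :            1 (fixed)
records used         : 1388 of 1500 (112 masked)
residual s.d.        :    9.243e+04 nm^2
P/<L> = 1.2
```

The fitted persistence length (899 nm here) estimates the generating
stiffness of the preset (800 nm) — single runs scatter by roughly ±10%, so
medians over seeds are the robust summary; 112 records were removed by the
±1 s.d. residual mask. A flexibility ratio P/⟨L⟩ near 1 marks a flexible
filament population (a stiff population like the wild-type design has a
ratio near 3.5).

The same stages are available from the command line
(`rnatube simulate-afm | trace | fit-wlc | simulate-guv | guv-analyze |
simulate-traj | traj-analyze | report`), each writing CSV/JSON outputs plus
a manifest echoing every parameter and seed.

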