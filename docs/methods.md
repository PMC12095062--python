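# Methods

`rnatube` reimplements, as a tested pipeline, the quantitative analyses used
to characterize genetically encoded RNA origami cytoskeletons: persistence
lengths of nanotubes traced from AFM scans, structural statistics of
coarse-grained nanotube trajectories, and morphometrics of giant unilamellar
vesicles (GUVs) expressing an RNA cytoskeleton. Because the original
microscopy and full-scale MD data are external, a synthetic-data generator
reproduces every input the pipeline consumes, with complete ground truth, so
that each stage can be benchmarked by parameter recovery.

## Worm-like-chain model and estimator

Filament stiffness is summarized by the persistence length *P* of the
worm-like chain (WLC). For a chain of contour length *L* whose tangent
correlation decays as exp(−s/P), integrating the tangent correlation gives
the mean squared end-to-end distance

    <R²> = 2sPL (1 − (sP/L)(1 − e^(−L/sP))),

with the surface parameter *s* fixed at 1 for surface-equilibrated
filaments. The estimator is a nonlinear least-squares fit of per-filament
(L, R²) records: initialization P₀ = max(L)/4, bounds (0, 10·max L),
relative parameter tolerance 1e-10, standard error from the fit covariance.
Records shorter than 200 nm are excluded before fitting (detections at that
scale are resolution-limited), with the threshold inclusive (L = 200 nm is
kept). After an initial fit, records whose residual magnitude exceeds one
residual standard deviation are removed and the model is refit once; an
iterate-to-convergence mode exists but is off by default. Fits that run into
the upper bound (R² ≈ L², no curvature information) carry a `stiff_limit`
flag instead of a finite estimate.

Two estimator properties matter for interpreting results and are verified by
the tests:

* On noiseless closed-form data the fit is exact (≤ 1e-6 relative) across
  P ∈ [100, 10⁵] nm.
* The ±1 s.d. residual mask is not neutral on stochastic data: because R² is
  bounded above by L², residuals are left-skewed, and the single masking
  pass shifts the fitted P upward by roughly 7–8% in the stiff regime
  (L < P). This is an inherent property of the masking rule, reported here
  so that masked and unmasked fits can be compared deliberately.

## Synthetic WLC chains

Chains are discrete equal-segment walks (default step Δ = 5 nm). In 2D the
per-step turning angle is Gaussian with variance σ² = 2Δ/P; since
E[cos θ] = e^(−σ²/2) exactly for a Gaussian angle, the tangent correlation is
e^(−Δ/P) per step by construction and the ensemble obeys the relation above
with s = 1 — the calibration is closed-form, and a brute-force ensemble fit
in the test suite confirms recovery of P within 2% for P ∈ [500, 5000] nm at
10⁴ chains. In 3D the step direction is drawn from a von Mises–Fisher
distribution about the previous tangent with concentration solved so the
mean cosine matches e^(−Δ/P). Contour lengths are either fixed or drawn from
a lognormal distribution parameterized by target mean and standard deviation
(moment matching) and truncated from below; the two AFM-like presets use the
experimental populations' summary values (WT-like: P = 3.4 μm, lengths
970.9 ± 735.1 nm; loop-out-like: P = 0.8 μm, lengths 706.1 ± 563.8 nm; both
truncated at the 200 nm detection floor).

## AFM rendering and tracing

A chain is rasterized (Bresenham) at the configured pixel size (presets:
4 nm/px, within the 2–10 nm/px range of the scans being emulated), dilated
with a disc combining the 5.5 nm tube radius and a 2 nm tip radius — a
morphological stand-in for tip convolution that reproduces apparent-width
broadening (≈ 20 nm footprint versus the 11 nm design diameter) without
tip–sample physics — and assigned a constant apparent height (default 6 nm)
over a flat background, plus optional Gaussian noise. The mask is exactly
the tip-dilated union of the rasterized chains when noise is zero.

Tracing thins the mask to a 1-px, 8-connected skeleton (topology-preserving
thinning) and resolves branches by the weighted-longest leaf-to-leaf path
(axial steps 1 px, diagonal steps √2 px; exact Dijkstra search over leaf
pairs, which equals the true longest simple path on tree-shaped skeletons).
Components with fewer than two leaves are handled explicitly: a loop with
one arm traces leaf-to-farthest-node, a pure cycle returns the full cycle
traversal from its lexicographically smallest pixel, and a leafless
junction graph uses the weighted diameter between junction pixels. Closed
rings are excluded from WLC fitting by default (`exclude_cycles=True`),
since their end-to-end distance is not WLC-meaningful; the flag exposes the
alternative. Contour length is the √2-weighted chain-code length times the
pixel size; end-to-end is the Euclidean distance between path endpoints.

A known property of chain-code measurement at this pixel scale: the minimal
8-connected digital path already overestimates a straight segment's length
by up to 8.2% depending on orientation (≈ +5.5% averaged over angles), and
no sub-pixel smoothing is applied. In the stiff regime (L < P) the fit draws
its information from 1 − R²/L², so a few percent of contour inflation is
amplified roughly (6/L)-fold on 1/P, depressing recovered P substantially;
the masking shift (+7–8%) offsets only part of it. Measured end to end on
the default (raw chain-code) stack, the recovery benchmarks give a median
≈ 19% below ground truth for the stiff preset (P = 3.4 μm, mean length
≈ 1 μm) and ≈ 5% below for the flexible preset (P = 0.8 μm). Two
corrections are implemented and available through `trace_mask`
(`length_weights="corrected"` for Kulpa-weighted chain code;
`reconstruct_ends=True` for endpoint reconstruction); near zero net length
error the stiff-regime fit response is steep and asymmetric, so the
corrected stacks overshoot upward by a comparable margin (the masking skew
then dominates). The bias is thus a property of the measurement convention
and the estimator's regime, not an implementation defect, and comparisons
of fitted P across filament populations traced with the same stack remain
meaningful even where the absolute value is biased.

## Nanotube assembly and synthetic trajectories

Tiles of three duplexes with 120° intrinsic curvature close a 360° layer in
threes; layers stack with a 10 nm rise (100 layers ≈ 1 μm, 300 tiles,
≈ 90,000 nucleotides at 300 nt/tile; tests use smaller tiles). Each tile is
one RNA strand. The designed-bond registry records stems (hairpin-folded
duplexes), internal kissing loops (12 designed pairs each, two per tile)
and external kissing loops that join layers corner-to-corner (a–a′, b–b′;
2 per tile per interface, so a 100-layer tube has 2 × 3 × 99 = 594).
Kissing-loop partners are placed 1 nm apart in the straight assembly so a
distance-based bond call is exact on noiseless frames. The two stem pairs
per tile that share a corner nucleotide with an external connector yield to
the connector geometry.

Synthetic trajectories bend the tube axis as a fresh 3D WLC of layer
centroids per frame (independent frames — adequate for per-frame statistics,
not for time-correlation analyses), decorate each layer rigidly via
parallel-transported frames, and can break designed bonds stochastically
(partners displaced 5 nm apart) or add isotropic per-nucleotide jitter.
Frames are written in the classic oxDNA text dialect (topology header
`N N_strands`; per-frame `t/b/E` headers then position, base vector, normal
vector, zeroed velocities; 1 simulation unit = 0.8518 nm), at the production
cadence being emulated: 10⁹ steps saved every 5×10⁵ → 2,000 frames, with the
final-10% rule (t ≥ 9×10⁸) keeping 201 frames per run.

The bond call is a distance criterion (default cutoff 2.5 nm) — an
engine-independent proxy for energy-based base-pair calls, exactly testable
on synthetic frames. Run-level quality control accepts a run only if every
internal kissing loop keeps a mean formed-bond count ≥ 11 of 12 over the
trajectory. Occupancy averages over pairs and then frames; the alternative
(per-region averaging first) coincides for equal-sized regions.

Per-frame persistence analysis restricts each frame to its middle 80% of
layers (dropping ⌈0.1·n⌉ per end: 100 layers → layers 11–90), forms one
(L, R²) record per layer pair, and fits with the same masking as the AFM
branch; no 200 nm filter is applied to simulated pairs by default (flag
available). The median per-frame estimate carries an intrinsic upward skew
of roughly +10–15%: within one frame the pair records share a handful of
bending degrees of freedom, the fit responds convexly to the realized
straightness of the conformation, and the median of the resulting
right-skewed distribution sits above the generating P (controls with
independent records on the same L grid are unbiased). Frames flagged
stiff-limit are excluded from summaries. This skew is a property of the
per-frame procedure itself and should be kept in mind when comparing
per-frame medians with ensemble fits.

Reduced-time conversion uses 1 oxDNA time unit = 3.03 ps, so dt = 0.003 is
9.09 fs per step and 10⁹ steps are 9.09 μs — a direct unit conversion, not a
kinetic mapping.

## GUV morphometrics

The generator renders vesicles as annular membrane rings, optionally
deformed by an area-preserving ellipse and/or low-order radial Fourier
modes r(θ) = r₀(1 + Σₖ aₖ cos(kθ + φₖ)), k ∈ {2, 3}, plus an RNA channel in
one of four modes (none / lumen / cortex / network). Analyses:

* **Detection**: circle Hough transform on Canny edges within a radius
  range, with non-maximum suppression; detection parameters are explicit
  config values echoed to the run manifest.
* **Segmentation**: Gaussian blur (σ = 3) → Li auto-threshold → fill holes →
  1-px erosion → connected components; the vesicle radius is half the major
  axis of the fitted ellipse.
* **Area fraction**: blur/threshold/erode of the RNA channel inside the
  vesicle ROI; vesicles with more than 1% positive area are retained.
* **Radial centre of mass**: mean intensity in 100 annular bins of
  normalized radius (bin centres (i−0.5)/100, intensities normalized to max
  1 — the normalization cancels in x_c = Σxᵢyᵢ/Σyᵢ but is kept for plotting
  fidelity).
* **Circularity**: R = 4πA/P². The default raster estimator takes the
  marching-squares boundary polygon subsampled at every 8th vertex and
  computes area and perimeter from that same polygon, so R ≤ 1 holds for
  every region (isoperimetric inequality) and smooth shapes are accurate to
  well under 2% (digitized disc: 0.993–0.996; 1.5:1 ellipse: 0.937 versus
  0.941 analytic). Raw √2-weighted chain-code and Crofton perimeters remain
  available behind the estimator flag; raster circularity is
  estimator-sensitive, so batch outputs name the estimator used. For
  z-stacks only the mean circularity over slices is reported.
* **Angular sampling**: for every 10th membrane boundary point, the mean RNA
  intensity in a 3 μm-wide rectangle from the centroid toward that point,
  with length 80% of the centroid–membrane distance; rectangles leaving the
  image are clipped with a warning.
* **Statistics**: Welch's unequal-variance t-test with Welch–Satterthwaite
  degrees of freedom, two-tailed.

## What the generator does and does not emulate

The generator reproduces the geometric and statistical structure the
analyses depend on: WLC tangent statistics, lognormal length populations,
tip-broadened ridge masks, annular membranes with controlled deformation,
rigid-layer nanotube conformations with a designed-bond registry. It does
not emulate scanner artefacts (only per-row offsets have a levelling step),
fluorescence shot noise statistics, vesicle crowding or adhesion, bond
kinetics, or sequence-level energetics. Passing recovery tests therefore
demonstrates correctness of the analysis chain under controlled conditions,
not robustness to every artefact of real microscopy.

## Problem sizes and numerical choices

Recovery benchmarks use 300–1,500 filaments per seed and 5–11 seeds per
preset (medians over seeds), sizes at which the median's seed-to-seed
spread is a few percent; single-seed fits of a few hundred filaments have
10–15% spread, which is why medians over seeds are the reported quantity.
Trajectory tests use 4–100 layers and 48–72 nt tiles; the full 300-tile,
90,000-nucleotide assembly is built and counted but not simulated at the
2,000-frame production length in tests. Degenerate inputs follow explicit
rules: empty masks give empty graphs (not errors), single-pixel skeleton
components are flagged and dropped, all-zero radial profiles and empty ROIs
raise, and ties in path search break on the lexicographically smallest
(row, col) endpoint so every traced path is deterministic. All lengths are
nm internally; μm appears only at I/O edges.
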