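# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `csfdyn`, and what the phantom-based verification does and
does not establish about behaviour on real data.

## Data model and conventions

All volumes are numpy arrays plus a 4×4 voxel-to-world affine in mm. Voxel
indices are 0-based; orientation is always derived from the affine (RAS+
world axes assumed), never from header flags. Gradient tables use the FSL
dialect (`.bval` one row; `.bvec` 3 rows × N columns); vectors with b > 0
are renormalized to unit length on read, and a zero vector paired with
b > 0 is rejected. Shell selection matches nominal b-values within an
absolute tolerance (default 50 s/mm²) because scanners report
nominal-adjacent values; a usable dataset must retain at least one b≈0
volume and six distinct diffusion directions.

Inputs are assumed spatially prepared: susceptibility/eddy/motion
correction, slice timing, and template registration are upstream concerns.
Segmentation masks (cortical GM, CSF, PVS, brain) are consumed as given.

## Diffusion tensor fit

Per voxel, the single-tensor model ln S = ln S₀ − b gᵀDg is solved by
ordinary least squares in a 7-parameter design (six tensor components plus
ln S₀), one pseudoinverse shared by all voxels. This is deterministic and
matches common practice; weighted or iterative (RESTORE-style) variants are
out of scope. The design must have full column rank — collinear direction
sets raise an error naming the deficiency. Signals ≤ 0 (possible under
noise) are clamped to 10⁻⁶ of the in-mask median b0 signal before the log:
low enough never to touch physiological intensities, high enough to avoid
−∞. Noiseless phantoms are recovered to ≈10⁻¹⁷ mm²/s, i.e. to machine
precision.

FA is computed from eigenvalues clipped at zero,
FA = √(3/2)·‖λ − λ̄‖/‖λ‖, with null tensors mapped to FA = 0. Clipping
guarantees FA ∈ [0, 1] even for indefinite fitted tensors.

## White-matter probability

Published ALPS pipelines obtain a WM posterior from a generic image
segmenter. Here the posterior comes from a two-component Gaussian mixture
fitted to the in-mask FA distribution by EM, with WM the component of
higher mean FA. Initialization is deterministic — component means at the
25th/75th FA percentiles, equal weights, shared sample variance — with at
most 200 iterations to a 10⁻⁶ log-likelihood tolerance and variances
floored at 10⁻¹⁰. Degenerate input (numerically constant FA) yields tied
posteriors of 0.5 everywhere; fewer than 100 in-mask voxels is an error.
EM non-convergence warns and returns the last iterate. The mixture is
fitted fresh per scan, so the 0.90 exclusion threshold refers to that
scan's own FA contrast.

## ROI placement and the ALPS index

ROIs are spheres defined in world coordinates (so anisotropic voxels are
handled correctly): a voxel belongs to the ROI if its world-space centre is
within the radius. The displacement search evaluates every integer
in-plane displacement (dx, dy) with |dx|, |dy| ≤ 2 voxels (dz = 0),
including (0, 0) — the undisplaced position is the conservative superset of
a "1 to 2 voxel" search, and the tie-break (smaller Euclidean displacement,
then lexicographic) prefers it. Any candidate sphere whose bounding box
leaves the grid is an error rather than a silent truncation.

Within each placed ROI, voxels with WM probability < 0.90 are excluded;
an ROI retaining zero voxels is an error naming the ROI. Per hemisphere
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc); the
reported index is the mean of left and right. Pooling by averaging
hemispheres (rather than one global four-ROI ratio) keeps per-hemisphere
indices available for laterality analyses; on symmetric inputs the two
conventions coincide. Being a ratio of means, the index is invariant to
uniform scaling of the tensor field, and equals exactly 1 on any isotropic
field.

Template-space ROI centres are site-dependent; `data/default_rois.yaml`
ships commonly published MNI152 lateral-ventricle-level coordinates
(projection x = ±26, association x = ±36, y = −14, z = 28 mm, r = 2.5 mm)
as a documented starting point. All tests use phantom-defined centres, so
correctness never rests on the literature values.

## BOLD-CSF coupling

Stages, in order, after discarding the first and last five volumes:

* **BOLD path**: per-volume Gaussian smoothing (FWHM 4 mm,
  σ = FWHM/(2√(2 ln 2)) converted to voxel units per axis, reflective
  boundary) → per-voxel OLS linear detrend → band-pass → z-transform →
  mean over the cortical GM mask → first difference assigned to the later
  timepoint → negate and clip at zero.
* **CSF path**: identical but *without* smoothing (the CSF signal lives in
  a handful of voxels; smoothing would dilute it with neighbouring tissue)
  → mean over the CSF mask restricted to the three most inferior slices.
  "Inferior" is resolved from the affine: the voxel axis closest to the
  world z direction, taking the end with smaller world z.

The band-pass (0.01–0.1 Hz) is a zero-phase ideal frequency mask: rFFT
bins with lo ≤ f ≤ hi are kept inclusive, DC always removed. An ideal mask
is linear, exactly idempotent, and has a testable closed-form contract; a
Butterworth realization was rejected because its order/ripple would be an
arbitrary untestable choice. Z-transform uses the population standard
deviation; zero-variance voxels become zero traces rather than NaNs.

The derivative shortens the BOLD trace by one sample; the CSF trace drops
its first sample so both index the same acquisition times. The coupling is
the maximal Pearson correlation over integer-TR lags with |lag| ≤ 20 s,
computed over overlapping samples only — zero-padding would bias long lags
toward zero. A minimum overlap (default 30 samples) guards short
acquisitions; shifts with zero-variance segments are recorded as undefined
in the profile. Ties are broken toward smaller |lag|, then the negative
lag. Sign convention (stated in every output): positive lag means the BOLD
regressor precedes the CSF signal. A negative coupling is a valid output
here; excluding such participants is the QC module's job, keeping marker
computation and cohort filtering separable.

## Cohort QC

Rules run sequentially in the published order (T1 motion top 1 % → DWI
motion top 1 % → CSF-voxel minimum → negative coupling → fMRI motion
top 1 %), each percentile computed on the non-missing values of the rows
still eligible at that point — mirroring per-modality exclusion counts in
cohort flowcharts. "Top 1 %" uses the "higher" quantile convention
(smallest value ≥ the 99th percentile), so the rule is metric ≥ threshold
and is deterministic on ties. Missing values never trip a percentile rule
and are tallied separately. Computed thresholds are echoed in the report,
making a rerun fully reproducible. Disease-history exclusions are a
user-supplied boolean flag column, not recomputed from health records.

## Phantoms

**DWI.** Signals follow S = S₀ exp(−b gᵀDg) with a background tensor and
spherical region overrides (regions must be positive semidefinite). The
default gradient scheme is one b0 plus six canonical directions (golden-
spiral extras beyond six); noise is Gaussian or Rician (magnitude MRI noise
is Rician; Gaussian is kept for linear-theory tests). The standard ALPS
layout plants four regions of radius 5.5 mm — covering each 2.5 mm ROI and
its whole ±2-voxel search neighbourhood — so expected per-ROI component
means equal the region tensors exactly and the expected index is available
in closed form. Default grid 40×20×16 at 1 mm, S₀ = 1000.

**fMRI.** A unit-variance global signal g(t) is a sum of four random-phase
sinusoids with frequencies on an evenly spaced lattice spanning
0.01–0.05 Hz with a common random offset. The lattice (rather than i.i.d.
frequency draws) is deliberate: half-wave rectification of the derivative
creates difference tones at |f_i − f_j| and sum tones at f_i + f_j, and the
lattice keeps all of them inside the 0.01–0.1 Hz analysis band, so the
planted optimum survives the CSF-path band-pass coherently. GM voxels
(upper half of the grid) carry g(t) times a smooth spatial weight on a
1000-unit baseline with a mild linear drift; CSF voxels in the bottom
three slices carry

    coupling_strength · max(0, −(g(t − lag) − g(t − lag − TR)))
    + (1 − coupling_strength) · independent band-limited noise,

i.e. the inflow is planted on the regressor scale so the phantom's optimum
coincides with the pipeline's definition of coupling (the phantom favours
the implemented convention, and is documented as such). White noise of
standard deviation σ is added per voxel; since g is unit-variance, temporal
SNR = 1/σ. The planted lag must be a multiple of TR so truth is exactly
representable. Defaults: 10×10×10 grid at 3 mm, TR 1 s, 490 volumes (480
after edge discard), lag 6 s, coupling_strength 1, σ = 0.

**Cohort.** Motion metrics are continuous uniforms with planted extreme
outliers sized exactly to the top-1 % count of the sub-cohort eligible when
each rule runs; low CSF counts and negative couplings are planted in known
rows. The truth record lists the planted ids per rule and the expected
survivors.

All phantom randomness flows through a single per-call seed; noise-free
phantoms contain no randomness beyond the seeded frequencies/phases and are
bit-reproducible.

### What the phantoms do not emulate

No anatomy, partial-volume effects, motion or physiological noise spectra,
susceptibility distortion, or multi-site variation. Passing phantom tests
establishes that the estimators implement their definitions correctly and
behave sensibly under noise — not that the markers are accurate on real
scans, where upstream preprocessing and segmentation quality dominate.

## Verification problem sizes

The shipped verification (tests and `scripts/acceptance.py`) uses:
noiseless ALPS identities on the 40×20×16 phantom; tensor-fit exactness on
10³ voxels; FA bounds on 10⁵ random PSD tensors; ROI-search oracle
equivalence on 50 random fields; 100 seeded coupling phantoms at SNR 5 for
lag recovery plus a 5-point noise grid with paired seeds for
monotonicity; 100 null phantoms against 1000-draw circular-shift
permutation nulls; a 400-row cohort table; and byte-level comparison of
repeated CLI runs. These sizes give stable pass/fail behaviour at
interactive runtimes.

## Known limitations

* The GMM-on-FA posterior is a stand-in for a full tissue segmenter; on FA
  maps without clear bimodality (e.g. heavy pathology) the 0.90 threshold
  may exclude aggressively. The `--wm-mode uniform` CLI escape hatch
  disables the filter for controlled inputs.
* The ideal band-pass assumes stationarity over the window and has
  rectangular spectral edges; results differ slightly from IIR
  implementations near the band edges.
* The lag grid is limited to integer multiples of TR; sub-TR lags are not
  interpolated.
* CLI NIfTI outputs are uncompressed `.nii` so reruns are byte-identical
  without depending on compressor metadata.
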