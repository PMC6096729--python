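# Methods

## The measurement model

All measurements treat the recorded grey value of a voxel as proportional to
local fluorophore concentration. No absolute intensity calibration is
assumed anywhere; every derived quantity is either a ratio (nuclear
fraction, attenuation), a geometric quantity (object volume, centroid, arc
position), or a comparison against a background estimated from the same
image.

### Nucleo-cytoplasmic partition

The soma mask is the largest 26-connected component of the thresholded
cytoplasmic (or membrane-filled) channel, hole-filled so the nucleus
interior belongs to the soma even where the soma marker is dim. The nuclear
mask is the thresholded nuclear-marker channel intersected with the soma —
operationalising "voxels containing both reporter and nuclear marker".
Cytoplasm is the set difference, so the three masks partition the soma
exactly and the two summed intensities add to the soma total bit-for-bit on
integer input. Thresholds default to Otsu per channel (computed on float
data so that the ≥-tie rule is meaningful) and can be fixed. Background
subtraction before summing is available but off by default; the validation
experiments turn it on, using the line-based estimate described below,
because an additive background otherwise dilutes the fraction toward the
voxel-count ratio of the two compartments.

Known bias: a finite PSF mixes intensity across the nuclear boundary. For a
nucleus much brighter than the cytoplasm the net flux is outward, biasing
the measured fraction low by roughly the boundary-layer volume fraction
(~σ · surface/volume). At the default geometry and optics this is a few
percent — the same bias a real confocal measurement carries — and it is why
the recovery tolerance is ±0.05 rather than noise-limited.

### Granule volumetry

Objects are connected components of above-threshold voxels (default
26-connectivity, the common 3D object-counter convention; 6 and 18
available), restricted to a mask (typically the nuclear mask), with
components under `min_voxels` (default 2) discarded. Volume is voxel count
× voxel volume with no subvoxel correction, matching plugin-style counters.
Labels are consecutive integers in raster-scan order of each object's first
voxel, so labelling is deterministic; equivalence with a from-first-
principles flood-fill oracle is asserted in the tests for all three
connectivities.

Validity regime: threshold volumetry measures the half-max isosurface. For
an object of radius r blurred by a PSF of width σ, that surface contracts
by ≈ σ²/r per axis (volume deficit ≈ 3σ²/r²). For ~0.02–0.05 µm³ granules
(r ≈ 0.18–0.22 µm) this is severe at confocal σ, so the volumetry
validation runs in the rasterization-limited regime (PSF ≈ half a voxel at
(0.1, 0.05, 0.05) µm voxels), where the per-object error is bounded by one
shell of boundary voxels and shrinks with voxel size. At realistic confocal
optics, absolute volumes of sub-resolution granules are systematically
underestimated — a limitation of the method itself, not of this
implementation; relative comparisons across equally imaged cells remain
meaningful.

### Axonal profiling

The axon path is an input polyline (phantom truth, SWC, or 3-column CSV in
µm) starting at the hillock — tracing is deliberately not reimplemented.
The path is resampled into fixed-length arc segments (default 1 µm); each
segment's mean grey value is taken over the voxels the line passes through
(sampling radius 0, the default, matching a pencil-line readout) or over a
tube of given radius. The whole-path mean is the length-weighted mean of
segment means, which makes it invariant to re-parameterization of the
polyline.

Background is the mean of per-line means over short line segments (default
two 8-µm lines) placed in regions without a positively expressing cell —
auto-placed in the darkest part of the image when not supplied. "Detected
along the axon" means the whole-path mean exceeds background by more than
2× the background sampling SD; this operational criterion is conservative
for path means (which average many voxels), giving a false-positive rate
well under 5% on empty-axon phantoms.

Spike detection: baseline is the mean of the first `window` frames; the
spike time is the earliest frame whose trailing `window`-frame mean exceeds
`min_fold` × baseline (default 3×, window 2). With a slow pre-spike ramp
staying under the fold threshold, the crossing lands on the spike frame.

### UV bleach attenuation

The UV column is modelled parallel to z (the laser propagation axis).
Voxels are binned by in-plane distance to the column centre; per-bin
attenuation is 1 − mean(post)/mean(pre); bins with zero pre-bleach
intensity are flagged NaN and excluded. Readout at arbitrary radius is
linear interpolation between bin centres.

### Statistics

Group summaries are mean ± SEM with sample SD (n−1). Group means are
compared by one-way fixed-effects ANOVA (scipy) with post hoc Tukey HSD on
the studentized range (statsmodels; Tukey–Kramer for unbalanced groups),
significance at P < 0.05 by default. Zero within-group variance with equal
means leaves F undefined and raises rather than returning NaN.

### Richardson–Lucy deconvolution

The standard multiplicative update `est ← est · (K* ⊗ (data / (K ⊗ est)))`
with reflective boundary handling (avoids edge ringing without importing
flux from outside the image), flat initialisation, non-negative output. A
delta PSF reproduces the input exactly; the Poisson deviance between the
forward-blurred estimate and the data is non-increasing on noiseless
problems; interior voxels agree with scikit-image's independent
implementation. Deconvolution is off by default in measurement pipelines —
it is provided for visualisation-style workflows and measurements must be
reproducible without it.

## The phantom

The synthetic neuron is an ellipsoidal soma (default semi-axes
(4.0, 4.5, 4.5) µm) containing an ellipsoidal nucleus
((3.0, 3.5, 3.5) µm — neuronal nuclei occupy roughly half the soma
volume), an optional axon modelled as a capsule tube (radius 0.4 µm) along
a polyline leaving the soma, and spherical nuclear granules with an
intensity multiplier (default 3× nucleoplasm) placed by seeded rejection
sampling without overlap. Granule sizes for volumetry experiments are drawn
83% uniform in 0.023–0.048 µm³ and the remainder log-uniform up to
5.7 µm³, emulating the observed size spectrum of nuclear accumulations.

Channel model: the nuclear marker fills the nucleus; the cytoplasmic marker
fills the whole soma and the axon (small cytosolic proteins equilibrate
through nuclear pores); the reporter has independent nuclear and
cytoplasmic densities. Given a target nuclear fraction f, the nuclear
density is solved in closed form from the compartment volumes (granule
excess included), so the stored truth is exact; a brute-force supersampled
grid integration recomputes it within 1e-3 as an invariant.

Rendering: each compartment is rasterized with 3×3×3 subvoxel partial-
volume supersampling (granules are near voxel scale; binary rasterization
would alias volumes), convolved with an anisotropic Gaussian PSF (default
σ = (0.3, 0.1, 0.1) µm, approximating a 63×/1.2 NA water-immersion
confocal; zero padding), plus a constant background (default 20 grey),
Poisson photon noise (default 0.5 photons per grey unit — an assumption,
since no absolute calibration exists) and Gaussian read noise (SD 2). A
Gaussian replaces a vectorial PSF deliberately: the measurement modules are
the point, and the deconvolution interface accepts any externally supplied
kernel. Default voxel size (0.4, 0.2, 0.2) µm is an assumption typical of
confocal z-stacks of single cells.

### Degeneration sequence

Parameters with defaults, all in seconds where temporal: swelling
interpolates the soma semi-axes linearly to a sphere of `swell_factor`
(1.5) × initial mean radius by `t_expand_end` (3600 s; the observed range
spans tens of minutes to several hours); a monotone redistribution curve
(default: linear ramp to 0.85 between 10% and 100% of `t_expand_end`)
moves that fraction of the initially nuclear reporter mass to the
cytoplasm; the nuclear fate is pyknosis (semi-axes shrink to 50% at
constant reporter mass) or karyorrhexis (≥2 condensed fragments with
Dirichlet volume shares drifting apart along orthogonal seeded directions,
conserving total mass); optional axonal influx ramps slowly from an onset
time and spikes sharply at a spike time (default peak 120 grey/µm³ over a
20-min spike width); optional fragments leave the membrane along seeded
outward rays at 0.003 µm/s carrying 2× cytoplasmic concentration; at
`dissolution_time` (7200 s, necessarily after full expansion) the
cytoplasmic and axonal signal is removed while the nuclear remnant
persists. Reporter mass is conserved by construction before dissolution —
axonal and fragment mass is debited from the cytoplasmic pool — and the
rendered total tracks the bookkept total within 1%.

The linear swelling interpolation, fragment trajectories and influx curve
shape are modelling choices where only endpoint morphologies and
qualitative time courses are known.

### UV bleach column

Survival is 1 − A·exp(−(r/ρ)²) with A = 1 − floor (floor = on-axis
survival, default 0.05) and ρ solved so attenuation is exactly 50% at the
configured half-attenuation radius (10 µm by default, about one cell
width). Only two attenuation readings exist to constrain the shape, so a
Gaussian profile was chosen for smoothness and monotonicity; it decays
faster than the reported ~80% attenuation at 20 µm (the model gives ~7%
there), which is why only the 10-µm anchor is treated as quantitative.

## What the phantom does and does not establish

Passing recovery tests shows the measurement chain is unbiased up to the
physics the phantom includes: partial-volume effects, Gaussian PSF blur,
Poisson/read noise, background, and geometry changes over time. The
phantom does not include: non-Gaussian PSF sidelobes, depth-dependent
aberrations and scattering in tissue, motion between frames or channels,
autofluorescence structure, chromatic offsets, or detector nonlinearity.
Real-data accuracy is therefore bounded below by the phantom results, not
established by them.

## Validation experiment sizes and numerical choices

Nuclear-fraction recovery: 4 targets (0.2, 0.5, 0.782, 0.95) × 5 seeds at
default optics and voxel (0.4, 0.2, 0.2) µm, mean absolute error < 0.05.
Granule volumetry: 132 granules across 3 nuclei at voxel
(0.1, 0.05, 0.05) µm in the rasterization-limited regime (above).
Connected components: 100 random 32³ volumes per connectivity against the
flood-fill oracle, exact. Bleach round trip: noiseless uniform volume,
1-µm bins, per-bin agreement within 2%. Axonal influx: 22 frames at 15-min
spacing, spike at 5 h, detection within ±2 frames; the uninjured baseline
uses the 2-SD criterion. Redistribution: 13 frames over the swelling hour
(Kendall τ < 0, p < 0.01); static control across 10 seeded renders within
±0.03. ANOVA calibration: 1000 null replicates (3 groups × 10), rejection
rate 0.05 ± 0.02. These sizes were chosen to make each estimate's own
sampling error small relative to its tolerance.

Ties at thresholds are included (≥). Masks are recomputed per frame in time
courses because the geometry deforms. Degenerate inputs (empty soma mask,
zero reporter total, zero-variance ANOVA with equal means, zero-length
background lines, paths leaving the volume) raise explicit errors rather
than returning NaN.

## Known limitations

- Sub-resolution granule volumes are PSF-biased at realistic optics (see
  above); counts are robust but merging of granules closer than the PSF is
  unavoidable.
- The partition carries a small PSF boundary-spill bias toward the dimmer
  compartment; deconvolution reduces it but is off by default.
- The bleach model is a two-parameter Gaussian constrained at one radius;
  its far-field shape is not validated.
- OME-TIFF writes embed a fresh UUID, so repeated runs are
  content-identical but not byte-identical at the file level (CSV outputs
  are byte-identical).
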