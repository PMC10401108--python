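# Methods

## Scope and data model

`ossify` quantifies the transport logistics of bone mineralization from 3D
volume-EM data of forming embryonic bone (chick femur at embryonic day 13
is the reference system). The measurement chain is:

1. a two-channel isotropic image stack (electron-density/BSE contrast and
   structural/Inlens-SE contrast) at 8 nm voxels, or a synthetic phantom of
   the same scene;
2. a global gray-level threshold separating mineralized from unmineralized
   tissue, and the mineralized volume it implies;
3. per-vesicle morphometry from segmentation label volumes (vesicles,
   precursor granules, cells): volumes, filling factors, per-cell counts;
4. a closed-form kinetic model converting the static census into vesicle
   shedding rates and intracellular transport velocities.

Segmentation itself (deep-learning or active-contour) is out of scope:
label volumes are inputs, produced externally or by the phantom generator.

## Kinetic model and assumptions

Each mineralizing cell is assigned the tissue volume implied by the
osteocyte lacunar density ρ_lac (per mm³): `V_cell = 10⁹/ρ_lac` µm³
(default 196 000 mm⁻³ → 5102 µm³, a 17.2 µm cube). That volume must be
mineralized within a duration T (default 1440 min). The precursor cargo
per vesicle is the product of the mean vesicle volume and the mean filling
factor. The shedding rate is `r = V_cell/(v_p·T)` vesicles per minute and
the release interval `60/r` seconds. With N standing vesicles per cell
(default 37 = density 0.037 µm⁻³ × an assumed 1000 µm³ pre-osteocyte) and
an intracellular travel distance d (default 10 µm), the mean velocity is
`v = d·r/(60·N)` µm/s.

Assumptions made explicit:

- **Mass-density equivalence.** Precursor inside vesicles is assumed to
  have the same mass density as the bone mineral phase, so the entire chain
  stays in volume units. If the precursor is more dilute (e.g. a liquid
  condensed phase), cargo per vesicle is underestimated and the required
  rate overestimated.
- **All counted vesicles participate.** Only vesicles containing
  electron-dense cargo are counted, and all of them are assumed to be en
  route; storage vesicles would bias the velocity downward.
- **Steady state.** The snapshot census is treated as a steady-state
  population with first-in-first-out turnover.

The serum budget divides the organism's total calcium mass (0.15 g) by the
molar mass (40.08 g/mol) and the serum concentration (2.55 mM), giving
1.468 L, and compares it with the skeleton volume (8.1 g at 1900 kg/m³ →
4.26 mL; ratio ≈344). Note an internal inconsistency in the published
inputs: 0.15 g of calcium is 3.74 mmol, not 3.5 mmol; the package follows
the mass route, which is the one consistent with the ~1.45 L figure. The
diffusion check uses the 3D mean-squared-displacement convention
`t = d²/(6D)` (a `"1d"` option gives `d²/(2D)`); no diffusion coefficient
is assumed — the user must supply one appropriate to the cargo scale.

## Threshold estimation

The per-slice threshold is the "horizontal slope" point of the gray-level
histogram: after a centered moving-average smoothing (default window
5 bins; the window is a reported configuration knob), the two dominant
modes are identified (a second mode counts only if the valley between it
and the first dips below half its height — otherwise the histogram is
declared unimodal and the slice fails explicitly). Between the modes the
bin with minimal |first derivative| is selected; its position is refined
to sub-bin precision by linearly interpolating the adjacent zero crossing
of the second derivative. Exact ties over a flat run resolve to the
midpoint of the maximal run, deterministically. The global threshold is
the mean of per-slice values; its uncertainty is their population standard
deviation (population rather than sample SD — the slices are the whole
stack, not a sample; this is a documented choice). Failed slices are
listed, never silently dropped.

`mineralized_volume` counts every voxel at or above the threshold, so on
phantoms the bright precursor voxels are included with the matrix — as a
real BSE threshold would behave. Their volume fraction (<0.1 % of typical
scenes) is far below the recovery tolerances quoted below.

## Morphometry conventions

- Connectivity for component labelling defaults to 26 (isotropic voxels);
  6 and 18 are available.
- A vesicle record requires positive precursor overlap (vesicles without
  cargo are excluded from all statistics) and a volume of at least
  `MIN_VESICLE_VOLUME`, the volume of a 40 nm sphere — below the smallest
  structure of interest.
- A precursor component is assigned whole to the vesicle covering the
  majority of its voxels, ties to the lower vesicle id; precursor voxels
  outside any vesicle are reported as an anomaly count (expected zero:
  precursor-bearing vesicles are exclusively intracellular).
- Vesicles truncated by the stack boundary are flagged but included by
  default, mirroring how partial cell volumes are treated.
- Two filling-factor statistics are computed and reported per stack: the
  unweighted mean of per-vesicle ratios (`filling_factor`, the statistic
  used downstream) and the ratio of summed volumes
  (`filling_factor_total`). Pooling across stacks is vesicle-count
  weighted; the two conventions explain how a ~9 % unweighted average and
  a 0.089 pooled value coexist.
- `precursor_per_vesicle` is defined as mean volume × mean filling factor
  (an identity held to float precision). Recomputing it from rounded
  per-stack summaries can disagree with values derived from unrounded data
  by up to ~10 % (stack 3 of the reference table); tests document this.
- The allometric fit is ordinary least squares on log10(precursor volume)
  vs log10(vesicle volume); a slope of 1 means a size-independent filling
  factor.

## The phantom generator

The generator emulates the imaged scene with exact, voxel-derived ground
truth: spherical cells with nuclei in an unmineralized region; a
mineralized slab (brighter BSE contrast) occupying a configurable fraction
of the volume; canaliculi as ~300 nm cylinders running from the slab
surface inward; a nanochannel phase occupying a set fraction (default
14 %) of the mineral volume; spherical vesicles packed without overlap
inside cells; monodisperse 80 nm precursor granules packed inside a subset
of vesicles until each vesicle's drawn filling factor is reached (overshoot
bounded by one granule volume). Defaults are the study conditions: 8 nm
voxels, 0.037 precursor-bearing vesicles per µm³ of cell volume, lognormal
vesicle volumes with mean 0.65 µm³, filling factor 0.09, gray-level means
(60, 180, 220) for unmineralized/mineral/precursor on the 8-bit scale,
noise SD 5.

Choices where the scene description is open:

- **Vesicle volume law.** Lognormal, calibrated to mean 0.65 µm³ with
  σ_log = 0.9. A lognormal with that mean cannot place exactly 80 % of
  vesicles below 1 µm³ (the minimum attainable is ≈82 %, at σ_log ≈ 0.93);
  σ_log = 0.9 gives ≈82 % < 1 µm³ — the closest attainable — and spans
  diameters ≈0.3–2.8 µm. Volumes too small to host one granule are
  resampled (negligible truncation at the default scale).
- **Vesicle census.** The density parameter counts precursor-bearing
  vesicles (the counting rule used for all statistics); the realized count
  is `round(density × voxelized cell volume)`. Empty vesicles are added on
  top so that `frac_empty_vesicles` (default 0.30 — "many but a minority",
  not quantified in the source data) is the empty fraction of all vesicles;
  they appear in the label volume but never in the truth table.
- **Nanochannels.** Generated as a Gaussian random field (correlation
  length = channel diameter) thresholded at the quantile that yields the
  target volume fraction exactly, rather than as explicit 40 nm tubes:
  tens of thousands of tube segments would be needed at 8 nm voxels, and
  only the volume fraction and gray level matter downstream — channel
  network topology is explicitly out of scope.
- **Geometry conventions.** Voxel-corner convention (position = index ×
  voxel size); spheres voxelized by a center-in-sphere test, with the
  acknowledged ±1 voxel-shell quantization. Truth-table volumes and
  filling factors are computed from the voxelized labels, never from the
  analytic spheres, so morphometry can be checked for exact agreement.
- **Corruption.** Gaussian noise plus per-slice, per-column uniform
  offsets emulating FIB curtaining; output clipped to the bit-depth range.
  Zero noise and zero striping return the input unchanged. All randomness
  flows from one seed; identical parameters give bit-identical output.
- **Cell placement** uses rejection sampling with a deterministic
  corner-anchor fallback, so feasible-but-tight packings (e.g. two large
  cells in a small volume) succeed for every seed; infeasible requests
  raise `PackingError` rather than silently truncating.

What the phantom does **not** emulate: real segmentation error (truth
labels are perfect — recovery tests validate the morphometry arithmetic,
not a segmenter), curtaining correction, slice misalignment, partial-volume
gray levels at interfaces, non-spherical vesicles, and spatially varying
mineral density. Passing recovery tests therefore demonstrates that the
measurement chain is unbiased on known geometry at realistic noise, not
that any particular segmentation of real data is accurate.

## Problem sizes and numerical tolerances

The test suite and acceptance script use a 96³-voxel scene at 40 nm voxels
for unit-level checks and a 256³-voxel scene (10.24 µm extent, two cells,
lognormal vesicles of mean 0.1 µm³ at density 0.3 µm⁻³) for end-to-end
recovery — a geometrically scaled version of the study scene chosen so
whole cells and tens of vesicles fit a volume that generates in seconds.
At 40 nm voxels the 80 nm granule spans two voxels, the coarsest
quantization at which the filling-factor bookkeeping still resolves
individual granules; recovery there is within a few percent, comfortably
inside the 10 % relative band used for acceptance. Threshold recovery is
checked against the equal-likelihood boundary of the generating gray-level
classes (the midpoint, for equal class SDs) within 2 gray levels for noise
SDs up to 8. Float comparisons elsewhere are exact where the arithmetic is
exact (label counts, voxel ratios) and at explicitly stated tolerances
otherwise.

## Known limitations

- The kinetic chain is a point estimate; no uncertainty propagation from
  the morphometry into rates and velocities is implemented.
- The threshold procedure requires a bimodal histogram per slice; heavily
  skewed or single-phase slices fail (by design, explicitly).
- The phantom's mineral slab is a half-space, not trabecular geometry;
  volume fractions, not shapes, are the validated quantities.
- TIFF is the only supported image dialect; no vendor formats, no
  registration or destriping correction.
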