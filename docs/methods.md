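# Methods

This note documents the models, conventions and numerical choices behind
`aortaflow`, in the order the pipeline runs them.

## Data model

A `VelocityField4D` holds three velocity components (m/s) and a magnitude
image on a regular grid over (x, y, z, t). Axis order is (x, y, z); world
coordinates of voxel centers are `origin + index·spacing` in millimetres;
frames are uniformly spaced over one cardiac cycle. The velocity-encoding
limit (venc, m/s) travels with the data because it defines both the
aliasing artifact and its correction.

## Phantom generator

The generator exists to provide data with exact answers, not to simulate
MR physics. Inside a tube of radius R the velocity is pulsatile Poiseuille
flow along the local centerline tangent:

    v(r, t) = 2·V̄(t)·(1 − (r/R)²)·t̂,

so the cross-sectional mean velocity is V̄(t) and the volumetric flow rate
at every station is Q(t) = V̄(t)·πR². Two geometries are built from the
same machinery: a straight tube and a "candy cane" (vertical ascending
limb, semicircular arch in the x–z plane, vertical descending limb) whose
analytic arc length is L_asc + π·R_arch + L_desc. Optional components:

- **Swirl**: an azimuthal component growing linearly to `swirl_amplitude`
  at the wall, modulated by the normalized waveform — a simple stand-in
  for helical flow. It is divergence-free and does not change Q(t).
- **Noise**: i.i.d. Gaussian velocity noise (m/s) everywhere, plus
  magnitude noise. Outside the lumen the field is noise only.
- **Aliasing** (`inject_aliasing`): the wrap `v ↦ venc − ((venc − v) mod
  2·venc)`, which maps onto (−venc, venc] and is idempotent.
- **Background phase** (`inject_eddy_offset`): a time-constant, spatially
  linear offset per component, the canonical residual eddy-current model.

Ground truth (lumen mask, per-station Q(t), per-voxel stasis and
cycle-summed KE from the noiseless field, centerline with tangents and the
peak speed) is returned with every phantom.

**Default study conditions.** 2.4 mm isotropic voxels, 20 frames over a
1000 ms cycle, venc 1.5 m/s, lumen radius 10 mm, candy-cane limbs
50/60 mm with a 30 mm arch radius. These sit inside typical clinical
acquisition ranges and are deliberately coarser than the 1 mm analysis
grid so the re-interpolation step is exercised. The default waveform is a
half-sine systolic lobe over the first 35% of the cycle with peak mean
velocity 0.5 m/s, a small negative lobe (10% of peak, 15% of the cycle)
immediately after systole, and zero diastole — enough structure to
exercise the forward/reverse decomposition, stasis counting and systole
detection. The `retrograde_fraction` parameter mixes the waveform with its
mirror image, `(1 − 2f)·V̄(t)`, so f = 0 is unchanged flow and f = 1 is
exact reversal. The magnitude image is 1 inside the lumen and 0.1 outside;
only its relative weighting matters (PC-MRA, noise masking).

**What the phantom does not emulate** — and hence what passing tests do
not demonstrate about clinical data: k-space sampling and partial-volume
effects, Womersley (rather than parabolic) profiles, turbulence, vessel
wall motion, eccentric valve jets, and segmentation error. The phantom
validates the *measurement pipeline*, not the biology.

The synthetic cohort generator draws subject-level regional parameters
from per-group (mean, sd) specifications; strictly positive parameters
(KE, FF, RF, peak velocity, diameters) are drawn log-normal with matched
moments so no negative values occur, stasis is drawn normal and clipped
to [0, 100]. Default group statistics are at published clinical scale for
a BAV-versus-control contrast. All draws come from one seeded generator;
there is no global random state anywhere in the package.

## Preprocessing

- **PC-MRA**: magnitude-weighted RMS speed, `sqrt(mean_t (M·|v|)²)`. The
  literature describes several variants; this one is monotone in both
  magnitude and speed and needs no tuning.
- **Noise masking**: voxels whose time-averaged magnitude falls below a
  configurable quantile (default 0.3) are excluded. A constant magnitude
  image keeps everything and warns.
- **Anti-aliasing**: temporal unwrapping per voxel and component with
  period 2·venc (`numpy.unwrap`). This recovers single wraps exactly
  provided the first frame is alias-free and true frame-to-frame jumps
  stay below venc; voxels exceeding 3·venc after unwrapping are counted
  as QC flags in the field metadata. No spatial region-growing is
  attempted.
- **Eddy-current correction**: per component, a first-order spatial
  polynomial (a + b·x + c·y + d·z) is least-squares fitted to the
  temporal-mean velocity over static-tissue voxels and subtracted from
  all frames; the operation is idempotent. Static tissue is auto-detected
  as voxels with temporal speed standard deviation below the 20th
  percentile and magnitude above the noise floor, or supplied explicitly.
  Fewer than 10 static voxels skips the correction with a warning.
- **Maxwell terms**: concomitant-gradient correction requires the
  sequence gradient waveforms, which are not part of the data model; the
  step is a logged pass-through so the pipeline slot remains explicit.

## Geometry

The centerline is extracted by 3D thinning of the mask, building the
26-connected skeleton graph (edge weights = Euclidean length), taking the
longest endpoint-to-endpoint geodesic through its minimum spanning tree,
smoothing with a cubic spline (residual budget ≈ half a voxel per point),
and resampling at 1 mm arc steps. Two refinements matter for accuracy:
the curve ends are extended along the end tangents to the lumen exit and
pulled back by the local inscribed radius (thinning systematically stops
short of tube ends), and each station is snapped to the centroid of its
normal-plane cross-section (two passes, 0.5 mm plane sampling), which
removes the skeleton's lattice bias. On discretized phantoms this recovers
the true axis to ≈0.3 voxel and the analytic arc length to ≈1%. Masks with
multiple components or genuine loops (cycle longer than ~10 voxels in the
skeleton graph) are rejected with a named error.

A thinning skeleton has no anatomical direction. `orient_centerline`
orients toward a known inlet; the pipeline otherwise orients so the
cycle-integrated bulk flux is positive ("downstream = net flow"), recorded
in provenance.

Every lumen voxel is matched to the centerline point at minimum Euclidean
distance (a KD-tree, verified against exhaustive search in the tests),
with ties broken toward the lower (upstream) index. Regions are assigned
by arc length: four boundaries split LVOT | AAo | Arch | PDAo | DDAo, each
voxel inheriting its matched point's region; a boundary station belongs to
the downstream region. Real anatomy needs landmark-based boundaries, which
are supplied per subject via configuration; the phantom default is
10/45/60/80% of the arc span, chosen so all five regions are populated.

Diameters are *effective* diameters, `2·sqrt(area/π)`, from the lumen
cross-section sampled on the plane normal to each station's tangent
(0.5 mm sampling, 30 mm capture radius) — robust to segmentation roughness
compared with a maximum-caliper reading; the convention is recorded in the
geometry report. Regional diameter = maximum over the region's stations.
BSA uses the Mosteller formula `sqrt(height·weight/3600)` (Du Bois
available); indexed diameter = diameter / BSA. Dilation classes from the
maximum AAo diameter: non-dilated < 35 mm, moderate 35 – <45 mm, severe
≥ 45 mm; the published strict inequalities leave the exact boundary values
undefined, so 35 and 45 are assigned to the higher class.

## Hemodynamic maps

All maps are computed on a 1 mm isotropic grid obtained by cubic-spline
interpolation of each component and frame over the mask bounding box
(mask resampled linearly, thresholded at 0.5). With v in m/s, Δt in s and
the 1 mm² voxel face, one frame contributes exactly `v·Δt` millilitres,
which puts per-voxel FF at the 0.1–0.2 mL/cycle scale observed clinically.

Numerical conventions worth stating:

- Stasis compares *speed* (vector magnitude), not axial velocity, against
  the 0.1 m/s threshold.
- KE is cycle-summed (not time-averaged) and uses the fixed unit voxel
  volume dV = 1 mm³; reported per voxel in µJ.
- Systole is the contiguous frame window containing the frame of maximal
  spatial-mean lumen speed, extended while the mean speed stays ≥ 25% of
  that maximum (threshold configurable, logged). An all-zero field returns
  every frame with a warning.
- Regional aggregation: FF, RF, stasis, KE as voxel means; peak velocity
  as the regional maximum. Empty regions report missing values, never 0.
- Projections (mean-intensity for FF/RF/stasis/KE, maximum-intensity for
  peak velocity) keep the background as NaN so silhouettes are distinct
  from true zeros.
- Reynolds number: the vena contracta is the station whose cross-section
  contains the global systolic peak-velocity voxel;
  `Re = ρ·v_peak·D/µ` with the effective diameter there, blood viscosity
  µ = 3.5 mPa·s by default (typical whole blood; configurable).

On noiseless phantoms the maps close the loop: summed per-voxel FF through
a 1 mm cross-sectional band of the straight limb reproduces the analytic
stroke volume to ≈2% (the residual is mask partial-volume and band
quantization at the grid/band resonance — curved-arch bands carry a wedge
correction error that averages out over neighbouring bands), KE and stasis
match their definitions to machine precision, and peak velocity recovers
2·V̄max to well under 3%.

## Statistics

Normality is tested per group (Shapiro-Wilk, α = 0.05); whether the gate
was applied per group or pooled is ambiguous in common practice, so
per-group is implemented and recorded. Two normal groups → Student's
t-test (equal variances); otherwise Mann-Whitney U; more than two groups →
one-way ANOVA with Tukey's post-hoc. Groups under 3 subjects skip the gate
and use the non-parametric branch with a warning. Percent change is
`100·(group − reference)/reference`, displayed rounded to integers.

Correlations use Pearson when both variables pass the gate, Spearman
otherwise, and the *joint* significance rule: p ≤ 0.05 **and** |R| > 0.25.
The multivariate model takes the BSA-indexed diameter (or any numeric
column) as dependent; hemodynamic candidates enter only if they pass the
joint univariate rule, then a pairwise collinearity screen drops the
weaker-|R| member of any pair with |r| > 0.7 (threshold configurable); age
is always retained. Variables are z-scored before ordinary least squares,
so coefficients are standardized β, reported with per-predictor p-values
and the overall multiple R. Exact collinearity that survives the screen is
dropped until the design has full rank, with warnings.

Calibration (recomputed by `scripts/acceptance.py` and the test suite):
type-I error of the two-group comparison is ≈0.05 over 1000 null
replicates; a 50 ± 10 vs 23 ± 11 stasis separation at n = 23/73 is
detected (p < 0.001) in essentially every replicate; standardized
coefficients on a linear synthetic cohort (n = 100, σ = 0.1) are recovered
to < 0.01.

## Problem sizes

The validation experiments run on the default phantom (≈45×20×53
acquisition grid → ≈82×22×113 at 1 mm, 20 frames), 1000 null replicates
for type-I calibration and 200 for power; the whole suite completes in
about a minute on one CPU. Larger grids change nothing structurally — all
operations are O(voxels × frames).

## Known limitations

- Temporal-only unwrapping cannot resolve multi-wrap or first-frame
  aliasing; such voxels are only QC-counted.
- The centerline requires a loop-free tubular mask; aortic dissection or
  touching vessels would need manual editing upstream.
- Region boundaries are arc-length fractions unless landmark positions
  are supplied; they are not detected anatomically.
- The per-voxel FF/RF face-area convention assumes locally
  plane-parallel flow; in strongly curved segments single-band flux has a
  wedge error (conserved only on average).
- The surgery flag in synthetic cohorts is an independent Bernoulli draw;
  no outcome model is implied.
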