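# Methods

`octbands` quantifies the outer retinal bands of eyes with geographic
atrophy (GA) from OCT layer-segmentation surfaces, summarizes them on the
ETDRS grid, and compares paired acquisitions from two devices with linear
mixed-effects models. This note records the model, the conventions and
tunable parameters, what the synthetic phantom does and does not emulate,
and the numerical choices made where the design was open.

## Measurement model

An acquisition is a fovea-centered 20° × 20° volume of `n_bscans` B-scans ×
`n_ascans` A-scans (defaults 49 × 1024). Five axial surfaces are given in
µm from a common reference, increasing posteriorly: ELM, the inner and
outer boundaries of the EZ band, and the inner and outer boundaries of the
RPE band. Missing segments (NaN) encode band loss — the segmentation line
is cut where the band's reflectivity ends. Three bands are derived:

| band | anterior → posterior | content |
|---|---|---|
| `ELM_MZ` | ELM → EZ inner | external limiting membrane + myoid zone |
| `EZ` | EZ inner → RPE inner | ellipsoid zone + interdigitation zone |
| `RPE` | RPE inner → RPE outer | RPE monolayer, excluding BLamD/drusen/BM |

Thickness is posterior − anterior per column; at loss columns it is
*missing*, not zero, so thickness means describe surviving tissue only and
loss is reported separately as an area. This exclusion convention is an
interpretation (the alternative, zero-filling atrophic columns, would
conflate thinning with loss); it is applied uniformly.

Loss masks flag columns where either defining boundary of a band is
missing. Columns carrying the SDD-disruption flag (deposits that visibly
displaced the EZ, a reader judgment encoded in the input) additionally
count as EZ loss, and EZ thickness is missing there by contract.

Subretinal drusenoid deposit (SDD) thickness is the gap between the EZ
outer and RPE inner boundaries where it exceeds **4 µm strictly** ("over a
threshold of" one axial pixel); smaller gaps are treated as 0, which
excludes diffuse stage-1-like material and absorbs segmentation error.
Volumes integrate thickness × per-column cell area and are reported in nL
(1 nL = 10⁶ µm³).

### Geometry conventions

Indices are 0-based; B-scan 0 is the inferior-most scan, A-scan 0 the
image-left column. `n` samples span the field of view with `n − 1`
intervals, so the A-scan pitch is `fov_um / (n_ascans − 1)` (≈5.73 µm by
default) and the derived B-scan spacing `fov_um / (n_bscans − 1)`
(122.08 µm ≈ the conventional "122 µm" protocol). The default lateral
calibration of 0.293 mm/degree is a reconstruction chosen exactly so that
48 intervals over 20° give 122 µm; it is configurable because device
exports may state a different scale. Loss areas and volumes are
rectangle-rule sums: each column represents a cell of A-scan pitch ×
slab width (6.99 × 10⁻⁴ mm² by default). Surfaces are stored in µm;
`axial_pitch_um` exists only to convert pixel-valued inputs on ingestion,
making everything downstream device-agnostic. A 97-B-scan acquisition can
be subsampled to the 49 quantified scans (every second index, doubling the
slab width).

## ETDRS topography

The grid is centered on the annotated fovea with ring radii 0.5 / 1.5 /
3.0 mm (central subfield, parafoveal ring, perifoveal ring; nominal areas
0.79, 6.28, 21.21 mm²) and quadrants split along the ±45° diagonals.
Distances use the anisotropic physical spacings; no isotropy is assumed.
Radius bins are half-open `[inner, outer)`; a column exactly on a diagonal
joins the counter-clockwise quadrant (invisible at float precision).
Laterality maps image left/right onto temporal/nasal (OD: nasal is
image-right); mirroring the map and flipping laterality leaves every
summary unchanged (tested).

Relative losses divide by the *nominal* ring areas even though a 20° field
(~5.86 mm) clips ~0.6% of the 6-mm circle — this matches the standard
normalization; the covered fraction is logged as a diagnostic. Two
consequences are accepted and tested: perifoveal percentages close exactly
from absolute losses, and a fully lost subfield can report slightly above
100% (column count × cell area exceeds the nominal disc area by a
sub-percent rasterization margin). SDD volumes are reported for the
central subfield and the four merged parafoveal+perifoveal quadrants, plus
an area-normalized nL/mm² variant for region comparisons. The cohort SDD
distribution map shifts lattices so fovea centers coincide, crops to the
common extent, and averages per-column volume (µm³) over eyes.

## Statistical comparisons

Cohorts include both eyes of some patients, so models use a random
intercept per patient plus an eye-within-patient variance component
whenever any patient contributes two eyes; if that fit is singular the
eye component is dropped and the result flagged as degraded (never a
silent fallback). Estimation is REML (statsmodels `MixedLM`).

Inference is Wald with a **t reference** using containment-style
denominator degrees of freedom `df = n_obs − n_eyes − (p − 1)` — for a
within-eye device contrast on E paired eyes this is E − 1, the paired
design's df. A plain normal reference is anticonservative at ~20–40 eyes
(empirical type-I ≈ 6–8% instead of 5%); with the t reference the null
rejection rate calibrates to nominal (tested over 200 re-seeded phantom
cohorts). This df choice, the Wald CIs and REML are conventional defaults;
nothing in the reporting scheme prescribes them.

Right-skewed loss areas are log-transformed before modelling
(`log_outcomes` in `RunConfig`); means and CIs are reported after
back-transformation, so intervals are asymmetric and contrasts become
ratios. Exact zeros are replaced by half the smallest positive observed
value before the log (configurable by pre-transforming the table);
negative values are an error naming the offending rows. Bonferroni
correction multiplies raw p-values by the number of tests (default m = 7
for the seven whole-field outcomes; pairwise region contrasts use the
contrast count) and caps at 1.

## The phantom generator

The generator emulates the *segmentation-level* structure of a paired
two-device GA cohort; it does not simulate reflectivity, speckle,
hypertransmission or RPE phenotypes. Defaults define the study conditions:

- **Design**: 32 patients, 25% contributing both eyes (exactly 8, so 40
  eyes), each imaged on two devices on identical lattices with identical
  fovea centers (follow-up-registered pairing). 40 eyes × 2 devices × 49
  B-scans = 3920 quantified B-scans.
- **Baseline thicknesses** (standard device): ELM+MZ 20 µm, EZ 27 µm,
  RPE 21 µm, with between-patient and between-eye SD 1.5 µm each and a
  per-acquisition offset SD of 0.8 µm (session variability). These center
  the simulated cohort near published GA reference magnitudes.
- **Device effects**: additive offsets ELM+MZ −1.5, EZ +1.1, RPE −5.1 µm
  on the high-resolution device (the published paired mean differences:
  better IZ/RPE demarcation thins the measured RPE band and thickens the
  EZ band), and SDD visibility 0.65 vs 1.0 (axial resolution limits how
  much of a shallow deposit is registered, so the high-resolution device
  reports larger SDD volumes, ratio ≈ 1.7).
- **Lesion**: concentric ellipses with nested extents (EZ-loss ⊇ ELM-loss
  ⊇ RPE-loss, margins +0.30/+0.15 mm over the RPE semi-axes 1.0 × 0.7 mm),
  lognormal per-eye scale (σ = 0.25, clamped to [0.5, 1.6]) giving
  right-skewed loss areas, centered ~0.4 mm from the fovea. Truth areas
  are polygon-clipped ellipse areas (shapely, relative error < 10⁻⁵).
  A lesion clipped by more than 25% of its area is rejected.
- **SDDs**: circular paraboloid caps (closed-form volume ½πr²h) carved
  into the EZ-outer/RPE-inner gap; ~30 per eye (Poisson), radius
  350 ± 50 µm, height 15 ± 3 µm, centers in a 0.85–2.45 mm annulus
  (sparing the central 1 mm) with anatomic-quadrant weights
  0.30/0.23/0.23/0.24 (superior predominance). Mounds are
  rejection-sampled to avoid each other, the lesion and the field edge,
  keeping the closed-form truth additive. Above-threshold truth uses the
  analytic factor `1 − (t/h)²`.
- **Drusen**: Gaussian elevations lifting all five surfaces equally —
  they deform geometry without changing any thickness or the SDD gap,
  matching their exclusion from the measurements.
- **Jitter**: i.i.d. Gaussian noise (SD 1 µm) per surface per column,
  then projection onto the ordering constraint (a crossed posterior
  surface is raised onto its anterior neighbour), so generated volumes
  always satisfy the ordering invariant.

Truth tables are computed from closed forms only and never call the
quantification modules, so recovery tests are a genuine cross-check.

### What the phantom does not emulate

Within-eye spatial covariance of thickness is a smooth low-order surface
plus independent jitter — real segmentation error is spatially correlated.
Loss extents are identical across devices (device effects touch
thicknesses and SDD visibility only), so simulated device contrasts for
loss areas are exactly 1; the published smaller EZ/ELM losses on the
high-resolution device reflect reader-visibility effects outside this
model. Lesions are single ellipses, not multifocal atrophy. Passing
recovery tests therefore demonstrates the *quantification pipeline's*
fidelity on known geometry, not realism of GA morphology.

## Numerical choices and known limitations

- **Rectangle-rule discretization**: counting columns whose centers fall
  inside a lesion has worst-case alignment error that scales with
  perimeter × cell size; across 122 µm slabs it is typically < 1.3% for
  semi-axes ≥ 0.5 mm but can reach ~2.5% for minor semi-axes near
  0.5–0.7 mm when the ellipse edge straddles a row of column centers.
- **Threshold × noise interaction**: for deposits whose visible peak is
  near the 4 µm threshold, jitter systematically converts sub-threshold
  material into measured volume; the closed-form truth of such marginal
  deposits is not recoverable by any thresholding measurement under
  noise. Volume recovery is validated at full mound visibility (peaks
  6–18 µm), where measured totals agree with the analytic above-threshold
  truth to within 5%.
- **Validation problem sizes**: repeated-inference studies (CI coverage
  of the injected −5.1 µm RPE effect over 100 re-seeded cohorts; null
  calibration over 200) run on reduced 128 × 13 lattices with ~24 eyes —
  the quantities tested (coverage, type-I error) are lattice-independent,
  and the reduced size keeps the studies cheap and deterministic.
- Sub-µm negative EZ-outer/RPE-inner gaps are tolerated as 0 SDD;
  ordering violations beyond 10⁻⁶ µm are rejected as corrupt input.
- All unit conversions are exact powers of ten; ring areas are kept
  unrounded internally and rounded to 2 decimals only for reporting.
- TSV I/O writes floats at 17 significant digits and reads with
  round-trip parsing, so write → read is bit-identical; re-running the
  pipeline on identical inputs and config reproduces all outputs
  bit-identically (the manifest records the config hash).
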