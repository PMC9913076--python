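# Methods

## The question

Texture features computed from PET tumor volumes depend not only on the
image but on how the per-slice / per-direction texture matrices are combined
into a single number — the *aggregation method*. This package quantifies that
dependence. For the co-occurrence (GLCM) and run-length (GLRLM) families,
which are directional, six aggregations exist: features averaged over every
(slice, direction) matrix (`2D_averaged`); directions merged per slice, then
features averaged over slices (`2D_s_merged`); slices merged per direction,
then averaged over the four in-plane directions (`2.5D_d_merged`); all 2D
matrices merged into one (`2.5D_merged`); features averaged over the 13
unique 3D directions (`3D_averaged`); and all 13 merged (`3D_merged`). The
size-zone, distance-zone and neighbourhood families (GLSZM, GLDZM, NGTDM,
NGLDM) are direction-free and have three variants: per-slice features
averaged (`2D`), slice matrices merged (`2.5D`), or one volumetric matrix
(`3D`).

Robustness of a feature across methods is measured by the one-way intraclass
correlation over a patient cohort,

    ICC = (BMS − WMS) / (BMS + WMS),

with BMS and WMS the between- and within-subject mean squares (df = n−1 and
n(k−1)), pairwise (k = 2 methods) or overall (k = all methods), categorized
as poor (<0.5), moderate (<0.75), good (<0.9) or excellent (≥0.9). The
literature sometimes attributes these mean squares to a Kruskal–Wallis
ANOVA, which produces rank statistics rather than mean squares; we use the
classical random-effects ANOVA on raw values (identical to ICC(1,1) at
k = 2) and expose a rank-transformed variant behind `rank_transform=True`
for sensitivity checks. Negative ICCs are reported as computed and
categorize as poor.

## Preprocessing chain

Stages run in the order: observer-mask intersection → body-weight SUV
(activity · weight / dose, activity assumed decay-corrected) → optional Van
Cittert partial-volume correction → fixed-bin-number discretization within
the VOI.

**Van Cittert deconvolution.** SUV⁽ⁱ⁾ = SUV⁽ⁱ⁻¹⁾ + α(SUV⁽⁰⁾ − h ⊗ SUV⁽ⁱ⁻¹⁾),
clamped to ≥ 0 each iteration; defaults α = 1, 10 iterations. The PSF h is a
separable 3D Gaussian parameterized by FWHM in millimetres (the sweep runs
FWHM 1–5 mm), truncated at ±3σ per axis and renormalized to sum 1, with
symmetric-reflect boundary handling (an edge voxel is its own mirror
neighbour) so small phantoms suffer no edge darkening. With a delta kernel
the iteration is an exact fixed point; on a blurred point source the peak
grows monotonically with iterations — both are tested.

**FBN discretization.** Within the (possibly PVC-corrected) VOI, grey =
1 at the VOI minimum, otherwise ⌈D (SUV − SUVmin)/(SUVmax − SUVmin)⌉, so the
maximum maps to D and the grey resolution is (SUVmax − SUVmin)/D. The
output is invariant under positive affine rescaling of the SUVs. Constant
VOIs degenerate to grey 1 everywhere and are logged.

**Resampling.** Tricubic spline for images (`resample_cubic`), nearest
neighbour for masks (binarity). The phantom emits volumes already on the
CT-like analysis grid, so the cohort analyses do not resample; the operation
exists for external NIfTI input, and whether PVC runs before or after it is
a config choice (default: resample first, mirroring registration-then-
correction practice).

## Texture matrices

Distance is fixed at 1 (Chebyshev). In-plane directions are the 4 unique
offsets up to sign; 3D uses the 13 unique offsets covering all 26
neighbours. Slicing is along the thick (axial) axis, array axis 0. Design
choices that matter for merging:

- The grey axis of every matrix always spans the full 1..D range of the VOI,
  so per-unit matrices are conformable; feature code masks grey levels
  without mass (the "levels present in the ROI" convention).
- A unit with no valid pair along its direction (GLCM) or no ROI voxel
  (other families) is empty-flagged; averaged methods skip it, merged
  methods receive zero counts from it. A single isolated voxel is a run of
  length 1 in GLRLM (runs exist in any direction), so GLRLM units are empty
  only when the slice holds no ROI voxel at all.
- Merged matrices carry the summed in-ROI voxel tally of their constituents,
  so run/zone/dependence percentages under 2.5D merging use the total voxel
  count of the contributing units.
- Zones use full connectivity (8 in-plane, 26 volumetric). GLDZM distance is
  the city-block distance to the nearest outside-ROI voxel with the grid
  border counting as outside and ROI-border voxels at distance 1; it is
  computed in-plane for 2D units.
- NGTDM records (nᵢ, sᵢ) per grey over voxels having ≥1 in-ROI
  Chebyshev-1 neighbour; NGLDM uses coarseness tolerance α = 0 and
  neighbourhood radius 1, so every ROI voxel is tallied (dependence-count
  percentage is exactly 1 at this setting).

## Features

95 features: 25 GLCM, 16 GLRLM, 16 GLSZM, 16 GLDZM, 5 NGTDM, 17 NGLDM,
following the standard (IBSI-style) formulas. Numerical conventions:
entropies in bits with 0·log 0 = 0; information correlation 2 uses the
base-2-consistent form √(1 − 2^(−2(HXY2 − HXY))); GLCM correlation is 1 for
a single-grey (zero-variance) matrix; information correlation 1 is 0 when
the marginal entropy vanishes; NGTDM coarseness is capped at 10⁶ when every
neighbourhood difference is zero, and contrast/busyness/strength take their
single-grey special values (0). Empty-flagged matrices yield NaN for the
whole family — the degenerate marker; ICC rows containing it are dropped
with a logged count. Every feature is verified against an independent
direct-sum implementation (explicit Python loops) to 1e-12 relative
tolerance on all fixtures and seeded random VOIs.

## The phantom cohort

Clinical PET data are not redistributable, so the study runs on a synthetic
cohort whose summary statistics are calibrated to the clinical ones: lesion
volume lognormal matched to MATV 50.9 ± 86.4 mL, peak uptake lognormal
matched to SUVmax 15.4 ± 7.77 g/mL, lesion-mean uptake targeted at
7.95 g/mL through the radial profile exponent, injected dose uniform over
306–468 MBq, body weight lognormal around 60 kg (only the SUV statistics
constrain it), and anisotropic 3 × 0.98 × 0.98 mm voxels. Each patient has
one ellipsoidal lesion (mildly anisotropic axes) whose interior is
background + (peak − background) · profile · (1 + a·GRF), where the GRF is
smoothed white noise with configurable correlation length (default 8 mm,
amplitude a = 0.35) — the texture matrices need non-degenerate grey
structure, and with no established model of uptake microstructure a
Gaussian random field is the minimal defensible choice. Because
oversize draws are resampled until they fit the grid, the volume lognormal
is shifted so its *truncated* mean still equals the configured mean.

The second observer's mask perturbs the ellipsoid level set with a
correlated noise field whose amplitude is bisected per patient to a Dice
target drawn around 0.87 (SD 0.02); the result is reduced to its largest
26-connected component with holes filled, so both masks are always single
components. (Per-voxel boundary flipping was considered and rejected: it
cannot cheaply preserve connectivity, and level-set noise produces the
spatially coherent disagreement real observers show.) With
`observer_dice_target = 1` the masks are identical.

What the phantom does **not** emulate: scanner noise and reconstruction
artefacts (no sinograms/OSEM), multiple lesions, non-ellipsoidal shapes,
inter-lesion background structure, or any physiological uptake model.
Passing tests therefore demonstrate correctness and internal consistency of
the measurement pipeline and the *structure* of the aggregation effect (for
example, same-dimension averaged-vs-merged pairs show near-perfect ICC
while cross-dimension pairs degrade), not clinical effect sizes: cohort ICC
magnitudes depend on between-patient heterogeneity, which is necessarily
simpler here than in patients.

## Problem sizes and determinism

The cohort analyses and the acceptance script use a desk-scale
parameterization (`reduced_params`): 128 patients on 48³ grids with the
lesion lognormal scaled to mean 8 mL / SD 6 mL so lesions fit the small
grid while keeping the clinical right skew. The full-scale default
(48 × 128 × 128 grids, clinical volume statistics) is used for calibration
checks and cohort summaries. All randomness flows from one integer seed
through `numpy.random.SeedSequence.spawn`, one child per patient, so
identical parameters give bit-identical cohorts and the end-to-end study is
reproducible table-for-table.

## Known limitations

- The 2D direction count (4) and 3D count (13) are the standard
  convention; no anisotropy-weighted direction schemes and no distances > 1.
- Fixed-bin-size discretization is not implemented (the study design is
  FBN-only), nor are Lucy–Richardson or regularized PVC variants.
- ICC confidence intervals are out of scope; only the point estimate and
  its category are reported.
- With six methods the overall ICC uses all six; a subset is configurable.
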