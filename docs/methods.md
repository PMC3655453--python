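# Methods

## Signal model and T1 estimation

A saturation-recovery series of T1-weighted volumes at repetition times
TR obeys, voxel by voxel,

    S(TR) = S0 (1 − e^(−TR/T1)),

where the amplitude S0 absorbs the instrument gain, spin density and the
echo-time/T2 weighting; none of those factors is estimated individually.
The default TR set is {1463, 2000, 3000, 5000} ms.

Fitting proceeds in two stages per voxel, both vectorized across the
volume:

1. *Initialization.* With a provisional asymptote `S0 = 1.02·max(S)`, the
   identity `ln(S0/(S0−S)) = TR/T1` turns recovery into a line whose inverse
   slope initializes T1. Points with `S ≥ S0` (noise above the asymptote)
   are dropped from this regression only.
2. *Refinement.* Joint `(S0, T1)` least squares by a Levenberg-style damped
   Gauss–Newton iteration that only accepts steps lowering the squared
   residual sum, so the refined fit is never worse than its initialization.
   Because the log-linear seed converges into a flat-model valley for
   near-saturated voxels (T1 well below the shortest TR), the refinement is
   additionally restarted from fixed guesses T1 ∈ {0.3, 1, 3}·TR_min and
   the best optimum kept; a closing pass with a fresh damping schedule
   polishes the winner. On noise-free recovery signals this recovers
   `(S0, T1)` to machine precision across the physiological range.

**NA classification.** A voxel is NA — no valid T1 — if the fit is
degenerate (constant signal), the fitted T1 falls below a 1 ms floor, or its
fitted amplitude is less than 5× the volume's noise floor. The last rule
encodes the physics of the NA class: bone cement contains almost no water,
so its voxels carry pure noise and must not receive a relaxation time. The
noise floor is estimated robustly from the median per-voxel residual power
(`median SSR / median χ²_{k−2}`), which the minority of genuinely poor fits
cannot move. `fit_quality` stores the coefficient of determination of the
nonlinear model in signal space.

At this TR set, T1 below roughly 400 ms leaves under 3% of the recovery
curve unsampled, so per-voxel estimates there are increasingly
noise-limited; this bounds the concentration range the method can quantify
(below).

## Noise filtering

The T1 map is filtered slice by slice with a 5-element plus-shaped median
(voxel + 4 in-plane edge neighbors, edge replication at borders, never
crossing the 2 mm slice gap). A single-voxel excursion — noise, or a lone
contrast-bearing voxel — is replaced by the median of its surroundings. NA
voxels are excluded from their neighbors' median sets and stay NA
themselves: the filter never invents a value for a voxel whose own fit
failed, which keeps the NA-volume endpoint meaningful at the cement
boundary.

## ROI mask

Per slice of the T1-weighted image: greyscale morphological opening (3×3
square), Otsu threshold, hole filling, removal of connected components
smaller than `min_component_px` (default 100; a component of exactly the
minimum survives), then binary closing. Otsu makes the mask invariant to
positive intensity rescaling. The greyscale-opening-first order follows the
processing description this pipeline reimplements; a switch
(`open_before_threshold=False`) applies a binary opening after thresholding
instead.

## Symmetric-histogram threshold

Within a tissue, released contrast only shortens T1, so the native
distribution's right half is uncontaminated. The construction: histogram
the defined T1 values (bins anchored at the sample minimum so the
statistics are shift-invariant; ties in the mode break toward the lower
bin), take the peak bin center, and mirror every value at or above the peak
about it. The standard deviation of that mirrored sample estimates the
native spread; the segmentation threshold is `peak − 1 SD`. The SD is
computed from the raw mirrored values, not binned counts. The peak is used
for thresholding and as the tissue-representative native T1; the mirrored
mean (equal to the peak by construction) is reported alongside.

The bin width must resolve the native spread: the default 50 ms suits
native SDs of several hundred ms and above (≈ SD/15 at the distributions
this method was built around); `recovery_experiment` derives it adaptively
as `IQR/1.349/15`, clipped to [1, 50] ms. A bin far coarser than the spread
mislocates the peak and collapses the SD, placing the threshold inside the
native bulk.

A legacy fixed threshold (e.g. the 1400 ms level used by earlier
blinded-reader protocols) can be supplied through
`SymmetricHistogramStats.from_peak_sigma`.

Note an inherent property: with the threshold one SD below the peak, about
16% of genuinely native voxels fall below it whatever the noise level;
those connected to the contrast region are segmented with near-zero
concentrations. Control (no-contrast) arms quantify this baseline.

## Segmentation

Candidates are the implant voxels plus every tissue voxel whose T1 is
defined and at or below the threshold *or* NA (cement and very high
concentrations both surface as NA). The contrast region is the union of
connected components of the candidate set touching the implant — a seeded
region grow. Connectivity defaults to 6 (face); 26 is available. Output is
monotone in the threshold: raising it never shrinks the region.

## Concentration conversion and validity

The linear relaxivity relation

    1/T1 = 1/T1_0 + r1 · C

is inverted for C with a single tissue-representative T1_0 (the histogram
peak) and r1 = 0.0038 mM⁻¹ ms⁻¹ for Gd-DTPA (the same figure is often
quoted per second; `r1_from_per_second` converts explicitly — with T1 in ms
the per-ms value is required for the worked numbers to come out right).
Negative raw values (T1 > T1_0) clamp to zero and are flagged. The relation
is trusted between 0.1 and 5 mM; voxels outside are flagged
`below_range`/`above_range`. Above roughly 10–50 mM a
paramagnetic-to-superparamagnetic transition corrupts spatial encoding;
such voxels appear as NA and no correction is attempted.

`sensitivity_analysis` propagates native-T1 spread: curves with T1_0 at the
mean and ±1 SD give an asymmetric error band (at T1 = 1650 ms with
2817 ± 852 ms: 66 +22/−40 μM; the relative band shrinks monotonically as T1
decreases). `fit_relaxivity` recovers r1 and 1/T1_0 by ordinary least
squares of 1/T1 on concentration over calibration vials.

## Registration

Rigid: the closed-form least-squares rotation/translation from paired
landmarks (centroid subtraction, SVD of the cross-covariance, determinant
sign fix), optionally with one uniform scale (Umeyama). Collinear landmark
sets are rejected. Deformation: per-landmark displacement (fixed − moving)
interpolated barycentrically over a Delaunay tetrahedralization; outside
the convex hull the nearest landmark's displacement applies, optionally
tapered linearly to zero over a margin (default: no taper, so constants are
reproduced everywhere). Resampling is pull-back trilinear interpolation;
out-of-support voxels are NA. `compare_t10_methods` builds concentration
maps under four native-T1 policies — unregistered, rigid, deformation,
isotropic — and their pairwise differences.

## Endpoints

With spacing in mm, voxel volume in mm³ equals μL (0.18 μL at
0.3 × 0.3 × 2 mm); concentration in mM equals nmol/μL. Region volume is
count × voxel volume; total mass is `Σ C·ΔV` over defined voxels (NA
contributes nothing); NA volume is reported both inside the segmented
region and volume-wide. The implant-adjusted volume subtracts the implant
volume derived from its weight and the cement density — the density is a
required parameter with no asserted default.

## Digital phantoms

The generator emulates a leg cross-section with a contrast-eluting rod: an
elliptic-cylinder muscle "leg", a femur with cortical shell and
intramedullary canal, and a cement rod in muscle (IMR-like, default) or in
the canal (IOR-like). Native T1 is drawn per tissue from truncated normals
(floor 200 ms): muscle 2817 ± 400 ms, canal 2817 ± 700 ms (broader, as
marrow is), cortex 1200 ± 150 ms. The 2817 ms center matches the native
tissue distribution this pipeline is calibrated around; the muscle SD is
kept below the all-tissue 852 ms figure because muscle is the narrower
component of that mixture.

The plume decays exponentially with in-plane distance from the rod:
`C(r) = C_peak·exp(−(r−r_start)/λ)` between `r_start` and `r_max`, with
`r_start` a 0.25 mm standoff beyond the rod radius — larger than any
subsample offset of a rod-labeled voxel, so no plume mass falls inside
cement and the closed-form integral

    M = 2π C_peak λ [(r_start + λ) − e^(−(r_max−r_start)/λ)(r_max + λ)] · L

is exact for the voxelized truth up to quadrature error. Per-voxel truth is
the profile averaged on a 3×3 in-plane subgrid, keeping that error a few
tenths of a percent. Defaults: C_peak 0.5 mM, λ 1.2 mm, r_max 4.5 mm. The
0.5 mM peak sits mid-scale of the 0–1 mM range in which in-vivo maps of
this preparation are rendered and inside the 0.1–5 mM calibration band; the
surface T1 it induces (~2250 ms⁻¹-rate, ≈ 445 ms) is at the edge of what
the study TR set resolves per voxel. A 5 mM surface concentration (T1 ≈
51.5 ms) is representable in scenes and exercises the relaxivity relation,
but is not per-voxel quantifiable at these TRs at realistic noise — the
method classifies such cores as NA or recovers them only after filtering;
`C_peak` is a free parameter for exploring that regime.

Acquisition simulation applies the recovery model per TR with per-tissue S0
(muscle 100, canal 90, cortex 30, cement/air 0) and adds Rician noise
(magnitude of a complex Gaussian perturbation; default σ = 2.5, SNR 40
against muscle) or Gaussian noise for linear-fit tests. Everything is
deterministic given the seed.

What the phantom does *not* emulate: release kinetics (the plume is a
static profile, not a diffusion solution), partial-volume mixing between
tissues, B1/flip-angle inhomogeneity, through-slice profile effects, motion
between TR acquisitions, and spatially correlated (structured) noise.
Passing recovery tests therefore demonstrate the correctness of the
processing chain under the stated signal model, not scanner-grade accuracy.

`recovery_experiment` runs the full chain (simulate → fit → filter →
threshold → segment → convert → summarize) and reports recovered vs true
mass and volume, NA volumes, and concentration RMSE by decade. Problem
sizes used in the shipped checks: 64 × 64 × 16 voxels at the study voxel
size, five fixed seeds for the noisy condition — small enough to run on one
CPU in seconds while leaving thousands of plume voxels per scene.

## Numerical choices and degenerate inputs

- Histogram mode ties break toward the lower bin; bins anchor at the sample
  minimum; fewer than two distinct values is a hard error.
- The mirrored-sample SD uses the n−1 normalization.
- `threshold = peak − sigma` holds bit-exactly on every stats object
  (enforced at construction).
- Gauss–Newton damping: λ starts at 1e-3, ×0.3 on accepted steps, ×5 on
  rejected ones, 60 iterations per start; steps producing non-finite or
  non-positive T1 are rejected.
- Constant or all-zero voxel signals → NA with a diagnostic, never an
  exception; empty contrast regions → empty maps with a warning; empty
  implant masks, degenerate landmark configurations and inconsistent
  geometries are hard errors.
- Resampling marks any sample point outside the input volume NA rather than
  extrapolating.

## Known limitations

- Single-compartment, single-exponential recovery; no multi-exponential T1,
  B1 correction, or T2 estimation.
- One isotropic T1_0 per tissue ignores intra-tissue heterogeneity; the
  sensitivity band quantifies but does not remove the resulting error,
  which is largest at low concentration (overestimation-skewed).
- Per-voxel quantification degrades below T1 ≈ 400 ms (above ≈ 0.5–1 mM)
  at the default TR set; total-mass endpoints remain accurate only while
  most plume mass lies in the resolvable band.
- Landmark registration quality is bounded by landmark placement; no
  intensity-based or regularized nonrigid registration is provided.
- The ANOVA/post-hoc statistics used to compare experimental arms are out
  of scope; summary tables export as tidy CSV for external tools.
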