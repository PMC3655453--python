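# gdmap

Spatiotemporal quantification of a locally delivered MRI contrast agent
(Gd-DTPA as a drug surrogate) from multi-TR T1-weighted acquisitions.

Controlled-release depots — for example antimicrobial-loaded bone cement
(ALBC) implanted at an orthopaedic infection site — are almost always
characterized *in vitro*, because measuring where the drug actually goes in
tissue is hard. Co-releasing a gadolinium contrast agent makes the
distribution visible by MRI: the agent shortens the longitudinal relaxation
time T1, and the shortening can be converted to concentration. `gdmap`
implements the full image-processing chain that turns a series of
T1-weighted scans into concentration maps and scalar endpoints (volume of
distribution, total released mass), plus digital phantoms that make every
stage testable without scanner data.

## Method

1. **T1 mapping.** A saturation-recovery series at repetition times
   TR ∈ {1463, 2000, 3000, 5000} ms obeys
   `S(TR) = S0·(1 − exp(−TR/T1))`. Each voxel's `(S0, T1)` is fit by
   log-linear initialization (`ln(S0/(S0−S))` vs TR; the inverse slope is T1)
   followed by damped Gauss–Newton refinement, vectorized over the volume.
   Voxels with no detectable water signal (cement, air) or a fit below the
   1 ms floor are NA.
2. **Filtering and ROI.** A slice-wise plus-shaped median filter (voxel + 4
   in-plane edge neighbors) suppresses single-voxel noise; the leg ROI comes
   from greyscale opening, Otsu thresholding, hole filling, small-component
   removal (< 100 px) and closing.
3. **Symmetric-histogram threshold.** Contrast contaminates only the short-T1
   side of a tissue's histogram, so the native spread is estimated by
   mirroring the values at or above the histogram peak about the peak; the
   segmentation threshold is `peak − 1 SD` of the mirrored sample.
4. **Seeded segmentation.** The contrast region is every subthreshold or NA
   voxel connected (face connectivity) to the implant within the tissue.
5. **Concentration.** The linear relaxivity relation
   `1/T1 = 1/T1_0 + r1·C`, with `r1 = 0.0038 mM⁻¹ms⁻¹` and a single
   tissue-representative native value `T1_0` (the histogram peak), converts
   T1 to concentration in mM; an asymmetric sensitivity band follows from
   re-evaluating at `T1_0 ± 1 SD`.
6. **Registration (optional).** Landmark-based rigid alignment (SVD of the
   point cross-covariance) and a Delaunay-interpolated displacement field
   support voxel-wise `T1_0` from a precontrast scan, for comparison with
   the isotropic-`T1_0` shortcut.
7. **Endpoints.** Region volume (voxels × 0.18 μL at 0.3 × 0.3 × 2 mm),
   NA-region volume, and total mass `Σ C·ΔV` (mM·μL = nmol).

## Worked example

```python
import gdmap as g

# a 64 x 64 x 16 phantom: muscle leg, femur, cement rod, 0.5 mM contrast plume
spec  = g.PhantomSpec(noise_sigma=2.5)          # Rician noise, SNR 40
report = g.recovery_experiment(spec, seed=101)
print(f"threshold     {report['threshold_ms']:7.1f} ms")
print(f"true mass     {report['closed_form_mass_nmol']:7.1f} nmol")
print(f"recovered     {report['recovered_mass_nmol']:7.1f} nmol")
print(f"rel. error    {report['mass_rel_error']:7.2%}")

# the printed concentration conversions behind the sensitivity analysis
print(g.t1_to_concentration(1650, 2817) * 1000)   # 66.07 uM
print(g.t1_to_concentration(51.5, 2817) * 1000)   # 5016.4 uM
```

Output for seed 101:

```
threshold      2302.2 ms
true mass       143.2 nmol
recovered       142.2 nmol
rel. error       0.65%
66.07185016467007
5016.444250715916
```

The threshold lands one (mirrored-sample) SD below the native muscle peak;
the recovered mass agrees with the closed-form integral of the phantom's
exponential plume to under a percent at this noise level.

A CLI mirrors the library stage by stage:

```sh
gdmap phantom --seed 7 --out scratch/ph
gdmap run-all --phantom-seed 7 --out scratch/run   # summary.csv + manifest
```

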