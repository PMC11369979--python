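# Methods

This note records the models, defaults and numerical choices behind the
package, what the synthetic cohort does and does not emulate, and the known
limitations of each.

## Synthetic cohort

### Measure-level model (the `skip_recon` path)

Each subject carries one latent severity `z ~ N(0,1)`. Group marginals for
the four SN measures (N1 volume, QSM-based volume, NMS-based volume, NMS
contrast range) are log-normal, fitted to published group medians and
inter-quartile ranges by quartile matching:

```
mu = ln(median),    sigma = (ln q3 − ln q1) / (2 z_0.75),  z_0.75 = 0.67449
```

The fit reproduces the median exactly and the quartile ratio q3/q1 exactly;
the individual quartiles are exact when the inputs are log-symmetric
(q1·q3 = median²), which the published rows approximately satisfy. A
degenerate zero-spread input is accepted with a warning (point mass).

Cross-measure dependence is a single-factor Gaussian copula: measure m uses
the standard-normal score `w_m = −(√ρ·z + √(1−ρ)·ε_m)`, so higher severity
lowers every measure while each group marginal stays exactly log-normal.
The loading defaults to `ρ = 0.3`. Rationale: the source tables publish no
correlation matrix, so ρ is genuinely free; 0.3 reproduces the published
composite–LEDD correlation magnitude (√(0.3·0.35) ≈ 0.32 against a reported
ρ ≈ −0.30) and keeps the composite's noise-averaging effective.

Hemispheres split each aggregate draw mean-preservingly,
`L, R = agg·(1 ± tanh(a))`, with `a ~ N(−offset·d·σ_m, (0.5 σ_m)²)`: the L/R
mean equals the aggregate draw exactly (so the aggregate marginals are exact
by construction), the jitter scales with each measure's log-spread (keeping
the contrast-range ratio near its physiologic band ≥ 1), and the left
hemisphere receives a configurable degeneration excess (default +5%) to
mirror the reported left-side advantage — a config knob, not a calibrated
claim.

Degeneration fractions map severity to [0,1]: `d = (0.35 + 0.55 Φ(z))·s`
for PD and `0.12 Φ(z)·s` for HC, where `s` is `degeneration_scale`. Setting
`s = 0` removes the group difference entirely (both groups draw from the HC
marginals), which is the null-calibration condition; intermediate values
interpolate the log-normal parameters between the HC and group-specific
fits.

Clinical covariates: PD UPDRS-III, LEDD and disease duration are
quartile-fitted log-normals sharing the severity factor (loadings 0.6,
0.35, 0.25), with a PD floor of 5 UPDRS points at zero severity; H&Y stages
are assigned by severity bands calibrated to the published stage
proportions; HC get stage 0, small UPDRS, and no LEDD/duration.

**Known limitation.** With the marginals pinned to the published quartiles,
a single-factor Gaussian copula caps the composite's achievable AUC near
0.87–0.91 — below the published 0.943 — because the log-effects of the
three factors sum against a log-noise floor set by those same quartiles.
The generator therefore reproduces the marginal behaviour of each measure
and the direction of all orderings, but understates the composite's
advantage over its components. Passing tests show internal consistency of
the pipeline, not that real data behaves this way.

### Image-level phantom

Geometry (mm, grid-centred): paired SN ellipsoids (semi-axes
3.5 × 5.5 × 6 mm, ±7 mm lateral), red-nucleus spheres (r = 2.5 mm) 7 mm
cranial of the SN centre, and a dorsolateral N1 sub-ellipsoid inside each
SN. The slice axis runs cranio-caudal with increasing index = caudal, so
the slice-selection rule (first slice where the RN fades, plus two caudal
neighbours) lands inside the SN slab. Default grid 96×96×32 at
0.5 × 0.5 × 1 mm; NMS volumes are generated on the same grid (the real NMS
acquisition uses 3 mm slices; the common grid is a simplification, with
anisotropic grids available through the grid config).

Degeneration d acts monotonically three ways: SN susceptibility rises
(`χ_SN = 40 + 50 r² + 110 d` ppb, red nucleus fixed at 100 ppb), the intact
low-χ (10 ppb) N1 core shrinks radially as (1 − d), and the NMS amplitude
over the SN falls with the neuromelanin level. Gaussian texture noise
(5 ppb / 1 signal unit) is seeded per subject. Masks are the exact rendered
supports; they stand in for manual segmentation, so segmentation error is
*not* modelled.

The GRE simulator convolves χ with the dipole kernel (zero-padding factor 2
to suppress wrap-around), adds a linear — hence harmonic, hence
SMV-removable — background field plus per-channel constant offsets, decays
magnitude with TE at an R2* that grows with paramagnetic load
(0.02 + 1e-4·χ ms⁻¹), and stores wrapped phase with per-channel complex
Gaussian noise (default sd 1% of base magnitude, 2 channels). What is not
emulated: realistic anatomy, flow/pulsation/motion artifacts, coil
sensitivity profiles, T1 effects, multi-site variability — the failure
modes the source study blames for misclassifications are exactly the ones a
geometric phantom cannot produce.

## Reconstruction

- **Brain mask**: threshold at 20% of the robust (99th-percentile) maximum,
  largest connected component, morphological closing (r = 2 voxels, with
  padding so the closing cannot eat the volume border).
- **Unwrapping**: cosine-spectral (Neumann) Poisson solve; the k = 0
  coefficient is zeroed, so outputs are mean-free and callers compare
  modulo a constant. Interior accuracy is ~1e-6 rad for smooth wrap-free
  phases and <0.05 rad for a 6π quadratic ramp at 48³.
- **Frequency fit**: per-voxel weighted least squares of phase against
  2πTE with intercept (absorbing receiver offsets); weights default to
  magnitude². A single echo requires an explicit intercept-free flag.
- **Background removal**: SMV/SHARP with a 2 mm sphere, deconvolution
  threshold 0.05, restricted to the radius-eroded mask. Constants are
  annihilated to machine precision; exterior-source fields to <5% RMS;
  interior sources retain >80% of their energy.
- **Dipole inversion**: truncated k-space division (sign-preserving,
  δ = 0.1) followed by iterative data-consistency refinement (default 30
  iterations; 12 in the desk-scale image runs) that enforces the measured
  field on {|D| > δ} and the brain-mask support in image space. The chain
  is linear; a 100-ppb sphere at 64³ comes back within ~0.5%. χ is
  referenced to zero mean over the mask — QSM is only defined up to a
  constant, and a fixed reference makes every downstream threshold
  reproducible.

The named components of the source processing chain (HARPERELLA, the
STI-Suite inversion) are not published as equations; this package's
explicit unwrap + SMV + truncated-inversion decomposition is a testable
stand-in with all constants exposed in config, not a claim of numerical
equivalence.

## Quantification choices

- "Maximized the difference between groups" is operationalized as
  maximizing the PD-vs-HC AUC of the thresholded volumes (scale-free,
  consistent with the nonparametric testing used throughout); ties break
  toward the smallest threshold; candidate grids default to 25 quantiles of
  the pooled in-region values.
- The RN "barely or no longer visible" criterion is a per-slice voxel count
  below ceil(0.1 × the RN's maximum per-slice count); the fraction is
  config.
- Percentiles (contrast range) use linear interpolation between order
  statistics — pinned because the P90/P10 ratio is reported to 3 decimals.
- The N1-volume stand-in counts SN voxels on the analysis slices whose SMWI
  exceeds 0.7 × the slice-wise robust background level (median SMWI over
  brain tissue outside the SN). It replaces a proprietary deep-learning
  tool's *functional contract* (a volume in mm³); no network is emulated.
- The contrast range is computed on the same three analysis slices as the
  volumes (the source text implies but does not state this).
- Hemisphere aggregation: arithmetic mean for continuous measures; binary
  ratings aggregate as Normal only if both sides are Normal.

## Statistics

ROC curves place one vertex per distinct score (tie groups), so the
trapezoidal AUC equals the Mann–Whitney statistic U/(n₁n₂) with tie
half-credit — verified exhaustively against a pairwise oracle. The Youden
cutoff breaks ties toward higher sensitivity (a deliberate
err-toward-false-positives choice). Percentages are reported to 2 d.p. and
AUC to 3 d.p. in tables. Chi-square is Pearson without continuity
correction and the t-test is pooled-variance Student — both choices
reproduce the published demographic p-values from the printed summaries.
Mann–Whitney uses exact enumeration for tie-free samples with min(n) ≤ 8
and the tie-corrected normal approximation otherwise. The Bonferroni m
defaults to the number of correlation tests actually run and is overridable
(the source fixes m = 40 without enumerating the family).

## Problem sizes and determinism

Seeding is counter-based: every per-subject stream derives from
(master seed, subject index, stage id), so results are independent of
execution order. Identical config + seed gives byte-identical cohort
tables, volumes and metrics.

Default study sizes: 82 PD / 107 HC. Calibration checks use 500 per group
(the group-median Monte-Carlo sd is then 3–6% of the target, inside the 10%
calibration band); the acceptance script uses 2000 per group to halve that
error. Null calibration uses 1000 replicates of 30 + 30. Full image-chain
runs default to a 96×96×32 grid; the mini-cohort smoke runs use 64×64×32
with 12 inversion iterations — at these sizes a subject takes about a
second end to end.
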