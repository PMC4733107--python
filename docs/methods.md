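# Methods

## Model and assumptions

A binary lesion mask on a fixed regular grid is treated as a realization of
a stationary random function; its spatial correlation structure is captured
by the indicator variogram γ(**h**), estimated separately along the three
grid axes. Stationarity is assumed only in the weak sense needed for the
variogram to be a meaningful summary; the method is insensitive to the
absolute position of lesions (translation invariance away from array
edges) and, by construction, blind to structure at lags beyond the cutoff.

Two modelling choices define the estimator:

- **Lags are exact integer multiples of the axis spacing** (1.5, 3.0, …,
  15.0 mm on the reference grid → 10 lags per axis). Sampling is gridded,
  so lag binning — a scattered-data device — is unnecessary and would only
  blur the estimate. γ at lag 0 is identically zero and not emitted.
- **The pair sum runs over the full rectangular array**, background
  included, with no wraparound; edge pairs simply drop out of n(h). A
  fixed denominator domain across patterns is what makes the sill
  comparable between exams and linear in total lesion volume. The
  alternative (restricting pairs to a brain mask) would make the sill
  depend on each subject's brain-mask size.

The exponential model γ(h) = c·(1 − e^(−3h/a)) is fitted per axis. With
the −3 factor, *a* is the *practical range*: γ(a) = c·(1 − e⁻³) ≈ 0.95 c.
Lesion patterns produce variograms that rise from the origin and level off
within the 15 mm window whenever typical lesion diameters are below the
cutoff; the exponential shape fits these curves well (R² typically
0.95–0.99) though not perfectly — a voxelized sphere population yields a
slightly kinked curve that no two-parameter model reproduces exactly.

## Fitting

Unweighted least squares over the ≤ 10 lag points, via trust-region
reflective minimization with bounds a ∈ (0, 10·cutoff], c ∈ (0, 0.5]
(the pointwise maximum of an indicator semivariance). Pair counts vary by
under 10% across the lag window on a 121-voxel axis, so weighting by n(h)
would be inconsequential. Initialization exploits the practical-range
property: c₀ = mean of the last three empirical values, a₀ = smallest lag
with γ ≥ 0.95·c₀ (falling back to cutoff/2). Tolerances are set to machine
level (1e-15) so that noiseless model curves are recovered to ~1e-12
relative error; the reported R² is the nonlinear pseudo-R²
1 − SS_res/SS_tot about the mean empirical γ. An all-zero variogram (empty
or constant mask) is a degenerate pattern and raises an error rather than
producing a meaningless fit; non-convergence returns the fit flagged with
a warning.

## Morphometry conventions

Lesion counting uses 26-connectivity by default (the common bright-
foreground convention in neuroimaging; 6 and 18 are exposed as options).
Surface area counts exposed voxel faces (2.25 mm² per face on the 1.5 mm
grid), including faces on the array boundary; face counting is exact and
directly testable against enumeration, unlike mesh-based areas which
depend on the triangulation. Absolute surface values therefore follow the
voxel-face convention and are larger than mesh areas for the same object;
ratios between patterns are unaffected.

## Summaries

Mean center and standard distance are computed on (ln a, ln c), the
coordinates of the a–c plot: both marginals are close to normal on the log
scale across realistic cohorts, and the plot itself is log-scaled, so the
SD annotates distances the reader actually sees. A coincident triple
returns SD = 0 exactly. SD symbol classes default to batch quartiles (four
classes) and accept fixed thresholds in configuration.

The TLL nomogram has two modes. The analytic default inverts the small-p
indicator-variance identity c ≈ p(1−p) ≈ p, giving V ≈ c̄·N·v (N voxels of
volume v). Because the exponential fit slightly overshoots the empirical
plateau, the analytic estimate runs high by roughly 10–15% for sphere-like
patterns (worse for strongly elongated lesions); the cohort-calibrated
mode regresses volume on fitted sill over a batch (R² ≈ 0.997 on the
synthetic cohort) and eliminates that bias where a cohort is available.

## Synthetic data

The generator produces unions of non-overlapping ellipsoids, voxelized by
center inclusion, on the 121×145×121 / 1.5 mm reference grid by default.
It emulates the gross geometry of normalized MS-lesion masks: 1 to a few
hundred compact lesions, total volumes 200–50,000 mm³ drawn log-normally
(real lesion-volume distributions are log-normally skewed), a configurable
fraction of axis-stretched lesions (default stretch (1,1,3), volume-
normalized so anisotropy does not change per-lesion volume), and a default
3 mm lesion radius so that cohort volume is controlled by lesion count at
fixed shape statistics — the regime in which sill ∝ volume is exact.
Lesion surfaces keep a 15 mm margin from the array boundary, as real
lesions do inside the MNI array; this also keeps directionally truncated
edge pairs from biasing the variograms. What the generator does *not*
emulate: anatomical predilection sites, confluent lesion shapes, irregular
surfaces, partial-volume fuzz. Passing tests therefore validate the
estimator and its documented properties, not segmentation realism.

Two placement refinements serve isotropy experiments: `snap_centers`
rounds centers to the voxel lattice so every equal-sized lesion is
voxelized identically (removing sub-voxel aliasing anisotropy, which for
random offsets leaves a ~5–10% spread in fitted directional ranges), and
`min_separation_mm` above the cutoff removes inter-lesion cross-pair
correlation. Under those settings the residual directional-range spread is
≈ 1.8% — a deterministic floor caused by the unequal axis lengths of the
reference grid (the (L−k)·A pair-count normalization differs slightly per
axis), not by randomness.

The aliasing probes (1–3 lesions of 1–4 voxels) exercise the documented
failure mode of the method at very small lesion loads: patterns under 16
foreground voxels trigger a warning, since their fitted parameters and SD
are unstable by construction.

## Numerical and degenerate-input choices

- Variogram arithmetic is integer mismatch counting divided by exact pair
  counts; the fast shifted-array estimator is bit-identical to literal
  pair enumeration.
- Binary validation is strict by default; lenient mode rounds values
  within 1e-3 of {0, 1} and rejects anything else.
- Anisotropic voxel spacing is accepted with a warning (per-axis lag
  distances then differ; directional ranges are not directly comparable).
- Follow-up mode requires strictly ascending exam dates and at least two
  exams; duplicate (id, date) manifest rows are rejected.
- Figures are rendered deterministically (fixed SVG hash salt, stripped
  date metadata); every figure writes a sidecar CSV containing exactly the
  plotted coordinates.

## Problem sizes

The test suite and the acceptance script generate all data at run time:
a 50-pattern cohort on the full reference grid for the sill–volume
regression, 20 matched isotropic/stretched pairs for anisotropy ordering,
100 (suite) / 30 (script) small random masks for oracle equivalence, and a
12-pattern radius sweep for the range–smoothness correlation. The whole
suite runs in well under a minute on one CPU.

## Known limitations

- Two-point statistics cannot distinguish patterns with identical
  second-order structure but different higher-order geometry; the 15 mm
  cutoff additionally discards long-range information (lesion layout,
  hole effects).
- The analytic TLL mapping inherits the fit's plateau overshoot (see
  above); use cohort calibration when absolute volumes matter.
- Only axis-aligned directions are estimated; oblique anisotropy projects
  onto the three axes and is underestimated.
- Patterns whose lesions are large relative to the cutoff (range beyond
  ~15 mm) leave the sill poorly constrained; the bounded fit still
  converges but c inherits extrapolation uncertainty.
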