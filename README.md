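# lesionvario

Geostatistical characterization of binary lesion patterns from 3D MRI.

White-matter lesions in multiple sclerosis vary enormously between patients
— in number, total volume, shape and orientation — and summarizing a whole
lesion *pattern* (all lesions seen in one exam) with a few interpretable
numbers is hard. When lesion masks are binarized and normalized to a common
space (e.g. the MNI grid, 121×145×121 voxels at 1.5 mm), every exam lives
on the same fixed voxel support, and tools from geostatistics apply
directly. This package implements that approach for neuroimaging
researchers: it turns a binary lesion mask into three directional variogram
curves, two fitted parameters per direction, and a single point (with an
anisotropy measure) in a standardized scatter plot that supports
cross-sectional and longitudinal comparison.

## The method

For a binary field *z*(**x**) ∈ {0, 1} the empirical (indicator) variogram
at lag **h** is

    γ(h) = 1 / (2 n(h)) · Σ [z(xᵢ) − z(xᵢ + h)]²,

half the fraction of voxel pairs at separation **h** that disagree. It is
estimated along the three grid axes — X (dextral–sinistral), Y
(caudal–rostral), Z (dorsal–ventral) — at integer multiples of the voxel
spacing up to a 15 mm cutoff, the window that carries lesion-scale
correlation structure. An exponential variogram model

    γ(h) = c · (1 − e^(−3·|h| / a))

is fitted per direction by least squares. The **range** *a* (mm) is the
practical correlation length — larger *a* means larger, smoother lesions —
and the **sill** *c* is the plateau semivariance, which for a binary
pattern with foreground fraction *p* approaches the indicator variance
*p*(1 − *p*) ≈ *p*, making *c* a proxy for total lesion load (TLL).
Direction-dependent ranges at a common sill (geometric anisotropy) reveal
lesion elongation along specific axes.

Each pattern's three (ln *a*, ln *c*) points are reduced to their **mean
center** and **standard distance**

    SD = √( Σᵢ(aᵢ − ā)²/n + Σᵢ(cᵢ − c̄)²/n ),    n = 3,

zero for a perfectly isotropic pattern. Two plots summarize cohorts: the
**a–c plot** (one symbol per axis per pattern, ln-scaled) and the **lesion
pattern discrimination plot (LDP)** — mean centers classed by SD, with a
secondary axis translating ln *c* into TLL (mm³). Classical morphometry
(lesion count, volume, face-counted surface area, and their ratios)
cross-checks the geostatistical parameters: *c* is linear in total volume
and ln *a* tracks ln(volume/surface), a pattern-smoothness measure.

## Worked example

```python
from lesionvario import SyntheticSpec, make_pattern, fit_all, morphometry, summarize

mask = make_pattern(SyntheticSpec(n_lesions=20, radius_mm=3.0, seed=7, id="demo"))
rep = morphometry(mask)
print(f"lesions: {rep.n_lesions}   volume: {rep.total_volume_mm3:.0f} mm^3   "
      f"surface: {rep.total_surface_mm2:.0f} mm^2")

fits = fit_all(mask, cutoff_mm=15.0)
for f in fits:
    print(f"axis {f.axis}: a = {f.a:5.2f} mm   c = {f.c:.5f}   R^2 = {f.r2:.3f}")

s = summarize(fits, mask.grid, pattern_id=mask.id)
print(f"mean center: (ln a, ln c) = ({s.mean_ln_a:.3f}, {s.mean_ln_c:.3f})")
print(f"standard distance: {s.sd:.4f}")
print(f"TLL estimate: {s.tll_estimate_mm3:.0f} mm^3 (true {mask.volume_mm3:.0f})")
```

Output:

```
lesions: 20   volume: 2268 mm^3   surface: 3321 mm^2
axis X: a =  8.48 mm   c = 0.00035   R^2 = 0.966
axis Y: a =  8.31 mm   c = 0.00035   R^2 = 0.967
axis Z: a =  8.71 mm   c = 0.00035   R^2 = 0.970
mean center: (ln a, ln c) = (2.140, -7.961)
standard distance: 0.0202
TLL estimate: 2499 mm^3 (true 2268)
```

Twenty spherical 3 mm lesions on the MNI grid: the three ranges agree
within ~5% and the standard distance is near zero (isotropy); the three
sills are equal to three decimals and the analytic sill→volume mapping
recovers the true lesion load within ~10%. A Z-stretched pattern would
instead show a_Z well above a_X, a_Y and an elevated SD.

## Command line

```bash
lesionvario simulate --n-patterns 20 --seed 1 --outdir cohort/
lesionvario batch cohort/manifest.csv --outdir results/     # tables + a-c plot + LDP
lesionvario single cohort/syn_000_iso.nii.gz                # one pattern
lesionvario followup exams.csv --outdir results/            # dated series + LDP path
```

All tabular outputs are CSV; figures are SVG/PNG with a sidecar CSV holding
exactly the plotted coordinates.

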