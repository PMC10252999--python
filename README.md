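# vesseliq

Objective and subjective image-quality analysis for coronary CT angiography
(CCTA) reconstruction grids — built for imaging scientists who need to
compare reconstruction kernels and sharpness levels quantitatively, and for
anyone validating such a comparison pipeline without access to patient data.

Modern photon-counting CT scanners reconstruct each CCTA acquisition with
several convolution kernels (Br = body regular, Bv = body vascular,
Qr = quantum regular) at several sharpness levels (36–48), trading spatial
resolution against noise. `vesseliq` implements the standard measurement
stack for choosing among them:

- **ROI metrics** — mean attenuation (HU) and image noise (SD) over circular
  ROIs placed in physical mm coordinates, and the contrast-to-noise ratio

  ```
  CNR = (HU_coronary − HU_fat) / SD_coronary
  ```

- **Vessel sharpness** — attenuation profiles sampled perpendicular to the
  vessel wall are fitted with a double-sigmoid pulse

  ```
  S(x) = b + A · [ 1/(1 + e^(−s(x−x₁)))  −  1/(1 + e^(−s(x−x₂))) ]
  ```

  by bounded nonlinear least squares; the shared slope `s` (1/mm) is the
  vessel-sharpness readout (≈3 /mm for a soft kernel, ≈10 /mm for a sharp
  vascular kernel).

- **Statistics layer** — one-way ANOVA with Tukey HSD across kernels/levels,
  tie-corrected Kruskal–Wallis tests and median (IQR) summaries for 5-point
  Likert ratings, and inter-reader agreement as ICC(2,1) (two-way random,
  absolute agreement) with the conventional interpretation bins
  (<0.2 poor … >0.8 excellent).

- **Digital vessel phantom** — since clinical DICOM data are rarely
  shareable, a generator produces vessel cross-section images with known
  ground truth: anti-aliased disks (≈800 HU lumen in −80 HU fat) blurred by
  a kernel-specific Gaussian PSF and corrupted by kernel-specific white
  noise, over the full 12-cell (3 kernels × 4 levels) grid, plus two-reader
  Likert tables from a latent-quality ordinal model. Everything is exactly
  reproducible from a seed.

## Worked example

```
python examples/fit_vessel_sharpness.py
```

```
baseline  b  =    -91.6 HU   (true  -80)
amplitude A  =    888.1 HU   (true  880)
sharpness s  =     4.98 /mm  (true  5.00)
edges x1, x2 = -0.02,  3.01 mm (true 0, 3)
rmse 34.7 HU, converged: True
```

A profile crossing a 3 mm vessel was synthesized with edge slope 5 /mm and
40 HU noise; the fit recovers the slope within half a percent. The rmse
(≈ the injected noise) and the `converged` flag are the fit diagnostics.

Cohort-level comparison over the full reconstruction grid
(`python examples/kernel_grid_comparison.py`, 8 simulated subjects):

```
cell      atten   noise    CNR  sharp
Br36      750.5    37.6   19.5   3.24
Br48      812.3    77.4   11.2   4.39
Bv36      802.3    37.9   25.1   5.08
Bv48      814.8    77.2   12.4   6.99
Qr36      723.6    36.8   20.4   3.37
Qr48      774.5    90.7   10.1   4.51
...
Trend checks across the grid: {'noise_increases_with_level': True,
'cnr_decreases_with_level': True, 'sharpness_increases_with_level': True,
'bv_sharpest_at_every_level': True}
```

Within every family, raising the sharpness level increases noise and
fitted vessel sharpness while CNR falls, and the vascular kernel is the
sharpest at every level — the trade-off that drives kernel selection.
`examples/roi_metrics_cnr.py` and `examples/reader_agreement.py` walk
through the ROI/CNR layer and the Likert/ICC layer in the same style.

A thin CLI wraps the same pipeline:

```
vesseliq simulate --seed 1 --out run1        # phantom cohort + full analysis
vesseliq measure  --config run.yaml --out m1 # your volumes + one ROI config
```

Each run writes `metrics.csv`, `fits.csv`, `ratings.csv`, per-cell
summaries, a formatted `report.txt`, and a `manifest.json` with SHA-256
hashes of every artifact.

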