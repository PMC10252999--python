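# Methods

## The measurement problem

Reconstructing one coronary CT angiography (CCTA) acquisition with three
kernel families (Br, Bv, Qr) at four sharpness levels (36/40/44/48) yields
12 images of the same anatomy that differ only in their resolution/noise
trade-off. `vesseliq` quantifies that trade-off per reconstruction with
four objective readouts — mean lumen attenuation, image noise, CNR, vessel
sharpness — plus ordinal reader scores, and compares the 12 cells
statistically.

## Vessel sharpness: the double-sigmoid edge model

An attenuation profile sampled perpendicular to a contrast-filled vessel is
a bright pulse: fat baseline, rising wall, lumen plateau, falling wall. It
is modelled as

    S(x) = b + A · [σ(s(x − x₁)) − σ(s(x − x₂))],   σ(t) = 1/(1 + e^(−t))

with baseline `b` (HU), amplitude `A` (HU), edge centres `x₁ < x₂` (mm) and
one shared slope `s` (1/mm). `s` is the sharpness readout; both edges share
it because a reconstruction kernel blurs both walls identically.
Assumptions: a single vessel in the profile window (no calcified plaque or
neighbouring structure), and symmetric edge response — adequate for clean
lumen crossings, wrong for multi-edge profiles, which are out of scope.

Fitting is bounded least squares (plain L2 loss, no weighting):

- parameterisation `(b, A, s, x₁, w)` with `x₂ = x₁ + e^w`, which enforces
  `x₁ < x₂` structurally instead of via a constraint;
- bounds `s ∈ (0, 100]` /mm (100 /mm is far sharper than any CT
  reconstruction resolves at 0.1 mm sampling); `w ∈ [−20, 20]`;
- gradient/step tolerances 1e-10, so noiseless round trips recover
  parameters to ~1e-12 relative error;
- the logistic is evaluated with the numerically stable `expit`, whose
  exponent saturates in double precision, preserving exact asymptotes;
- non-convergence sets a flag on the result rather than raising; summaries
  exclude flagged fits and report how many were excluded.

Initialization is heuristic: baseline from the outer 10% of samples on each
side, amplitude from the peak, edge centres from the first/last
half-maximum crossings (linear interpolation between samples), and
`s₀ = 4·max|∇y|/A₀`, which maps the steepest observed finite-difference
slope to the logistic's maximal slope `A·s/4`. A profile whose maximum does
not exceed both endpoints has no pulse shape and is rejected by name.

Profiles default to 0.1 mm sampling with 4–5 mm half-length: ≥10 samples
across the sharpest expected edge (s ≈ 10 /mm) and ample baseline on both
sides. Profile extraction uses bilinear interpolation in physical
coordinates (pixel (i, j) centre at ((i+0.5)·Δ, (j+0.5)·Δ), 0-based), which
is exact for affine intensity fields.

## ROI metrics

Attenuation and noise are the mean and sample SD (n−1) over pixels whose
centres fall inside a circular ROI — the pixel-centre rule matches the
circular-ROI semantics of the common measurement tools, and ROIs are
specified in mm so a single configuration applies unchanged to every
reconstruction of a subject. CNR uses the coronary ROI's own SD in the
denominator, exactly as the formula above prescribes; the fat-ROI SD is
reported separately as the "image noise" column of the summary (clinical
reports measure noise in adipose tissue). Both are computed; the summary
labels which is which. Per-cell summaries pool subjects and coronary ROIs
by default, with an optional proximal/distal split (the left main is
grouped proximal); per-site versus site-averaged sharpness aggregation is a
flag (`site_mean`), since either convention is defensible for repeated
sites per reconstruction.

## The digital phantom

Each simulated reconstruction is an analytic scene rendered on a 0.3 mm
grid: disks of lumen attenuation (default 800 HU) in fat (default −80 HU),
anti-aliased by 8×8 supersampling (a hard-thresholded disk would imprint
grid artifacts on the edge fits), convolved with an isotropic Gaussian PSF,
then corrupted with i.i.d. Gaussian noise. The subject scene holds seven
vessel cross-sections (left main 4 mm; proximal RCA/LAD/LCX 3.5 mm; distal
RCA/LAD/LCX 2 mm) and a fat reference region, so the standard 8-ROI /
6-profile-site reading layout applies to one image. Profile sites are
centred on the vessel axis so every profile is a complete
baseline–edge–plateau–edge–baseline pulse.

Per-cell kernel parameters:

- `noise_sd` (HU): 37.9/50.5/72.4/79.3 (Br), 38.0/48.8/71.3/78.1 (Bv),
  37.4/48.0/70.6/90.8 (Qr) for levels 36→48 — the noise scale of a clinical
  photon-counting CCTA protocol, strictly increasing with level.
- `psf_sigma` (mm): calibrated by root finding so the noiseless pipeline's
  mean fitted sharpness per cell equals 3.2/3.8/4.0/4.4 (Br),
  5.1/5.8/6.5/6.9 (Bv), 3.3/3.7/4.0/4.4 (Qr) /mm — clinically observed
  values, ordered Bv > Br ≈ Qr and increasing with level. Result: 0.482/
  0.397/0.375/0.336 (Br), 0.282/0.241/0.208/0.192 (Bv), 0.465/0.410/0.375/
  0.336 (Qr).
- `attenuation_bias` (HU): +40 (Br), +15 (Bv), 0 (Qr), folded into the
  lumen value *before* blurring (equivalent to rendering a brighter disk);
  this orders mean attenuation Br > Bv > Qr without modelling spectral
  physics.

Noise is white (added after the PSF), so an ROI's SD estimates `noise_sd`
directly. Real CT noise is spatially correlated with a kernel-dependent
noise power spectrum; white noise is adequate for exercising the metric
layer but understates the variance of small-ROI SD estimates relative to
real images — a deliberate simplification. Likewise the phantom has no
calcifications, stents, motion, or beam-hardening, so passing trend tests
demonstrates the *measurement stack*, not clinical image quality.

One divergence from clinical experience: on the default grid the Bv family
has slightly higher CNR than Br at every level, because Br's stronger blur
erodes contrast in the small-vessel ROIs faster than its +40 HU attenuation
offset adds to it; in patients the soft-tissue kernel typically wins CNR.
The within-family monotone trends — the decision-relevant ones — are
unaffected.

## Synthetic reader ratings

Ratings follow a latent-quality ordinal model: per (subject,
reconstruction, rater, criterion), a latent value — cell quality + rater
bias + N(0, σ) noise — is cut by thresholds 1.5/2.5/3.5/4.5 into scores
1–5. Default cell qualities encode: overall quality and sharp-coronary
reproduction best for Bv at levels 36–40, perceived noise tracking the
level only. Defaults (σ = 0.15, biases 0/−0.05) put the two readers in the
substantial-to-excellent agreement range (ICC ≈ 0.76–0.91). The model has
no subject random effect, so agreement is driven entirely by
between-reconstruction differences; pushing ICC to the ≈0.95–0.98 observed
between trained readers would require latent heterogeneity across subjects
that this deliberately minimal model does not claim to represent.

## Statistics layer

- One-way ANOVA (`scipy`) with Tukey HSD post hoc (`statsmodels`).
  All-constant input is reported as degenerate (F = 0, p = 1) instead of
  propagating 0/0. The ANOVA treats repeated measurements per subject as
  independent observations — the convention of the comparison it mirrors —
  and carries that caveat.
- Kruskal–Wallis with tie correction (`scipy`); all-identical input
  reports H = 0, p = 1.
- ICC(2,1) — two-way random effects, absolute agreement, single measure —
  computed in-module from the mean-squares decomposition
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`; a table with zero
  variance everywhere is perfect agreement (ICC = 1). Interpretation bins:
  <0.2 poor, 0.2–0.4 fair, 0.4–0.6 moderate, 0.6–0.8 substantial,
  >0.8 excellent; boundary values go to the lower bin, deterministically.
- Likert summaries: median and IQR with linear-interpolation (type-7)
  quantiles, rendered "m (q1–q3)".

## Reproducibility and problem sizes

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning, so a pipeline run is byte-identical
across repeats, and a `manifest.json` of SHA-256 hashes accompanies every
run. Default cohort size is 30 subjects (a realistic single-centre study);
the test suite exercises the grid-trend property over 20 cohort seeds at
that size and smaller cohorts elsewhere, and validates the noisy-recovery
claim with 200 replicates at 40 HU noise against a 0.01-resolution
grid-search oracle on a subset.

## Known limitations

- No DICOM ingestion; volumes enter as NIfTI or NPY + JSON sidecar.
- 2D analysis plane: 3D volumes are sliced before measurement.
- No automatic vessel segmentation or ROI placement; configurations are
  authored by the user (or the phantom's defaults).
- The phantom does not emulate iterative-reconstruction nonlinearity,
  spectral imaging, correlated noise, or pathology.
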