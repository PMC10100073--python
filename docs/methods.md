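# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `coce` pipeline.

## Forward model (phantom simulator)

**Geometry.** A B-scan plane of `depth_px × lateral_px` pixels (default
4 µm pitch in both directions; 500 × 512 px ≈ 2.0 × 2.0 mm, capped at the
2 mm scanning depth of the emulated instrument). The reference silicone
layer occupies exactly the topmost rows (default 300 µm); tissue shapes
(rectangles/ellipses, in microns, z measured from the silicone–tissue
interface) are rasterized by pixel-center membership, later shapes
overwriting earlier ones.

**Mechanics.** Each mechanical class carries a zero-stress tangent modulus
`E0` (kPa) and a dimensionless stiffening rate `β` with
`E_t(σ) = E0 + β·σ` — the simplest law producing the pronounced
nonlinearity of soft-tissue stress–strain curves. Mechanics is a 1-D
series stack per lateral column: every pixel carries the full applied
stress, so the cumulative strain has the closed form
`ε(σ) = ln(1 + βσ/E0)/β` (→ `σ/E0` for linear material). Lateral
coupling, silicone–probe stiction and silicone thinning under compression
are neglected; this is exactly the regime the reference-layer calibration
assumes. Compression is applied from the top and compressive strain is
positive throughout the codebase. Non-scattering mucin pockets get a
nominal effective modulus of 150 kPa solely so that the displacement of
material beneath them is bookkept; they contribute no signal.

**Optics.** Fully developed speckle: a circular-Gaussian scatterer field
scaled by each class's backscatter amplitude (silicone 0.8, tissue 1.0,
mucin 0.0), blurred by a Gaussian PSF of 15 µm axial × 25 µm lateral FWHM
(1310 nm instrument). The speckle realization is frozen across frames and
only the phase advances, by `(4πn/λ)·u(z)` with `u` the running depth
integral of strain — so interframe decorrelation comes only from strain
and additive noise, matching the assumption of the phase-resolved
estimator. Complex white Gaussian noise is added per frame at `snr_db`
(default 25 dB) relative to mean signal power. The refractive index is
not a measured instrument property here; n = 1.4 (typical soft tissue) is
the configurable default.

**Loading.** Stress rises linearly from 0 to `max_stress_kPa` (default
6 kPa) over `n_frames` (default 100, the typical protocol). The simulator
refuses protocols in which any signal pixel's interframe strain would
exceed 1%, the tracking limit of the estimator.

**What the generator does not emulate.** Scatterer advection and
strain-induced speckle decorrelation, depth-dependent attenuation and
focus, lateral tissue motion, probe tilt, silicone thickness change, and
3-D effects. Passing tests therefore demonstrate correctness of the
*processing chain* under its own stated assumptions, not robustness to
every artifact of real acquisitions.

## Strain estimation

The interframe field is `conj(a)·b`. The vector method forms axial lag
products `P(z) = conj(F(z))·F(z+ℓ)` (default lag ℓ = 3 px = 12 µm),
averages them as complex numbers over a rectangular window — default
100 × 100 µm, the upper end of the 80–100 µm range used in practice — and
takes the phase last: `ε = arg⟨P⟩·λ/(4πnℓΔz)`. Strong-signal pixels
dominate the average through their amplitude; incoherent (noise-only)
phases cancel vectorially.

Validity: a pixel is invalid where `|⟨P⟩|` falls below 0.25 of the window
mean lag-product amplitude (this mirrors non-signal dropout without a
separate SNR channel), or where less than half the window is in-image
(windows are truncated at borders, never padded). The working range is
~1% strain per frame pair — the per-lag phase increment stays inside
(−π, π] up to `ε ≈ λ/(8nℓΔz) ≈ 1.9%` at the defaults — and the achieved
resolution is about half the window (a sharp strain step spreads to a
≤50 µm 25–75% transition under a 100 µm window).

Cumulative strain is the running pixelwise sum of interframe estimates in
the *lab frame*, without re-registering pixels between frames; the bias
this introduces is second order for the ≤10% total strains used here and
is absorbed by the stated tolerances. Random errors add in quadrature
while strain adds linearly, so the relative noise of the cumulative strain
falls along the series.

## Stress calibration and tangent modulus

Applied stress per frame is `E_sil` times the mean cumulative strain over
the interior silicone rows (eroded by half a window plus the lag from both
the probe window and the tissue interface, where averaging mixes
materials), estimated per lateral column by default; a config switch
(`per_column_stress=False`) gives frame-global stress. This per-column
estimate is a simplified stand-in for full local-stress standardization.

The tangent modulus at the standardized 4 kPa stress is the secant
`Δσ/Δε` between the frames where the column's stress first crosses 3 and
5 kPa, interpolated linearly *in stress* (ties toward the earlier frame).
For the affine law the secant at the 3–5 kPa window differs from the true
tangent at 4 kPa only at second order. Pixels are masked where the strain
increment is non-positive, the record was invalid in >30% of frames, or
the recovered modulus exceeds 5 000 kPa (far beyond any observed tissue
value; treated as an artifact). A run whose stress never reaches 5 kPa is
an error ("insufficient compression") rather than a silently truncated
window.

## Segmentation and subtype rules

Class boundaries (kPa, configurable): signal floor 1, stroma 92–515
(values in the printed 515–520 gap are assigned to stroma — conservative
toward fewer false cancer calls), cancer-gland 520–950 (upper bound
inclusive), very-high >950. Masked pixels are non-signal.

Image-level features:

* **has_520_950 / has_gt950** — at least one 8-connected component of that
  class covering one full analysis ROI (110 × 110 µm ≈ a 7 × 7 speckle
  block); single-pixel outliers never flag a class.
* **has_gland_like** — ≥2 cancer-gland components of ≥ROI size covering
  together <70% of the signal area: discrete stiff nests in a softer
  background, as opposed to the contiguous stiff field of high-grade
  tumors. The paper-style description gives no numeric rule; these three
  constants are config keys.
* **nonsignal_fraction** — non-signal pixels over total pixels in the
  tissue rows within 500 µm of the silicone–tissue interface (fraction of
  *total* ROI area, the reading consistent with the ≥50%-of-tissue-area
  mucinous criterion; the depth limit is measured from the interface, not
  the image top). Fractions below 2% (`loss_floor`) are reported as zero:
  isolated dropouts are estimator noise, not lumina.

Decision table, evaluated in order: no cancer-range class → NON_CANCEROUS;
loss > 50% → MAC if very-high stiffness present without gland-like
architecture, else INDETERMINATE (conflicting evidence is surfaced, never
coerced); 0 < loss ≤ 50% with gland-like nests and no very-high class →
cribriform; gland-like without very-high and without loss → low-grade;
very-high without gland-like and without loss → high-grade; everything
else INDETERMINATE. A sample is *flagged cancerous* when one full ROI of
contiguous ≥520 kPa pixels exists anywhere in the tissue.

## Agreement statistics

Pearson r with the t-transform p-value; Bland–Altman bias and 95% limits
of agreement using sample SD (n−1) and the 1.96 large-sample multiplier
(exact-t multiplier behind a flag); one-tailed two-sample Student's t with
pooled variance (Welch behind a flag; zero-variance ties return p = 0.5 by
convention). Summaries print as `mean ± SD [min; max]` — the form every
printed instance of the source material actually uses, although its label
reads "[Max.; Min.]". `run_agreement_experiment` accepts any ≥3 pairs
(`min_samples` configurable) and emits the per-sample CSV, a JSON of the
statistics, and scatter/Bland–Altman plots.

## Cohort templates

`make_cohort` draws subtypes from a mix (default 20% normal, 10% adenoma,
30% low-grade, 20% high-grade, 10% cribriform, 10% MAC) and realizes each
as geometry: mucosa 58 kPa or adenoma 46 kPa backgrounds; stroma 295 kPa
with gland nests 724 kPa (low-grade); a solid 954 kPa field (high-grade);
wide-lumen 724 kPa rings with non-scattering centers (cribriform); mucin
fields covering most of the shallow 500 µm band plus a small 954 kPa nest
(MAC). Mild stiffening rates (β = 1–10) keep each class inside its
stiffness range at 4 kPa. Cancer-area targets are spread over the
requested range, clipped to what each template's geometry can tile; the
exported truth percentages are recounted from the rasterized label maps.
Cohort acquisitions default to 350 × 320 px grids and 60 frames to 6 kPa —
sizes chosen so a full 30-sample cohort simulates and analyzes in a couple
of minutes on one CPU while keeping ≥100 speckle cells per structure.

## Numerical and design choices

* Seeds are explicit everywhere; no global random state is touched.
* The lag product is centered between its source rows (offset ℓ//2); the
  half-pixel asymmetry for odd lags is far below the window scale.
* Strain-at-stress interpolation is per column, vectorized over depth.
* Homogeneous-region summaries exclude a 120 µm margin below the interface
  and above the image bottom, where window truncation and material mixing
  bias the estimate.
* File formats: HDF5 for complex frame series (lossless real/imag pairs
  plus optical metadata), 32-bit float TIFF + JSON sidecar for stiffness
  and truth maps, 8-bit paletted PNG for categorical maps (white
  non-signal, red tones for soft tissue, turquoise/blue for cancer
  classes), CSV/JSON for reports. None of these is intrinsic to the
  method.

## Known limitations

* Lab-frame strain summation and frozen speckle overstate the estimator's
  real-world SNR; decorrelation-induced bias is not modeled.
* The per-column stress estimate ignores lateral stress redistribution by
  stiff inclusions; truth-vs-recovered cancer areas consequently show a
  small systematic deficit at nest borders (~50 µm blur).
* The subtype rules assume the acquisition covers representative tissue;
  sampling error across a heterogeneous tumor is out of scope.
* Thresholds are point estimates from one tissue system; they are config
  keys, not constants of nature.
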