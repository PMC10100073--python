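# coce — compression optical coherence elastography for colorectal tissue

`coce` is a Python package for **compression optical coherence elastography
(C-OCE)** analysis of colorectal tissue: it simulates complex-valued OCT
B-scan series of a reference-silicone/tissue sandwich under compression,
reconstructs maps of the tangent Young's modulus by phase-resolved strain
estimation, segments the maps into morphological tissue classes by
stiffness thresholds, calls colorectal-cancer morphological subtypes from a
small decision table, and quantifies how well the elastographic
morphometry agrees with ground truth.

It is aimed at researchers developing or validating quantitative OCE
pipelines: every processing stage is exposed as a library function, a
synthetic phantom generator provides labeled test data with exact
mechanical ground truth, and a thin CLI chains the stages together.

## The method

An axial displacement `u` of a scatterer changes the OCT phase by
`Δφ = (4πn/λ)·u`. During slow compression, consecutive complex frames are
combined pixelwise into the interframe field `conj(a)·b`, whose argument is
the interframe phase variation. The **vector method** estimates its axial
gradient — the interframe strain — without phase unwrapping: axial lag
products `P(z,x) = conj(F(z,x))·F(z+ℓ,x)` are averaged *as complex
numbers* over an 80–100 µm window and only then is the phase taken,

```
ε = arg(⟨P⟩) · λ / (4π n ℓ Δz),
```

which tolerates interframe strains up to ~1% even where the raw phase
wraps many times along depth. Summing several tens of interframe strains
gives cumulative strains at a few percent total compression.

Stress is never measured directly. A pre-calibrated, highly linear
reference silicone layer on the tissue surface reports it through Hooke's
law, `σ = E_sil · ε_sil`. Plotting `σ` against the local cumulative tissue
strain gives a per-pixel stress–strain record; because tissue is markedly
nonlinear, its slope — the **tangent Young's modulus** `E_t = dσ/dε` — is
evaluated at a standardized applied stress of 4 kPa (secant between the 3
and 5 kPa crossings).

Stiffness separates colorectal morphology: cancer cells occupy
**520–1418 kPa** (520–950 kPa for the gland-like structures of low-grade
adenocarcinoma, >950 kPa for non-glandular high-grade foci), tumor stroma
92–515 kPa, and normal mucosa/submucosa/adenoma lie below that. Mucin and
wide gland lumina return no signal. Four image-level features — presence
of the 520–950 kPa class, presence of >950 kPa, discrete gland-like stiff
nests, and the non-signal fraction of the shallow 500 µm of tissue — feed
a decision table that distinguishes non-cancerous tissue, low-grade and
high-grade adenocarcinoma, the cribriform pattern, and mucinous
adenocarcinoma (non-signal over half the shallow ROI).

## Worked example

```python
import coce

phantom = coce.template_phantom("low_grade", cancer_fraction=0.3, seed=7)
acq = coce.AcquisitionSpec(n_frames=60, max_stress_kPa=6.0, snr_db=25.0, seed=7)
series, truth = coce.simulate_compression_series(phantom, acq)

result = coce.run_sample(series)
glands = result.stiffness.values[result.class_map.classes == coce.TissueClass.CANCER_GLAND]
print("subtype call:       ", result.call.call.value)
print("cancer area (C-OCE):", f"{result.call.cancer_area_percent:.1f}%")
print("cancer area (truth):", f"{truth.cancer_area_percent:.1f}%")
print("gland-range stiffness:", coce.summarize(glands))
```

prints

```
subtype call:        LOW_GRADE_CRAC
cancer area (C-OCE): 22.8%
cancer area (truth): 28.7%
gland-range stiffness: 695.021 ± 78.6275 [520.057; 776.394]
```

The phantom embeds stiff gland nests (E₀ = 724 kPa) in softer stroma
(295 kPa); the pipeline recovers the gland-range stiffness distribution,
flags the sample as cancerous, calls the low-grade subtype from the
discrete-nest architecture, and measures the cancer area within a few
percentage points of the rasterized truth (the residual deficit comes from
the ~50 µm resolution of the strain window blurring nest borders).

The same stages are available from the shell:

```sh
coce simulate --subtype low_grade --cancer-fraction 0.3 --seed 7 --out sample.h5
coce reconstruct --series sample.h5 --out stiffness.tiff --stress 4
coce segment --stiffness stiffness.tiff --out-prefix sample
coce evaluate --cohort 30 --seed 7 --outdir results/
```

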