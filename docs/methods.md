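# Methods

This note documents the models, algorithms and design choices behind
`hsi_tta`, in the package's own terms: what is computed, under which
assumptions, and what the synthetic experiments can and cannot show.

## Problem setting

Intraoperative hyperspectral imaging (HSI) records a reflectance spectrum
per pixel (here: 100 bands, 500–995 nm at 5 nm). Organ-segmentation
networks for HSI are trained almost exclusively on well-perfused tissue.
Surgical interventions change perfusion — arterial ischemia (inflow
blocked), venous congestion (outflow blocked), avascular tissue (both) —
which changes tissue oxygen saturation (StO2) and blood volume fraction
(VHb) and thereby the spectra, so a frozen network can fail badly at
deployment. `hsi_tta` implements a test-time augmentation that corrects
such out-of-distribution (OOD) pixels *in input space*, leaving the model
untouched:

1. **Digital twin.** Every pixel spectrum is matched (exact nearest
   neighbor, Euclidean distance on L1-normalized spectra) against a large
   synthetic database of forward-simulated tissue spectra, annotating the
   image with the generative parameters (StO2, VHb, scattering, ...) of the
   matched records.
2. **OOD detection.** Pixels whose retrieved StO2 *or* VHb falls outside a
   percentile band fitted on physiological training twins are flagged
   (boundary values count as in-distribution). The default band is the
   interquartile range (25–75); a conservative 5–95 setting is available
   and `select_percentile_setting` chooses between them by validation DSC.
3. **Hybrid image.** Each flagged pixel is replaced by the L1-normalized
   mean of its real spectrum and the nearest synthetic spectrum drawn from
   a *median-constrained pool*: database records whose StO2/VHb lie within
   box tolerances (default ±0.05 / ±0.02) of the physiological medians.
   Unflagged pixels pass through bit-exact.

## Forward model

Diffuse reflectance uses the closed-form semi-infinite diffusion
approximation

    R_d = a' / (1 + 2k(1-a') + (1 + 2k/3) √(3(1-a'))),   a' = μs′/(μa+μs′),

with internal-reflection factor `k = (1+r_id)/(1-r_id)` and the empirical
fit `r_id = -1.440 n⁻² + 0.710 n⁻¹ + 0.668 + 0.0636 n`. A Monte Carlo
photon-transport simulation would be more faithful near boundaries and for
layered media, but the diffusion closed form preserves exactly the
dependencies the pipeline exploits — R decreases monotonically in
absorption, increases in reduced scattering, and depends on the refractive
index through boundary reflection — while being deterministic and fast
enough to build 10^5-record databases in seconds.

Absorption is a linear chromophore mix,

    μa(λ) = VHb · C_hb · ln10 · (StO2 · ε_HbO2(λ) + (1-StO2) · ε_Hb(λ))
            + w_water · μa_water(λ),

with C_hb = 150 g/L ÷ 64500 g/mol (whole-blood hemoglobin molarity), so
VHb reads directly as a blood volume fraction. Reduced scattering follows
the Mie power law `μs′(λ) = μs′(500) · (λ/500)^(-b)`.

Parameter ranges (uniform, independent in the database): StO2 0–1,
VHb 0–0.3, μs′(500) 5–50 cm⁻¹, scattering power 0.3–3, anisotropy
0.8–0.95, refractive index 1.33–1.54, thickness 0.002–0.2 cm, water
0.8–0.9. Anisotropy and thickness are carried in the parameter vector for
fidelity to the full simulation parameter set but are not consumed by the
diffusion model (scattering enters already reduced; the layer is treated
as optically thick). A layered extension would slot in behind the same
`diffuse_reflectance` surface.

### Chromophore table

The bundled table (`data/chromophores_synthetic.tsv`) is a **synthetic
stand-in** for digitized literature extinction curves: sums of Gaussian
bands reproducing the qualitative features of the real chromophores
(Soret bands near 414/432 nm, the HbO2 alpha/beta doublet at 541/577 nm,
the Hb bands at 556 and 760 nm, the NIR crossover, the 970 nm water peak).
At each crossing of the two extinction curves the nearest grid point is
snapped to exact equality, so isosbestic wavelengths (514, 544, 572, 592,
870 nm in 500–995) are exact grid points and StO2-invariance there is an
exact, testable property. Absolute magnitudes are calibrated to give
physiological absorption (a few cm⁻¹ at VHb ≈ 0.05 in the visible), but
the table is not suitable for quantitative oximetry of real data.

### Camera twin

The 100-band camera is modeled per band as a response-weighted average on
the 2 nm simulation grid (300–1000 nm, 351 points). The default response
is a 5 nm boxcar centered on each band (the simplest shape consistent
with a 5 nm sampling pitch); a Gaussian response with FWHM equal to the
band width is available. Band weights are renormalized after truncation
at the grid edge. Resampling is linear, so the twin commutes with linear
combinations of spectra (tested to 1e-12).

## Retrieval

The nearest-neighbor index is an exact chunked brute-force search: squared
distances from the norm expansion evaluated with BLAS in memory-bounded
chunks, `argmin` per query (NumPy's first-minimum rule gives a
deterministic lowest-id tie-break), and the final distance recomputed
exactly for the selected pair. Approximate indexes were deliberately
avoided — exactness is part of the contract and 100-dimensional spaces
defeat KD-trees anyway. Searching happens in camera space on L1-normalized
spectra because that is the space real pixels live in and the input
convention of the frozen model; both the metric and the space are recorded
in the database metadata.

With the default forward model, 1,000 noiseless queries against a
100,000-record database recover StO2 with a median absolute error well
below 0.05 (the acceptance script recomputes this). Recovery degrades
gracefully with sparser databases; a property test asserts the
improvement with density.

## Synthetic scenes

Because the in vivo data the method targets is not public, `scene_sim`
generates labeled stand-in scenes entirely from the forward model. The
default scene (32×32) has three classes:

| class | StO2 | VHb | μs′(500) | b | role |
|---|---|---|---|---|---|
| background | 0.40–0.90 | 0.01–0.05 | 15–35 | 0.3–0.9 | connective-tissue analog |
| kidney analog | 0.55–0.85 | 0.03–0.10 | 10–25 | 1.8–2.6 | target organ (ellipse) |
| vein analog | 0.25–0.50 | 0.10–0.25 | 30–50 | 0.3–0.6 | blood-rich failure sink |

Class identity is deliberately carried by scattering, which perfusion
manipulation does not touch, while perfusion state is carried by
StO2/VHb. This mirrors the clinical failure mechanism: a congested kidney
spectrally approaches venous blood, an ischemic one approaches poorly
vascularized tissue — and it is what makes input-space correction
possible at all, because the constrained nearest-neighbor replacement
preserves the scattering signature while restoring median perfusion.

The four states modify only the target organ's StO2/VHb ranges:
physiological 0.55–0.85 / 0.03–0.10, avascular 0.00–0.15 / 0.02–0.08,
arterial ischemia 0.00–0.15 / 0.01–0.05, venous congestion 0.00–0.20 /
0.12–0.30. Within every class StO2 and VHb are coupled by a Gaussian
copula (ρ = 0.5): better-perfused tissue tends to be better oxygenated.
Besides realism, this coupling matters statistically — with the OR rule
over two exactly-50% marginal exceedances, independent parameters would
put the resubstitution OOD fraction exactly at 75%; physiological
correlation keeps it comfortably inside (50%, 75%).

Subjects differ through per-state sub-intervals: the StO2/VHb sampling
interval shrinks to 70% of the state range and slides within it, drawn
once per subject, so images of a subject share physiology and all true
parameters stay inside the declared state ranges. Sensor noise is
multiplicative Gaussian (relative SD 0.02, clipped at zero, then
re-normalized) — a simple, seedable stand-in that does not model striping,
specular highlights or motion.

**What the scenes do not emulate:** real organ texture and shape, mixed
pixels at organ boundaries, specularities, chromophores beyond
hemoglobin and water (bile, fat, cytochromes), and the layered anatomy of
real organs. Passing end-to-end tests therefore demonstrates that the
pipeline's machinery behaves as designed under controlled shift, not that
it reaches any particular accuracy on real surgical data.

## Frozen model

The deployed network is out of scope; its *contract* — frozen,
spectra in, labels out — is filled by a pixel-wise nearest-centroid
classifier on L1-normalized spectra (default), with a regularized LDA
(lsqr, automatic shrinkage) as an alternative. Nearest-centroid was chosen
as the default after comparing both: its failure under perfusion shift is
large and interpretable (malperfused kidney pixels migrate to the vein or
background centroid), while LDA's shrunken decision boundary happened to
be insensitive to the low-blood states, giving a less representative
shift. Models serialize to HDF5 and a content hash asserts immutability
across the pipeline.

## Evaluation

DSC is the standard `2|P∩R| / (|P|+|R|)` per image and organ, with the
both-empty convention fixed at 1. Aggregation is hierarchical: mean over
images within subject, then over subjects, per organ — so subjects with
many images do not dominate. The overall score used for percentile
selection is the mean of per-organ hierarchical scores.

Domain gaps are measured on per-image median organ spectra: one PCA
(2 components) fitted on the union of original and augmented spectra of
all states, Gaussian KDE (Scott bandwidth) per state on the plane, and
the Euclidean distance between each state's embedded mean and the
physiological mean, before and after augmentation.

## Problem sizes and numerical choices

The default end-to-end configuration — 50,000-record database, 12 subjects
split 7 training / 5 held-out, 2 images per subject and state, 32×32
scenes — is the package's chosen study scale: large enough that the
replacement pool at the default tolerances holds several hundred records
(sparser pools visibly degrade the congestion recovery) and that DSC
aggregates are stable, small enough for a desk run. Percentiles use
NumPy's linear interpolation between order statistics. Ties in the
nearest-neighbor search break to the lowest record id. Empty replacement
pools widen tolerances by doubling until nonempty (logged). Degenerate
inputs (all-zero spectra, empty masks, non-finite pixels) raise typed
errors naming the offending entity.

## Known limitations

* The diffusion approximation is inaccurate for high absorption
  (μa ≈ μs′), short source–detector separations and thin layers; the
  database inherits these biases consistently on both the database and
  scene side, which flatters retrieval relative to real data.
* The synthetic chromophore table is qualitative; absolute StO2/VHb
  retrieved from real spectra with it would be biased.
* StO2/VHb retrieval is ill-posed at very low VHb (no blood, no
  saturation signal); median statistics absorb this, per-pixel values at
  VHb < 0.01 are unreliable.
* The hybrid average moves an OOD pixel only halfway toward the
  physiological manifold; severely shifted states (venous congestion)
  recover partially, consistent with correction in input space rather
  than retraining.
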