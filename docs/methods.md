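# Methods

`holoassay` implements a label-free cytotoxicity assay based on quantitative
phase imaging (QPI) with off-axis digital holographic microscopy (DHM), from
raw interferograms to the three biological readouts: temporal dry-mass
development, the 12-h dry-mass increment (DMI), and the fraction of rounded
cells. Because no raw image data from such assays is publicly deposited, the
package includes a first-class synthetic-data module that emulates the
acquisition and the cell biology, providing a complete ground-truth manifest
against which every downstream stage is validated.

## Physical model

**Hologram formation.** Each recorded frame is the scalar two-beam
interference intensity |R·e^{2πi f·r} + e^{iφ(r)}|², with a tilted plane
reference at carrier frequency **f** (default: diagonal, Nyquist/3 per axis)
and a unit-amplitude object wave carrying the specimen phase φ. The object
phase is the sum of the cell phase, a smooth instrument background (random
tilt + curvature, scale 0.3 rad), and a per-frame parasitic sinusoidal
pattern (amplitude 0.08 rad, ~0.01 cycles/µm) standing in for
coherence-induced disturbances from internal reflections. Seven frames per
position and time point share the cell phase and instrument background but
carry frame-decorrelated parasitic patterns, emulating acquisition under
modulated illumination. Shot noise is Gaussian with σ = 0.05·√I per pixel
(≈ 2000–4000 detected photons per pixel), and optional free-space defocus is
applied by angular-spectrum propagation. This is deliberately a scalar,
fully coherent model: no partial coherence, no vectorial effects, no
bright-field channel.

**Geometry.** The field of view is 450 µm × 338 µm (λ = 532 nm); the full
sensor grid is 1024 × 770. Most studies in this package run on a 512 × 384
grid over the same physical FOV (pixel pitch 0.88 µm), which keeps a six-arm,
20-FOV-per-condition recovery study to a few minutes while leaving >500
pixels per cell. The coarser grid lowers the carrier and hence the usable
sideband: the demodulation passband is ≈ 0.11 cycles/µm, i.e. a spatial
resolution of roughly 5 µm. Consequences of this band limit are handled
explicitly (see *Validation phantoms* and *Filter choice*).

**Dry mass.** Population dry mass follows dm = λ/(2πα)·Δφ̄·S with
α = 0.19 µm³/pg (equivalently 0.19 mL/g, the specific refractive increment
of cellular protein) and Δφ̄ the mean phase over valid pixels. Δφ̄ is taken
over the whole FOV, not only segmented cells (a masked variant exists for
sensitivity analysis), and is multiplied by the matching valid-pixel area so
that the product is the phase integral; for a fully valid frame this is
exactly Δφ̄·S_FOV, and for reconstructed frames it excludes the apodized
border strip from both factors, which would otherwise bias dm by the
invalid-area fraction. Relative dry mass subtracts the t = 0 value
(DM(t) = dm(t) − dm(0)), keeping units (ng) and making DM(12 h) identical to
DMI = dm(12 h) − dm(0 h); a ratio mode is available by flag. DMI may be
negative (cell lysis).

## Reconstruction pipeline

Per frame: (1) carrier location as the dominant spectral peak outside a DC
disc of 10% Nyquist, refined to sub-bin precision by parabolic interpolation
— the residual tilt from any remaining carrier error is absorbed by the
polynomial background stage; (2) apodization with a 10% Tukey border window;
(3) demodulation to baseband and circular low-pass filtering (radius
0.7×|carrier|, full-width cosine rolloff); (4) optional angular-spectrum
refocusing; (5)
reliability-guided 2D unwrapping (scikit-image). The seven unwrapped frames
are piston-aligned (background median) and averaged; a polynomial background
surface (default order 2) fitted iteratively to background pixels is then
subtracted, leaving a zero-median background.

**Filter choice.** The sideband filter is a raised-cosine with the rolloff
spanning the full radius (a Hann-type radial response) rather than a
mostly-flat filter with a narrow edge. A sharp-edged filter produces Gibbs
ringing at steep cell boundaries, and because the phase is the *argument* of
the filtered field, that ringing rectifies into a systematic, state-dependent
dry-mass overestimate of ~3% — enough to corrupt DMI, which is a small
difference of large numbers. The full-width rolloff removes the ringing; its
radius (0.7×|carrier|) is chosen so the half-power bandwidth matches a
conventional flat-top filter of 0.35×|carrier|, because cutting the
bandwidth instead causes the opposite, blur-driven bias: the complex field
averaged over a wide kernel partially cancels across a tall cell's phase
range, and its argument then under-integrates the cell mass. The narrow-edge
variant remains available (`filter_edge_frac`) and is the better choice when
pointwise phase fidelity on band-limited structures matters more than
integral accuracy.

**Background classification.** Cells are strictly positive phase objects, so
the iterative background fit classifies asymmetrically: pixels more than 2
robust standard deviations *above* the fitted surface are cells; a wide 4σ
guard is kept on the negative side. The iteration is seeded from the
below-median half of the image, which presumes a sub-confluent FOV. When a
bimodal split assigns less than 20% of pixels to background, the fit falls
back to the border frame with a warning; blind background estimation on
near-confluent FOVs is not reliable and such data should be compensated
against a reference (empty-well) hologram instead — not modelled here.

**Autofocus.** Grid search with parabolic refinement on the total variation
of the amplitude over the central 80% (the apodization border carries strong
amplitude gradients with no focus information). This metric is accurate in
the weak-phase regime; for strong phase objects (peaks ≳ 1.5 rad) the
interplay of defocus phase contrast with the band-limit amplitude rims
shifts the minimum by up to tens of percent of the defocus. Focus-cue
strength also scales inversely with the squared feature size: structures
much larger than the resolution limit sit inside their own depth of field
and cannot be focused at all (the flat-cost warning path). The validation
phantom for refocusing therefore uses weak (≤0.6 rad) blobs near the
resolution limit.

## Morphometry

Segmentation thresholds the compensated phase (Otsu with a 0.15 rad floor by
default; fixed threshold available), fills holes, labels with
8-connectivity, and discards regions with S_cell ≤ 350 µm² (the debris
filter). Circularity C = 4π·S/P² is clipped at 1; cells with C > 0.8 count
as rounded. Touching cells are *not* split — the simulator keeps overlap
rare by construction, and threshold-based single-cell analysis of clustered
cells is a known limitation of the assay itself. Border-touching regions are
retained by default (flag available).

**Perimeter.** P is the length of the marching-squares 0.5-level contour of
the region mask after polygon simplification (tolerance 1 px), which removes
the rasterization staircase and makes the estimate orientation-independent:
discs of r ≥ 15 µm give C ≥ 0.97 converging to 1, squares give π/4 ± 0.015
at any orientation, and a 2:1 ellipse matches the Ramanujan-perimeter value
0.841. Naive pixel-edge counting would overestimate P by up to ~27% and push
circles below the C > 0.8 rule; few-direction Crofton estimators are
orientation-biased in the opposite direction (an axis-aligned square comes
out at C ≈ 0.88). For deeply concave lobed shapes the estimator still
overestimates C somewhat (0.70 vs 0.62 true for a strongly lobed 2.8:1
blob), which is acceptable here because classification only requires such
shapes to stay below 0.8.

**Region dry mass** integrates the phase over the region footprint dilated
by 2 µm (shape metrics use the undilated mask). The threshold contour cuts
the soft phase skirt at the cell edge; without the dilation the sum of
single-cell masses underestimates the whole-FOV dry mass by 6–7% on
spread-cell FOVs, with it the two agree within ~2%.

## Synthetic populations

Each FOV starts with 50 spread cells (dry mass lognormal, mean 300 pg,
CV 20%), placed by dart throwing with a minimum centroid separation of
0.7×(sum of semi-major axes) and an inset margin so cells lie wholly inside
the FOV; after bounded retries a cell is placed anyway and flagged. Spread
area tracks mass at approximately constant dry-mass surface density
(300 pg / 550 µm² ≈ 0.55 pg/µm², 10% lognormal jitter), which keeps phase
plateaus comparable across cells as in real adherent monolayers. Cells do
not migrate between timepoints.

Cell footprints are super-Gaussian profiles exp(−ln2·ρ^{2p}) on elliptical
supports modulated by 2–3 low-order boundary lobes; the half-maximum contour
encloses the nominal area, and each patch is rescaled after rasterization so
its phase integral encodes the manifest dry mass exactly. Spread cells: axis
ratio 2.6–3.8, lobe amplitudes 4–10%, p = 8 (their true circularity is
0.55–0.75, below the rounded threshold even after reconstruction blur).
Rounded cells: near-circular smooth domes (ratio ≤ 1.08), area 360–520 µm²,
p = 6, hence 2–3× higher peak phase — tall enough (up to ~4 rad for grown
cells) to exercise unwrapping. Debris fragments: 40–200 µm², always below the 350 µm²
filter.

**Dynamics** (hourly steps, hazards converted to probabilities as
1 − e^{−rate·dt}): controls grow exponentially at 0.03/h (doubling time
≈ 23 h, chosen so a control FOV gains ~6–8 ng over 12 h); each spread cell
independently appears transiently rounded with probability 0.10 per
timepoint (mitotic rounding), setting the control rounded fraction near 10%.
Dose–response is Hill-shaped per agent and effect. The cytostatic agent
(EC50 6 µg/mL, h = 1.3, max 0.85) converts spread→rounded permanently, with
conserved mass and arrested growth. The detergent (rounding EC50 8 µg/mL;
lysis EC50 60 µg/mL, h = 3) rounds cells first and lyses them second —
rounded (dying) cells carry a 6× lysis-hazard multiplier, reflecting that
rounding is an early event of cell death. Lysis retains 15–35% of the cell
mass as 2–4 sub-threshold debris fragments and removes the rest. This
ordering reproduces the characteristic dose pattern: the rounded fraction
rises at intermediate detergent doses and collapses at saturating doses
because the rounded cells themselves disappear into sub-threshold debris,
while the population dry mass falls monotonically with dose. The inert
particle agent only produces measurable rounding near the top of its
concentration grid. Per-experiment biology varies by lognormal factors on
growth rate (CV 12%) and seeding density (CV 8%). The default plate design
is a medium control, the detergent at 0.1/5.5/20/140 µg/mL, and two
particle-like agents at 2/8/32/128 µg/mL, with n = 3 FOVs × N = 3
experiments.

All randomness derives from one seed through per-(experiment, condition,
FOV) seed-sequence spawning; identical configs are bit-reproducible,
including every output file (for this reason wall-clock timings are logged
but never written into result files).

## Validation phantoms and what passing tests show

The reconstruction round trip is validated with a smooth blob phantom
(super-Gaussian p = 2, radii 25–40 µm, peaks to 4 rad) whose spectrum lies
inside the demodulation passband: the full chain recovers it to < 0.05 rad
RMS (typically ≈ 0.03) over the central 90% at default noise. Structure
sharper than the passband cannot be represented by *any* sideband method at
this sampling, so dense sharp-edged cell populations are validated through
blur-tolerant metrics instead: whole-FOV dry mass and DMI (the pipeline DMI
is within 5% — typically ~1% — of the manifest change for control and
cytostatic arms over 20 FOVs), the pooled rounded fraction (within ±0.1,
typically ±0.04), and the detergent dose ordering. The statistics stage
(two-factor ANOVA, condition × experiment, via statsmodels, with the
three-level star annotation at p < 0.05/0.01/0.005) is calibrated under the
null to a 5% ± 2% type-I error over 1000 simulations.

What passing tests do *not* show about real data: the simulator has no
optical aberrations beyond a polynomial background, no partial-coherence
speckle, no cell–cell contact or migration, no border-clipped cells, no
focus drift, and its debris/lysis morphology is stylized. Real rounded-cell
fractions also count mitotic figures that threshold segmentation merges with
neighbours; the 350 µm² filter value and the C > 0.8 rule are taken as given
rather than optimized.

## Numerical and interface choices

Degenerate inputs: a fully lysed FOV segments to an empty region list;
rounded-fraction 0/0 is reported as missing (never 0); single-FOV groups
report a missing sd; zero-variance ANOVA groups yield a missing p with a
warning; a flat autofocus landscape returns 0 with a warning; >50% invalid
pixels make dry mass an error. The carrier must lie strictly between 3× the
nominal object-spectrum half-width and Nyquist. Hologram stacks are written
as 16-bit multi-page TIFF (time-major, then frame 0–6) with the linear scale
in embedded JSON metadata; phase images as 32-bit float TIFF plus a mask;
tables as CSV; the manifest as JSON. The CLI (`holoassay
simulate|reconstruct|run|compare`) is a thin wrapper over these library
stages.

Known limitations, beyond the simulator realism above: no watershed
splitting of touching cells; no reference-hologram (double-exposure)
compensation; no GPU path; no EC50 fitting across the four-point
concentration grids; the interlaboratory mode perturbs parameters
(seeding density, growth rate, noise) but does not model distinct
instruments.
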