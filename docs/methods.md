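# Methods

This note documents the models, parameter choices and numerical decisions
behind `resistweed`, and what the synthetic experiments do and do not show.

## Scene simulator

The simulator generates co-registered multispectral (B, G, R, RE, NIR at
450/560/650/730/840 nm) and RGB scene pairs of a maize field with two weed
species under herbicide stress, plus exact per-pixel ground truth. It is a
*phenomenological* generator: it encodes the ordinal spectral structure that
the analysis relies on, not radiative transfer.

### Spatial layout

* Plots default to 3 m × 5 m with maize rows at 0.6 m spacing (plants every
  25 cm, 6 cm canopy radius).
* Total weed count is Poisson with mean = seeding rate × area; the rates for
  the low/moderate/high density treatments are 40/160/320 plants m⁻².
* Barnyardgrass (85% of weeds by default) grows in clustered *blocks*: a
  parent–offspring (Thomas-type) process with ~20 plants per block
  (σ = 12 cm, plant radius 4.5 cm). Parents keep a soft 0.45 m hard-core
  spacing so blocks remain distinct gradable units; at high density the
  hard-core constraint becomes infeasible and blocks crowd — exactly the
  regime in which field grading is hardest.
* Velvetleaf grows as isolated individuals (hard-core radius 15 cm, plant
  radius 7 cm).

### Resistance truth and per-plant survival

Each barnyardgrass block draws a biotype (resistant with probability 0.447,
the share of resistant observations in the reference dataset) and then a
day-14 death fraction: uniform on [0.05, 0.65] for resistant blocks,
[0.80, 1.0] for susceptible ones. Crucially, **survival is realized per
plant**: with probability equal to the block's death fraction a plant
follows the susceptible (dying) trajectory, otherwise the resistant
(surviving) one. A level-3 resistant block (51–75% dead) therefore really
is mostly dead canopy, and blocks near the 75% grading boundary are
genuinely ambiguous — the property that caps classification accuracy below
1.0 in the field. Velvetleaf is labeled per plant (survive/die).

### Spectral model

Unstressed class signatures are fixed 5-band means with small per-band
standard deviations. Their ordinal structure is the modeled content: soil
is spectrally flat (NIR/R ≈ 1.2), vegetation shows the red-edge jump
(NIR/R > 3), resistant biotypes sit slightly below susceptible ones in the
visible bands and above them at red-edge/NIR, velvetleaf is brighter than
barnyardgrass in the visible range, and the species differ in band-ratio
structure (R/G separates maize from the weeds; NIR/RE separates the two
weeds) — without which no spectral species segmentation could work.
Absolute levels are free parameters and config-overridable.

Herbicide stress moves a signature linearly toward the soil signature by a
per-day stress fraction *s*: susceptible barnyardgrass at 0.12/day
(velvetleaf, with its slower stress response, 0.10/day), capped at 0.95;
resistant biotypes at 0.02/day until their recovery day (4 days after
application for barnyardgrass — the watershed time — and 7 for velvetleaf),
then relaxing back exponentially (rate 0.4/day). The bands respond in the
physiological order of photosystem damage: red-edge and NIR carry the full
stress fraction immediately; red (the chlorophyll absorption band) carries
15% of it early; blue/green discoloration — visible yellowing — begins at
day 3 and ramps to full effect over 8 days, with red completing alongside.
This ordering is what makes the multispectral WSRI informative days before
an RGB image changes.

### Noise model

Pixel reflectance = plant brightness factor × stressed class mean +
N(0, √(sd_band² + noise_sd²)), clipped to [0, 1]; `noise_sd` defaults to
0.005, the scale of a calibrated reflectance product. Brightness is a
persistent multiplicative canopy property with a per-plant component
(CV 0.20) and a per-block component (CV 0.15, local illumination/soil
moisture, which does not average out over a block's plants). The RGB camera
is *not* radiometrically calibrated, so its render carries an extra per-day,
per-block brightness factor (CV 0.10) and — importantly — per-channel
chromatic jitter (CV 0.20: shadow color, sun angle, white balance —
the campaign mixes clear and cloudy acquisition days). The
chromatic term is what keeps RGB band ratios from trivially revealing early
physiological change; WSRI, computed from the calibrated multispectral
product, cancels the multiplicative terms by construction.

With `noise_sd = 0`, zero signature sds and zero brightness CVs, every pixel
equals its class mean exactly (the degenerate contract used in tests).

### Determinism

The layout (and everything persistent: brightness, survival, death
fractions) derives from `default_rng([seed, 0])`; each acquisition day's
rendering from `default_rng([seed, 1000 + day + 2])`. Identical configs are
bit-identical; a time series shares one layout and evolves only spectra.

### What the simulator does not model

No radiative transfer, BRDF, wind or orthomosaic seams; no within-plant
texture beyond disk geometry; no soil moisture gradients; no weather
covariates. Plants are hard-edged disks with no sub-pixel mixing, which
*overstates* aliasing at fine ground sampling distances (see Fusion below).
Passing tests show the pipeline's machinery is correct and that its
qualitative field behavior (day trends, feature ordering, density effects)
is reproduced under the stated spectral assumptions — not that the absolute
accuracies transfer to real imagery.

## Calibration

Per-band empirical line: OLS of known panel reflectance on measured DN;
`reflectance = gain·DN + offset`, clipped to [0, 1] (clipping, not masking,
keeps downstream [0, 1] assumptions). The fit requires ≥ 2 distinct DN
levels per band (panel + dark reading); a gain-only fallback (offset 0)
supports single-panel campaigns. Noiseless synthesis-and-recovery round
trips are exact to 1e-10 relative.

## Gram–Schmidt pan-sharpening

The simulated low-resolution pan band is a weighted combination of the
multispectral bands — uniform over (B, G, R) and zero on (RE, NIR), because
the RGB camera senses only the visible range; the high-resolution pan is
the uniform mean of the RGB channels. The multispectral stack is upsampled
(bilinear by default; kernel configurable) to the pan grid, mean-removed,
and orthogonalized with the simulated pan as the first component (inner
products over valid pixels, covariance form). The real pan is matched to
the simulated pan by mean/sd standardization, substituted for the first
component, and the transform inverted. Substituting a pan identical to the
simulated pan reproduces the upsampled input to 1e-6 (tested), and the
whole operation commutes with a joint affine rescaling of the inputs.

Consistency is assessed Wald-style: degrade the fused product back to the
multispectral grid (exact block mean at integer resolution ratios) and
correlate per band. Because simulated plants are hard-edged disks, scenes
rendered at the field GSD (0.79 cm, plants only 4–9 px across) are
aliasing-dominated — the upsample/degrade round trip alone caps correlation
near 0.975 with no fusion involved. Consistency is therefore evaluated on
noiseless scenes at the same 2:1 GSD ratio with adequately sampled plants
(0.4 cm MS pixel), where per-band correlation exceeds 0.99. Real canopies
at the field GSD are adequately sampled because vegetation patches are
contiguous; the disk canopy is the simulator's limitation, not the
sharpener's.

## Vegetation indices

The ten-index registry evaluates fixed band arithmetic per pixel. Pixels
with any nodata input, or with a denominator magnitude below 1e-6, are
nodata (the WSRI denominator RE − B genuinely vanishes on soil-like
spectra; masking is honest, clipping is not). Legacy labels NDVI-RE,
RVI-RE and MCTI are accepted as aliases of RENDVI, RERVI and MTCI.
Biotype separability uses Welch's two-sample t (the exact test behind the
published violin-plot stars is unstated; Welch is the conservative default
for unequal variances), with stars at 0.05/0.01/0.001/0.0001.

## Segmentation

Otsu's threshold is computed over a 256-bin histogram by exhaustive
between-class-variance maximization, ties toward the lower cut; a manual
offset supports threshold fine-tuning. It is applied to NDVI for the
soil/vegetation mask (the band choice is unstated in the protocol this
mirrors; NDVI is the standard choice). Species separation uses an RBF SVM
(C = 10, γ = scale, standardized inputs — hyperparameters config-exposed)
on per-pixel features: five band reflectances plus GLCM contrast,
homogeneity, energy and entropy at 1-pixel offset averaged over four
directions on a 5×5 green-band window. Per-pixel windows are quantized to
64 gray levels (a 25-pixel window cannot populate an 8-bit co-occurrence
matrix; the standalone `texture_features` defaults to 256 levels).

## Grading and dataset construction

Death-fraction grading uses upper-closed intervals: level 1 = [0, 0.25],
2 = (0.25, 0.50], 3 = (0.50, 0.75], 4 = (0.75, 0.95], 5 = (0.95, 1] — an
exhaustive non-overlapping cover of [0, 1] honoring the printed scale's
95→100 jump; resistant ⇔ level ≤ 3. Patches are 4-band stacks ordered
(WSRI, R, G, B): WSRI from the sharpened product clipped to [−1, 3], RGB
reflectance in [0, 1]. Patches are cut from the *segmentation image* —
pixels outside the target species (soil, maize, the other weed) are zeroed
in all channels — because the crop is spectrally indistinguishable from
healthy resistant weed. ROIs are either block bounding boxes or fixed
squares centered on blocks (the equal-rectangle survey protocol); the
desk-scale experiments use fixed 40 cm squares at native resolution, which
avoids resampling blur on plants a few pixels wide. The 8:2 train/validation
split is drawn over ROIs *before* the four clockwise rotations (0/90/180/
270°), so no rotated copy of a training region reaches validation.

## Classifier

The network is built and trained in numpy (im2col convolution, manual
backprop): a 3×3 stem convolution mapping the 4 input channels to 3, a
backbone (`small_cnn`: two conv/pool stages and global average pooling;
`resnet18`/`resnet50`: residual networks with the canonical 2-2-2-2 /
3-4-6-3 stage depths at reduced widths so they run on one CPU), then a
dense head with dropout 0.30 before the 2-class output. Training follows
the reference protocol: Adam at learning rate 1e-4 with decoupled weight
decay 1e-3 (the "decay" is read as weight decay, not a learning-rate
schedule), batch 128, 300 epochs × 10 random batches, a fresh random
rotation per sampled patch each batch, and metrics averaged over five
repeats of randomized 8:2 holdback cross-validation re-drawn per repeat.

Desk-scale experiments use `desk_config()`: 20–30 epochs at learning rate
3e-3 (compensating the ~15× fewer optimizer steps), batch 64, width-8
`small_cnn` — chosen as the package's CPU-scale operating point. Feature
types select patch channels: `wsri` (channel 0), `rgb` (1–3), `wsri_rgb`
(all four); the stem adapts its input width.

## Synthetic experiment design

The per-day / per-feature evaluation grid simulates a low-density field
(4 m × 3 m at 2 cm MS / 1 cm RGB pixels, several independent layouts
pooled) on days 2/4/6/8 after application. Under the spectral model above
this reproduces the qualitative field findings: accuracy is non-decreasing
in days-after-application for every feature type; the multispectral WSRI
outperforms uncalibrated RGB on average; and their fusion is best. The
absolute values depend on the generator's noise scales and are not field
estimates. The coarsened pixel sizes (2 cm rather than 0.79 cm) keep one
scene's raster small enough for CPU experiments; blocks still span ~20–25
pixels, preserving the block-versus-plant geometry that matters.

## Known limitations

* The generator's spectral separations are designed, not measured; only
  ordinal claims transfer.
* GS fusion injects visible-band detail into RE/NIR with global gains;
  fine-scale fused WSRI is accordingly noisy around canopy edges (a real
  property of GS sharpening, amplified here by independently rendered
  MS/RGB noise).
* The SVM species stage trains on ground-truth pixel labels (the field
  protocol's manually tagged templates); its reported accuracy is a clean-
  label upper bound.
* `resnet50` at full width/epochs is not practical on one CPU; the default
  backbone is `small_cnn`.
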