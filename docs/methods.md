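# Methods

This note documents the models, statistical procedures and numerical
choices behind `icdecode`, in the order data flows through the package.

## Stimulus geometry

All geometry is expressed in idealized visual degrees on a 96° × 96° canvas
rasterized at 4 px/deg (binary primitives, no anti-aliasing — overlap
audits are exact set algebra on pixel masks). Four circles of diameter 30°
sit on the canvas diagonals with 46° between diagonally opposed centers,
leaving a 16° central gap. Inward inducer segments are 16°-long black bars
running from a circle's inner edge along its diagonal; outward segments are
flush with the outer edge. With bar length L = 16° and gap g = 16° the
support ratio of the illusory bar is 2L / (2L + g) = 2/3. The inducer bar
width (8°) and the background encoding (gray 0.5, circles 1.0, ink 0.0;
polarity invertible) are package choices; the `ink_mask` of an image
excludes the circle layer, which is identical in every image and carries no
discriminative pixels.

Probe images are built so that their ink overlap is *exactly* balanced
between the training images they are meant to arbitrate:

- `T_REk` contains the inducer segment shared by `I_Ck` and `L_Ck` plus an
  outlined real bar running from that inducer's inner edge to the canvas
  center. Ending at the center keeps the bar equidistant from the two
  inducer positions that distinguish `I_Ck` from `L_Ck`, so both the pixel
  overlap and the receptive-field drive are balanced (a bar spanning the
  whole gap would abut the distinguishing inducer on one side and bias
  neurons whose receptive fields straddle the gap boundary).
- `X_REk` contains all four inward inducers plus a full-length (48°)
  outlined bar at the orientation of `I_Ck`'s illusory bar; its
  intersections with the two `I_C` inks reduce to the two (equal-sized)
  inducer pairs, so the overlap balance is exact.

Configuration 0 is the whole battery rotated 315° clockwise; the rotation
is applied to the geometric primitives before rasterization, never by
image resampling. The `L_C` images are defined by half-splicing the `I_C`
primitives about the horizontal midline in the canonical frame, which makes
the recombination identity (`ink(L_C1)` = bottom half of `ink(I_C1)` ∪ top
half of `ink(I_C2)`) exact at any raster resolution.

## Generative model of a session

Each neuron i responds on a trial with

```
r_i = b_i + g_i · B_i(stim) · O_i(stim) + c_i · T_i(stim) + ε,   ε ~ N(0, σ_i²)
```

- **B (bottom-up contrast drive).** For the battery images, B is the
  RF-weighted mean *local contrast* (gradient magnitude) of the raster,
  scaled by a fixed edge-energy constant. Contrast, not mean luminance, is
  the right bottom-up variable here: the white circle fill is shared by
  every image and is not an oriented feature, while bars and outlines drive
  exactly the neurons whose receptive fields cover their edges. For the
  RF-mapping block (a grating patch on a plain gray background, cycling
  through all drift directions) B is the RF-weighted luminance contrast
  (patch coverage) and O = 1.
- **Receptive fields** are Gaussian with σ = 3° by default, truncated at 2σ
  (a classical RF with finite extent). The truncation matters: untruncated
  tails reach across the 8° gap radius and give "faithful" neurons spurious
  sensitivity to the illusory-bar region, which would contaminate the
  chance calibration of inference decoding.
- **O (orientation tuning)** is a von Mises factor
  `exp(κ(cos 2Δ − 1))` on the angle Δ between the neuron's preferred
  orientation and the dominant edge orientation inside its RF, estimated
  from orientation-binned gradient energy (8 bins over 180°); O = 1 when
  the RF contains no oriented ink.
- **T (emergent drive)** is 1 when the stimulus contains the neuron's
  emergent feature: for an IC1-encoder, `{I_C1, T_RE1, X_RE1, I_RE_135}`
  (the illusory/real 135° bar), and analogously for IC2; LC-encoders
  respond only to their `L_C` image. The inclusion of the real-edge images
  is the generative hypothesis under which inference decoding is positive;
  `emergent_drives_real_edges=False` simulates the corresponding null.

Default study conditions: 200 V1 neurons per session (24 IC-encoders, 80
segment responders, 20 gap-centered neurons, background with random RFs),
100 repeats per battery image, emergent amplitude c = 3σ with σ = 1.
Training-image repeats are a desk-scale version of the recorded sessions'
400–500; probe images use 100 repeats (the upper end of the 50–100 used in
the holography sessions), because hard-label probe fractions at 50 repeats
carry ±0.07 binomial noise per session. The gain default (4) places
decoding well above chance without hard saturation. Random background RFs
and segment-responder jitters are drawn in 90°-rotation pairs, so the
population is symmetric between the two image sets by construction.
Simulated sessions are a pure function of (parameters, seed).

What the simulator does **not** model: calcium-indicator kinetics and
imaging noise, biophysical dynamics, adaptation, correlated (shared) trial
noise, eye-position-dependent receptive-field shifts, and any dependence of
emergent responses on stimulus history. Passing tests therefore show that
the *analysis chain* recovers planted structure faithfully and is
calibrated under its null — not that real cortical data contain that
structure.

## Functional classification

- **IC-encoders**: Kruskal–Wallis across blank / `I_C1` / `L_C1` / `L_C2` /
  `I_C2` at α = 0.05, followed by a Tukey–Kramer-style comparison on mean
  ranks (pooled, tie-corrected rank variance against the studentized-range
  critical value with infinite df — the behavior of the classic
  kruskalwallis → multcompare chain; a pairwise rank-sum + Holm fallback is
  available). A neuron is IC1 iff `I_C1` > blank is significant, `I_C2` vs
  blank is not, and neither `L_C` vs blank is. "Respond" requires a
  positive sign; neurons significant for both `I_C` images are excluded.
- **Segment responders**: one-sided rank-sum inward > outward per quadrant
  at α = 0.05; a neuron's class is the significant quadrant with the
  smallest p, ties broken by larger AUROC. Where an analysis needs segment
  responders *per se* (subset decoding, holography targeting), neurons that
  also carry an encoder label are excluded.
- **Center-exclusive neurons**: two-sided rank-sum of each RF-mapping
  position against gray trials, Holm-corrected over the nine positions;
  kept iff the center is significantly positive and all eight others are
  non-significant.
- **Ensemble balancing** trims each quadrant group to the size of the
  smallest, keeping the top neurons by inward-vs-outward AUROC
  (Mann–Whitney U / n₁n₂).

## Decoding

The decoder is a linear SVM (C = 1) in a one-vs-one multiclass scheme with
majority vote; vote ties break by summed signed decision-function margins,
then by lowest class index. Stratified 10-fold cross-validation; each fold
standardizes the response matrix by its training trials only (zero-variance
training columns have their SD floored at a machine-epsilon-scaled
constant). Probe trials are standardized with each fold's training
statistics and never influence them; probe fractions are hard-label
fractions averaged over the ten fold models. Zeroing a neuron subset
happens *after* standardization, so a zeroed column sits at the training
mean in raw units; the raw-zeroing alternative is exposed as a flag via
the probe/evaluate API. Session-level statistics follow the nonparametric
conventions of the analysis family: two-sided Wilcoxon signed-rank on
paired (frac_IC, frac_LC), one-tailed signed-rank against chance for
holography.

Holography-evoked response matrices are normalized per neuron across *all*
holography trials (not with the visual fold statistics; `standardize="fold"`
restores the alternative). Non-photoactivated neurons are those farther
than 50 µm from every target of the ensemble (25 µm in mesoscope mode);
targets are valid only if a neuron lies within 10 µm; ensembles enter the
analysis only with ≥ 10 targets.

## Cross-correlograms

The CCG at 1-ms bins sums coincidences over the edge-trimmed range
t ∈ [1 + τ_max, L − τ_max] (τ_max = 100 ms) and normalizes by
√(λ₁λ₂) with λ taken from the full trains. The raw CCG is computed by
exact integer pair counting on spike times and equals the naive double loop
bin for bin. The smoothing correction subtracts the CCG of the trains
smoothed with a centered 25-ms boxcar (Gaussian optional); it is computed
in the correlogram domain — raw counts extended to ±(τ_max + 24) ms
convolved with the boxcar's autocorrelation (a triangular kernel) — which
equals cross-correlating the smoothed trains up to O(kernel width) edge
terms. A putative excitatory connection pre → post is called when the
corrected CCG peaks in the 1–10 ms window above 7× the SD of the corrected
CCG over 50 ≤ |τ| ≤ 100 ms; both directions are evaluated per pair.

## Planted circuitry

`build_connectivity` plants the circuit hypothesis being tested:
IC-encoders of class k project to every V1 neuron whose noiseless visual
drive to `I_Ck` exceeds baseline by 0.5 noise SD (per-source weight
`w/n_sources`, so targeting the whole class delivers ≈ w·d of summed
drive); non-emergent segment-driven V1 neurons project feedforward to
higher-visual-area neurons responsive to the same quadrant segment;
feedback (optional) runs from `I_C`-responsive HVA neurons to the matching
IC-encoders. A holography trial gives targets the direct drive d, routes
`Σ_i∈S M[i,j]·d` through the planted weights, and subtracts a global
suppression s from everyone (the average effect of sparse ensemble
photoactivation on the non-photoactivated population).

## Degenerate inputs and edge handling

Zero-variance z-scoring blocks raise instead of propagating NaNs. Empty
spike trains make the CCG undefined (error); trains shorter than 2τ_max
are rejected. Receptive fields outside the canvas produce a warning and
B = 0 (the emergent term survives). Pupil-trace trials with no samples
pass the gaze filter. Overlap of two empty ink masks is defined as 1 for
identical labels and 0 otherwise (only the `gray` image is affected).

## Known limitations

Probe classification of a perfectly ambiguous stimulus is decided by
session-level margin noise, so single-session inference scores fluctuate
(≈ ±0.1–0.2 under the default conditions) even when their expectation is
zero; conclusions should always be drawn across sessions or seeds, as the
test suite does. The Tukey–Kramer emulation uses large-df studentized-range
quantiles rather than the exact rank-permutation distribution, which is
anticonservative for very small trial counts (< ~10 per condition). The
spike simulator plants independent Poisson baselines; it does not model
refractoriness or bursting, which sharpen real CCG structure.
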