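# Methods

## Scope and data model

The package analyzes intravascular multispectral FLIm pullbacks: ordered
stacks of cross-sectional frames, each frame an angular grid of readout
locations. The grid is fixed at 2,048 OCT A-lines per frame grouped 4 per
fluorescence location, giving 512 locations and 512 × 6 = 3,072 readout
values (three channel lifetimes, three intensity ratios) per frame.
A-line spans are half-open and 0-based; angle 0° sits at 12 o'clock and
increases clockwise. These conventions are fixed because the
histology-to-frame co-registration depends on them.

Since no in vivo data ship with the package, a seeded generator supplies
every input. Its defaults define the study conditions used by the test
suite and the acceptance script; they are chosen once and documented here.

## Forward model (synthetic_data)

Each location belongs to one of five component classes (normal wall,
fibrotic, lipid, macrophage, lipids+macrophage). Its trace in channel
*c* is

    counts(t) ~ Poisson( B + A · d · exp(-t/τ) ⊛ IRF(t) )

with dark count *B* = 1 count/bin, a Gaussian IRF of 0.5 ns FWHM centred
at the 4 ns excitation pulse on a 300-bin, 0.2 ns grid (60 ns window — long
enough that an 8 ns decay loses < 1 % of its first moment to truncation),
amplitude scale *A* = 2000 counts, and a per-location distance factor *d*
drawn log-uniformly in [0.3, 1.0] and **shared by all channels**, which
makes intensity ratios distance-insensitive by construction.

Mono-exponential decays are the simplest model that exercises the
estimators; real tissue autofluorescence is multi-exponential, so the
lifetime estimates here should be read as effective (average) lifetimes.

Per-location lifetimes and per-channel intensity jitter (log-normal,
σ = 0.15) are *tissue* properties: they are drawn from a random stream
derived from the phantom's seed, not the acquisition seed. Re-simulating
the same phantom therefore redraws only counting noise and (optionally)
distance factors, which is what a repeated catheter pullback of the same
artery does.

### Signature table

The per-class lifetime/intensity values are free synthetic parameters, not
measured tissue values. They were chosen once to satisfy the qualitative
similarity structure of the five classes:

| class | ch.1 FL (ns) | ch.2 FL (ns) | IR1 = I₁/I₂ |
| --- | --- | --- | --- |
| normal | 4.0 | 2.0 | 1.2 |
| fibrotic | 4.0 | 4.5 | 2.0 |
| lipid | 6.5 | 6.0 | 0.8 |
| macrophage | 2.5 | 3.5 / 5.5 (bimodal) | 0.4 |
| lipids+MΦ | 6.5 | 6.0 | 2.8 |

so that lipid vs. lipids+MΦ are indistinguishable on both lifetimes but
split cleanly on IR1, fibrotic vs. normal coincide on ch.1, macrophage
vs. fibrotic coincide on the ch.2 *mean*, and every pair differs on at
least one feature. Within-class lifetime SD is 0.3 ns. Channel 3 carries
~10 % of the ch.2 intensity in every class to emulate its weak
signal-to-noise ratio; it is simulated and processed but never used for
classification.

The macrophage ch.2 bimodality is realized as a two-component mixture
*over locations* (superficial vs. deep sub-populations, mixing weight
0.5), not within one trace. Inside labeled macrophage ROIs the split is
allocated exactly at the mixing weight, reflecting that macrophage regions
contain both depth populations; this keeps ROI means stable while the
location-level histogram stays clearly bimodal.

### IHC fixtures

Section images are rendered in Beer-Lambert optical-density space:
`rgb = exp(-density · OD_stain)` on a white background, one single-stain
image per stain (ORO → lipid, PM-2K → macrophage, SMA → smooth muscle),
over an annular 200 µm band outside a circular lumen (600 µm radius,
4 µm/pixel). The OD vectors are synthetic, chosen for good conditioning
rather than calibrated chromogen spectra. Class-to-stain densities:
fibrotic and normal are SMA-positive (0.9 vs. 0.25), lipid/macrophage
stain their own marker at 0.8, lipids+MΦ stains both at 0.5/0.45 so the
dual-threshold co-presence rule (below) recovers it.

## Lifetime estimation (flim_processing)

The default estimator is an IRF-centroid-corrected **average delay**:

1. subtract the dark-count background (in frame assembly the offset is
   estimated per channel pooled over all locations of the frame, because
   a per-trace estimate from the short pre-pulse window is noisy enough
   to push signal-free traces over the validity threshold);
2. clip negatives, smooth with a 5-bin boxcar, and take as support the
   contiguous run of bins above `max(0.002 · peak, 2.5 σ̂/√5)` that
   contains the peak (σ̂ is a per-trace MAD noise estimate; restricting
   the support to the run containing the peak keeps late noise bumps from
   dragging the window);
3. compute the count-weighted mean arrival time with the mid-bin
   convention t_k = (k + ½)Δt, subtract the pulse/IRF centroid t₀;
4. invert the truncated-exponential mean, m(τ) = τ − T e^(−T/τ)/(1 −
   e^(−T/τ)) with T the support span, by fixed-point iteration, which
   removes the tail-truncation bias of step 2.

On the default noise model this recovers τ ∈ [1, 8] ns with a median
relative error of ~1–4 % at 10³–10⁴ integrated counts (see the test
suite). A mono-exponential least-squares fit of `A·exp(-t/τ) ⊛ IRF`
(scipy `curve_fit`, initialized from the moment estimate) is available as
`method="monoexp_fit"`; on mono-exponential truth the two agree within
5 %. The exact estimator of the original instrument is not published in
algorithmic detail, so both methods are validated against closed-form and
numeric-integration oracles instead of against the instrument.

A location is **invalid** when its ch.1 or ch.2 integrated counts fall
below 100 (below this the average-delay variance is unusable); invalid
locations are flagged, never zero-filled, and an intensity ratio is
undefined (NaN) when its denominator is below the same floor.

## Statistics (roi_analysis, reproducibility)

* Group comparisons average features per ROI (component-specific
  analysis) or per frame, then gate on per-group Shapiro-Wilk normality
  at α = 0.05: all groups normal → one-way ANOVA with Tukey HSD;
  otherwise Kruskal-Wallis with Dunn's rank-based post hoc. Dunn P values
  are Holm-adjusted (family-wise control, uniformly more powerful than
  Bonferroni). The report records which branch ran; pairwise matrices are
  symmetric with unit diagonal.
* Bimodality is operationalized as a 1- vs. 2-component Gaussian-mixture
  BIC comparison that additionally requires Ashman's D > 2, so
  heavy-tailed unimodal samples do not flag.
* Repeated-pullback agreement uses ICC(2,1) — two-way random effects,
  absolute agreement, single measures (the two pullbacks act as two
  "raters" of each frame) — computed through pingouin and verified
  against the variance-components closed form to 10⁻⁸ in the tests.
  Bland-Altman limits of agreement are exactly mean ± 1.96 SD of the
  paired differences. Frame pairing is an expert input consumed from a
  CSV; a class whose per-frame proportions have zero variance in either
  pullback is reported as degenerate rather than given an ICC.

## Classification

Random forest with 100 trees, unlimited depth, √p features per split and
a mandatory seed (robust defaults; no tuning was performed). Training
rows are *locations* (each contributes its ch.1 FL, ch.2 FL, IR1), but
cross-validation folds are stratified **by ROI** so no ROI straddles the
train/test split — neighbouring locations of one ROI are strongly
correlated and would otherwise leak. Multiclass ROC is one-vs-rest on
out-of-fold probabilities with a macro-averaged AUC. Accuracy is reported
at location level (headline) and at ROI level (majority vote). The burden
index divides by validly classified locations only, with normal wall
counted as a class, and always sums to 100 %.

## IHC quantitation

Color deconvolution solves the per-pixel 3×3 linear system in OD space
(−ln rgb against the stain OD matrix, least squares for < 3 stains),
clipping negative densities at zero; collinear OD vectors are rejected.
The multiplexed overlay is an additive blend of display colors on black,
fully determined by the stored density maps. Quadrangular ROIs anchor on
the luminal contour (periodic interpolation of r(θ)), one per 1° step,
extending 200 µm radially outward — the FLIm penetration depth. The
representative component of a ROI is the argmax of mean densities above
per-stain positivity thresholds (default 0.1), with ties broken
macrophage > lipid > smc (inflammation-sensitive, configurable); a ROI
is lipids+MΦ when lipid and macrophage both exceed threshold and neither
dominates by more than 2:1 — IHC has no joint stain, so the joint in vivo
class must be reconstructed from co-presence. Angular registration
between section and frame is always a required input, never inferred.
In the in-vivo-vs-IHC agreement table, SMA-positive ROIs match fibrotic
or normal, unstained ROIs match normal, and the lipids+MΦ in vivo class
matches lipid, macrophage or co-presence.

## Problem sizes and determinism

The default labeled dataset is a 20-frame pullback carrying 297 ROIs
(79 fibrotic / 66 lipid / 41 macrophage / 38 lipids+MΦ / 73 normal), each
2 frames × 16 locations, i.e. ~9.5 k location rows; the repeatability
experiment uses a 49-frame atheroma phantom simulated twice. Both are
desk-scale: the full test suite and the acceptance script each run in
well under a minute of compute per stage on one CPU. All randomness flows
from explicit seeds; fixed seeds reproduce every artifact byte-for-byte.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — class-separable signatures with the documented similarity
pattern, distance-invariant ratios, Poisson counting noise, weak ch.3 —
but not OCT image formation, catheter motion or non-uniform rotation
artifacts, blood/flush attenuation, spectral bleed-through between
channels, multi-exponential decays, or real chromogen spectra and
staining variability. Near-perfect classification and ICC values on these
conditions therefore validate the *pipeline implementation* (feature
extraction, leakage-free evaluation, agreement statistics), not clinical
performance on real arteries, where class overlap is substantially
larger.

## Known limitations

* The signature table is synthetic; absolute lifetime values should not
  be compared against tissue measurements.
* `monoexp_fit` loops per trace through `curve_fit` and is ~100× slower
  than the vectorized average delay; it is intended for verification, not
  bulk processing.
* The IHC luminal contour must be star-convex about the supplied center
  (r(θ) interpolation); strongly folded lumens are out of scope.
* Frame pairing between repeated pullbacks is consumed as expert input;
  no automatic landmark registration is attempted.
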