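# Methods

## Generative model of the striation signal

SHG signal in cardiac muscle originates from the myosin thick filaments.
Along a fiber axis we model the expected photon rate as

    I(s) = B + C · Σⱼ [ g(s − sⱼ + ABL/2) + g(s − sⱼ − ABL/2) ],
    g(x) = exp(−x² / 2σ²),   σ = TTIL / (2√(2 ln 2)),

where the M-band positions sⱼ are spaced SL apart, the two Gaussian peaks of
a sarcomere are its A-band segments, and TTIL is by convention the FWHM of
one peak.  Z-discs emit no signal, so they need no explicit dark object: the
gap between consecutive peak pairs is the Z-disc.  The same convention is
used by the simulator and the fitter; it is the single documented width
constant of the package.  The peak shape is not dictated by physics at this
resolution; Gaussians are the standard choice for diffraction-limited
imaging and give the ACF a closed form.

In 2-D a fiber is this axial pattern times a transverse Gaussian envelope
(σ_t = 0.5 µm); images hold several near-parallel fibers at ≈45° (within-
image angular jitter 0.5°: myocardial fibers in one optical section are
nearly parallel, and strongly diverging synthetic neighbors would cross).
Noise is Poisson on the expected photon counts plus additive Gaussian read
noise (σ_read = 1 count); the default contrast is 12 photons at peak over a
2-photon background, a deliberately photon-starved budget typical of
label-free SHG.  A scalar noise level ν scales the shot-noise amplitude
(exposure 1/ν²) and read noise together; ν = 0 disables noise.

## Autocorrelation model and fit

The mean-subtracted, variance-normalized ACF of the infinite periodic
profile is

    m(τ) = (w(τ) − dc) / (w(0) − dc),   h(x) = exp(−x²/4σ²),
    w(τ) = Σₖ [ 2 h(τ − kSL) + h(τ − kSL − ABL) + h(τ − kSL + ABL) ],
    dc   = 8√π σ / SL,

a comb of Gaussian lobes of variance 2σ²: weight-2 lobes at multiples of SL
(peaks aligning with their own kind) and weight-1 lobes at kSL ± ABL (cross
terms), minus the flat mean term.  The sum is truncated dynamically to cover
the requested lags (default max lag 6 µm ≈ 3 periods).

The empirical ACF uses the biased (divide-by-N) estimator so values stay in
[−1, 1]; the fit multiplies the model by the exact triangular taper
(1 − lag/N), so the estimator choice introduces no bias.  Fitting is bounded
trust-region least squares over five parameters: SL ∈ [1.0, 2.5] µm,
ABL ∈ [0.4, 1.2] µm, TTIL ∈ [0.04, 0.2] µm (brackets all physiological
cardiac values with margin) plus an amplitude and an offset.  The nuisance
pair matters: photon noise adds variance only at lag 0, damping every
off-zero lobe by a common factor, and finite-profile mean estimation shifts
the baseline; without them both effects would leak into TTIL.  Lags below
0.08 µm are excluded (white-noise spike at the origin, plus short-range
correlation introduced by interpolation).  Initialization is automatic:
SL₀ = lag of the highest off-zero ACF peak inside the SL bounds,
ABL₀ = SL₀/2.15, TTIL₀ = 0.1 µm; failure to find an off-zero peak marks the
fit non-converged (never silently dropped).  Tolerances: ftol 1e−10,
max 2000 function evaluations.

Identifiability: at SL/ABL = 2 the lobe comb degenerates to a perfect comb
of period SL/2 and (SL, ABL) are no longer identifiable — the physical
counterpart of the quality rule.  Fibers with fitted SL/ABL strictly above
2.25 are excluded (a ratio of exactly 2.25 is kept); non-converged fits are
always excluded, with reasons recorded.  The rule is applied per fiber (the
conservative granularity) and a per-image mean ratio with the same threshold
is reported alongside.

## Orientation, tracing, profile extraction

Orientation uses the structure tensor with a Gaussian window of 400 nm
(10 px at the 40 nm pitch; the image is pre-smoothed by 1 px).  In a
striation image the intensity varies fastest along the fiber, so the leading
eigenvector is the fiber axis directly; coherence (λ₁−λ₂)/(λ₁+λ₂) is zero
for isotropic neighborhoods and angles are NaN where gradient energy
vanishes.

Tracing walks at 1 px steps along the angle field from seeds placed at local
maxima of a band-free ridge image (Gaussian blur at 0.8 µm, which averages
out the striation).  Background is estimated as the 5th percentile of the
ridge — not the median, which sits at fiber level in fiber-dense images.
Each step applies a damped transverse recentering servo (gain 0.3, window
±10 px) toward the intensity centroid of a lightly smoothed image (0.16 µm:
wide enough to be stable, narrow enough that a neighboring fiber 2 µm away
exerts no pull).  Walks stop on low coherence (< 0.2, with up to 25 dim
steps bridged — coherence dips between striations), on the ridge falling
below 15% of the running maximum above background (a dim seed cannot
authorize wandering through gaps), or at the image border.  Traced fibers
claim an 8 px stripe so later seeds on the same ridge are skipped; traces
shorter than 8.5 µm (≈5 periods, the minimum for an informative ACF) are
discarded.  Tracing is deterministic.

Profile extraction first replaces the traced polyline by a global cubic
polynomial per coordinate and resamples it to an exactly constant arc-length
pitch.  Both steps are load-bearing: per-step recentering jitter otherwise
(i) smears the profile axially, inflating TTIL by several nm, and
(ii) inflates the polyline arc length by ~1–3%, which would rescale every
measured distance (a +2.6% path inflation maps to +43 nm on SL).  A global
cubic is adequate for gently curved, non-branching myofibrils — the regime
this pipeline targets.  Intensity is then sampled by cubic-spline
interpolation (bilinear interpolation along a 45° line smooths by ~1/6 px²,
a +7 nm TTIL bias at this peak width) and averaged over 7 transverse offsets
within ±3 px.  Transverse averaging is safe for near-straight fibers because
the bands run perpendicular to the axis; for strongly curved fibers it would
blur TTIL.

Measured single-fiber accuracy at default noise (fetal-control geometry,
5 fibers/image, 20 seeds): median |error| ≈ 0.3 nm (SL), 1.4 nm (ABL),
1.9 nm (TTIL); biases within ±1 nm.  This is far better than the ~20 nm
accuracy quoted for the technique on real tissue because the synthetic
images lack the error sources that dominate there (optical PSF and
aberrations, tissue heterogeneity, contraction-state variation, sectioning
artefacts).  Raising the noise until the fit error reaches 20 nm is not a
usable operating point: fiber *tracking* collapses first (detection drops
from 100% to ~5% between noise levels 1 and 4 while fit errors are still a
few nm).  Passing recovery tests on synthetic data therefore validates the
algorithm, not the instrument error budget.

## Cohort simulation

Heart-level geometry is drawn per group as (SL, SL/ABL ratio, TTIL) with
ABL = SL / ratio.  Drawing SL and ABL independently would be inconsistent
with the observed data pattern: the ratio is tight across hearts (SD ≈ 0.02
against a naive ≈ 0.17 under independence), and independent draws would push
~25% of hearts over the 2.25 QC cut.  The (SL, ratio) parameterisation
reproduces the observed ABL spread (0.045 vs 0.044 µm) as a consequence.
Defaults per group (µm, mean ± between-heart SD):

| age   | group   | SL            | ABL           | TTIL            | ratio SD |
|-------|---------|---------------|---------------|-----------------|----------|
| fetal | control | 1.658 ± 0.094 | 0.772 ± 0.044 | 0.104 ± 0.006   | 0.02     |
| fetal | IUGR    | 1.531 ± 0.114 | 0.705 ± 0.060 | 0.096 ± 0.007   | 0.03     |
| adult | control | 1.720 ± 0.068 | 0.817 ± 0.036 | 0.103 ± 0.005   | 0.02     |
| adult | IUGR    | 1.626 ± 0.084 | 0.772 ± 0.041 | 0.097 ± 0.005   | 0.01     |

Cohorts are paired: control heart i and IUGR heart i are littermates and
share a maternal random effect, implemented as correlation 0.5 between their
heart-level deviations.  The variance split between and within hearts is not
derivable from group-level summaries; within-heart fiber-to-fiber SDs
default to 0.04 µm (SL), 0.02 (ratio), 0.003 µm (TTIL) — chosen as
plausible, configurable, and not claimed to match real animals.

By default drawn heart means are recentred so each group's realized truth
mean equals its configured mean exactly (`center_heart_means`).  This is a
benchmarking choice: with 7 hearts the sampling error of the mean
(σ/√7 ≈ 36 nm for fetal SL) would otherwise dominate cohort-recovery
comparisons at the 20 nm scale, turning them into tests of seed luck rather
than of the pipeline.  Dispersion, pairing and within-heart structure are
preserved; switch it off for fully random cohorts.

Scaled-down study sizes are used throughout (7+7 hearts as in the emulated design, but
3 images/heart instead of 8–10 and ~5 fibers of ~14 sarcomeres per image
instead of ~15 of ~200); cohort means are then estimated from ~100 fibers
per group, ample for the recovery tolerances tested.  The power benchmark
runs 100 replicate cohorts in profile mode (analytic profiles + noise,
skipping rendering/tracing): measurement error arises almost entirely at the
ACF-fit stage, and the image stage is exercised separately.

Aggregation is fiber → heart directly (unweighted); fiber → image → heart is
available via configuration.  Group comparisons report both the two-sided
paired t-test and a classical one-way ANOVA, each labelled.  Pairs broken by
QC exclusion are dropped from the paired test; a pair absent from one
group's roster is an error.  All-zero paired differences give t = 0, p = 1;
constant nonzero differences are degenerate and flagged.

## Gene-set scan

Annotations are first closed upward over the GO DAG (a gene annotated to a
term is annotated to every ancestor up to the root); cycles are an error.
For each of n evenly spaced rank cuts (default 30) and each term, the 2×2
table (annotated vs not) × (above vs below cut) is tested with Fisher's
exact test (two-sided, with the one-sided upper tail also reported);
Benjamini–Hochberg runs jointly over all term × cut tests, and each term is
summarized by its minimum adjusted p.  The BH family definition and the
partition count are documented choices — the original tooling's settings are
not published.  The enrichment benchmark embeds a block annotating 1.6% of
the top half and 0.69% of the bottom half of a ranked list; at microarray
scale (20 000 genes) this is detected with raw p ≈ 1e−10.  At n = 2000 the
same fractions give counts of 16 vs 7, whose best-cut Fisher p is only
≈ 0.05 — block detectability at these percentages requires array-scale
lists, so the benchmark uses one.  A permuted-order null over 200
permutations yields a raw-p<0.05 fraction of ≈ 0.042, slightly conservative
as expected for a discrete exact test.

The five M-band reference genes and their reported fold changes ship as
package data (`mband_genes.tsv`).  The GO edge fixture
(`synthetic_go_cc_edges.tsv`) is a synthetic miniature of the
cellular-component lineage around the M-band term, not an ontology excerpt.

## Numerical and degenerate-input choices

* ACF requires ≥ 2× max-lag samples and a nonzero-variance profile (errors
  otherwise); value at lag 0 is exactly 1 by construction.
* Rendering evaluates the analytic model at pixel centers (no area
  integration); images are written as 16-bit TIFF with the pixel pitch in a
  JSON image description, and read back with explicit errors for
  multi-channel data or a missing pitch.
* Fibers whose pattern would degenerate (TTIL ≥ half the smallest inter-peak
  gap) or whose endpoints leave the image are rejected at simulation time.
* Invalid parameter draws in the cohort generator are redrawn with a bounded
  retry (error after 100 attempts).
* All randomness flows from explicit integer seeds; identical spec + seed
  reproduces images bit-for-bit.

## Known limitations

* No optical PSF beyond Gaussian peak shape, no polarization dependence of
  SHG, no 3-D stacks, no fiber branching or crossing: results on synthetic
  data bound algorithmic error only, not instrument error on tissue.
* The cubic-centerline regularization assumes gently curved fibers.
* Per-sarcomere (non-averaged) length maps and contraction-state modelling
  are out of scope; estimates are per-fiber averages.
* The within-heart variance split and the pair correlation are plausible
  defaults, not fitted quantities.
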