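# Methods

fibrilkit quantifies the two arms of collagen-I deposition — secretion of
procollagen-I (PCI) into the medium, and assembly of secreted collagen into
D-periodic fibrils — from four kinds of measurement: pulse-SILAC peptide
tables, photoswitchable-fluorophore (Dendra2-type) time-lapse traces, AFM
height profiles and fluorescence fibril images, and nanoluciferase (Nluc)
luminescence series. Every estimator ships with a synthetic-data generator
that produces data with exactly the statistical structure the estimator
assumes, plus the ground truth, so each stage is validated by parameter
recovery rather than by eye.

## SILAC turnover model

During a heavy-lysine pulse of length `pulse_h` (default 48 h), newly made
protein is heavy and the pre-existing light pool decays exponentially with
rate constant `k` while cell division dilutes it at `ln 2 / doubling_h`
(default 72 h doubling). With no new light synthesis during the pulse, the
heavy/light intensity ratio HL of a protein's peptides obeys

    k = ln(HL + 1) / pulse_h − ln 2 / doubling_h,     t½ = ln 2 / k.

Model assumptions: exponential decay of the light pool, total protein
doubling once per cycle, and complete label incorporation into new protein.

**Censoring.** When HL ≤ 2^(pulse/doubling) − 1 (≈ 0.58740 at defaults),
k ≤ 0: the protein is lost no faster than dilution alone removes it, and
its half-life is reported as censored (not estimable), never as a negative
time. A protein with zero light signal is censored on the other side
(half-life below detection).

**Evidence filter.** A protein enters estimation only with ≥ 3 peptide
observations pooled over replicates, ≥ 1 heavy observation, and presence
in ≥ 2 distinct replicates. The pooled reading is the weakest condition
consistent with the filter's wording; counting distinct sequences instead
of observations, and the per-replicate reading, are config options
(`peptide_unit`, `min_*`).

**Ratio roll-up.** Default `intensity-sum` (HL = Σheavy/Σlight over all
peptide observations) is robust when channels share peptides unevenly;
`peptide-median` (median of per-peptide ratios) is available because the
aggregation level is a genuine modelling choice. Both are scale-invariant.

**Precision at the design conditions.** With 8 peptides/protein, 2
replicates and 20% intensity CV, peptide base abundances spanning ~1.3
decades concentrate the intensity-sum ratio on the few brightest peptides,
so the effective number of observations is well below 32; the median
relative half-life error under these conditions sits near 5% and varies
by a percentage point or two across seeds. This is a property of the
design, not of the estimator.

## Synthetic SILAC tables

True half-lives are log-normal with median 46 h and σ_log 0.5, matching
proteome-wide turnover surveys of cultured fibroblast-like cells. Peptide
counts are Poisson (mean 8); base abundances log-normal (σ = 1) shared
across replicates; intensity noise is multiplicative log-normal with unit
mean (mass-spectrometric intensity error is scale-dependent); dropout, off
by default, removes observations independently of intensity. The expected
light fraction per protein is f = exp(−(ln2/t½ + ln2/doubling)·pulse), so
noise-free tables invert exactly through the estimator.

## Photoswitch trace kinetics

The generator integrates

    dG/dt = s0 (1 + a sin(2πt/P)) − k_sec G        (green: synthesis − loss)
    dR/dt = −k_sec ρ(t) R                          (red: loss only)

with a single switch event at `switch_time_h` moving a fraction η of G to
R (G + R is continuous at the switch), and ρ(t) jumping from 1 to the
nucleation multiplier at `nucleation_time_h` — fibril nucleation drains
the cellular pool faster than steady secretion. The red channel uses the
piecewise closed form; the green channel uses fixed-step RK4 at one tenth
of the sampling interval, so results do not depend on an adaptive solver.
The default initial green pool is the steady state s0/k_sec: cells are at
synthesis/secretion homeostasis when imaging begins, which also means the
rhythm spectrum is not contaminated by a start-up transient. `switch_time_h
= None` generates switch-free (rhythm-only) experiments.

**Decay fitting** is log-linear least squares on ln(I − bg), exact on
noise-free data and transparent about its weighting (uniform by default,
matching multiplicative noise). The confidence interval comes from
residual resampling (default B = 500, seeded). Photobleaching is assumed
negligible over the 48 h window — cellular signal loss is dominated by
secretion — so no k_pb term is fitted by default.

**Rhythm detection**: linear detrend, Hann window, periodogram, peak
constrained to a 6–48 h period band, refined by log-power parabolic
interpolation. Significance uses Fisher's g-test on the rectangular-window
periodogram (P(g > x) ≈ m(1−x)^(m−1) under white noise, α = 0.01). The
resolution bound reported is one frequency bin mapped to the period
domain (p²Δf), about ±8 h at 24 h on a 72 h trace; the interpolated
estimate is typically within 0.2 h on clean data.

**Nucleation/secretion rate ratio.** The loss rate during nucleation is
the steepest negative log-slope over a sliding window after the
nucleation frame on normalized traces (reference frame = 1, background =
0), averaged over cells; the secretion loss rate is the mean fitted decay
constant of switch-only traces. The steepest-window statistic is an
extreme statistic: with the default 3-frame window it is exact on clean
data but biased upward under noise, so for noisy traces a window spanning
several hours (e.g. 15 frames at 0.5 h sampling) should be used; at 10%
intensity CV this keeps the recovered 5× ratio within 20%.

## Fibril morphometry

**Flattening**: per-scanline polynomial (order 0–2) least-squares removal,
the standard AFM bow/tilt correction. Idempotent by construction.

**D-period**: after linear detrending (which makes the estimate exactly
invariant to added ramps), method A takes the dominant non-zero-lag
autocorrelation peak in a 40–100 nm search band with sub-sample parabolic
refinement; the band covers the canonical ~67 nm repeat and the observed
65 ± 7 nm range while excluding the first harmonic. Method B reports the
mean ± sd of successive smoothed peak positions — that sd measures
repeat-to-repeat spacing variation along the fibril, which is a different
quantity from the estimator's uncertainty, and both are reported.
Profiles with no in-band autocorrelation above 0.2, or no variance, give
"no periodicity detected". The generator's gap-overlap waveform is an
asymmetric three-harmonic series that is strictly periodic at the set
period, mimicking the ~54/46 overlap/gap duty of collagen banding.

**Segmentation**: greyscale-opening background subtraction (rolling-ball
style, radius 15 px default), Otsu or fixed threshold, skeletonization,
junction splitting (pixels with ≥ 3 skeleton neighbours removed), pruning
below 1 µm. A noise guard treats the image as fibril-free when the Otsu
threshold falls inside the robust noise floor (median + 5·1.4826·MAD of
the background-subtracted image); without it, thresholding a signal-free
image segments pure noise.

**Length measurement.** Each skeleton piece's geodesic diameter (two
Dijkstra passes over the 8-connected pixel graph, diagonal steps √2) gives
the traced path; the reported length sums Euclidean chords between every
5th path pixel, because raw chain-code length overestimates oblique
straight lines by up to ~8%. Thinning erodes ridge tips by a variable
0–3 px, so each end is extended along its local tangent until the
interpolated intensity falls to half the interior ridge level — the FWHM
criterion places the end of a PSF-blurred fibril at exactly that point —
minus half a pixel for the tip's own footprint. On high-SNR synthetic
images this yields mean |length error| ≈ 0.5% with worst cases ~3% (one
pixel on the shortest fibrils, which is the quantization floor).

Crossing fibrils are split at skeleton junctions and not re-joined; counts
on dense, crossing layouts will overestimate. Recovery validation
therefore uses non-crossing layouts (`min_separation_px` in the image
generator), which is also the regime the per-cell counting assay images.

**Per-cell assignment**: majority overlap of the skeleton polyline with a
cell label map; segments overlapping no cell are assigned to the nearest
cell centroid (deposited fibrils commonly extend beyond the footprint of
the cell that made them). With no masks, the global count is divided by
the cell number.

**Group comparison**: pooled-variance and Welch t statistics are computed
from the standard formulas in-module with p from the t distribution;
Mann-Whitney is available as the rank-based alternative. Degenerate inputs
(zero variance in both groups) give p = 1 for equal means, p = 0
otherwise. Type-I error at α = 0.05 is calibrated to 0.05 ± 0.02 in the
test suite's null simulations.

## Secretion flux

The Nluc standard curve is an ordinary least-squares line through (mol,
RLU) standards spanning ≥ 10×; its inverse converts a medium luminescence
series to a concentration, scaled by the medium volume to total moles.
(The generator's readout convention RLU = slope·M/V makes the calibration
inverse a concentration in mol/mL; the estimator multiplies by V.) The
secretion rate is the slope of mol(t) over the largest initial window
whose linear fit keeps R² ≥ 0.99, converted to molecules/cell/h with the
exact Avogadro constant. Pool turnover time is simply content/rate.

The perfused bioreactor is modelled as a single well-mixed compartment
(CSTR): static concentration C_s(t) = r t/V; under flow Q,
C_f(t) = (r/Q)(1 − e^(−Qt/V)) with steady state r/Q; percent reduction
100(1 − C_f/C_s) increases monotonically in both t and Q. The medium
volume of the real device is not known, so a measured reduction can only
be bracketed over plausible volumes, not matched exactly: with V = 2 mL
and Q = 0.05 mL/min (3 mL/h) over 72 h the model gives 99.07%, the same
order as reductions reported for comparable setups.

## What the synthetic data do not emulate

Peptide-level: no missed cleavages, no intensity-dependent dropout by
default, no protein-inference ambiguity, no chromatographic batch drift.
Traces: a single instantaneous switch, no photobleaching, no cell
movement or segmentation error. Images: straight fibrils on uniform
background with disk-shaped cells — no crossing-resolution, no
out-of-focus light, no real cell morphology. Luminescence: no enzyme
saturation or substrate decay. Passing recovery tests therefore shows the
estimators are correct under their stated models; it does not certify
performance on every real-data pathology.

## Problem sizes in the test suite

Recovery tests use 200 proteins × ~8 peptides (SILAC), 97-frame traces
with 1–5 cells per group, 10-period profiles at 2 nm sampling, fifty
256×256 images of 12 fibrils each, and 1000 null simulations for t-test
calibration — sizes at which every stochastic check is stable at the
asserted tolerances while the whole suite runs in well under a minute.
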