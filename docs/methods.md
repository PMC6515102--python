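# Methods

This note records the models, numerical choices and limitations behind
`qamskit`, in the order the pipeline runs them.

## Quantification model

Calibration is strictly linear and unweighted: `response = a·conc + b`
fitted by ordinary least squares, with r² the squared Pearson correlation.
The published regressions report a single slope/intercept per analyte with
no weighting scheme, and the package mirrors that. Inversion
`conc = (area − b)/a` is always performed; concentrations outside the
calibrated span are *flagged* (`below-range` / `above-range`) rather than
rejected, because routine sample extracts legitimately fall outside the
published ranges (the printed linear ranges are themselves hard to
reconcile with the reported sample contents — they may actually be in µg
injected; the package stores them verbatim and only flags).

The relative correction factor of analyte *k* against marker *s* is the
slope ratio `f_k/s = a_k/a_s`. The single-marker content formula as
published omits the marker-concentration term of textbook practice; read
with `A_s` as the marker's calibration *slope* (consistent with the
published definition of `a_s`), it reduces to the intercept-free
`C_k = A_k/a_k · F`. The alternative reading — `A_s` as the marker's
sample peak area combined with a slope-only estimate of the marker's
concentration — cancels to the identical expression, so nothing hinges on
the choice. Two consequences drive the whole validation design:

* QAMS is linear in areas (doubling areas doubles contents);
* per cell, `C_esm − C_qams = −(b_k/a_k)·F` **exactly**. Method agreement
  is entirely a statement about intercepts being small relative to
  signals.

The marker itself is quantified through its full external-standard curve
(it is the one analyte whose standard exists); a switch forces slope-only
quantification for symmetry experiments.

The extraction factor `F` (mL of extract per g of dry material, including
dilutions) defaults to 1, i.e. contents are reported on the mg/mL scale of
the peak-area table. The published sample-preparation text ("2.0 mg in
25 mL") cannot be reconciled with mg/g contents of the order 3–27, so the
true mass/volume chain is unrecoverable; `F` is a single configurable
constant and reproduction of absolute published contents from raw areas is
not attempted.

## Validation statistics

All dispersion statistics use the sample (n−1) standard deviation. This
is not a free choice: the published between-batch C.V. row is reproduced
to 0.1 percentage points for all seven analytes only with the n−1
denominator (the marker column gives 49.7% with n−1, 48.5% with n).

For a two-value pair, relative error `100·|x−y|/mean` and pair RSD obey
`RE = √2·RSD` identically; the agreement report checks this at machine
precision as an internal-consistency invariant (it also visibly holds in
the published per-sample table, e.g. the 1.76%/1.25% pair).

The paired t-test computes `t = mean(d)/(sd(d)/√n)` on the content
differences with n−1 degrees of freedom; the two-sided p-value is
evaluated through the regularized incomplete beta function,
`p = I_{df/(df+t²)}(df/2, 1/2)`, and agrees with an independent
t-distribution oracle to 1e-9. Degenerate inputs follow explicit
conventions: all differences zero → (t=0, p=1); zero-variance differences
with nonzero mean → (±∞, p=0).

A finding worth recording: the published per-analyte p-values (0.80–0.99)
are reproduced almost exactly by an **unpaired** two-sample t-test on the
content columns, whereas the paired test — the statistically appropriate
one for method agreement on the same samples — is highly significant for
several analytes, precisely because it detects the systematic
intercept-term offset derived above. The package keeps the paired test as
the contract of `compare_methods` and reports the unpaired p-values
alongside it in the reproduction report. The published "no significant
difference" conclusion rests on a test that is insensitive to the one
systematic difference the two methods are guaranteed to have.

Spike-recovery supports the published convention
`recovery % = (found − known)·100/added`. The published recovery means
themselves require wet-lab spikes and are out of reach of a desk
reproduction; synthetic replicate tables exercise the code path instead.

## Fingerprints

Peak detection baseline-corrects the trace with a rolling-minimum filter
(2-min window) smoothed by a rolling mean, estimates noise as
1.4826×MAD of a linearly detrended baseline region (or, by default, of
the quietest one-minute window of the trace), and takes local maxima above
10× noise with prominence above the same floor. Integration bounds are
the valley minima between neighbouring apices, capped at twice the
half-prominence width on each side — the cap stops a slowly decaying
solvent-front tail from stretching the local baseline, which otherwise
biases small peaks by several percent — then tightened to where the
corrected trace falls into the noise. The area is trapezoidal above a
straight line joining the raw trace at the two bounds (valley-to-valley
baseline, the standard default absent any statement in the source
method). On a noiseless Gaussian this integrates to h·σ·√(2π) within
~0.6%, bounded by tail truncation rather than grid resolution.

Retention-time correction is multipoint: apices matched mutual-nearest
within a 0.5-min window become anchors of a monotone piecewise-linear
warp, identity outside the anchor span; the warped trace is resampled on
the reference grid. The consensus reference is the pointwise median
(mean optional) of the aligned traces. Similarity is the Pearson
correlation of the two full intensity vectors (cosine optional); a
matched-peak-vector variant can be had by correlating integrated areas,
but full traces are the default because that is how the commercial
similarity software used in this field behaves as described. Exact parity
with that closed-source tool is not claimable and is not asserted
anywhere.

## Clustering

Profiles are z-scored per analyte (sample sd; constant columns are an
error, not silently dropped) and clustered agglomeratively on Euclidean
distances. The published figure states neither distance nor linkage; of
ward/average/complete, all three reproduce the published
{S1,S2}-together / {S19,S20}-together split on the packaged panel, and
**ward** is the recorded default. Only that pairwise split is asserted:
full three-group membership is underdetermined by the published
description, and the tie-breaking of equal merges follows the
deterministic lowest-index order of the condensed distance matrix.

## Synthetic data

The generator renders what the analysis assumes, on the full 0–130 min,
0.01-min grid of the published gradient (trimmed grids are used in fast
tests):

* **Peaks** are exponentially modified Gaussians; `tau = 0` (pure
  Gaussian) is the default so analytic area checks stay exact, and a
  positive `tau` produces the right-skewed shapes used in shape tests.
  Retention times are not printed in the source (figure only); the
  defaults place the seven analytes at 10–65 min in the published elution
  order, spaced far beyond the 0.5-min matching window. Peak widths
  (σ = 0.12–0.18 min) give the >1.5 resolution the published separation
  reports.
* **Responses** are the published calibration slopes; mean concentrations
  are the published mean contents (mg/mL at unit extraction factor).
* **Between-batch dispersion** is lognormal per analyte with the published
  C.V. row (32.2–96.5%) as targets, converted exactly via
  `σ_log = √ln(1+CV²)`; lognormality keeps areas positive at CVs
  approaching 100%, where a normal model would go negative.
* **Nuisance structure**: retention jitter N(0, 0.067 min) per analyte
  per batch (so batch shifts stay within ±0.2 min at 3σ), a slow
  sinusoidal drift (amplitude 5, period 40 min), Gaussian detector noise
  (sd 2), and optional per-analyte constant area offsets that emulate
  detector bias and realize the intercept terms end to end.
* **Shared matrix background**: every batch also carries a fixed template
  — a solvent front at 2.8 min (amplitude 2×10⁶, far off the analyte
  scale, as solvent fronts at 220 nm are), a broad late-gradient hump at
  90 min, and 18 minor matrix peaks placed clear of the analyte windows —
  rescaled per batch by a 10% lognormal factor.

The background deserves its own paragraph because it carries a
substantive point. With only the seven analyte peaks, batch-to-batch
similarity to the median reference *cannot* exceed 0.95 for all batches
once the marginal area CVs reach the published 32–97% — the profile
swings are simply too large; even the published peak-area table itself
gives matched-peak correlations down to ~0.5 for the most divergent
batches. The published similarities of 0.96–0.99 and the published CV row
are jointly consistent only if shared trace structure dominates the trace
energy, which is exactly the standing critique of full-trace fingerprint
similarity: it is driven by what all batches share (solvent front, common
matrix constituents), not by the quantified panel. The generator
therefore includes the shared background, scaled once at design time so
that generated batch similarities fall in the published 0.96–0.99 band;
under these conditions the all-batches-above-0.95 property holds with
margin across seeds. Passing similarity tests consequently demonstrate
the pipeline's alignment and scoring machinery — not that similarity
scores discriminate composition, which (by this very construction) they
largely do not.

What the generator does **not** model: gradient-dependent retention or
peak-width changes, UV spectra, detector saturation, the
gastrodin ↔ *p*-hydroxybenzyl alcohol interconversion chemistry, and any
correlation structure between analyte concentrations across batches
(concentrations are drawn independently per analyte). Passing tests
therefore say nothing about those aspects of real data.

All randomness flows from a single `numpy` `default_rng` seed; equal
seeds give bit-identical panels, traces and reports.

## Problem sizes and tolerances

The packaged tables are 21 samples × 7 analytes; synthetic runs default
to 21 batches on the full 13 001-point grid, and unit tests use 3–8
batches or 20-min grids. End-to-end area recovery is asserted at 5% per
cell (measured ~1–2% at the default noise level); calibration-slope
recovery at 3% under 1% multiplicative noise; the noise estimator within
[0.95, 1.05] at n = 10⁴; dispersion recovery of a 50% CV target within
[43%, 57%] at n = 200 (the lognormal sampling band); reproduction of
printed values at the precision each table prints (4 d.p. for correction
factors, 0.1 for C.V. percentages, 2 d.p. for contents).

## Known limitations

* Two published values are not reproducible from the printed tables and
  their tests are deliberately left failing: the parishin C correction
  factor (printed 1.6771 vs slope ratio 1.67651 — the published factors
  were evidently computed from unrounded or multipoint-averaged data) and
  the parishin C method correlation (printed ≥0.998 vs 0.9923 on the
  2 d.p. printed contents, whose rounding noise is large relative to that
  analyte's ~0.15 mg/g scale).
* The content table carries its printed anomalies verbatim (a 0.00
  single-marker parishin A cell for S2; a three-decimal 0.531 cell for
  S7); no "corrections" are applied anywhere downstream.
* Absolute contents from raw chromatograms depend on the unrecoverable
  extraction factor; only ratios and fixture-based contents are
  meaningful.
* LOD/LOQ estimation scans a measured dilution series; it does not
  extrapolate below the lowest tested concentration.
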