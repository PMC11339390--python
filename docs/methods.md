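# Methods

This note documents the models, conventions and numerical choices behind
`todsense`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show.

## Signal model and synthetic data

The reporter generator draws

    value(t) = B·e^(−b t) + A·e^(−d t)·cos(2πt/P + φ) + u·A·cos(2πt/12) + ε_t,

clipped at 0, with Gaussian noise ε_t.  Defaults emulate a typical
luminescence recording: period P = 24 h, 120 h duration at 10-min sampling,
baseline B = 5·A decaying at b = 0.005/h, oscillation damping d = 0.01/h
(about one e-fold over 4 days), noise 10% of amplitude.  The 12-h term
models ultradian contamination and is off by default.  The anti-phasic pair
shifts the phase of the second channel by π with independent noise.

Growth is exponential (optionally logistic toward a carrying capacity)
with unit-mean lognormal multiplicative noise — counts are positive and
downstream analyses are fold-change based, so multiplicative noise is the
natural error model — rounded to integer counts.  Dose-response panels
invert the GR relation: GR(c) from the sigmoid, treated rate
k(c) = k0·log2(GR(c) + 1), so the full fitting chain can be checked
against planted (GRinf, GEC50, Hill).  ToD experiments draw the fold
change at circadian time T from base·(1 − depth·cos(2π(T − acrophase)/24))
with lognormal noise, reported as count pairs at treatment and at
treatment + 96 h; defaults are depth 0.15, acrophase 12 h, two replicates,
CV 5%, on the standard reset/treatment schedule.  Expression matrices are
Gaussian per gene (mean 5 log2 TPM, sd 1) with a planted linear outcome.

Every generator is a pure function of (parameters, seed); substreams are
derived from one root seed by hashing a module tag, so runs are
reproducible end to end.

What the generators deliberately do not model: mechanistic clock-gene
networks, cell-cycle/clock coupling, density-dependent drug effects,
plate-position or evaporation artifacts, and segmentation errors in the
imaging readout.  Passing the recovery benchmarks therefore shows the
estimators are correct and stable under realistic noise, not that real
recordings satisfy the damped-cosine or exponential-growth assumptions.

## Circadian analysis

**Detrending.** A Hamming-windowed sinc low-pass with cutoff *period*
48 h (kernel length ≈ 4 cutoff periods, symmetric reflection padding)
estimates the trend; the detrended signal is the residual.  Records
shorter than one cutoff period are rejected.

**Amplitude envelope.** sqrt(2) × the rolling RMS over a 48-h window.
This is exact for a constant-amplitude sinusoid and tracks exponential
damping to within a few percent, where a window max−min estimate lags the
decay by ~25%.  Samples with an envelope below 1e−9 of the signal sd are
masked.  The Hilbert magnitude serves as an independent oracle in tests.

**Autocorrelation.** Biased normalization (divide by N): it damps
spurious long-lag peaks and is the common library default.  The second
peak is the first prominence-≥ 0.05 local maximum at positive lag; the
white-noise 95% band is 1.96/√N.  Note the finite-record bias: for a
120-h record of a damped 24-h cosine the (1 − k/N) factor and the damping
envelope pull the second peak 0.2–0.7 h early.  This is a property of the
estimator, not a defect; recovery benchmarks therefore assess the lag in
aggregate across seeds.  A lag in [16, 32] h (mirroring the circadian
multiresolution band) sets the circadian flag; out-of-window traces are
flagged, never dropped.

**Wavelet spectrum and ridge.** Complex Morlet (`cmor`, bandwidth 1.5,
center frequency 1.0 — a balanced time-frequency trade-off; recorded in
the spectrum object) on a period grid of 2–40 h in 0.25-h steps.  Power is
normalized so unit-variance white noise has expected power 1 in every
cell: the per-scale filter energy is read off the transform of a unit
impulse, which avoids any analytic approximation of the discretized
wavelet.  On this scale the fixed ridge threshold 40 cleanly separates
persistent oscillations (ridge power O(10²) for a 10:1
signal-to-noise sinusoid) from noise (expected 1, exponential tail).  The
adaptive alternative thresholds at half the spectrum's maximum and is used
for period and phase readouts.  Ridge length counts the union of
contiguous above-threshold segments (a weak, interrupted ridge still
accumulates support); a `longest_only` flag restricts to the longest
segment.  Sinusoid amplitude is recovered as 2|W|/gain with the per-scale
peak frequency response, read from the transform of the detrended
(un-normalized) signal.  Phase differences are taken between the two
channels' complex coefficients along their own ridges and reduced by a
circular mean.

**Multiresolution analysis.** `db20` discrete-wavelet MRA (additive
details + smooth, symmetric extension, level 6) on the detrended trace
block-averaged to Δt = 0.5 h.  Level j spans 2^j·Δt–2^(j+1)·Δt, so
D1+D2 = 1–4 h (noise), D3+D4 = 4–16 h (ultradian), D5 = 16–32 h
(circadian), D6 = 32–64 h.  D6 is reported under the conventional
"infradian (32–48 h)" label with its true dyadic bounds kept in the
result, since a dyadic grid cannot realize a 48-h edge.  Band fractions
divide each band's variance by the summed variance of all five components
(including the residual smooth), so they add to exactly 1 and are
conservative; after 48-h detrending the smooth is typically negligible.
At level 6 on ~240 samples every coefficient sees the boundary; symmetric
extension keeps reconstruction exact and edge artifacts small for the
order-20 filters.

**Global circadian strength.** Each of (autocorrelation peak, ridge
length, circadianicity) is divided by its maximum over the panel and the
three ratios are averaged.  Negative peaks are floored at 0 before
scaling (strength is non-negative; clock-knockout lines can produce
slightly negative peaks), degenerate all-zero columns are dropped from the
mean with a flag, and a `minmax` scaling option is provided for display
conventions that rescale to [0, 1].  Per-reporter metrics are averaged per
model; single-reporter models pass through.

## Growth and dose response

Smoothing is robust locally weighted quadratic regression (tricube
distance weights, default span 10% of points with a floor of 7, four
bisquare reweighting passes).  The bisquare scale is the *local* window
MAD rather than a global one: growth data are strongly heteroscedastic
(residuals scale with counts), and a global scale would zero-weight the
entire well-fitted large-count tail.

Doubling time is computed as t·ln2/ln(y_t/y_0) — positive for growth,
negative for decline — with the 96-h default horizon; y_t is linearly
interpolated.  The exponential rate fixes y0 = 1 after normalizing to the
first timepoint and fits k by nonlinear least squares, falling back to the
log-linear slope (flagged) on non-convergence.

GR fits bound GRinf ∈ [−1, 1], GEC50 ∈ [min dose/10, max dose·10] and the
Hill slope ∈ [0.1, 5] (the customary range in the GR-metrics literature),
with three starts spreading GEC50 across the dose range.  GR50 is the
closed-form inversion of the sigmoid at 0.5 and is undefined when
GRinf ≥ 0.5.  GR_AOC is the trapezoidal mean of (1 − GR) over log10 dose,
normalized by the spanned log range so different dose designs are
comparable; the EC50 sigmoid restricts Emin to [0, 1] and its slope to
[0.5, 10].  Control (dose-0) wells define k(0).  Clustering is
average-linkage (UPGMA) on Euclidean distances after nearest-column
imputation: a missing cell is filled from the column minimizing RMS
distance over jointly observed rows.

## Time-of-day profiling

Circadian time is (treatment − reset) − 24 h, so the standard design
yields exactly {0, 4, 8, 16, 20, 24}; non-standard designs may produce
negative values, which are retained and also reported mod 24.  Times 0 and
24 h are distinct measurements (24 h apart in culture time) and are never
averaged; circularity is imposed only in histograms, where 24 wraps into
the bin of 0.

Responses are fold changes over a fixed 96-h horizon after a 4-h moving
average of the counts, and are normalized to the response at circadian
time 0 (replicates averaged, per-time s.d. kept).  The ToD curve is a
cubic smoothing spline minimizing p·Σ(y−f)² + (1−p)·∫f″² with p = 0.7 on
an hour-scaled abscissa — the parameter's meaning is scale-dependent, so
this convention is fixed explicitly (internally lam = (1−p)/p).  ToD_MR is
max − min of the smoothed curve on a 0.1-h grid; the unsmoothed max − min
is reported alongside as a smoothing-artifact control, and the two
correlate at r ≥ 0.9 across synthetic panels.

Benefit is reference − cancer on a common dense grid (positive where the
cancer model is relatively more suppressed); fold changes are
reference/cancer so values > 1 mean net benefit, an invertible convention
stated with every output.  Extremum ties break toward the earliest time
and are flagged.  The chronotherapeutic index is the mean (± s.d.) of the
benefit fold changes per model across drugs and per drug across models,
ranked descending.

## Determinants

Features are standardized (zero mean, unit variance) before every
multivariate analysis, so attribution shares are comparable across units.
Pairwise correlations report Pearson r, R² and unadjusted two-sided p.
The prediction path screens features at training |r| ≥ 0.5 and fits one
simple linear model per screened feature (the per-feature route keeps the
responsible feature identifiable; a mean-of-predictions column is
provided); Bland–Altman agreement is bias ± 1.96·sd of the differences
(sample sd).

Shapley (dominance) shares are exact over all 2^k predictor subsets up to
k = 20, using the standard ordering weights s!(k−s−1)!/k!; beyond that,
10,000 seeded permutation samples.  R² comes from minimum-norm least
squares, which is the ridge limit for rank-deficient designs (flagged), so
exactly duplicated features split their combined share equally.
Completeness (shares sum to the full-model R²), symmetry and the dummy
property are asserted against an independent all-orderings oracle in the
tests.

LDA binarizes the outcome at its median (ties to the high class, flagged —
panels usually have even n, so ties are rare), fits a single-component
discriminant on standardized features inside a scaler pipeline, and
defines contributions as |coefficient|/Σ|coefficients|·100; when n does
not exceed the feature count a shrinkage covariance estimator is
substituted and flagged.  Robustness is the leave-one-out CV accuracy of
the same pipeline.  PCA reports explained-variance fractions and loadings
with each component's sign chosen so its largest-magnitude loading is
positive.  Spearman gene correlations use correlation-distance
single-linkage clustering for display order.

## Problem sizes and tolerances

The test and benchmark suites run on the generators' default conditions:
120-h reporter records at 10-min sampling, 96-h growth records at 2-h
sampling with ~1000 starting cells, 6 log4-spaced doses, the standard
6-point ToD schedule, and 8–15-model phenotype panels.  Multi-seed checks
use 20–200 seeds depending on the statistic.  Noiseless closed-form
identities are asserted at 1e−9–1e−12; ACF values against the brute-force
oracle at 1e−10; noiseless nonlinear-fit recoveries at 1e−4 relative
(integer count rounding is the limiting quantization); noisy recoveries at
5–20% depending on the stage.

## Known limitations

- The autocorrelation lag estimator carries the finite-record bias
  discussed above; comparisons between models are unaffected, absolute
  lags are biased slightly low.
- Ridge periods are quantized to the 0.25-h grid, so monotone drifts show
  single-bin dithering.
- The dominance enumeration is exponential in the feature count; panels
  beyond 20 features switch to sampled permutations.
- The smoothing-spline parameter p is tied to the hour-scaled abscissa;
  curves from tools using a different abscissa scaling are not directly
  comparable at equal p.
- Rhythm detection is descriptive (no Lomb–Scargle/cosinor significance
  testing), and growth models are exponential/logistic only.
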