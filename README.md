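# todsense

Deep circadian phenotyping and time-of-day (ToD) drug-sensitivity profiling
for cancer cell models.

Cancer cells often retain a functional circadian clock, and the efficacy of
many drugs depends on the internal time at which they are given.  `todsense`
implements the computational side of a chronopharmacology screening
pipeline: it quantifies how strong a cell model's clock is from luminescence
reporter recordings, characterizes growth and drug sensitivity from
live-imaging cell counts, builds time-of-day response profiles, and asks
which cellular features determine that time-of-day dependence.  It is aimed
at chronobiologists and pharmacologists analyzing long-term reporter and
live-imaging data, and ships a synthetic-data generator so every stage can
be exercised — and its planted parameters recovered — without raw
recordings.

## What it computes

**Clock strength.** Reporter traces (e.g. *Bmal1*-Luc / *Per2*-Luc, ~10-min
sampling over ~5 days) are detrended with a sinc filter (48-h cutoff
period), amplitude-normalized by a sliding 48-h envelope, and summarized
by:

- the autocorrelation second peak (value and lag),
- a Morlet continuous-wavelet ridge (mean period, amplitude and ridge
  length in days; power is calibrated so unit-variance white noise has
  expected power 1, making the fixed ridge threshold of 40 comparable
  across signals),
- a Daubechies-20 multiresolution decomposition at Δt = 30 min whose
  dyadic bands are noise (1–4 h), ultradian (4–16 h), circadian (16–32 h)
  and infradian (32–64 h); the circadian variance fraction is the
  "circadianicity".

The global circadian strength of model *i* across a panel is

    GCS_i = mean(peak_i / peak_max, ridge_i / ridge_max,
                 circadianicity_i / circadianicity_max).

**Growth and drug sensitivity.** Count trajectories are smoothed by robust
local quadratic regression; doubling time is t·ln2 / ln(y_t / y_0) and the
exponential rate k comes from fitting y(t) = e^{kt} to counts normalized at
t = 0.  Drug effects use the growth-rate-inhibition framework

    GR(c) = 2^{k(c)/k(0)} − 1,

fitted over dose to GR(c) = GR_inf + (1 − GR_inf) / (1 + (c/GEC50)^h),
yielding GR_inf, GEC50, the Hill slope, GR50 (closed-form inversion at
GR = 0.5), GR_AOC (mean of 1 − GR over log10 dose) and classical
EC50/Emin fits, plus UPGMA clustering with nearest-column imputation for
panel heat maps.

**Time-of-day profiling.** Staggered clock resets (0/4/8 h) with
treatments at 32/48 h map to circadian times {0, 4, 8, 16, 20, 24} h.  The
response at each time is the 96-h fold change in cell number, normalized
to the response at circadian time 0; a cubic smoothing spline (parameter
0.7) gives the ToD response curve and its max − min is the ToD maximum
range (ToD_MR).  Comparing a cancer curve with a non-malignant reference
yields benefit times, benefit fold changes, circular benefit-time
histograms and the chronotherapeutic index (mean fold change across drugs
or models).

**Determinants.** Feature matrices (clock, growth, drug-sensitivity
metrics or clock-gene expression) are related to drug-specific ToD_MR by
pairwise regression, |r| ≥ 0.5-screened prediction with Bland–Altman
agreement, Shapley-value (dominance) decomposition of the regression R²,
median-split LDA contributions with leave-one-out cross-validation, PCA
loadings and Spearman gene correlations.

## Worked example

```sh
python examples/circadian_strength.py
```

```
Per-trace clock metrics:
  cell_model channel  ac_peak  ac_lag_h  ridge_length_d  circadianicity
strong_clock   Bmal1    0.773    23.667           5.007           0.894
strong_clock    Per2    0.785    23.833           5.007           0.923
  weak_clock   Bmal1    0.200     2.167           1.229           0.472
  weak_clock    Per2    0.246     0.500           1.472           0.484

Global circadian strength (max-normalized mean of peak, ridge, circadianicity):
cell_model
strong_clock    1.000
weak_clock      0.361

Bmal1-Per2 circular mean phase difference: +3.12 rad (pi = 3.14 would be perfectly anti-phasic)
```

The strong-clock model keeps a near-24-h autocorrelation peak (0.77 at
23.7 h), a wavelet ridge spanning the whole 5-day recording and ~90% of its
detrended variance in the circadian band, so it takes the maximal GCS of 1;
the noisy, fast-damping model scores 0.36.  The two reporters are recovered
as anti-phasic (phase difference ≈ π).

The other examples follow the same pattern: `growth_and_dose_response.py`
recovers planted GR parameters from a simulated dose panel,
`tod_profile.py` builds ToD curves and benefit annotations, and
`determinants_of_tod_sensitivity.py` attributes a planted expression
determinant.

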