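# Methods notes

## Detrending model

Each transect's increment-width series is treated as a smooth ontogenetic
decline times stationary multiplicative variation:
`w(t) = s(t) · I(t)`.  The smooth part is estimated by a cubic smoothing
spline and the indices `I = w / s` are dimensionless with mean ≈ 1, so
later averaging steps weight fish equally regardless of absolute growth.

The spline's flexibility is specified by its 50% frequency cutoff: the
sinusoid wavelength (years) at which the fitted curve passes half the
amplitude.  For annual spacing the smoothing parameter follows the
standard penalised-spline frequency-response relation
`p = 1 / (1 + (1−f)(cos(2π/w)+2) / (12 f (cos(2π/w)−1)²))` with response
`f = 0.5` and cutoff `w`; the solve uses
`scipy.interpolate.make_smoothing_spline` with `lam = (1−p)/p`.  The
relation is *verified, not trusted*: the test suite fits pure sinusoids
and measures the realised gain (0.50 at the cutoff, ≥ 0.99 at 4× the
cutoff, ≤ 0.01 at cutoff/4, monotone across a frequency grid).

Defaults: `cutoff_years = 9` for analysis, configurable; a 22-year cutoff
is the conventional stiffer alternative and both appear in the rigidity
scan.  The spline is fitted on the full series with no padding; end years
therefore carry more fitting variance, a known property of all spline
detrending.  If a fitted curve turns non-positive (possible on very short,
steeply declining series) the series falls back to a horizontal-mean
detrend and is flagged in the detrend report rather than failing the run.

**Rigidity scan.**  `select_rigidity` runs the full detrend → IMS →
windowed-statistics pipeline per candidate cutoff and tabulates r̄, s.e.,
EPS, pair count and mean sensitivity.  The default choice maximises the
selected-window EPS, ties going to the stiffer spline (less risk of
fitting noise).  The scan is a diagnostic: no single scalar criterion is
canonical in the field, so the table is always returned for inspection.
A flexible (9-yr) cutoff beats a stiff (22-yr) one exactly when
individual-level noise is concentrated in the 9–22-year band; a stiff
spline retains *more* of any sub-22-year common signal, so flexible
cutoffs are not automatically better.

## Individual mean series and chronology

Transect indices are combined by year-wise arithmetic mean into the IMS
(averaging across k transects shrinks measurement noise by 1/k), and IMS
into the mean index chronology the same way.  A Tukey biweight mean
(c = 9) is available for the chronology when outlier years are a concern;
it is only applied at sample depth ≥ 6, where the median/MAD scale is
stable.

## Signal statistics and window selection

For each sliding window (default 15 years, step 1) the statistics use only
series *fully* covering the window, keeping r̄ and its sample depth n
mutually consistent.  `rbar` is the mean of the n(n−1)/2 pairwise Pearson
correlations; its standard error is `sd(pairs)/√n_pairs`, which treats
pairwise correlations as independent although pairs share series — a
simplification matching the plainness of the selection criterion itself,
and slightly anti-conservative.  EPS uses the same n.  A window qualifies
when `rbar − 2·se > 0`; among qualifiers the one with the most pairwise
correlations is selected, ties to the earliest start.  No qualifying
window is a legitimate result ("no adequate signal"), reported as such
rather than raised as an error.

## Crossdating quality control

Dating is screened, never corrected: each series is compared with a
leave-one-out master built from all other series after high-pass
filtering (the detrending spline at a 15-year cutoff), AR(1) prewhitening
and z-scoring.  Fifteen-year segments at 50% overlap are correlated with
the master at lags −2…+2.  A lag is only assessed when the full segment
overlaps the master — truncated edge overlaps produce unstable
correlations and spurious flags.  Flags: best lag ≠ 0, or lag-0
correlation below the one-tailed 99% critical value
`t₀.₉₉/√(t₀.₉₉² + n − 2)`.

Sign convention: `best_lag = +1` means the series looks dated one year
too old (shifting its labels forward by one aligns it with the master);
this is pinned by a unit test.

Flag rates must be read against signal strength.  With a strong common
signal (share ≈ 0.8, segment r ≈ 0.9) well-dated series are flagged
< 5% of the time; at the weak-signal levels typical of fish
biochronologies most series trip flags simply because 15-year segment
correlations of weakly correlated series often fall below the critical
value.  The crossdating report is therefore a screening device, not a
rejection rule.

## Autoregressive standardization

Each IMS is prewhitened with an AR(p) model, p chosen by AIC over
0…3 (statsmodels `AutoReg`); non-stationary fits fall back to order 0
with a flag.  AIC is deliberately permissive: under a white-noise null it
accepts a spurious AR term with probability ≈ P(χ²₁ > 2) ≈ 0.16 per
candidate order, so roughly 30% of null series get a nonzero order —
harmless for prewhitening, and the per-series orders are reported.  The
residual chronology is the mean of the recentred residual series; the
"ar_standardized" variant re-runs the pooled AR recursion (coefficients
averaged over series, weighted by length) over the residual chronology,
restoring the common persistence structure.  All three variants
(standard, residual, ar_standardized) are always produced; downstream
correlation defaults to the ar_standardized one, with the variant
selectable everywhere.

## Environmental correlation

Seasonal means use the austral convention with DJF(y) = mean(Dec y−1,
Jan y, Feb y); seasons and annual means require every constituent month.
Sea-level-like series are linearly detrended (OLS on year) before
correlation.  The windowed chronology is paired with each variable at the
growth year ("current") and one year earlier ("previous"); p-values come
from the exact t-transform of r with n−2 degrees of freedom, two-sided,
uncorrected for multiplicity by default (a Benjamini–Hochberg option
exists).  Annual means are taken over the calendar year, not the
November–October growth year; this is configurable by supplying a
pre-aggregated series.

## Synthetic data generator

`generate_dataset` draws, per fish, a capture year (2005–2011), an age at
capture (27–49) and 3–5 transects; increments exist for ages 13 and above
and for growth years up to the year before capture (the forming increment
is partial; the default capture month of March, chosen because capture
months are genuinely unknown for mid-year fisheries, makes the last
complete growth year capture_year − 1).  Expected widths follow the annual
differences of a von Bertalanffy radius curve (`r_inf = 4` mm,
`k = 0.06 yr⁻¹`, giving a ~9-fold decline from age 13 to 49 and widths of
~0.11 down to ~0.013 mm).  Growth variation is log-normal:
`beta·Z(t−lag) + fish-year noise (σ_f = 0.10) + transect noise
(σ_t = 0.15)`, with Z a standardized AR(1) driver (φ = 0.5).  These σ
values put the IMS mean sensitivity near 0.13 and the nominal
common-variance share converts to beta via
`beta² = v/(1−v)·(σ_f² + σ_t²/k̄)`.

The emitted environment is: the driver plus a linear trend (a
sea-level-like proxy that must be detrended before use), two monthly SST
series loading 0.8/0.7 on the driver, and an independent decoy index.
Ground truth (driver, beta, lag, realised share, per-fish design) is
stored with every dataset.

What the generator does *not* emulate: age-reading error, within-year
growth seasonality, density dependence, non-stationary noise variance,
and real spatial structure in SST.  Passing tests therefore demonstrate
that the pipeline recovers known structure under the stated noise model,
not that any particular field dataset is correctly dated or driven.

Two consequences of spline detrending show up in validation and are
expected: (1) the realised windowed r̄ for a nominal share of 0.035 is
~0.02, because the 9-year spline removes part of the driver's
low-frequency variance from every series before correlations are taken;
(2) chronology-versus-driver recovery is judged against the identically
high-pass-filtered driver, since the chronology cannot contain frequencies
detrending removed.

## Problem sizes used in validation

Replicated checks use the study-scale design (44 fish, 15-year windows)
with 50 replicates for calibration/recovery rates, 200 replicates for
dating-error detection (at 20 series × 40 years), and 10,000 draws for
the null rejection rate of the correlation test — sizes at which the
binomial noise on each asserted rate is comfortably inside the asserted
bands.

## Known limitations

- The s.e. of r̄ ignores the dependence between pairs sharing a series.
- No variance stabilisation for changing sample depth, and no subsample
  signal strength statistic.
- Crossdating is flag-only; re-dating is left to the analyst.
- EPS at a given printed precision pins sample depth only loosely: at
  r̄ = 0.035, depths 41–42 give 0.60 while 43–44 give 0.61.
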