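# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `seasonflow`. Nothing here states an empirical result
that the test suite does not itself compute.

## Data model and QC

A `SampleTable` holds a samples × taxa integer count matrix with
per-sample plant, ISO-8601 date and optional replicate link. The QC
order is fixed and deliberate:

1. `filter_min_reads` (default 10 000, strict "less than") on raw
   counts;
2. rarefaction-based alpha diversity on the filtered raw counts
   (rarefaction needs integers);
3. `merge_replicates` — replicate groups collapse to the arithmetic mean
   of their relative abundances; the merged table is proportion-valued
   and flagged as such, so count-only operations refuse it;
4. `aggregate_to_species` — ASVs sharing a species label are summed,
   unclassified ASVs stay as their own species-level units (totals
   conserved exactly);
5. `retain_abundant_species` — maximum relative abundance > 0.05 %
   (strict) in at least one sample.

Replicates are identified by an explicit `replicate_of` column; if a
group's anchor sample was removed by the read filter, the surviving
replicate stands alone rather than erroring.

## Compositional transform

The robust centred log-ratio divides each taxon's reads by the geometric
mean over the *observed* (non-zero) taxa of the sample before taking
natural logs; zeros remain missing (NaN). Natural log is used throughout
— the base only rescales amplitudes, not p-values, Fs, phases or
cohorts. rclr is scale-invariant per sample, so it can be applied to the
proportion-valued merged table without change.

Before decomposition, missing rclr values are set to 0 (the sample's
geometric mean) by default, because STL needs complete series; an
`interpolate` mode instead drops missing observations and interpolates
across them. Which choice the field's workflows make is usually
unstated; the default is the more conservative (a species not observed
is placed at the community's typical level, biasing its amplitude
towards zero rather than inventing signal).

## Weekly grid and STL with a periodic seasonal window

Observations every 7–10 days are linearly interpolated onto an exact
7-day grid starting at the first observation, with no extrapolation.
Decomposition requires at least two full 52-week cycles.

The STL implementation follows the classic inner loop with the periodic
simplification: each cycle-subseries (all values sharing a week-of-year,
index t mod 52) is replaced by its mean; a low-pass filter (moving
averages of length 52, 52, 3, then a degree-1 loess with window 53)
removes trend leakage from the seasonal; the trend is a degree-1 loess
(default window 79, the smallest odd integer ≥ 1.5 × frequency) of the
deseasonalised series. The loess is the standard local linear fit with
tricube weights over the q nearest neighbours. After the loop the
seasonal is re-averaged per week-of-year — the reference R
implementation applies the same post-processing for `s.window =
"periodic"`, which is what makes its seasonal exactly periodic.

Two numerical choices differ from the reference defaults:

* **Inner iterations** run to convergence (seasonal change < 1e-9, at
  most 30 passes) instead of a fixed 2. At 2 passes both this
  implementation and the reference leave visible seasonal leakage on a
  pure linear ramp (max |seasonal| ≈ 0.06 for slope 0.01/week); at
  convergence the ramp decomposes exactly (< 1e-9). Agreement with the
  reference on a frozen noisy fixture is RMSE ≈ 0.003, far inside the
  0.05 cross-implementation tolerance.
* **Remainder** is defined as `input − (trend + seasonal)` and stored,
  making the additive identity exact by construction; re-summing the
  three components reproduces the input to the last rounding step
  (≤ 1e-12), since bitwise equality under re-summation is not a
  property IEEE arithmetic can guarantee.

Robustness (outer) iterations with bisquare weights are available but
default to 0, matching the reference when robustness is not requested.
Weeks beyond index 52 in long years simply fold into the 52-week cycle
via the modular week index of the regular grid.

## Harmonic model, peak week, confidence interval

The annual harmonic *y(t) = m + A·cos(2πt/P − φ)*, P = 52 weeks, is
fitted by OLS on the basis {1, cos(2πt/P), sin(2πt/P)}; A is the norm of
the two trigonometric coefficients, φ their atan2. Significance is the
exact F-test of the two trigonometric terms jointly against the
intercept-only model (2 numerator df); ties at the threshold count as
significant (p ≤ α, default α = 0.01). A constant series returns A = 0,
p = 1.

By default the harmonic is fitted to the STL *seasonal component*,
mirroring the standard workflow. Those p-values are anti-conservative:
the seasonal component is smoothed and repeats by construction, so its
residuals are not independent. A `fit_on="raw"` mode fits the
regularised rclr series directly; on pure Gaussian noise that mode is
exactly calibrated (the acceptance suite checks the 1 % level against
the exact binomial interval over 1 000 null series). Consumers who need
honest per-species error rates should use raw mode; the default
reproduces the field's practice.

The peak position on the series' own weekly axis is converted to a
calendar day-of-year through the series start date (week t is
(t−1)·7 days after the start, modulo 365); the reported `peak_week` is
the continuous calendar week (day−1)/7 + 1, folding week 53 into week 1
(a < 1-day distortion at the year boundary). The 95 % CI is a residual
bootstrap (default 1 000 draws): residuals are resampled with
replacement, the harmonic refitted (vectorised through the design
pseudo-inverse), and percentiles taken as circular deviations around the
point estimate, so intervals wrap correctly across the week-52/week-1
boundary. Zero amplitude yields the flagged full-year interval (0, 52).

## Seasonal strength and cohorts

Fs = 1 − var(remainder)/(var(remainder) + var(seasonal)), population
variances, clipped to [0, 1]. Categories are left-closed: Fs ≥ 0.75 very
strong, [0.55, 0.75) strong, [0.35, 0.55) moderate, [0.15, 0.35) weak,
else very weak; non-significant fits are categorised "non-significant"
regardless of Fs (the verbal strict-inequality definitions in common use
leave exact boundary values unassigned; left-closed is the documented
choice).

**Known estimator bias.** With a periodic seasonal window the seasonal
component is a per-week mean over the observed years, so with Y years it
retains σ²/Y of the noise variance while the remainder keeps roughly
σ²(1 − 1/Y). For a latent sinusoid of amplitude A in noise σ the
population target is Fs\* = (A²/2)/(A²/2 + σ²), and the STL-based
estimator is biased upward by ≈ (σ²/Y)/(A²/2 + σ²): about +0.11 at
Y = 3, A/σ = 2. This is a property of the decomposition itself (the
reference implementation shares it), not of this implementation; Fs
values from short series should be read as upper estimates, and
comparisons should use equal series lengths. The acceptance test for Fs
recovery at three years documents this bias by failing the ±0.05 bound.

Cohort windows are the northern-hemisphere astronomical seasons on a
365-day calendar: winter 21 Dec–20 Mar, spring 21 Mar–21 Jun, summer
22 Jun–22 Sep, autumn 23 Sep–20 Dec. The verbal definitions in common
use overlap by two days at the autumn/winter boundary (autumn "to
22 Dec" vs winter "from 21 Dec"); 21–22 Dec is resolved to winter, which
begins astronomically on 21 Dec. A single function (`season_of_day`) is
the only source of these windows — the synthetic generator's ground
truth labels and the analysis-side cohort assignment both call it.

## Growth groups from the immigration mass balance

At steady state, a species' reactor biomass X (relative abundance ×
total cells) obeys V·dX/dt = Q·C_in + k·V·X − (V/SRT)·X = 0, giving the
closed form **k = 1/SRT − C_in/(X·HRT)** per day. This is the simplified
steady-state estimator determined by three assumptions: steady state,
first-order net growth, and biomass ∝ relative abundance × total cells;
outputs are labelled "apparent net growth rate (simplified
steady-state)". Richer paired-sample regression estimators exist but are
out of scope. Per species, per plant, k is aggregated by median across
sampling dates (robust to outlier pairs); groups require agreement
across all plants: growing (every k > ε), disappearing (every k < −ε),
surviving (every |k| ≤ ε, default ε = 0.005 d⁻¹ since "k ≈ 0" needs an
operational width), otherwise ambiguous. Species whose maximum relative
read abundance never reaches 0.05 % are ambiguous regardless of k.
Species absent from the reactor have no defined k and are excluded with
a log entry. Total cell concentrations and SRT/HRT are required inputs —
there are no defensible defaults for a specific plant.

## Cross-plant comparison

Shared-species membership is a boolean species × plants table;
cohort-intersection tables record each shared species' per-plant cohort,
the multiset of distinct labels, and an agreement class: *identical*
(one distinct seasonal cohort), *concomitant* (exactly two distinct,
cyclically adjacent seasons — winter–spring, spring–summer,
summer–autumn, autumn–winter; the wrap pair autumn–winter is adjacent by
the cyclic definition), *mixed* (anything else — in particular the
opposite pairs winter–summer and spring–autumn can never be identical or
concomitant, a structural rule of the classifier), or
*all-non-significant*. Non-significant labels are ignored by the
adjacency test but kept in the intersection key. Cumulative group series
(per growth group or cohort) sum relative abundances per label —
a partition, so labels sum to 1 per sample — then regularise and fit the
harmonic, reporting the fit only at p ≤ α.

## Synthetic generator: what it emulates and what it does not

Each species has a latent log-abundance λᵢ(t) = baselineᵢ +
trendᵢ·t/365.25 + Aᵢ·cos(2π(t − τᵢ)/365.25) + N(0, σᵢ²); reads are drawn
multinomially with probabilities ∝ exp(λᵢ(t)) at a per-sample depth
uniform over the plant's range. A log-linear latent signal is chosen
because its rclr is approximately sinusoidal, matching the analysis
assumptions. Defaults state a realistic survey: 4 plants × 200 species ×
3 years of weekly sampling, depth range 10 893–170 639 reads (the range
reported for multi-year AS surveys of this design), 80 % of species
seasonal with A ~ U(0.5, 2.5) and σ ~ U(0.2, 0.6), peak days uniform
over the year, 5 % of sampling points duplicated as replicates, 2 % of
samples forced below the 10 000-read threshold to exercise QC, and a
growth-rate mixture (45 % growing, 35 % disappearing, 20 % surviving,
all k < 1/SRT). Influent/reactor pairs are constructed so the mass
balance holds exactly for each species' prescribed k, then perturbed by
multiplicative lognormal noise (default sd 0.2 on the log scale); the
lognormal influent is a stand-in, not an inference about real influent
communities. Same seed ⇒ byte-identical output.

The generator does **not** simulate sequencing error, chimeras, primer
bias, influent chemistry or temperature covariates, nor inter-species
correlation beyond the compositional constraint. A green test therefore
establishes statistical correctness of the estimators under the stated
generative model — not robustness to PCR artefacts or to ecological
dynamics outside that model. The generator's annual period is 365.25
days while the analysis grid assumes 52 × 7 = 364; the < 1 day/year
mismatch (≈ half a week of phase over three years) is absorbed by the
reported tolerances.

## Pipeline and determinism

`RunConfig` is the single place thresholds live (read filter, abundance
threshold, α, frequency, Fs cut points, ε for k, rarefaction depth,
bootstrap draws, seeds); there are no hidden defaults in code paths. All
randomness derives from the master seed via fixed per-stage offsets;
reruns with the same config are identical (the test suite checks table
digests). The manifest JSON echoes the config, library versions,
per-stage row counts and runtime; per-plant retained species always
equal seasonality rows. Logging goes to stderr; results never to the
log.

## Known limitations

* Seasonal-mode p-values are anti-conservative (see above); raw mode is
  calibrated but less sensitive for trended series.
* Fs from short series is biased upward by the noise retained in the
  periodic seasonal mean (quantified above).
* The growth estimator assumes steady state between each influent/
  reactor pair; transients violate it and only the median across dates
  guards against that.
* Peak CIs assume exchangeable residuals; autocorrelated remainders
  (common after interpolation) make them somewhat narrow.
* A single annual harmonic cannot represent bimodal seasonality; such
  species show moderate Fs with unstable peaks across plants.
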