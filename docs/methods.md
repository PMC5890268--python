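# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `catenaflux`, in the order the pipeline runs.

## Chamber flux estimation

A closed chamber of headspace volume V (default 0.02951 m³) and basal area A
(default 0.1964 m²) accumulates gas during a ~10-minute closure. Two models
are fitted to each concentration trace:

* **Linear**: ordinary least squares of concentration on elapsed time; the
  slope standard error comes from the residual variance (zero when the fit
  is exact).
* **Saturating exponential**: c(t) = c∞ + (c₀ − c∞)·e^(−kt), parametrised
  internally as c(t) = c₀ + s₀(1 − e^(−kt))/k so that the quantity of
  interest — the t = 0 tangent rate s₀ = k(c∞ − c₀) — is itself a fit
  parameter and carries its standard error directly from the covariance
  matrix (numerically identical to the delta method on (c₀, c∞, k)). The
  t = 0 rate is reported, not the mean slope over the closure, because the
  tangent corrects the flux-suppression feedback of the accumulating
  headspace. k is bounded to [10⁻⁸, 1] s⁻¹; the fit starts from the linear
  slope and retries from four k starting points; non-convergence yields a
  flagged estimate with infinite uncertainty rather than an exception.

Concentration rates (ppm s⁻¹ for CO₂, ppb s⁻¹ for CH₄) become surface molar
fluxes through the ideal-gas bridge F = (dc/dt)·PV/(RTA); because
concentrations are mole fractions, ppm maps to µmol m⁻² s⁻¹ and ppb to
nmol m⁻² s⁻¹ with no extra factor.

**Model selection and QC.** The model with the smaller uncertainty ratio
se/|F| is selected (exact ties go to the simpler linear model). A closure
is rejected when: both ratios exceed `max_uncertainty_ratio` (default 1.0);
duration falls outside [540, 660] s; the initial concentration deviates
more than 25% (relative) from ambient (failed flush); chamber temperature
leaves [10, 45] °C, RH exceeds 100% or is negative, or pressure leaves
[85, 110] kPa; or the trace has fewer than 8 samples. The first 30 s of
every closure are excluded from fitting (headspace mixing artifact). All
thresholds live in `QcPolicy`; the duration window is the only one with an
authoritative external value — the others are sensible field defaults and
are deliberately configurable. Unordered or sub-3-sample traces are hard
errors, not flags: they indicate corrupted files rather than bad closures.

## Soil-moisture segmentation

The series segmented is the daily mean over all 35 sensors (per-variable
option exposed). Gaps up to 3 days are linearly interpolated; longer gaps
split the record and the longest contiguous chunk is segmented.

For a candidate breakpoint count m the globally RSS-optimal partition into
m + 1 segments — each fitted with its own intercept and linear time trend,
each at least ⌈h·n⌉ observations long (h = 0.15) — is found by dynamic
programming over a precomputed O(n²) triangle of segment RSS values
(prefix-sum closed forms). This is exactly the exhaustive optimum; a test
verifies DP ≡ brute-force enumeration on hundreds of random series.

m is chosen by BIC(m) = n·ln(RSS_m/n) + p_m·ln(n) with
p_m = 2(m + 1) + m + 1 (two regression coefficients per segment, m break
positions, one error variance). Equal RSS prefers fewer breaks. The supF
statistic is the maximum over admissible split points of the F test of
one-break vs. no-break; its p-value comes from ≥999 simulated null series
of iid Gaussian noise — the statistic is invariant to the null's intercept,
trend and variance, so simulating standard normals is fully general.
Simulation was chosen over asymptotic response-surface approximations for
exactness at this series length; with 999 replicates the smallest
reportable p is 0.001. Breakpoints are reported as the date of the first
observation of the new segment.

## Period × zone statistics

Cell summaries report n, mean, s.d. (ddof = 1), s.e.m. = s.d./√n, and the
90th percentile. Quantiles use linear interpolation between order
statistics (NumPy default, R type 7) — stated explicitly because published
90th percentiles are convention-sensitive.

The flux record is analysed with a repeated-measures two-way ANOVA:
chamber is the subject, drought period the within-subject factor, zone the
between-subject factor (each chamber sits in one zone). Observations are
aggregated to chamber × period means before the ANOVA, which tempers the
strong serial correlation of closures repeated every two hours; a
chamber-day aggregation and a no-aggregation mode are exposed for
sensitivity analysis. CO₂ is log-transformed (non-positive values dropped,
with the count reported); CH₄ is left untransformed because uptake makes it
sign-indefinite. Soil chemistry, sampled from fresh random locations each
campaign, uses an ordinary two-way ANOVA with interaction. Significant main
factors get Tukey HSD pairwise comparisons. Hot moments are observations
strictly above the per-period 90th percentile; a period needs at least 10
observations for its threshold.

## Monte Carlo upscaling

Inputs are period × zone × gas means and standard deviations of the
retained fluxes. Each simulated day draws one flux per zone from
Normal(mean, s.d.) — independent across days and zones, the minimal reading
of "mean (±s.d.) flux rate". CH₄ draws keep their sign; CO₂ draws below
zero are redrawn (truncation at zero), since bulk soil respiration cannot
be negative. The zone draws are combined with weights ridge 0.17 /
slope 0.65 / valley 0.18 and converted by
F·(mol per unit)·86400 s·10⁴ m² ha⁻¹·M·GWP/1000 to kg CO₂e ha⁻¹ day⁻¹
(M = 44.01/16.04 g mol⁻¹, GWP 1/34 for CO₂/CH₄).

The study window is 326 days decomposed as pre-drought 63 + drought 121 +
recovery 92 + post-drought 50 days: the chamber record begins in late
February, and this start date makes the 50-day post-drought rebound window
coincide with the in-window post-drought days. All period lengths, the
window and the weights are configurable. The default 5000 simulations give
percentile 95% CIs; the offset statistic (post-drought rebound ÷ drought +
recovery sink) is computed per paired draw, draws with a non-positive sink
are excluded and counted, and its CI may legitimately exceed 100%.

## The synthetic campaign

The generator emulates the study conditions, not just convenient test
fixtures; its defaults are the conditions every statistical test runs
under.

* **Sensors.** Hourly moisture, O₂ and temperature for 5 transects × 7
  positions over 2014-11-01 → 2016-02-15, with true breakpoints at
  2015-04-25 / 2015-08-24 / 2015-11-24. Within a period each series is
  stationary AR(1) noise (hourly coefficient 0.9) around the period mean;
  periods join through a linear ramp centred on the breakpoint. Regime
  anchors: ridge moisture 0.36 → 0.13 (pre → drought, s.d. 0.08 → 0.02),
  valley 0.51 → 0.37; valley O₂ 5.6% → 11.2% while ridges stay near-oxic;
  post-drought moisture returns to pre-drought values while valley O₂ lags.
  Intermediate positions interpolate linearly between ridge and valley
  anchors, preserving the monotone catena gradients (enforced invariants).
  Recovery-period values are interpolations — no observed end-member exists
  — and `truth.json` flags them as such.
* **Transition window: 7 days.** Belowground drought onset in this system
  is fast — order one to three weeks for moisture, with valley O₂ doubling
  within a single week — and the segmentation model this series feeds is
  piecewise linear with abrupt parameter changes. A 7-day ramp is the
  faithful emulation of that regime structure; with windows ≳2 weeks the
  generated series is no longer "four regimes with three breakpoints" but
  visibly trends inside segments, and BIC (correctly) starts spending a
  fourth break on the transition itself.
* **Shared weather noise.** 75% of each sensor's temporal variance is a
  plot-wide common AR(1) component, the rest idiosyncratic. The sensors sit
  within a 50 × 50 m hillslope and see the same rainfall, so their
  fluctuations co-vary strongly; the split keeps each sensor's marginal
  s.d. at its configured value while giving the catena-mean series the
  day-to-day wander real aggregated records have.
* **Rainfall.** Wet-day/gamma daily totals; the drought calendar year is
  scaled to exactly 2035 mm and each of ten baseline years to 4219 mm; the
  climatology is the baseline day-of-year mean.
* **Chamber traces.** Nine chambers (three per zone), up to 12 closures per
  chamber-day. True fluxes are drawn per period × zone × gas from a
  Gaussian bulk (printed means and s.d. where available: slope CO₂
  3.79 ± 2.92 → 6.06 ± 4.26 µmol m⁻² s⁻¹; valley CH₄ 17.43 ± 29.60 →
  1.67 ± 4.09 nmol m⁻² s⁻¹; ridge CH₄ −0.64 pre with a 76% stronger drought
  sink; slope CH₄ 0.15 → 15.16 post; unprinted cells are interpolations
  flagged in the ground truth) plus, for CH₄ outside the drought, a
  lognormal hot-moment spike mixture (weight 0.08, scale 3× the cell s.d.)
  — printed s.d. far above the mean implies a heavy right tail, which is
  what makes 90th-percentile hot moments meaningful. Traces are built by
  inverting the flux model (linear or saturating with k = 8×10⁻⁴ s⁻¹),
  adding instrument noise (0.2 ppm CO₂, 2 ppb CH₄). Malfunctions — short
  (<9 min) and long (>11 min) closures, failed flushes (±35–80% initial
  offset), covariate spikes, whole-day outages — are injected with
  configured probabilities and recorded in the truth table.
* **Soil chemistry.** Six replicates per campaign × zone with Gaussian
  noise (15% CV; pH ± 0.1), truncated at zero, pH clipped to [2, 9]. Cell
  means encode the observed directions: valley inorganic P −60%, organic P
  +301% (valley) / +126% (ridge) / +56% (slope), Fe(II) down, Fe(III) up,
  valley pH down.

What the generator does **not** emulate: spatially explicit hydrological
routing between positions (positions are statistically, not physically,
coupled), instrument drift, diel flux cycles, rain-pulse flux events
correlated with the rainfall series, or water-vapour dilution in the
chamber. Passing tests therefore demonstrate that the estimators recover
the truth under the assumed statistical structure, not that the structure
captures every feature of real field data.

## Problem sizes

The test suite and the acceptance script run the campaign at reduced scale
chosen for desk-scale runtimes: 50 replicate drought years for breakpoint
recovery; 60 chamber days (15 per period, vs. ~150 in a full campaign) at
6 closures per chamber-day for the flux pipeline; 500 replicates for ANOVA
type-I calibration and 40 for power; 5000 Monte Carlo draws (the full
count) for upscaling. Sample-moment checks use n = 10⁴ draws.

## Known limitations

* The exponential fit can be weakly identified when curvature is tiny
  (k·t_max ≪ 1); its inflated standard error then correctly routes model
  selection to the linear fit, but the fitted k itself is meaningless there.
* The ecosystem totals depend on the interpolated recovery/post-drought
  flux cells; with a fully observed campaign table those cells would come
  from data, and the offset statistic in particular is sensitive to them.
* The repeated-measures ANOVA uses chamber × period aggregation rather than
  a mixed model with explicit AR errors; with nine subjects the sphericity
  assumption is taken as-is (no correction applied to the reported p).
* supF p-values are simulation-based and bounded below by 1/(reps + 1).
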