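# Methods

This note records the models implemented by `squant`, the assumptions they
make, the defaults chosen where the procedure leaves freedom, and what the
synthetic test bed does and does not establish about real recordings.

## Synthetic recordings

A simulated voltage-clamp trace is

    I(t) = I_hold + Σ_k s · A_k · K(t − t_k) + ε(t),

low-pass filtered as a whole (4th-order Butterworth, zero-phase, 1.5 kHz
default at 10 kHz sampling). `s` is −1 for inward (sEPSC at −60 mV) and +1
for outward (sIPSC at 0 mV) events; events sum linearly with no
driving-force saturation, appropriate for the small-current regime this
tool targets.

* **Kernel** K: bi-exponential `exp(−t/τ_d) − exp(−t/τ_r)`, peak-normalized
  so a drawn amplitude is reproduced exactly. The kinetics of the modelled
  currents are not pinned by the analyses themselves, so τ_r = 0.5 ms and
  τ_d = 6 ms are exposed defaults, not measured values; event charge is
  analytic (A·(τ_d − τ_r)/peak), which gives every trace an exact
  ground-truth charge (truncated analytically at the trace end).
* **Amplitudes**: two-component normal mixture, truncated at 0 by
  redrawing (clipping would pile probability mass at 0 and distort the
  CDF). Defaults are the wild-type-like sIPSC values: small ≈ 28 ± 8 pA,
  large ≈ 95 ± 25 pA, 4:1 weight.
* **IEI processes**: exponential (Poisson train), gamma/lognormal renewal,
  constant, and an AR(1)-copula (latent Gaussian AR(1) pushed through the
  gamma quantile function). The copula's latent Pearson coefficient is
  ρ = 2 sin(π ρ_S/6) so the lag-1 Spearman correlation converges to the
  requested target while the marginal stays exact. Default rate 10
  events/s, inside the 6–11 Hz range the analyses are designed for.
* **Noise**: white Gaussian, σ = 7 pA before filtering. The filter leaves a
  baseline SD of ≈ 3.9 pA, matching the baseline Gaussian widths the
  all-point histogram method reports on real wild-type recordings
  (σ ≈ 2.5–3.9 pA); this matters because the 1 pA binning and 17-point
  smoothing of the phasic analysis implicitly assume a baseline at least a
  few bins wide.
* A trace whose expected event occupancy (rate × above-5%-of-peak kernel
  duration) exceeds 50% triggers a summation-regime warning.

What the generator does **not** emulate: series-resistance and dendritic
filtering (kinetics are identical for all events), amplitude–kinetics
correlations, slow drifts of the holding current, seal-test transients
(exclusion windows are honoured but no artifact waveform is synthesized),
and non-stationary event rates. Passing tests therefore certify the
*estimators* under controlled conditions, not detection performance on
drifting or poorly clamped recordings.

## Event detection

The detector is deliberately parameter-light and auditable: orient the
trace so events are positive; Savitzky–Golay-smooth (order 2, 2 ms window)
and differentiate; flag upward crossings of k·MAD of the derivative
(k = 4); take the extremum before the derivative's next zero crossing as
the peak; the local baseline is the median of a 2 ms pre-onset window.
Events smaller than 4 robust noise SDs are discarded. Two peaks closer
than (first event's RT10–90 + 1 ms) merge into one event — summated events
are kept as one, never decomposed. Amplitudes are stored as positive
magnitudes; polarity is table metadata.

The 2 ms derivative window was chosen because the filtered noise carries
most of its derivative power near the 1.5 kHz corner while a ~1 ms rising
phase lives near 300 Hz; a window much shorter than 2 ms lets noise set the
MAD threshold above the slope of small events (measured recall on 28 pA
events collapses), while a much longer one blunts genuinely fast events.
At SNR ≥ 10 the detector's recall and precision are ≥ 0.95 on synthetic
traces (tested); both degrade gracefully at lower SNR.

RT10–90 is measured scanning back from the peak — the last 10% and first
90% upward crossings before it — with linear sub-sample interpolation, and
RR = 0.8·A/RT10–90 holds for every emitted record by construction.

Per-cell summaries use a seeded *contiguous* run of events (default quotas
161 sEPSCs / 626 sIPSCs) rather than i.i.d. subsampling, so the IEI
sequence stays intact for the burstiness/memory analysis.

## Amplitude mixture and A_th

The fit target is the empirical CDF at every sorted amplitude, with Hazen
plotting positions (i − ½)/n; ordinary least squares against
Σ wᵢ Φ((x−μᵢ)/σᵢ), five multistarts from quantile splits (0.35–0.85) with
quartile-based σ guesses, bounds keeping σ > 0 and w ∈ (0, 1), and
relabelling to enforce μ₁ < μ₂. Parameter counts are p₁ = 2 and p₂ = 5
(w₁ free, w₂ = 1 − w₁). The nested F statistic and its p value use exactly
the printed formula with n = number of fitted points.

**Caveat (documented deliberately):** ECDF residuals are autocorrelated, so
the classical F test on per-point CDF fits is anticonservative — on truly
unimodal synthetic cells it still yields p ≈ 0. The procedure is kept
as specified because it is the procedure under study; the protection
against spurious splits is the *separation* criterion: when the fitted
components overlap (|μ₂ − μ₁| < σ₁ + σ₂, ~82% of unimodal cells at
n = 626), `amplitude_threshold` attaches a low-separation warning and the
threshold should not be interpreted.

"Where the first distribution ends" is operationalized as the cumulative
level y_break = w₁·Φ(3) (the first component's weight attained at
μ₁ + 3σ₁, i.e. 99.87% of component 1 below); A_th is the abscissa where
the fitted two-component CDF crosses y_break (Brent root finding — the CDF
is monotone so the root is unique). Both y_break and the rule are emitted
so alternative readings can be compared. A_th scales exactly with a
uniform rescaling of the currents.

## Burstiness and memory

B = (σ − μ)/(σ + μ) with the sample SD (ddof = 1; immaterial at the
161–626-event quotas but fixed and documented), computed on the same
contiguous runs as the summaries. A zero-variance sequence returns −1
exactly (short-circuited before floating-point noise can perturb it).
M is the lag-1 Spearman correlation with average ranks for ties; an
all-tied sequence has no defined ranking and is reported missing rather
than 0. B is scale-invariant; M is invariant under any strictly monotone
transform. Both B and M are exposed for IEIs of all events and of each
size class, since the class-wise and pre-split readings are both
legitimate.

## Phasic charge and E/I

Segments of 15 s are drawn with integer-second start times by rejection
(regenerating on overlap with accepted segments or exclusion windows).
Sequential rejection can deadlock near full packing, so after a run of
consecutive rejections the placement restarts from scratch; 10 000 total
rejections raise a capacity error.

For each segment: all-point histogram at exactly 1 pA bins; Savitzky–Golay
smoothing (order 2, window 17) locates the peak; the skew side is the sign
of (mean − median) of the samples — splitting raw counts at the peak bin
is fragile when the baseline mean sits near a bin edge and can flip the
side on a symmetric histogram. The baseline Gaussian is least-squares
fitted from the far end of the non-skewed side through the peak to the
first skew-side bin at 95% of the smoothed peak. The Gaussian itself is
fitted to the **raw** counts: fitting the smoothed counts demonstrably
broadens the baseline (σ 3 → 4.2 pA on pure noise), which would both bias
the PTX σ check and swallow event mass under the mirror. On optimizer
failure a flagged fallback uses the mode and half-width at e^(−½) of the
peak.

Phasic charge: excess(i) = max(counts(i) − mirrored Gaussian(i), 0) on the
skewed side of the fitted mean, and

    charge [pC] = Σ excess(i) · |i − I_hold| / f_s ,

dimensionally exact (pA·s = pC). The per-excess-point normalized variant
is also emitted; the E/I ratio is identical under either normalization
because the common factor cancels. Negative excess is clamped to zero
(noise protection) and flagged.

Measured recovery on synthetic 10 Hz segments is ~90% of ground-truth
charge, stable across rates of 5–15 Hz (additivity): the missing mass is
event-tail charge within ~2 baseline SDs of the holding current, which is
intrinsic to the mirror-subtraction idea and cancels to first order in the
E/I ratio.

E/I: ratios[j,k] = (7·E_j)/(6·I_k) over m × n segment charges (100 at the
m = n = 10 default), the 7/6 factor equalizing the ~60 mV (AMPA/NMDA at
−60 mV) and ~70 mV (GABA_A at 0 mV) driving forces. The fractional
deviation is implemented as t₀.₉₇₅,N₋₁·σ/(μ·√N) — with √N in the
denominator: the printed rendering of the formula is ambiguous, but only
the √N form is a confidence-interval half-width and only it reproduces the
reported ~0.12 magnitude at N = 100 with CV ≈ 0.6. It is strictly
decreasing in N and ~N^(−1/2) asymptotically.

The PTX contamination check is a paired Wilcoxon test on per-cell baseline
σ before/after GABA_A blockade; a significant *decrease* indicates small
outward sIPSCs were inflating the sEPSC-side baseline.

## Group statistics

Mann–Whitney uses the exact null distribution for combined n ≤ 16 without
ties and the tie-corrected normal approximation otherwise; the paired
Wilcoxon drops zero differences and uses full sign-pattern enumeration
(permutation method) for ≤ 15 pairs so ties in |d| stay exact. All p
values are two-sided; α = 0.05.

The nested one-way ANOVA is the hierarchical (fully nested) decomposition:
each level's SS is the count-weighted squared deviation of unit means from
their parent means; dfs sum to N − 1; each level's MS is tested against
the MS of the level immediately below (lowest level against the within
MS). Variance components come from the method of moments with **exact**
expected-mean-square coefficients computed from the design counts: the
coefficient of σ²_k in E[SS_l] is C(l,k) − C(l−1,k) with
C(l,k) = Σ_{u∈level l} (Σ_{v∈level k, v⊆u} n_v²)/n_u — for balanced
designs this reduces to the textbook coefficients, and for unbalanced ones
it reproduces the classical average-coefficient (spreadsheet) algebra
without approximation. Components are estimated bottom-up; negative
estimates are clamped to 0 for the percent-of-total report with the raw
value retained. A level with one unit per branch has df = 0 and is
reported untestable. Under a balanced null the group-level test is exact
(measured type-I ≈ 0.047 at α = 0.05 over 2000 replicates).

## Study pipeline

`run_study` simulates per-arm cohorts with per-animal and per-cell
log-normal multipliers on rates and amplitude scales (defaults 0.15 and
0.10 log-SD), so the nested ANOVA's among-animal/among-cell variance
structure is non-trivial, then chains detection → summaries → mixture
split → kinetics → (B, M) → phasic E/I → group tests. Everything is
deterministic given the study seed; any failing stage is recorded in a
per-stage status rather than aborting the report. Default cohort sizes
mirror the study conditions (12 cells/arm, 161/626 event quotas, 4-min
traces, 10 + 10 segments); the test suite exercises reduced cohorts
(2–5 cells, 75-s traces, 3 segments) chosen to keep the full suite fast
while leaving every stage's preconditions satisfied.

## Known limitations

* Detection is not a deconvolution method: overlapping events merge, so
  measured frequencies undercount at high rates and large "events" may be
  summations (by design, matching the merge rule).
* The F test's anticonservativeness (above) means model choice between one
  and two components should lean on the separation flag, not the p value.
* Phasic charge is a lower bound (~10% low at the defaults); comparisons
  across conditions with similar kinetics are unbiased, absolute charges
  are not.
* The nested ANOVA treats the design as fully nested and random below the
  top level; crossed factors or covariates are out of scope, as are
  REML/mixed-model estimates.
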