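# Methods

## The arrest-chase kinetic model

The model (`bufferscan.sim`) captures the competition between folding and
degradation for newly made protein. Species, all in µM: template S
(mRNA/ribosome complexes competent to initiate synthesis), nascent
unfolded protein U, natively folded protein F, and a translation inhibitor
I dosed at the arrest time. Rate constants (s⁻¹ unless noted):

| parameter | meaning | default | rationale |
|---|---|---|---|
| `k_trans` | lumped transcription/translation rate of S → U | 0.01 | one initiation per template per ~100 s; sets only the overall scale of U and F (the system is linear in S0·k_trans) |
| `k_f` | folding rate U → F | 0.03 | mid-range of the scanned 10⁻⁴…1 s⁻¹ window |
| `k_deg` | degradation rate acting on U | 0.01 | the fixed degradative capacity against which folding competes |
| `k_block` | inhibition rate of S by I (µM⁻¹s⁻¹) | 10 | quench half-time ≪ 1 s at a 1 mM dose, i.e. arrest is effectively instantaneous on the folding time-scale |
| `S0` | initial template pool | 1000 µM | large pool so concentrations are far from single-molecule noise |
| `I_dose` | inhibitor dose | 1000 µM (1 mM) | saturating chloramphenicol-like dose |
| `t_arrest` | dosing time | 300 s | a brief induction pulse before arrest |

Catalytic mode (default) treats the template as reusable: translation does
not consume S, only inhibition does. A `consuming` mode subtracts
`k_trans·S` from dS/dt for the opposite reading. The degradation term acts
on U only — the native state is modelled as protease-resistant, which is
what lets folding rate masquerade as degradation rate in the observable.

**Inhibitor treatment.** After dosing, I is held constant at `I_dose`
(pseudo-first-order approximation), so S decays as
exp(−k_block·I_dose·(t−t_arrest)) and the full system is linear with a
piecewise-constant generator. This is what makes an elementary closed-form
solution possible (`closed_form_chase`), used as the analytic oracle for
the numerical integrator. A stoichiometric variant
(`inhibitor_depletion=True`) consumes I mole-for-mole with S; it is
exposed for completeness but cannot be compared against the closed form.

**Numerics.** The dose is a genuine discontinuity: integration stops at
`t_arrest` and restarts with the inhibitor present, so no solver step
straddles the jump. The implicit Radau method is used because the quench
time-scale (10⁻⁴ s at defaults) is ~10⁷-fold stiffer than the folding
time-scale; tolerances are rtol 10⁻¹⁰ / atol 10⁻¹⁰·S0. Measured agreement
with the closed form is ~10⁻⁷ relative or better across a 100-point random
sweep of all three rates over 10⁻⁴…1 s⁻¹. The closed form itself switches
to series/repeated-root expressions when |k_f + k_deg − k_block·I_dose| is
small, to avoid catastrophic cancellation.

**Apparent degradation rate.** `apparent_degradation_rate` fits the
post-arrest intact series (U+F) to P + A·exp(−k_app·(t−t_arrest)). Two
readings exist and they behave differently:

* with the plateau **free**, the fitted exponential recovers the
  relaxation rate of U, which is exactly k_f + k_deg — it *rises* with
  folding rate;
* with the plateau **fixed at zero** (`fix_plateau=True`), the fit reports
  a total-loss rate, which *falls* monotonically as folding diverts
  nascent chains away from degradation. This is the quantity that mirrors
  a chase-gel reading ("how fast does total intact protein disappear") and
  is what the monotonicity checks and the demo report.

The free-plateau fit remains the default of the function because it is the
statistically natural three-parameter model; callers interested in the
folding/degradation trade-off should use the fixed-plateau rate, and the
demo and tests do.

## DMS enrichment scoring

`bufferscan.dms` starts from three TSVs: per-mutant counts
(`mutant_id, position, sample, count`), per-position coverage
(`sample, position, coverage`) and a sample sheet
(`sample, strain, condition, replicate`).

* **Normalization**: (count + pseudocount)/coverage at the mutant's
  position. Pseudocount default 0.5 reads so zero-count mutants stay
  finite through the ratio steps; the full pipeline is exactly invariant
  to per-sample depth rescaling at pseudocount 0.
* **Enrichment**: E = selected/unselected replicate-mean frequency.
  Mutants absent from some replicates are averaged over the present ones
  and flagged `partial`; mutants absent from a whole condition are
  reported as `dropout`, never as E = 0.
* **z-classification**: z uses the sample (n−1) standard deviation —
  appropriate for small mutant panels — with default cuts at ±1:
  `more_active` / `near_average` / `less_active`.
* **Cross-strain comparison**: ordinary least squares of log B on log A
  over shared mutants (natural log internally; fold-changes reported in
  log₂ where displayed). The default band is the **prediction** interval
  at 99%: flagging individual mutants is a question about single new
  observations, for which the narrower mean-response confidence band would
  be badly anti-conservative. The confidence band is available as an
  option (`band="confidence"`). Mutants below the lower band are
  `reduced`, above the upper band `enhanced`.

**Calibration and its limits.** On null strain pairs built from unselected
multinomial counts, the measured flag rate of the 99% band is ~0.7% —
slightly conservative, as expected for a t-based prediction interval
evaluated at its own training points. Under strong selection the picture
changes: a fitness spread of ~2 natural-log units makes counts (hence
log-count noise) vary several-fold across mutants, and a pooled-variance
band then over-flags the low-count mutants (~1.4% measured at 99%
nominal). The band is still effective at its job — a planted 10-fold
reduction is recovered as the unique flag in 50/50 random panels at depth
10⁶ — but per-point calibration guarantees only hold under approximately
homoscedastic noise. A count-variance-weighted band would remove this
limitation and is deliberately out of scope here.

## MIC pipeline

Growth fractions are OD(c)/OD(0) per replicate (an unselected OD below
0.05 is an error naming the well — too little signal to anchor a ratio).
Replicates are averaged before calling. MIC = smallest tested
concentration with mean fraction < threshold; threshold default 0.1
(near-complete inhibition, standard broth-microdilution practice), always
carried in the output metadata since the underlying assays do not fix a
universal cut-off. MICs are reported on the tested grid without
interpolation, matching how serial-dilution plates are read; series that
never fall below threshold are censored as `>max` and excluded from
percent-MIC (a ratio of censored values carries no information).
percent_mic = 100·MIC_mutant/MIC_Wt within the same strain, which cancels
strain-intrinsic drug sensitivity and is invariant to concentration units.

## Kinetic fitters

All fitters use bounded least squares with five data-driven restarts
(rates initialized from the time-to-half-signal or a log-linearized
slope; Tm from the steepest point of a lightly smoothed curve) and fit on
a unit-rescaled signal, so rates and Tm are exactly invariant to uniform
rescaling of y. Standard errors come from the Jacobian at the optimum. A
fit that only exhausts its evaluation budget (e.g. an exponential fit to
perfectly linear data, which is a k → 0 ridge) returns its best iterate
with `converged=False` rather than raising, so callers always get
diagnostics.

* **Refolding**: y₀ + A(1 − e^(−kt)). Decreasing traces are fit but
  tagged `model_mismatch`. Median |k̂/k − 1| over a 50-case randomized
  suite (rates 10⁻⁴…10⁻¹ s⁻¹, 5% multiplicative noise, acquisition window
  scaled to ~5/k) is ~2%.
* **Chase**: y normalized to the first time point, then
  P + (1−P)e^(−k_app·t) with P ∈ [0,1]; `fix_plateau=True` pins P = 0
  (see the apparent-rate discussion above — with 4–5 gel time points the
  two-parameter variant is also simply better determined). Flat traces
  return k_app = 0 with a `stable_protein` tag instead of a degenerate
  three-parameter fit.
* **Melt**: the default model is a two-state logistic transition between
  two *sloped* linear baselines; Tm is the half-transition temperature. A
  literal straight-line read-off of the midpoint (`linear_midpoint`) is
  retained because melt midpoints are often reported that way; on clean
  two-state curves the two agree to well under a degree, and the sigmoid
  is far more robust to noise (≤ 0.3 °C error at 5% noise on a 1 °C grid).
  Curves whose fitted transition amplitude is below ~5× the point-noise
  estimate raise a no-transition error rather than reporting a spurious
  Tm.
* **Reporter ratios**: per-event GFP/mCherry ratios (events with a
  non-positive channel are dropped and counted), summarized as the median
  and log₂(median/reference). The median is used because the event
  distribution is heavy-tailed log-normal; the mCherry channel cancels
  expression and induction differences.

## Synthetic data: what it emulates, and what it does not

`bufferscan.synthetic` generates every input with known truth:

* **Count tables**: pre-selection frequencies from a near-homogeneous
  Dirichlet (α = 100, ~10% CV — designed mutant libraries are built for
  even coverage); selection reweights by exp(f·T) with T = 10 generations
  of competitive growth and f·T spanning 2 natural-log units; counts are
  multinomial at 10⁶ reads/sample, two independent replicates per
  condition; per-position coverage carries a smooth quadratic bias, so
  coverage normalization is genuinely exercised (and the generator
  guarantees count ≤ coverage). Optional Dirichlet-multinomial
  overdispersion and planted per-strain log-fold effects (ground truth for
  buffering calls).
* **Chase series**: the closed-form model sampled at 0/15/30/60/120 min
  post-arrest with multiplicative log-normal noise.
* **Traces**: rising exponential (refolding) and two-state melt on a
  25–90 °C, 1 °C ramp; "SNR 20" means 5% multiplicative noise per point.
* **Growth matrices**: Hill suppression 1/(1+(c/c₅₀)^h), h = 8, over a
  two-fold dilution series 0–800 µg/ml, four replicates. The threshold
  crossing is placed at MIC/√2 — half a dilution step below the nominal
  MIC — so the noise-free grid call recovers the nominal MIC exactly and
  the call is robust to moderate OD noise, rather than sitting on a
  knife-edge at the grid point.
* **Event tables**: log-normal two-channel events; the true median ratio
  is exp(Δ log-median).

Everything flows through one `numpy.random.default_rng(seed)` per call;
fixed seed ⇒ byte-identical files, and each truth sidecar contains enough
(config + seed) to regenerate its dataset bit-for-bit.

What the generators deliberately do **not** model: sequencing error and
read-level artifacts, PCR jackpots beyond the optional overdispersion
switch, plate-position and evaporation effects in growth assays,
fluorophore maturation kinetics, multi-phase folding, and cell-to-cell
expression correlation between reporter channels. Passing the recovery
tests therefore demonstrates correctness of the *analysis* under the
stated statistical assumptions, not robustness to every artifact of real
instruments.

## Problem sizes

The shipped tests and the acceptance script use: 100-parameter random
sweeps for the integrator oracle; 100-mutant panels at depth 10⁶ (scoring
recovery) and 10⁵ (the 1000-table null-calibration run and the demo); a
50-case fitter-recovery suite; 66-point melt curves; and a 601-point time
grid over 0–1200 s for chase simulations. These sizes give Monte-Carlo
errors comfortably below the tolerances being checked while keeping a full
run in the minutes range.
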