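# Methods

## Model structure and assumptions

The cohort model tracks the proportion of a closed cohort across nine
states: prehypertension, hypertension L1/L2/L3, myocardial infarction
(MI), stroke, congestive heart failure (CHF), end-stage renal disease
(ESRD), and death. Cycle length is 1 year; the default horizon is 65
cycles, by which point essentially the whole cohort has died. Core
assumptions:

* Patients under management never return to normotension;
  prehypertension is the best attainable state. Follow-up *records* may
  contain normotension, but transitions into it are ignored when the
  annual matrix is estimated (see below).
* Blood-pressure states reach death only through background mortality;
  the complication states add a disease-specific annual death
  probability on top of it.
* MI, stroke, CHF and ESRD have no recovery transitions; their residual
  probability stays in-state.
* Background mortality is the national all-cause annual probability per
  5-year age band from 35 to 100+; the model enters at age 35 (the
  first band) so that the 65-cycle horizon spans the table. Start age
  is configurable.
* Costs, utilities and (discounted) life-years accrue on the state
  occupied at the start of each cycle, the first year undiscounted,
  then 1/(1+r)^cycle with r = 5% (sensitivity range 0–8%). No
  half-cycle correction by default, matching the plain per-cycle
  accumulation of the original spreadsheet implementation;
  `run_cohort(..., half_cycle=True)` enables the standard correction.

## Parameter estimation conventions

**Transition probabilities.** The estimator counts one transition per
patient — baseline level versus final-visit level — and divides by the
whole analyzable cohort, reproducing the source tabulation (e.g.
383/1248 = 0.3069 for L1 → prehypertension). This denominator bakes the
baseline prevalence into each "study probability"; it is not the
conventional row-conditional estimate, but it is what the published
annual matrix was derived from, so it is the default. A per-origin
denominator (`denominator="origin"`) and a visit-to-visit counting
alternative are available for users who want the conventional
estimator. The 2-year study probabilities are annualized cell-wise via
rate = −(1/t)ln(1−p), annual = 1−exp(−rate), with t = 2 years (twelve
bi-monthly follow-ups). Transitions recorded into normotension are
dropped before annualization (default); this choice, rather than
folding them into prehypertension, is what reproduces the published
annual values exactly (folding would inflate L1 → prehypertension from
0.1675 to 0.1757). Folding remains available via `normotension="fold"`.

**Control rate.** The share of post-baseline SBP measurements strictly
below 120 mmHg, pooled over all patients and visits in an arm (the
SPRINT-style control definition). A per-patient-then-average variant is
provided but off by default.

**Utilities.** EQ-5D indices are predicted from the eight SF-36
dimension scores with the published linear mapping (intercept 0.03256).
The mapping is affine and can exceed 1 at the healthy extreme (all-100
scores map to 1.04456) — a known overprediction of the source model;
predictions below 0 are clamped to 0 with a warning so QALY weights
stay defined, while state-level utilities entering the model are
required to lie in [0, 1].

**Costs.** All monetary values are USD at 2021 prices: CNY amounts are
converted at ¥1 = $0.156 and inflated at 2.5%/year from their record
year. Programme labour cost uses the human-capital formula
(mean annual salary / 250 days / 8 h) × additional hours.

## The arm-effect mechanism

The source study never states how the arm-level control rates enter the
Markov model; this is the main structural choice in the package. We
scale every *improvement* transition (a move to a strictly less severe
blood-pressure level: L1→pre, L2→pre/L1, L3→pre/L1/L2) by
`control_rate / reference_control_rate`, with usual practice (0.61) as
the reference, absorbing the change in the origin's residual stay
probability. The mechanism is monotone in the control rate, keeps rows
stochastic, and reduces exactly to the estimated matrix for the usual
arm. It is exposed as a hook (`arm_effect` in
`build_transition_matrix`) so alternative mechanisms can be plugged in.
Because of this unavoidable structural freedom the *absolute* lifetime
totals are not expected to equal the published ones; the package's
validation therefore pins the published quantities that are
mechanism-free (annualization, decision arithmetic, utility mapping,
lifetime absorption) and checks the mechanism-dependent results
qualitatively (cost/QALY orderings, dominance pattern, PSA winner).

**Intervention cost allocation.** Arm-level human and project costs are
trial-scale totals; they are divided by the enrolled patients per arm
(415 ≈ 1,245/3) and the 1.5-year intervention span to give a per-person
per-cycle cost, applied in every cycle by default (the programme is
treated as a permanent service); a finite number of funded cycles is
configurable.

## Sensitivity analysis

One-way analysis re-runs all arms with one parameter at each end of its
published range (95% CI where given, otherwise ±20%; discount rate
0–8%) and ranks parameters by the induced swing in the
option2-vs-usual ICER. The probabilistic analysis assigns beta
distributions to probabilities, control rates and utilities and gamma
distributions to costs, with hyperparameters moment-matched to the
published mean and range read as a 95% interval (SD = range/3.92).
Draws are independent across parameters (no correlation structure is
published) and shared across arms within an iteration; transition draws
are re-normalized through the residual stay probability. The CEAC grid
runs from 0 to 4× the reference willingness to pay in 100 steps and
always contains $1,599.16 exactly; ties for highest NMB are split
equally (relevant only in degenerate configurations).

## Synthetic-trial generator

The generator emulates the study conditions: three arms × 416 patients,
baseline level mix 0.32/0.53/0.12/0.03, twelve bi-monthly visits over
two years, level evolution by a 2-month Markov matrix obtained
cell-wise from the annual matrix (1−(1−p)^(1/6)), per-visit drop-out
calibrated to the observed 12.63% overall loss, arm control frequencies
0.62/0.69/0.61 drawn independently per visit, SBP/DBP uniform within
the occupied level's cutpoint band (controlled visits force SBP into
90–120), and SF-36 scores normal around equal-dimension state means
chosen so the mapped utilities equal the published per-state values
(noise SD 10 points, truncated to [0, 100]). What it does *not*
emulate: any causal pathway from the interventions to state dynamics
(arms share one transition matrix and differ only in control frequency
and costs), within-patient correlation of measurement noise,
state-dependent drop-out, covariates, or secular trends — so recovery
tests validate the estimators under the model's own assumptions, not
robustness to real-data violations of them.

Recovery is checked against an estimator-independent oracle: the
expected whole-cohort study probability of each (baseline i, final j)
pair is πᵢ(M^12)ᵢⱼ by matrix power, and estimates must fall within 3
binomial standard errors (delta-method propagated through the
annualization) on a ~5,000-patient cohort. This cohort size keeps the
recovery test sharp while running in seconds.

## Numerical choices and degenerate inputs

* Transition matrices are validated row-stochastic to 1e-9 each cycle;
  occupancy conservation holds to 1e-12 over the full horizon.
* A row whose off-diagonals exceed 1 (after arm scaling) raises
  immediately with the offending state and age.
* `probability_to_rate` rejects p ≥ 1 (infinite hazard) and negative
  inputs; log1p/expm1 forms are used for small-probability accuracy.
* Zero-width sensitivity ranges degenerate to fixed parameters; a CI
  implying a beta variance ≥ m(1−m) is rejected as incompatible.
* Mortality lookup uses the terminal open-ended band for ages ≥ 100 and
  rejects ages below 35.

## Known limitations

* The published ESRD incidence decreases with hypertension severity
  (L1 0.0152 > L2 0.0078 > L3 0.0017) — likely a transcription artifact
  in the source; the values are implemented as printed.
* Three published sensitivity ranges are internally inconsistent
  (low > high or excluding the base value); the packaged fixtures use
  the evident intended value or the ±20% fallback rule, documented in
  the file.
* The whole-cohort denominator convention makes the annual
  "probabilities" prevalence-weighted; treat the resulting matrix as a
  reproduction of the source analysis rather than a population
  transition model.
* Utilities, costs and non-mortality transitions are age-invariant.
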