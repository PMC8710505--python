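# htncea

Cost-utility analysis of integrated care models for community
hypertension management, built around a nine-state Markov cohort model.

Rural primary-care systems often deliver fragmented hypertension care;
integrated-care programmes (multidisciplinary teams, shared clinical
pathways, prepaid performance-based budgets) promise better blood-pressure
control at some organisational cost. This package asks the health-economic
question: over a patient's lifetime, do such programmes buy
quality-adjusted life-years (QALYs) at an acceptable price compared with
usual practice? It is aimed at health-economics researchers and modellers
who want a scriptable, testable version of the classic
spreadsheet workflow: estimate transition probabilities from trial
follow-up data, run a cohort state-transition model, and wrap the result
in deterministic and probabilistic sensitivity analysis.

## The model

Nine health states: prehypertension, hypertension grades L1–L3 (standard
SBP/DBP cutpoints), myocardial infarction, stroke, congestive heart
failure, end-stage renal disease (ESRD), and absorbing death. The cohort
starts distributed over the four blood-pressure levels
(0.32/0.53/0.12/0.03) and advances in 1-year cycles over a 65-year
horizon, with age-band background mortality added to every living state.

Annual transition probabilities between blood-pressure levels come from
2-year trial follow-up via the constant-hazard conversion

    r = -(1/t) ln(1 - p_study),      p_annual = 1 - exp(-r),

where `p_study` is the whole-cohort frequency of each baseline-to-final
level change over the window `t` = 2 years. Per-state utilities are
EQ-5D indices mapped from the eight SF-36 dimension scores through a
published linear model (`EQ-5D = 0.03256 + 0.0037·PF + 0.00111·SF + …`).
Strategy arms differ through their blood-pressure control rate (share of
follow-up measurements with SBP < 120 mmHg) and their intervention cost;
the control rate scales the model's "improvement" transitions relative
to usual practice.

Decision statistics at willingness-to-pay λ ($1,599.16/QALY):

    ICER = ΔC/ΔE,   NMB = λ·ΔE − ΔC,   NHB = ΔE − ΔC/λ,

with dominance classification, a tornado-style one-way sensitivity
analysis, and a 1,000-iteration second-order Monte Carlo probabilistic
sensitivity analysis summarised as cost-effectiveness acceptability
curves. A synthetic-trial generator emulates the source study (three
arms, ~1,248 analyzable patients, 12 bi-monthly visits, 12.63% loss to
follow-up) so every estimation stage can be validated against known
ground truth.

## Worked example

```sh
python examples/02_basecase_cea.py
```

prints (packaged parameter tables, start age 35, 5% discount):

```
usual     discounted cost $ 18197.44   QALYs 11.4481   life-years (undisc.)  41.94   dead at 65y 98.6%
option1   discounted cost $ 18812.23   QALYs 11.4503   life-years (undisc.)  41.95   dead at 65y 98.6%
option2   discounted cost $ 17788.77   QALYs 11.4643   life-years (undisc.)  42.07   dead at 65y 98.6%

incremental comparisons at WTP $1599.16/QALY:
        comparison  delta_cost  delta_qaly      icer    icer_flag     nmb    nhb                   verdict
  option1 vs usual      614.78       0.002 288563.54 well_defined -611.38 -0.382 not_cost_effective_at_wtp
  option2 vs usual     -408.67       0.016 -25292.01     dominant  434.51  0.272                  dominant
option2 vs option1    -1023.46       0.014 -72959.79     dominant 1045.89  0.654                  dominant
```

Option 1 (teams + pathway) adds cost for a marginal QALY gain — not
worth the threshold; option 2 (adding the prepaid performance-based
budget) is cheaper *and* more effective than both comparators, i.e.
dominant. The other examples cover transition annualization
(`01_annualize_transitions.py`), sensitivity analysis
(`03_sensitivity.py`) and the simulate-then-recover loop
(`04_synthetic_recovery.py`). The same analyses are available from the
shell via the `htncea` CLI (`simulate`, `estimate`, `basecase`,
`oneway`, `psa`).

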