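# sealcua

Markov cohort cost-utility analysis of school-based dental sealant
programs for first permanent molars (FPM).

School dental services must decide whether sealing every newly erupted
first permanent molar is worth its cost compared with simply treating
caries as it appears. `sealcua` implements the full decision-analytic
pipeline for that question from the public payer's perspective: it derives
caries-prevalence schedules for a sealed and an untreated cohort,
micro-costs the procedures involved, propagates a cohort of molars through
a five-state Markov model, and reports the incremental cost-utility ratio
with deterministic and probabilistic sensitivity analyses. It is intended
for health-economics practitioners and oral-public-health planners who
want a transparent, scriptable, fully testable version of this class of
model.

## Model

A molar occupies one of five states — *sound*, *sealed*, *filled*,
*extracted (caries)*, *extracted (other)* — and transitions in 2-year
cycles from age 6 to age 12 (examinations at ages 6, 8, 10, 12).

* **Epidemiology.** Cumulative caries prevalence in the untreated
  population follows a fitted linear trend: 25% at age 6 rising 10.3% per
  cycle (35.3 / 45.6 / 55.9% at ages 8/10/12). The sealed arm's
  prevalence is `p_sealed(t) = p_untreated(t) · (1 − e(t))` where `e(t)`
  is sealant effectiveness (78 / 60 / 48% at 2/4/6 years after
  application), giving 8 / 18 / 29%. Cumulative prevalences are converted
  to per-cycle conditional incidences
  `i_k = (p_{k+1} − p_k) / (1 − p_k)` so cohort occupancy reproduces the
  schedule exactly.
* **Events and costs.** Direct costs only, micro-costed bottom-up (staff
  minutes × per-minute wage + supplies + amortized equipment):
  sealant USD 5.406, filling USD 11.129, extraction USD 3.989, per-molar
  examination USD 0.192. Sealants are resealed at 3%/cycle, restorations
  replaced at 1%/cycle, molars lost to caries at 1/1000 and to other
  causes at 1/10000 per cycle. USD↔CLP conversion at 681.09.
* **Outcomes.** Quality-adjusted tooth years (QATY) valued at each
  examination age: 1.0 for a sound or sealed molar, 0.81 for a filled
  molar, 0 for an extracted one. Costs and effects are discounted at
  3%/year (discounting of effects is a configuration switch).
* **Decision rule.** The incremental cost-utility ratio
  ICUR = ΔC / ΔQATY is compared against a willingness-to-pay threshold of
  USD 29.36 per QATY; strategies that are cheaper *and* more effective
  are labelled dominant instead of reported as a ratio.

## Worked example

```python
from sealcua import base_case_fixture, compare_strategies

fx = base_case_fixture()
result, no_seal, seal_all = compare_strategies(fx.params, fx.costs, fx.config)
print(f"no-seal  cost {no_seal.total_cost:6.2f}  utility {no_seal.total_qaty:.3f}")
print(f"seal-all cost {seal_all.total_cost:6.2f}  utility {seal_all.total_qaty:.3f}")
print(f"ΔC {result.incremental_cost:.2f} USD, ΔQATY {result.incremental_utility:.3f}, "
      f"ICUR {result.icur:.2f} USD/QATY")
```

prints

```
no-seal  cost   8.40  utility 3.390
seal-all cost   9.69  utility 3.577
ΔC 1.29 USD, ΔQATY 0.187, ICUR 6.91 USD/QATY
```

Sealing every molar costs USD 1.29 more per molar over six years, buys
0.19 additional quality-adjusted tooth years, and therefore costs about
USD 6.9 per QATY gained — far below the USD 29.36 threshold, so the
program is cost-effective. With undiscounted effects the per-arm utilities
are 3.690 and 3.895 QATY (ΔQATY 0.204).

The same pipeline is available from the shell:

```sh
sealcua run  -o out/            # base-case traces, CUA table, CE-plane point
sealcua dsa  -o out_dsa/        # one-way tornado table
sealcua psa  -o out_psa/ -n 1000 --seed 1
sealcua cost-report -o out_cost/
```

Each command accepts a YAML configuration (defaulting to the bundled base
case, `src/sealcua/data/base_case.yaml`) in which every scientific input —
prevalence trend, effectiveness schedule, event rates, unit costs,
sampling distributions — can be edited.

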