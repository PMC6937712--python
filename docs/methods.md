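# Methods

This note records the model, its structural conventions, the choices made
where the design was genuinely open, and what the tests do and do not
establish.

## Cohort model

The unit of analysis is a single first permanent molar; molars are treated
as independent (no within-mouth correlation). A unit cohort of molars is
propagated through five states — SOUND, SEALED, FILLED, EXTRACTED_CARIES,
EXTRACTED_OTHER (the last two absorbing) — in three 2-year cycles from age
6 to 12, with outcomes valued at the four examination ages 6, 8, 10, 12.

Epidemiological inputs arrive as *cumulative* ("ever carious") prevalence
schedules. The engine converts them to per-cycle conditional incidences
among still-at-risk molars, `i_k = (p_{k+1} − p_k) / (1 − p_k)`, which is
the unique choice that makes cohort occupancy reproduce the schedule
exactly while keeping every transition probability in [0, 1] as
prevalence grows. The sealed arm's schedule applies effectiveness to the
untreated prevalence at the matching age,
`p_sealed(t) = p_untreated(t) · (1 − e(t))`; this is the arithmetic that
yields the whole-percent sealed-arm values 8 / 18 / 29 from
35.3 / 45.6 / 55.9 with effectiveness 78 / 60 / 48%. The effectiveness
schedule carries an explicit entry at 0 years since application with
effectiveness 1.0: a sealant placed on a sound molar leaves it caries-free
at placement, which is also what makes the "useless sealant" limit
(effectiveness ≡ 0) collapse the two arms onto identical epidemiology.

### Event and cost conventions

* No half-cycle correction. Transitions happen at cycle boundaries;
  treatment events during a cycle are costed at the examination age that
  closes it; baseline events are costed undiscounted at age 6.
* Baseline prevalent caries (25% of untreated 6-year-olds) is converted
  to FILLED at cycle 0 with a filling cost in both arms' accounting (it
  is zero in the sealed arm's base case). This is the only reading
  consistent with a 25% prevalence at the age-6 examination.
* A sealed molar that develops caries moves SEALED→FILLED directly (the
  sealant has failed); there is no separate sealed-and-carious state.
* **Filled molars remain at risk.** A filled molar develops a new carious
  lesion (another surface, or recurrent caries at a margin) at the same
  per-cycle conditional incidence as the arm's at-risk pool; each new
  lesion is treated with another restoration — a cost event that leaves
  the state unchanged. Without this convention the untreated arm's
  restorative workload is implausibly light (a molar filled at age 6
  would never need caries-related care again) and the sealant program's
  avoided-treatment savings are understated by roughly USD 1.4 per molar.
  Scheduled restoration replacement (the 1%/cycle refill rate) is a
  separate maintenance event on top of this.
* Resealing (3% of sealed molars per cycle, at the sealant price) and
  refilling (1% of filled molars per cycle, at the filling price) are
  applied to post-transition occupancy at each follow-up examination;
  neither procedure has a separately priced variant.
* Molars are lost to caries only from FILLED (1/1000 per cycle, accruing
  the extraction cost) and to other causes from any live state (1/10000
  per cycle, no program-attributable cost).
* Every live molar accrues the per-molar examination cost at each of the
  four examination ages in both arms.

### Valuation and discounting

QATY weights: 1.0 (sound or sealed), 0.81 (filled), 0 (extracted), summed
over the four examination ages — the maximum attainable is therefore
4 QATY per molar. Costs are discounted at 3%/year,
`(1.03)^{−(age−6)}`. Discounting of effects defaults to on but is a
configuration switch: undiscounted accrual gives per-arm utilities
3.690 / 3.895 (ΔQATY 0.204), discounted accrual 3.390 / 3.577
(ΔQATY 0.187); both round to the headline 0.2, and the ICUR moves between
6.36 and 6.91 USD/QATY accordingly.

## Micro-costing

Procedure costs are component sums: staff minutes × per-minute wage,
supplies, clinical-site preparation and straight-line amortized equipment
(ten-year obsolescence). The printed component costs are authoritative;
per-minute rates are carried only as provenance (the printed rates are
rounded — 15 × 0.236 ≠ 3.546 exactly). One source-table inconsistency is
resolved in favour of the totals actually used downstream: the oral-exam
total (4.603 = dentist + assistant + equipment) excludes its supplies
line, and the per-molar exam cost is 4.603 / 24 = 0.192; the base-case
item list therefore omits that supplies line, at the price of slightly
different derived low/high bounds for the exam (0.164–0.229). Costs are
carried in USD at full precision; CLP conversion (× 681.09) happens only
at display, and small (±2 CLP) inconsistencies in printed CLP figures are
not forced.

## Sensitivity analysis

**One-way (tornado).** Each parameter is set to the low and high end of
its stated range with everything else at base, the full pipeline is
re-run, and bars are sorted by the absolute ICUR span. The default
parameter set is the distributed epidemiological quantities, one scalar
at a time: the per-cycle prevalence increment (±2 percentage points),
each effectiveness time point over its own 95% CI, the reseal rate
(0–13%), the refill rate (0–14%) and the two extraction rates (±20%).
Unit costs can be added by name (`sealant_cost`, …), varied over their
supplier-quote ranges. When an endpoint makes the seal-all strategy
dominant, the raw signed ratio ΔC/ΔQATY is kept for span computation and
the endpoint is labelled "dominant" textually.

**Probabilistic.** Each iteration jointly redraws the distributed
parameters, re-runs the deterministic pipeline and records the
cost-effectiveness-plane point and its classification at the USD 29.36
threshold (dominant / cost-effective trade-off / not cost-effective —
a partition of iterations). Distribution choices:

* *Prevalence*: the per-cycle increment is Normal with mean 10.3% and
  sd = 2/1.96% (the stated ±2 read as a 95% half-width); the age-6
  baseline is held fixed. Sampling the increment rather than each age's
  prevalence independently preserves the monotone cumulative schedule
  that the conditional-incidence derivation requires.
* *Effectiveness*: a single common quantile is drawn and mapped through a
  Normal approximation of each time point's 95% CI, preserving monotone
  decay across 2/4/6 years.
* *Reseal/refill and extraction rates*: Beta, matching the stated mean
  with 95% of mass inside the stated range where that equation has a
  solution (solved for the shape by root-finding); otherwise the range is
  read as a 95% interval and method-of-moments is used. Rates without a
  printed range use sd = 0.2·mean/1.96.
* Parameters are sampled independently; unit costs stay at base in the
  probabilistic analysis.

Dominant iterations are excluded from mean-ICUR summaries (the ratio is
undefined there) and reported as a separate fraction.

## Synthetic data and the microsimulation oracle

`random_valid_fixture(seed)` draws internally consistent parameter sets —
non-decreasing prevalence schedules within [0, 1], monotone effectiveness
decay, valid rates, positive costs — for property testing. These fixtures
exercise the machinery, not reality: they do not emulate sampling noise
in prevalence estimates, correlated molars within a mouth, secular trends
in caries, or behaviour outside the 6–12-year window, so passing them
shows internal correctness, not external validity.

`microsim_oracle` is an independently coded per-tooth event simulator: it
samples each molar's path with the same per-cycle probabilities and
prices and returns Monte-Carlo means with standard errors. The cohort
engine is required to agree with it within 3 standard errors (100 000
teeth for the base case; 50 000 for each of 20 random fixtures — sizes
chosen to keep the full suite under a few seconds while leaving standard
errors well below the effects being checked). The oracle shares type
definitions with the engine but none of its propagation or accrual code.

## Numerical choices and degenerate inputs

* Occupancy conservation is asserted at 1e-12 every cycle.
* `incidence_from_prevalence` rejects decreasing cumulative prevalence
  and returns 0 at saturation (p = 1).
* Prevalence-trend evaluation clips to [0, 1]; beta fits cap the variance
  below the Bernoulli bound; table-sampled effectiveness is clipped to
  [0, 1] and forced non-increasing after clipping.
* Ratios are computed and compared against the threshold at full
  precision; rounding (e.g. to whole percent or two decimals) happens
  only in display paths.
* Equal-utility comparisons leave the ICUR undefined and decide dominance
  on cost alone.

## Known limitations

Interproximal caries, root-canal therapy, risk-targeted sealing
strategies, indirect/societal costs and quality-of-life (QALY) mapping
are out of scope. The absolute per-arm cost totals depend on
unobservable upstream accounting (e.g. program overheads common to both
arms) and are not a calibration surface; the incremental quantities are.
The expert-elicited rates (reseal, refill, extractions) carry no formal
uncertainty beyond their stated ranges.
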