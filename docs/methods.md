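# Methods

## Model

`wellcost` implements a cost-consequence analysis of a workplace
mental-wellbeing intervention against current practice, from the employer's
perspective, over a one-year horizon. Three consequences are monetised:

* **absenteeism** — sick days avoided, valued at a cost per working day
  (wage plus on-costs such as employer national insurance and pension);
* **presenteeism** — lost-productivity days avoided while at work, valued at
  its own per-day cost, typically higher than the absenteeism rate because
  the inverse association between earnings and sickness absence does not
  carry over to presenteeism;
* **staff turnover** — leavers avoided, valued at a replacement cost per
  case (recruitment, onboarding, lost output).

Each component's incremental cost is `−N × effect × unit_cost` (with the
turnover effect expressed in percentage points of the participating
headcount, so cases avoided are `N × Δturn/100`), and the intervention
itself contributes `N × cost_per_person + fixed_cost`. The total is the sum
and the net cost per person divides by `N`.

Assumptions baked into this structure:

* **Sign convention.** Savings are *negative* incremental costs, matching
  how such results tables are conventionally printed. Intuition often
  expects positive "savings"; the README and docstrings state the
  convention prominently instead of flipping it.
* **Participating headcount.** `n_participants` is the number of employees
  who actually receive the intervention (e.g. 75 opt-ins at a 250-person
  company), and it is both the multiplier on effects and the denominator of
  the per-person result.
* **Attribution.** Any modelled reduction is attributed entirely to the
  intervention; there is no counterfactual trend, no decay, no discounting.
* **Linearity.** Effects and costs scale linearly in headcount and in each
  other — the human-capital costing philosophy (gross wage for the full
  duration of lost time). Friction-cost or multiplier approaches, multi-year
  horizons, QALY/wellbeing valuation and societal-perspective costs are out
  of scope.
* **Omission vs zero.** A consequence with no evidence is left unmodelled
  (omitted from results) rather than claimed as zero savings; an effect may
  be negative to encode a worsening.

## Parameters

| Parameter | Units | Constraint |
|---|---|---|
| `n_participants` | persons | ≥ 1; stored as a float so sensitivity/break-even analysis can treat headcount as continuous (a fractional break-even headcount is still decision-relevant) |
| `cost_per_person` | currency/participant/year | ≥ 0 |
| `fixed_cost` | currency/year | ≥ 0; organisation-level outlays that do not scale with headcount (lump-sum licences, released working time) |
| `absenteeism_per_day`, `presenteeism_per_day` | currency/day | ≥ 0, optional |
| `turnover_per_case` | currency/case | ≥ 0, optional |
| `absenteeism_days_avoided`, `presenteeism_days_avoided` | days/participant/year | any sign, optional; requires the matching unit cost |
| `turnover_reduction_pp` | percentage points of headcount/year | any sign, optional; requires the matching unit cost |

All arithmetic runs at full double precision. Rounding to whole currency
units happens only at the reporting layer, half-away-from-zero (4.6 → 5,
−22,099.5 → −22,100), and total rows round the exact total rather than
summing rounded components.

## Sensitivity and break-even analysis

One-way deterministic sensitivity analysis substitutes one scalar input at a
time and re-evaluates; tornado output sorts parameters by the span of the
total across their ranges, with ties broken by a fixed canonical parameter
order so output is byte-stable. No empirical input distributions exist for
this model, so the default range is a scale-free ±50% of each base value,
overridable per parameter in the config or on the command line.

The total incremental cost is affine in every scalar input, so the
break-even threshold — the input value at which the total crosses zero — is
solved in closed form from the affine slope and the base evaluation, rather
than by iteration; the test suite verifies the closed form against an
independent bisection on the evaluator to 10⁻⁶ relative tolerance across
randomly generated scenarios. Two inputs genuinely have no threshold: any
parameter the total does not depend on (zero slope), and headcount when
there is no fixed cost (the total scales proportionally and never crosses
zero); both raise a distinct error. A threshold outside an input's valid
domain (e.g. a negative unit cost) is returned as-is for the analyst to
interpret.

## Inflation adjustment

Unit costs drawn from older sources are restated in the analysis price year
by the ratio of annual consumer-price-index values:
`amount × index[year_to] / index[year_from]`. The index series is
user-supplied as a two-column (year, index) text file — annual averages
only, no monthly interpolation — because published index values revise over
time. The bundled case studies store their unit costs directly in the
analysis price year, so no series ships with the package.

## Bundled case studies

Six hypothetical case studies are bundled
(`src/wellcost/data/case_studies.yaml`): a 50-person base case with
absenteeism and presenteeism effects, and five scenario-analysis variants
covering a 600-person company with lump-sum intervention costs, an opt-in
programme where only 75 of 250 employees participate, turnover-only
effects, and a micro company whose intervention *worsens* absenteeism.
These are demonstration inputs, not empirical data: they exercise every
model pathway (fixed vs per-head costs, omitted components, negative
effects, each unit-cost type) but say nothing about any real organisation,
and passing tests against them shows arithmetic fidelity, not predictive
validity.

One provenance note: the source case study from which the base case is
taken prints a presenteeism incremental cost of −£174,575 (and hence a
total of −£210,373 and −£4,207 per person), which does not follow from its
own stated inputs — 50 × 9.6 × £379.51 = £182,164.80. This package applies
the stated formulas, giving −£182,164.80 / −£217,963.20 / −£4,359.26 for
those three quantities; its absenteeism component (−£40,798 rounded) agrees
with the printed value either way. Neither number is "corrected": the
formulas are authoritative here and the discrepancy is recorded rather than
hidden.

## Numerical and design choices

* Closed-form break-even over bisection: exact and O(1); the bisection
  survives only as the test-suite oracle.
* Strict config parsing (unknown keys rejected with the offending name):
  the intended users are not programmers, and a silently ignored typo in
  `cost_per_person` would corrupt a decision.
* YAML configs (JSON accepted by the same reader) for hand-editability.
* The CLI is deterministic — the model has no randomness — so repeated
  identical invocations are byte-identical; error paths exit with distinct
  codes (documented in `wellcost/cli.py`) and a single-line diagnostic.
* The benefit-cost ratio (`(−benefit components) / intervention cost`) is a
  convenience metric for the "£X per £1 invested" framing; it is undefined
  (an error) when the intervention component is not positive.
* Degenerate inputs: a one-way range with `low == high` is legal and
  reproduces the base evaluation; an empty tornado range list returns an
  empty result; a scenario whose base total is already zero has its
  break-even at the base value.

## Problem sizes

The structural checks (closed-form-vs-bisection agreement, headcount
affinity, additivity, inflation round-trips) run on 1,000 randomly generated
scenarios in the test suite and 200 in the acceptance script; the model
evaluates in microseconds, so these sizes complete in seconds while covering
all 2³ component-presence patterns and both fixed-cost regimes.

## Limitations

Beyond the scope exclusions above: the model cannot express uncertainty
(no probabilistic sensitivity analysis), assumes effects are homogeneous
across participants, and values nothing an employer does not pay for —
employee wellbeing itself, healthcare-system or wider societal effects are
invisible to it, so a cost-saving result is a lower bound on the case for an
intervention, not the whole case.
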