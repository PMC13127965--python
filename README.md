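# wellcost

Cost-consequence modelling of workplace mental-wellbeing interventions, for
health economists, HR analysts and employers who want to know whether a
wellbeing programme pays for itself.

Poor mental wellbeing drives sickness absence (absenteeism), reduced on-the-job
productivity (presenteeism) and staff turnover. An employer considering an
intervention — a stress-reduction programme, CBT sessions, manager training —
faces a simple question with messy inputs: over one year, do the productivity
savings outweigh what the programme costs? `wellcost` answers it with a
deterministic, employer-perspective model, plus the analyses a decision maker
needs around it: one-way sensitivity analysis, tornado ordering, closed-form
break-even thresholds, and price-year inflation adjustment of unit costs.

## The model

For a participating headcount *N*, per-participant annual effect sizes
Δ<sub>abs</sub>, Δ<sub>pres</sub> (days avoided) and Δ<sub>turn</sub>
(percentage points of headcount), and unit costs *c*<sub>abs</sub>,
*c*<sub>pres</sub> (per day) and *c*<sub>turn</sub> (per case), the
incremental cost components versus current practice are

```
absenteeism   = −N · Δabs  · c_abs
presenteeism  = −N · Δpres · c_pres
turnover      = −N · (Δturn / 100) · c_turn
intervention  =  N · c_int + C_fixed
```

and the total incremental cost is their sum, with the net cost per person
dividing by the *participating* headcount. **Savings are negative incremental
costs** — a result of −£5,215 means the employer is £5,215 better off. The
time horizon is one year, single currency, no discounting. Because the total
is affine in every scalar input, break-even values are solved exactly.

A component with no modelled effect is *omitted*, not counted as zero savings
claimed; an effect may be negative (an intervention that worsens absenteeism
is a negative days-avoided).

## Worked example

Six hypothetical case studies ship with the package (`wellcost fixtures`
lists them), spanning a micro company of 5 to a large company of 600.
Scenario 4 is a 40-person company with high staff turnover: a £52-per-head
intervention and a 2 percentage-point reduction in turnover at £9,119 per
case.

```sh
$ wellcost evaluate --fixture scenario_4
scenario_4
  Cost of staff turnover       -£7,295
  Intervention cost             £2,080
  Total costs                  -£5,215
  Net cost per person            -£130
```

Turnover savings of 40 × 2% × £9,119 = £7,295.20 against £2,080 of
intervention cost leave the employer £5,215 ahead — £130 per participant
(values displayed rounded to whole pounds, halves away from zero; the
arithmetic underneath is unrounded). How small could the turnover effect be
before the programme stops paying for itself?

```sh
$ wellcost breakeven --fixture scenario_4 --parameter turnover_reduction_pp
scenario_4: turnover_reduction_pp break-even at 0.570238
```

Anything above a 0.57 pp reduction is cost saving. The same machinery is
available as a library:

```python
from wellcost import bundled_fixtures, evaluate, break_even

scenario = bundled_fixtures()["scenario_4"]
result = evaluate(scenario)
result.total_incremental_cost   # -5215.200000000001
break_even(scenario, "turnover_reduction_pp")  # 0.5702379646891105
```

Scenario files are plain YAML (JSON works too) — see
`src/wellcost/data/case_studies.yaml` for the schema by example: a
`scenarios` list of `{name, intervention, unit_costs, effects}` records and
an optional `sensitivity_ranges` map. Parsing is strict; unknown keys are
rejected by name.

`wellcost tornado --fixture base_case --format csv` runs one-way sensitivity
on every modelled input (default range ±50% of the base value, overridable
with `--range PARAM=LOW:HIGH`), sorted by impact on the total.
`wellcost inflate` restates an amount between price years using a
user-supplied two-column (year, index) consumer-price-index file.

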