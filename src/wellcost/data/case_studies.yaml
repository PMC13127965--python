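# Bundled hypothetical case studies: a base case plus five scenario-analysis
# variants spanning company sizes from micro (5 employees) to large (600).
#
# Note on the base case: the source case study reports a presenteeism
# incremental cost of -174,575, a total of -210,373 and a net cost per person
# of -4,207, but those figures do not follow from its own inputs
# (50 x 9.6 x 379.51 = 182,164.80). This package applies the stated formulas,
# giving -182,164.80 / -217,964.80 / -4,359.30 for those three quantities;
# the absenteeism component (-40,798 after rounding) agrees either way.
scenarios:
  - name: base_case
    intervention:
      n_participants: 50
      cost_per_person: 100
    unit_costs:
      absenteeism_per_day: 189.76
      presenteeism_per_day: 379.51
      turnover_per_case: 18488.43   # no effect evidence, so no turnover effect below
    effects:
      absenteeism_days_avoided: 4.3
      presenteeism_days_avoided: 9.6

  # Large company, high absenteeism and presenteeism. The intervention is a
  # 5,000 online stress-reduction programme plus 105,000/year of released
  # working time; both are lump sums, so they are fixed costs.
  - name: scenario_1
    intervention:
      n_participants: 600
      fixed_cost: 110000
    unit_costs:
      absenteeism_per_day: 216
      presenteeism_per_day: 216
    effects:
      absenteeism_days_avoided: 1.3
      presenteeism_days_avoided: 2.5

  # Medium company (250 employees), opt-in CBT: 75 employees opted in, and
  # the participating headcount is what the model uses.
  - name: scenario_2
    intervention:
      n_participants: 75
      cost_per_person: 160
    unit_costs:
      absenteeism_per_day: 259
    effects:
      absenteeism_days_avoided: 0.6

  # Small company, medium absenteeism and staff turnover.
  - name: scenario_3
    intervention:
      n_participants: 100
      cost_per_person: 300
    unit_costs:
      absenteeism_per_day: 370
      turnover_per_case: 22799
    effects:
      absenteeism_days_avoided: 1.1
      turnover_reduction_pp: 0.5

  # Small company, high staff turnover; turnover is the only modelled effect.
  - name: scenario_4
    intervention:
      n_participants: 40
      cost_per_person: 52
    unit_costs:
      turnover_per_case: 9119
    effects:
      turnover_reduction_pp: 2

  # Micro company: absenteeism worsens by 0.3 days (a negative days-avoided),
  # presenteeism improves by 1.8 days.
  - name: scenario_5
    intervention:
      n_participants: 5
      cost_per_person: 165
    unit_costs:
      absenteeism_per_day: 148
      presenteeism_per_day: 148
    effects:
      absenteeism_days_avoided: -0.3
      presenteeism_days_avoided: 1.8
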