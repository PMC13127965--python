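"""Deterministic cost-consequence arithmetic for workplace wellbeing interventions.

The model compares an intervention against current practice over a one-year
horizon, from the employer's perspective. Each modelled consequence
(absenteeism, presenteeism, staff turnover) contributes an *incremental cost*:

    absenteeism   = -N * d_abs  * c_abs
    presenteeism  = -N * d_pres * c_pres
    turnover      = -N * (d_turn / 100) * c_turn
    intervention  =  N * c_int + C_fixed

where ``N`` is the participating headcount, ``d_*`` are annual per-participant
effect sizes, and ``c_*`` are unit costs. Savings therefore appear as
**negative** incremental costs — the sign convention used throughout. The
total incremental cost is the sum of the components, and the net cost per
person divides it by the *participating* headcount (not the whole company).

All arithmetic is carried out at full floating precision; rounding to whole
currency units is a presentation concern handled in :mod:`wellcost.io`.
"""

from __future__ import annotations

from typing import Dict, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import UndefinedRatioError

#: Canonical ordering of cost components in results and report tables.
COMPONENT_ORDER = ("absenteeism", "presenteeism", "turnover", "intervention")

#: Effect components (everything except the intervention cost itself).
EFFECT_COMPONENTS = ("absenteeism", "presenteeism", "turnover")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class InterventionSpec(_StrictModel):
    """Who participates and what the intervention costs.

    ``n_participants`` is the number of employees actually receiving the
    intervention (e.g. the opt-in headcount, not the company size). It is
    typed as a float so that sensitivity and break-even analysis can treat
    headcount as continuous; real scenarios use whole numbers.

    ``cost_per_person`` scales with headcount; ``fixed_cost`` covers
    organisation-level outlays that do not (licence fees, released working
    time paid as a lump sum, ...).
    """

    n_participants: float = Field(ge=1)
    cost_per_person: float = Field(default=0.0, ge=0)
    fixed_cost: float = Field(default=0.0, ge=0)


class UnitCosts(_StrictModel):
    """Monetary value of one unit of each consequence, in currency units.

    A component left as ``None`` is *not modelled* (no savings claimed for
    it), which is different from a unit cost of zero.
    """

    absenteeism_per_day: Optional[float] = Field(default=None, ge=0)
    presenteeism_per_day: Optional[float] = Field(default=None, ge=0)
    turnover_per_case: Optional[float] = Field(default=None, ge=0)


class EffectSizes(_StrictModel):
    """Annual per-participant effect of the intervention.

    ``absenteeism_days_avoided`` and ``presenteeism_days_avoided`` are days
    per participant per year; ``turnover_reduction_pp`` is percentage points
    of the participating headcount per year (2.0 means 2% of participants no
    longer leave, i.e. ``N * 0.02`` cases avoided). Negative values encode a
    worsening — e.g. an intervention that *increases* absenteeism by 0.3
    days is ``absenteeism_days_avoided = -0.3``.
    """

    absenteeism_days_avoided: Optional[float] = None
    presenteeism_days_avoided: Optional[float] = None
    turnover_reduction_pp: Optional[float] = None


_EFFECT_FIELD = {
    "absenteeism": "absenteeism_days_avoided",
    "presenteeism": "presenteeism_days_avoided",
    "turnover": "turnover_reduction_pp",
}
_UNIT_FIELD = {
    "absenteeism": "absenteeism_per_day",
    "presenteeism": "presenteeism_per_day",
    "turnover": "turnover_per_case",
}


class Scenario(_StrictModel):
    """One workplace setting: an intervention, unit costs and effect sizes."""

    name: str
    intervention: InterventionSpec
    unit_costs: UnitCosts = UnitCosts()
    effects: EffectSizes = EffectSizes()

    @model_validator(mode="after")
    def _effects_require_unit_costs(self) -> "Scenario":
        for component in EFFECT_COMPONENTS:
            effect = getattr(self.effects, _EFFECT_FIELD[component])
            unit = getattr(self.unit_costs, _UNIT_FIELD[component])
            if effect is not None and unit is None:
                raise ValueError(
                    f"effect size given for '{component}' but no matching "
                    f"unit cost ({_UNIT_FIELD[component]}) is set"
                )
        return self

    def modelled_components(self) -> tuple:
        """Effect components with both an effect size and a unit cost."""
        return tuple(
            c
            for c in EFFECT_COMPONENTS
            if getattr(self.effects, _EFFECT_FIELD[c]) is not None
        )


class ModelResult(_StrictModel):
    """Evaluated incremental costs for one scenario.

    Invariants (pre-rounding, exact in floating arithmetic):
    ``total_incremental_cost == sum(component_costs.values())`` and
    ``net_cost_per_person * n_participants == total_incremental_cost``.
    """

    scenario: str
    n_participants: float
    component_costs: Dict[str, float]
    total_incremental_cost: float
    net_cost_per_person: float


def component_costs(scenario: Scenario) -> Dict[str, float]:
    """Incremental cost of each modelled component, in canonical order.

    Savings are negative. Effect components absent from the scenario are
    omitted from the map; the intervention component is always present.
    """
    spec = scenario.intervention
    n = spec.n_participants
    out: Dict[str, float] = {}
    effects, units = scenario.effects, scenario.unit_costs
    if effects.absenteeism_days_avoided is not None:
        out["absenteeism"] = -n * effects.absenteeism_days_avoided * units.absenteeism_per_day
    if effects.presenteeism_days_avoided is not None:
        out["presenteeism"] = -n * effects.presenteeism_days_avoided * units.presenteeism_per_day
    if effects.turnover_reduction_pp is not None:
        out["turnover"] = -n * (effects.turnover_reduction_pp / 100.0) * units.turnover_per_case
    out["intervention"] = n * spec.cost_per_person + spec.fixed_cost
    return out


def evaluate(scenario: Scenario) -> ModelResult:
    """Evaluate the full model: components, total, and net cost per person."""
    costs = component_costs(scenario)
    total = sum(costs.values())
    n = scenario.intervention.n_participants
    return ModelResult(
        scenario=scenario.name,
        n_participants=n,
        component_costs=costs,
        total_incremental_cost=total,
        net_cost_per_person=total / n,
    )


def benefit_cost_ratio(result: ModelResult) -> float:
    """Net benefit per unit of intervention spend.

    Returns ``(-sum of non-intervention components) / intervention
    component`` — the "£X returned per £1 invested" framing. A scenario with
    no modelled benefit components returns 0.0.

    Raises:
        UndefinedRatioError: if the intervention component is not positive.
    """
    intervention = result.component_costs.get("intervention", 0.0)
    if intervention <= 0:
        raise UndefinedRatioError(
            "benefit-cost ratio is undefined without a positive intervention cost"
        )
    benefits = sum(
        v for k, v in result.component_costs.items() if k != "intervention"
    )
    return -benefits / intervention
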