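"""One-way deterministic sensitivity analysis and break-even thresholds.

The total incremental cost is an affine function of every scalar input, so
one-way analysis needs only two model evaluations per parameter, and the
break-even (threshold) value — the input at which the total crosses zero —
has a closed form derived from the affine coefficients.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field

from .errors import NoThresholdError, UnknownParameterError
from .model import ModelResult, Scenario, evaluate

#: Closed list of scalar model inputs, in canonical (tie-breaking) order.
PARAMETERS = (
    "n_participants",
    "cost_per_person",
    "fixed_cost",
    "absenteeism_per_day",
    "presenteeism_per_day",
    "turnover_per_case",
    "absenteeism_days_avoided",
    "presenteeism_days_avoided",
    "turnover_reduction_pp",
)

_INTERVENTION_PARAMS = {"n_participants", "cost_per_person", "fixed_cost"}
_UNIT_PARAMS = {"absenteeism_per_day", "presenteeism_per_day", "turnover_per_case"}
_EFFECT_PARAMS = {
    "absenteeism_days_avoided",
    "presenteeism_days_avoided",
    "turnover_reduction_pp",
}


class TornadoEntry(BaseModel):
    """One parameter's contribution to a tornado diagram."""

    model_config = ConfigDict(frozen=True)

    parameter: str
    low_value: float
    high_value: float
    total_at_low: float
    total_at_high: float
    span: float = Field(ge=0)


def check_parameter(scenario: Scenario, parameter: str) -> None:
    if parameter not in PARAMETERS:
        raise UnknownParameterError(
            f"unknown parameter '{parameter}'; expected one of {', '.join(PARAMETERS)}"
        )
    if parameter in _UNIT_PARAMS and getattr(scenario.unit_costs, parameter) is None:
        raise UnknownParameterError(
            f"parameter '{parameter}' is not modelled in scenario '{scenario.name}'"
        )
    if parameter in _EFFECT_PARAMS and getattr(scenario.effects, parameter) is None:
        raise UnknownParameterError(
            f"parameter '{parameter}' is not modelled in scenario '{scenario.name}'"
        )


def parameter_value(scenario: Scenario, parameter: str) -> float:
    """Current (base-case) value of ``parameter`` in ``scenario``."""
    check_parameter(scenario, parameter)
    if parameter in _INTERVENTION_PARAMS:
        return getattr(scenario.intervention, parameter)
    if parameter in _UNIT_PARAMS:
        return getattr(scenario.unit_costs, parameter)
    return getattr(scenario.effects, parameter)


def substitute(scenario: Scenario, parameter: str, value: float) -> Scenario:
    """A copy of ``scenario`` with one scalar input replaced and re-validated."""
    check_parameter(scenario, parameter)
    data = scenario.model_dump()
    if parameter in _INTERVENTION_PARAMS:
        data["intervention"][parameter] = value
    elif parameter in _UNIT_PARAMS:
        data["unit_costs"][parameter] = value
    else:
        data["effects"][parameter] = value
    return Scenario.model_validate(data)


def one_way(
    scenario: Scenario, parameter: str, low: float, high: float
) -> Tuple[ModelResult, ModelResult]:
    """Evaluate the model at the two ends of one parameter's range.

    Everything else is held at its base value. ``low`` and ``high`` must
    respect the type invariants of the field they replace (e.g. unit costs
    must stay non-negative).
    """
    if low > high:
        raise ValueError(f"one-way range for '{parameter}' has low {low} > high {high}")
    return (
        evaluate(substitute(scenario, parameter, low)),
        evaluate(substitute(scenario, parameter, high)),
    )


def tornado(
    scenario: Scenario, ranges: Sequence[Tuple[str, float, float]]
) -> List[TornadoEntry]:
    """One-way analysis over several parameters, sorted for a tornado diagram.

    Entries are ordered by descending span (|total_at_high - total_at_low|);
    ties break by the canonical parameter order so output is byte-stable.
    An empty range list yields an empty result.
    """
    entries = []
    for parameter, low, high in ranges:
        at_low, at_high = one_way(scenario, parameter, low, high)
        entries.append(
            TornadoEntry(
                parameter=parameter,
                low_value=low,
                high_value=high,
                total_at_low=at_low.total_incremental_cost,
                total_at_high=at_high.total_incremental_cost,
                span=abs(
                    at_high.total_incremental_cost - at_low.total_incremental_cost
                ),
            )
        )
    entries.sort(key=lambda e: (-e.span, PARAMETERS.index(e.parameter)))
    return entries


def default_ranges(
    scenario: Scenario,
    fraction: float = 0.5,
    overrides: Optional[Dict[str, Tuple[float, float]]] = None,
) -> List[Tuple[str, float, float]]:
    """Symmetric +/-``fraction`` ranges around each present parameter's base.

    The model carries no empirical input distributions, so the default range
    is scale-free: ``base * (1 -/+ fraction)`` (ends swapped for negative
    bases; headcount floored at 1). ``overrides`` replaces the range for
    individual parameters.
    """
    overrides = overrides or {}
    ranges: List[Tuple[str, float, float]] = []
    for parameter in PARAMETERS:
        try:
            base = parameter_value(scenario, parameter)
        except UnknownParameterError:
            continue
        if parameter in overrides:
            low, high = overrides[parameter]
        else:
            low, high = sorted((base * (1 - fraction), base * (1 + fraction)))
            if parameter == "n_participants":
                low = max(low, 1.0)
        ranges.append((parameter, low, high))
    return ranges


def affine_coefficients(scenario: Scenario, parameter: str) -> Tuple[float, float]:
    """Slope and intercept of total incremental cost in ``parameter``.

    ``total(v) = slope * v + intercept`` with all other inputs at base.
    """
    check_parameter(scenario, parameter)
    spec = scenario.intervention
    n = spec.n_participants
    effects, units = scenario.effects, scenario.unit_costs

    if parameter == "n_participants":
        per_head = spec.cost_per_person
        if effects.absenteeism_days_avoided is not None:
            per_head -= effects.absenteeism_days_avoided * units.absenteeism_per_day
        if effects.presenteeism_days_avoided is not None:
            per_head -= effects.presenteeism_days_avoided * units.presenteeism_per_day
        if effects.turnover_reduction_pp is not None:
            per_head -= (effects.turnover_reduction_pp / 100.0) * units.turnover_per_case
        slope = per_head
    elif parameter == "cost_per_person":
        slope = n
    elif parameter == "fixed_cost":
        slope = 1.0
    elif parameter == "absenteeism_per_day":
        eff = effects.absenteeism_days_avoided
        slope = 0.0 if eff is None else -n * eff
    elif parameter == "presenteeism_per_day":
        eff = effects.presenteeism_days_avoided
        slope = 0.0 if eff is None else -n * eff
    elif parameter == "turnover_per_case":
        eff = effects.turnover_reduction_pp
        slope = 0.0 if eff is None else -n * eff / 100.0
    elif parameter == "absenteeism_days_avoided":
        slope = -n * units.absenteeism_per_day
    elif parameter == "presenteeism_days_avoided":
        slope = -n * units.presenteeism_per_day
    else:  # turnover_reduction_pp
        slope = -n * units.turnover_per_case / 100.0

    base_value = parameter_value(scenario, parameter)
    base_total = evaluate(scenario).total_incremental_cost
    return slope, base_total - slope * base_value


def break_even(scenario: Scenario, parameter: str) -> float:
    """Parameter value at which the total incremental cost is zero.

    Solved in closed form from the affine coefficients. Because the analysis
    is continuous, a fractional headcount threshold is a legitimate answer
    for ``n_participants``.

    Raises:
        NoThresholdError: if the total does not depend on the parameter
            (zero coefficient), or for ``n_participants`` with no fixed cost
            (the total scales with headcount but never crosses zero).
    """
    base_value = parameter_value(scenario, parameter)
    base_total = evaluate(scenario).total_incremental_cost
    if base_total == 0:
        return base_value
    slope, _ = affine_coefficients(scenario, parameter)
    if parameter == "n_participants" and scenario.intervention.fixed_cost == 0:
        raise NoThresholdError(
            "total scales proportionally with n_participants (fixed_cost is 0) "
            "and never crosses zero"
        )
    if slope == 0:
        raise NoThresholdError(
            f"total incremental cost does not depend on '{parameter}' "
            f"in scenario '{scenario.name}'"
        )
    return base_value - base_total / slope
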