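"""Shared fixtures and helpers for the wellcost test suite."""

from __future__ import annotations

import numpy as np
import pytest

from wellcost import EffectSizes, InterventionSpec, Scenario, UnitCosts
from wellcost.sensitivity import substitute
from wellcost.model import evaluate

#: Valid domain of each scalar parameter, used for oracle bracketing.
PARAMETER_DOMAINS = {
    "n_participants": (1.0, 1e6),
    "cost_per_person": (0.0, 1e7),
    "fixed_cost": (0.0, 1e7),
    "absenteeism_per_day": (0.0, 1e6),
    "presenteeism_per_day": (0.0, 1e6),
    "turnover_per_case": (0.0, 1e7),
    "absenteeism_days_avoided": (-1e3, 1e3),
    "presenteeism_days_avoided": (-1e3, 1e3),
    "turnover_reduction_pp": (-100.0, 100.0),
}


def make_random_scenario(rng: np.random.Generator, name: str = "random") -> Scenario:
    """A random but valid scenario with a random subset of components."""
    components = {
        "absenteeism": rng.random() < 0.7,
        "presenteeism": rng.random() < 0.7,
        "turnover": rng.random() < 0.7,
    }
    unit_costs = {}
    effects = {}
    if components["absenteeism"]:
        unit_costs["absenteeism_per_day"] = float(rng.uniform(0, 600))
        effects["absenteeism_days_avoided"] = float(rng.uniform(-3, 8))
    if components["presenteeism"]:
        unit_costs["presenteeism_per_day"] = float(rng.uniform(0, 1200))
        effects["presenteeism_days_avoided"] = float(rng.uniform(-3, 12))
    if components["turnover"]:
        unit_costs["turnover_per_case"] = float(rng.uniform(0, 40000))
        effects["turnover_reduction_pp"] = float(rng.uniform(-2, 5))
    return Scenario(
        name=name,
        intervention=InterventionSpec(
            n_participants=float(rng.integers(1, 2000)),
            cost_per_person=float(rng.uniform(0, 800)) if rng.random() < 0.8 else 0.0,
            fixed_cost=float(rng.uniform(0, 150000)) if rng.random() < 0.5 else 0.0,
        ),
        unit_costs=UnitCosts(**unit_costs),
        effects=EffectSizes(**effects),
    )


def bisect_break_even(scenario: Scenario, parameter: str):
    """Threshold of the total in ``parameter`` found by bisection on evaluate.

    Independent of the closed-form solver: brackets within the parameter's
    valid domain and bisects ``evaluate(substitute(...))``. Returns None when
    the total does not change sign anywhere in the domain.
    """
    from scipy.optimize import brentq

    lo, hi = PARAMETER_DOMAINS[parameter]

    def g(v: float) -> float:
        return evaluate(substitute(scenario, parameter, v)).total_incremental_cost

    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if np.sign(g_lo) == np.sign(g_hi):
        return None
    return brentq(g, lo, hi, xtol=1e-10, rtol=1e-14)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
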