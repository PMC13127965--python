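"""Scenario configuration files, bundled case studies, and report rendering.

Configurations are YAML documents (JSON, being a YAML subset, is accepted by
the same reader) with a top-level ``scenarios`` list and an optional
``sensitivity_ranges`` map. Parsing is strict: unknown keys are rejected so a
typo cannot silently drop an input.

Report tables present rounded whole-currency values. Rounding is
half-away-from-zero and happens at display time only; total rows round the
exact total rather than summing rounded components (-22,099.5 must display
as -22,100, not -22,099 or -22,101).
"""

from __future__ import annotations

import io as _io
import math
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigError, ConfigSyntaxError
from .model import COMPONENT_ORDER, ModelResult, Scenario
from .sensitivity import PARAMETERS, TornadoEntry

COMPONENT_LABELS = {
    "absenteeism": "Cost of absenteeism",
    "presenteeism": "Cost of presenteeism",
    "turnover": "Cost of staff turnover",
    "intervention": "Intervention cost",
}
TOTAL_LABEL = "Total costs"
PER_PERSON_LABEL = "Net cost per person"


class ScenarioConfig(BaseModel):
    """Parsed configuration: scenarios plus optional per-parameter DSA ranges."""

    model_config = ConfigDict(extra="forbid")

    scenarios: List[Scenario] = []
    sensitivity_ranges: Dict[str, Tuple[float, float]] = {}

    @field_validator("sensitivity_ranges")
    @classmethod
    def _ranges_valid(cls, v: Dict[str, Tuple[float, float]]):
        for parameter, (low, high) in v.items():
            if parameter not in PARAMETERS:
                raise ValueError(
                    f"unknown sensitivity parameter '{parameter}'; "
                    f"expected one of {', '.join(PARAMETERS)}"
                )
            if low > high:
                raise ValueError(f"range for '{parameter}' has low {low} > high {high}")
        return v


def read_config(text: str) -> ScenarioConfig:
    """Parse a YAML/JSON configuration document into a validated config."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigSyntaxError(
            f"configuration is not valid YAML/JSON: {exc}"
        ) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigSyntaxError(
            f"configuration root must be a mapping, got {type(raw).__name__}"
        )
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_summarise_validation_error(exc)) from exc


def _summarise_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "invalid configuration: " + "; ".join(parts)


def read_scenarios(text: str) -> List[Scenario]:
    """Parse a configuration document and return its scenarios."""
    return read_config(text).scenarios


def read_config_file(path: Union[str, Path]) -> ScenarioConfig:
    path = Path(path)
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise
    try:
        return read_config(text)
    except ConfigError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_scenarios(
    scenarios: Sequence[Scenario],
    sensitivity_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> str:
    """Serialise scenarios (and optional DSA ranges) back to YAML.

    Round-trips: ``read_scenarios(write_scenarios(s)) == list(s)``.
    """
    doc: dict = {
        "scenarios": [s.model_dump(exclude_none=True) for s in scenarios]
    }
    if sensitivity_ranges:
        doc["sensitivity_ranges"] = {
            k: list(v) for k, v in sensitivity_ranges.items()
        }
    return yaml.safe_dump(doc, sort_keys=False)


def bundled_fixtures() -> Dict[str, Scenario]:
    """The six bundled hypothetical case studies, keyed by name.

    Returns ``base_case`` plus ``scenario_1`` … ``scenario_5``, in that
    order. See ``data/case_studies.yaml`` for provenance notes, including
    the non-reproducible published base-case presenteeism figure.
    """
    text = (
        resources.files("wellcost").joinpath("data/case_studies.yaml").read_text()
    )
    return {s.name: s for s in read_scenarios(text)}


def round_currency(value: float) -> int:
    """Round to whole currency units, halves away from zero (4.6 -> 5,
    -22,099.5 -> -22,100, -130.375 -> -130)."""
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def format_currency(value: int) -> str:
    """Whole currency units with a sign before the symbol: ``-£5,215``."""
    sign = "-" if value < 0 else ""
    return f"{sign}£{abs(value):,}"


class ReportTable:
    """Rounded per-scenario cost breakdown in the published table layout.

    One row per present component, then a total row (rounded from the exact
    total) and a net-cost-per-person row, for each scenario.
    """

    def __init__(self, results: Sequence[ModelResult]):
        rows = []
        for result in results:
            for component in COMPONENT_ORDER:
                if component in result.component_costs:
                    rows.append(
                        (
                            result.scenario,
                            COMPONENT_LABELS[component],
                            round_currency(result.component_costs[component]),
                        )
                    )
            rows.append(
                (result.scenario, TOTAL_LABEL, round_currency(result.total_incremental_cost))
            )
            rows.append(
                (result.scenario, PER_PERSON_LABEL, round_currency(result.net_cost_per_person))
            )
        self.frame = pd.DataFrame(rows, columns=["scenario", "item", "cost"])

    def to_csv(self) -> str:
        return self.frame.to_csv(index=False, lineterminator="\n")

    def to_text(self) -> str:
        lines = []
        for scenario, group in self.frame.groupby("scenario", sort=False):
            lines.append(scenario)
            width = max(len(i) for i in group["item"])
            for _, row in group.iterrows():
                lines.append(f"  {row['item']:<{width}}  {format_currency(row['cost']):>12}")
            lines.append("")
        return "\n".join(lines).rstrip() + "\n"


def render_results(results: Sequence[ModelResult]) -> ReportTable:
    """Build the rounded report table for a batch of evaluated scenarios."""
    return ReportTable(results)


def tornado_to_csv(entries: Sequence[TornadoEntry]) -> str:
    """One-way sensitivity results as CSV (unrounded currency)."""
    frame = pd.DataFrame(
        [
            (e.parameter, e.low_value, e.high_value, e.total_at_low, e.total_at_high, e.span)
            for e in entries
        ],
        columns=["parameter", "low", "high", "total_at_low", "total_at_high", "span"],
    )
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()
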