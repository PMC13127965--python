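"""Exception hierarchy for wellcost.

All domain errors derive from :class:`WellcostError` so callers (and the CLI)
can distinguish model/configuration problems from programming errors.
"""


class WellcostError(Exception):
    """Base class for all wellcost domain errors."""


class ConfigError(WellcostError):
    """A scenario configuration could not be parsed or validated."""


class ConfigSyntaxError(ConfigError):
    """The configuration text is not well-formed YAML/JSON."""


class UnknownParameterError(WellcostError):
    """A parameter identifier is not in the closed list, or the component it
    refers to is not modelled in the given scenario."""


class NoThresholdError(WellcostError):
    """The total incremental cost never crosses zero as the parameter varies
    (zero coefficient, or pure per-head scaling with no fixed cost)."""


class UndefinedRatioError(WellcostError):
    """Benefit-cost ratio requested for a scenario with no positive
    intervention cost."""


class MissingYearError(WellcostError, KeyError):
    """A price-index lookup referenced a year absent from the series."""

    def __init__(self, year: int):
        super().__init__(f"year {year} is not in the price index series")
        self.year = year

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return self.args[0]
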