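"""Price-year adjustment of unit costs with a consumer price index series.

Unit costs drawn from older sources must be restated in the analysis price
year (e.g. uplifted to 2024 prices with the UK CPIH). The series itself is
user-supplied — annual index values revise over time, so none is bundled —
as a two-column delimited text file (year, index) with a header row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple, Union

from .errors import ConfigError, MissingYearError


class PriceIndexSeries:
    """An annual price index: a mapping from calendar year to index value.

    Index values are dimensionless and must be positive; years must be
    unique. Annual averages only — no monthly interpolation.
    """

    def __init__(self, values: Union[Mapping[int, float], Iterable[Tuple[int, float]]]):
        items = values.items() if isinstance(values, Mapping) else list(values)
        series: Dict[int, float] = {}
        for year, index in items:
            year = int(year)
            if year in series:
                raise ConfigError(f"duplicate year {year} in price index series")
            if not index > 0:
                raise ConfigError(
                    f"price index for year {year} must be positive, got {index}"
                )
            series[year] = float(index)
        self._values = dict(sorted(series.items()))

    def __getitem__(self, year: int) -> float:
        try:
            return self._values[year]
        except KeyError:
            raise MissingYearError(year) from None

    def __contains__(self, year: int) -> bool:
        return year in self._values

    def __len__(self) -> int:
        return len(self._values)

    def years(self) -> Tuple[int, ...]:
        return tuple(self._values)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PriceIndexSeries":
        """Read a (year, index) series from a delimited text file.

        The first row is a header (column names are free); the delimiter
        (comma, tab or semicolon) is sniffed from the content.
        """
        text = Path(path).read_text()
        try:
            dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
        except (csv.Error, IndexError) as exc:
            raise ConfigError(f"cannot parse price index file {path}: {exc}") from exc
        rows = list(csv.reader(text.splitlines(), dialect))
        pairs = []
        for lineno, row in enumerate(rows[1:], start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ConfigError(f"{path}:{lineno}: expected two columns (year, index)")
            try:
                pairs.append((int(row[0]), float(row[1])))
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: {exc}") from exc
        return cls(pairs)


def inflate(
    amount: float, year_from: int, year_to: int, series: PriceIndexSeries
) -> float:
    """Restate ``amount`` from ``year_from`` prices to ``year_to`` prices.

    Returns ``amount * series[year_to] / series[year_from]`` at full
    precision. Composition is multiplicative (a->b then b->c equals a->c)
    and the adjustment is linear in the amount.
    """
    return amount * series[year_to] / series[year_from]
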