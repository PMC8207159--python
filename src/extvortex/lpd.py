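"""Living Planet Database dialect I/O and extirpation-series selection.

The input format is the wide layout used by the Living Planet Database
(LPD): one row per monitored population, a block of metadata columns
(``ID, Binomial, Class, Country_aggregate, Units``) followed by one column
per calendar year. A population qualifies for extinction-vortex analysis
only if its time series actually documents an extirpation: it must end in
a run of at least two zero-abundance observations, contain no interior
zero that is later followed by a nonzero count, have at least five
nonzero observations before the extinction year, have its last nonzero
observation in the year immediately preceding the first zero, and span at
least ten years from the first observation to the first zero. Aggregated
country-wide series are excluded.

Accepted series are re-indexed on *years to extinction* (YTE): calendar
time counted backward from the first zero-abundance year, so YTE = 0 is
the extinction year in every population. Abundances are scaled within
each series by the series maximum; because each accepted series ends in
zeros, the scaled values span exactly [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PopulationTimeSeries",
    "FilteredSeries",
    "RejectionReport",
    "LpdParseError",
    "LpdValidationError",
    "parse_lpd_table",
    "write_lpd_table",
    "apply_selection_criteria",
    "derive_yte",
    "scale_abundance",
    "filter_table",
    "to_long_frame",
]

METADATA_COLUMNS = ["ID", "Binomial", "Class", "Country_aggregate", "Units"]

#: Codes for the seven selection checks.
END_NONZERO = "END_NONZERO"
INTERIOR_ZERO = "INTERIOR_ZERO"
PREFIX_OBS_LT_5 = "PREFIX_OBS_LT_5"
TERMINAL_ZEROS_LE_1 = "TERMINAL_ZEROS_LE_1"
GAP_GT_1YR = "GAP_GT_1YR"
SPAN_LT_10 = "SPAN_LT_10"
COUNTRY_AGGREGATE = "COUNTRY_AGGREGATE"

MIN_PREFIX_OBS = 5
MIN_SPAN_YEARS = 10


class LpdParseError(ValueError):
    """Raised when the CSV layout cannot be interpreted."""


class LpdValidationError(ValueError):
    """Raised when a row violates the data contract (e.g. negative counts)."""


@dataclass
class PopulationTimeSeries:
    """One population's annual abundance record.

    ``observations`` maps calendar year to abundance; missing years are
    simply absent from the map.
    """

    series_id: str
    species_binomial: str
    taxon_class: str = ""
    is_country_aggregate: bool = False
    observations: dict[int, float] = field(default_factory=dict)
    units_note: str = ""

    def __post_init__(self) -> None:
        self.observations = dict(sorted(self.observations.items()))
        if not self.observations:
            raise LpdValidationError(
                f"series {self.series_id!r}: no observations"
            )
        for year, value in self.observations.items():
            if value < 0:
                raise LpdValidationError(
                    f"series {self.series_id!r}: negative abundance {value} in {year}"
                )

    @property
    def years(self) -> list[int]:
        return list(self.observations)

    @property
    def values(self) -> list[float]:
        return list(self.observations.values())


@dataclass
class RejectionReport:
    """Outcome of the seven-way selection screen for one series."""

    series_id: str
    accepted: bool
    failed_criteria: list[str]


@dataclass
class FilteredSeries:
    """An accepted series with its years-to-extinction index.

    ``yte`` maps every observed year to ``extinction_year - year``; the
    terminal zeros after the extinction year carry negative values and are
    excluded from analysis (``analysis_years`` keeps YTE >= 0 only).
    ``scaled_abundance`` is filled by :func:`scale_abundance`.
    """

    base: PopulationTimeSeries
    extinction_year: int
    yte: dict[int, int]
    n_prefix_obs: int
    span_years: int
    scaled_abundance: dict[int, float] = field(default_factory=dict)

    @property
    def analysis_years(self) -> list[int]:
        return [y for y in self.base.years if y <= self.extinction_year]


def _year_columns(columns) -> list[str]:
    return [c for c in columns if re.fullmatch(r"\d{4}", str(c).strip())]


_TRUTHY = {"1", "true", "t", "yes", "y"}


def parse_lpd_table(csv_path) -> list[PopulationTimeSeries]:
    """Read a wide LPD-dialect CSV into one record per row.

    Blank and ``NA`` year cells become missing years. Metadata is kept
    verbatim; a missing ``Country_aggregate`` column defaults to false.
    """
    frame = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    year_cols = _year_columns(frame.columns)
    if not year_cols:
        raise LpdParseError(
            f"{csv_path}: header has no four-digit year columns "
            f"(found {list(frame.columns)[:8]}...)"
        )
    for required in ("ID", "Binomial"):
        if required not in frame.columns:
            raise LpdParseError(f"{csv_path}: missing metadata column {required!r}")

    records: list[PopulationTimeSeries] = []
    for _, row in frame.iterrows():
        obs: dict[int, float] = {}
        for col in year_cols:
            cell = str(row[col]).strip()
            if cell == "" or cell.upper() in {"NA", "NAN", "NULL"}:
                continue
            try:
                value = float(cell)
            except ValueError as exc:
                raise LpdParseError(
                    f"series {row['ID']!r}, year {col}: unparseable abundance {cell!r}"
                ) from exc
            obs[int(col)] = value
        aggregate = str(row.get("Country_aggregate", "")).strip().lower() in _TRUTHY
        records.append(
            PopulationTimeSeries(
                series_id=str(row["ID"]),
                species_binomial=str(row["Binomial"]),
                taxon_class=str(row.get("Class", "")),
                is_country_aggregate=aggregate,
                observations=obs,
                units_note=str(row.get("Units", "")),
            )
        )
    return records


def write_lpd_table(series: list[PopulationTimeSeries], csv_path) -> None:
    """Write records back to the wide dialect (missing cells as empty strings)."""
    years = sorted({y for s in series for y in s.observations})
    rows = []
    for s in series:
        row = {
            "ID": s.series_id,
            "Binomial": s.species_binomial,
            "Class": s.taxon_class,
            "Country_aggregate": "1" if s.is_country_aggregate else "0",
            "Units": s.units_note,
        }
        for y in years:
            v = s.observations.get(y)
            row[str(y)] = "" if v is None else format(v, "g")
        rows.append(row)
    pd.DataFrame(rows, columns=METADATA_COLUMNS + [str(y) for y in years]).to_csv(
        csv_path, index=False
    )


def _terminal_zero_run(values: list[float]) -> int:
    n = 0
    for v in reversed(values):
        if v == 0:
            n += 1
        else:
            break
    return n


def apply_selection_criteria(series: PopulationTimeSeries) -> RejectionReport:
    """Screen one series against all seven selection checks.

    Every failed check is reported, not just the first.
    """
    years = series.years
    values = series.values
    failed: list[str] = []

    if series.is_country_aggregate:
        failed.append(COUNTRY_AGGREGATE)

    if values[-1] != 0:
        failed.append(END_NONZERO)

    # interior zero followed by any later nonzero
    seen_zero = False
    interior = False
    for v in values:
        if v == 0:
            seen_zero = True
        elif seen_zero:
            interior = True
            break
    if interior:
        failed.append(INTERIOR_ZERO)

    run = _terminal_zero_run(values)
    if values[-1] == 0 and run <= 1:
        failed.append(TERMINAL_ZEROS_LE_1)

    if values[-1] == 0 and not interior:
        extinction_year = years[len(years) - run]
        nonzero_years = [y for y, v in series.observations.items() if v > 0]
        prefix = [y for y in nonzero_years if y < extinction_year]
        if len(prefix) < MIN_PREFIX_OBS:
            failed.append(PREFIX_OBS_LT_5)
        if prefix and extinction_year - max(prefix) > 1:
            failed.append(GAP_GT_1YR)
        if extinction_year - years[0] < MIN_SPAN_YEARS:
            failed.append(SPAN_LT_10)

    return RejectionReport(series.series_id, accepted=not failed, failed_criteria=failed)


def derive_yte(series: PopulationTimeSeries) -> FilteredSeries:
    """Index an accepted series on years to extinction.

    The extinction year is the first year of the terminal zero run; every
    observed year ``y`` gets ``yte = extinction_year - y`` (negative after
    extinction, flagged out of analysis).
    """
    report = apply_selection_criteria(series)
    if not report.accepted:
        raise ValueError(
            f"series {series.series_id!r} was rejected "
            f"({', '.join(report.failed_criteria)}); derive_yte requires acceptance"
        )
    years = series.years
    run = _terminal_zero_run(series.values)
    extinction_year = years[len(years) - run]
    yte = {y: extinction_year - y for y in years}
    nonzero_prefix = [
        y for y, v in series.observations.items() if v > 0 and y < extinction_year
    ]
    return FilteredSeries(
        base=series,
        extinction_year=extinction_year,
        yte=yte,
        n_prefix_obs=len(nonzero_prefix),
        span_years=extinction_year - years[0],
    )


def scale_abundance(fs: FilteredSeries) -> FilteredSeries:
    """Scale each series by its own maximum so values span [0, 1].

    Because accepted series end in zeros, dividing by the maximum is the
    same as min-max scaling with the zero anchor preserved.
    """
    peak = max(fs.base.observations.values())
    if peak <= 0:
        raise ValueError(f"series {fs.base.series_id!r}: degenerate series (all zero)")
    fs.scaled_abundance = {y: v / peak for y, v in fs.base.observations.items()}
    return fs


def filter_table(
    series: list[PopulationTimeSeries],
) -> tuple[list[FilteredSeries], list[RejectionReport]]:
    """Screen every series; return scaled accepted series plus all reports."""
    accepted: list[FilteredSeries] = []
    reports: list[RejectionReport] = []
    for s in series:
        report = apply_selection_criteria(s)
        reports.append(report)
        if report.accepted:
            accepted.append(scale_abundance(derive_yte(s)))
    return accepted, reports


def to_long_frame(accepted: list[FilteredSeries]) -> pd.DataFrame:
    """Tidy long table: one row per observed year of each accepted series."""
    rows = []
    for fs in accepted:
        for y, v in fs.base.observations.items():
            rows.append(
                {
                    "series_id": fs.base.series_id,
                    "species": fs.base.species_binomial,
                    "year": y,
                    "abundance": v,
                    "scaled_abundance": fs.scaled_abundance.get(y),
                    "yte": fs.yte[y],
                    "in_analysis": fs.yte[y] >= 0,
                }
            )
    return pd.DataFrame(rows)
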