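"""Reading, validating and unit-normalizing two-column melting data.

Input files are plain text with exactly two numeric columns and no header:
temperature (K or degrees C) and either a normalized helicity degree (CD) or
a baseline-subtracted molar heat capacity (DSC).  Comma-, tab- and
whitespace-delimited layouts (.csv/.txt/.dat) are all accepted; the delimiter
is sniffed from the first row.  All data are canonicalized to K and
J mol^-1 K^-1, sorted by temperature with duplicate temperatures averaged.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import (
    ConfigError,
    DataFormatError,
    HeaderDetectedError,
    InsufficientDataError,
    NotNormalizedError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import FitResult

__all__ = [
    "ThermalCurve",
    "read_two_column",
    "write_two_column",
    "convert_value_units",
    "write_result_table",
    "read_result_table",
    "MIN_POINTS",
    "CD_RANGE_TOLERANCE",
]

#: Minimum number of usable data rows for a melting curve.
MIN_POINTS = 10

#: Helicity may stray outside [0, 1] by this much before the file is
#: rejected as un-normalized raw signal.
CD_RANGE_TOLERANCE = 0.05

#: Thermochemical calorie.
_CAL_TO_J = 4.184

#: Multiplicative conversions to the canonical J/(mol K).
_DSC_FACTORS = {
    "J/(mol*K)": 1.0,
    "J": 1.0,
    "kJ/(mol*K)": 1e3,
    "kJ": 1e3,
    "cal/(mol*K)": _CAL_TO_J,
    "cal": _CAL_TO_J,
    "kcal/(mol*K)": 1e3 * _CAL_TO_J,
    "kcal": 1e3 * _CAL_TO_J,
}

_CD_UNITS = {None, "", "dimensionless", "fraction", "helicity"}


@dataclasses.dataclass(frozen=True)
class ThermalCurve:
    """A canonicalized melting dataset.

    temperatures are in K and strictly increasing; values are dimensionless
    helicity (kind="cd") or J mol^-1 K^-1 per mole of protein (kind="dsc").
    ``source_units`` records what the file declared before conversion.
    """

    temperatures: np.ndarray
    values: np.ndarray
    kind: str
    source_units: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)
        if self.kind not in ("cd", "dsc"):
            raise ConfigError(f"kind must be 'cd' or 'dsc', got {self.kind!r}")
        if t.ndim != 1 or t.shape != v.shape:
            raise DataFormatError("temperatures and values must be equal-length 1-D arrays")
        if t.size < MIN_POINTS:
            raise InsufficientDataError(
                f"melting curve needs >= {MIN_POINTS} points, got {t.size}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise DataFormatError("non-finite entries in melting curve")
        if np.any(np.diff(t) <= 0):
            raise DataFormatError("temperatures must be strictly increasing")
        if self.kind == "cd" and (
            v.min() < -CD_RANGE_TOLERANCE or v.max() > 1.0 + CD_RANGE_TOLERANCE
        ):
            raise NotNormalizedError(
                "CD values outside [0, 1]: helicity must be normalized before fitting "
                f"(range found: [{v.min():g}, {v.max():g}])"
            )

    @property
    def n_points(self) -> int:
        return int(self.temperatures.size)


def _sniff_fields(line: str, decimal_comma: bool) -> list[str] | None:
    """Split one line into exactly two fields, trying delimiters in order."""
    delimiters = (";", "\t", None) if decimal_comma else (",", ";", "\t", None)
    for delim in delimiters:
        fields = [f for f in (line.split(delim) if delim else line.split()) if f.strip()]
        if len(fields) == 2:
            return [f.strip() for f in fields]
    return None


def _parse_float(token: str, decimal_comma: bool) -> float:
    if decimal_comma:
        token = token.replace(",", ".")
    return float(token)


def read_two_column(
    path: str | Path,
    format: str | None = None,
    temp_unit: str = "K",
    value_unit: str | None = None,
    kind: str = "cd",
    decimal_comma: bool = False,
) -> ThermalCurve:
    """Parse a two-column, header-free melting data file.

    Parameters
    ----------
    path:
        CSV/TXT/DAT file; the ``format`` argument is accepted for interface
        symmetry but the delimiter is always sniffed, so the three layouts
        parse identically.
    temp_unit:
        "K" or "C"; Celsius temperatures are shifted by 273.15.
    value_unit:
        For kind="dsc" one of J, kJ, cal, kcal per (mol K); for kind="cd"
        the values must already be a normalized, dimensionless helicity.
    decimal_comma:
        Accept decimal commas (and restrict delimiters to ';'/whitespace so
        the comma is unambiguous).  Off by default: silently guessing the
        locale corrupts data.

    Raises
    ------
    HeaderDetectedError
        if the first row is non-numeric (files must not have headers).
    DataFormatError
        for rows without exactly two numeric fields.
    InsufficientDataError
        for fewer than 10 usable rows.
    """
    path = Path(path)
    if format is not None and format.lower().lstrip(".") not in ("csv", "txt", "dat"):
        raise ConfigError(f"unsupported file format {format!r}")
    if temp_unit not in ("K", "C"):
        raise ConfigError(f"temp_unit must be 'K' or 'C', got {temp_unit!r}")
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise InsufficientDataError(f"{path} is empty")

    temps: list[float] = []
    vals: list[float] = []
    for i, line in enumerate(lines):
        fields = _sniff_fields(line, decimal_comma)
        if fields is None:
            raise DataFormatError(
                f"{path}:{i + 1}: expected exactly two columns, got {line!r}"
            )
        try:
            t = _parse_float(fields[0], decimal_comma)
            v = _parse_float(fields[1], decimal_comma)
        except ValueError:
            if i == 0:
                raise HeaderDetectedError(
                    f"{path}: first row {line!r} is not numeric -- data files "
                    "must not have headers"
                ) from None
            raise DataFormatError(f"{path}:{i + 1}: non-numeric row {line!r}") from None
        temps.append(t)
        vals.append(v)

    t = np.asarray(temps, dtype=float)
    if temp_unit == "C":
        t = t + 273.15
    v = convert_value_units(np.asarray(vals, dtype=float), value_unit, kind)

    # canonical order: sort, then average duplicate temperatures
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    uniq, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if uniq.size != t.size:
        sums = np.zeros_like(uniq)
        np.add.at(sums, inverse, v)
        t, v = uniq, sums / counts
    if t.size < MIN_POINTS:
        raise InsufficientDataError(
            f"{path}: only {t.size} usable rows, need >= {MIN_POINTS}"
        )
    return ThermalCurve(
        temperatures=t,
        values=v,
        kind=kind,
        source_units={"temperature": temp_unit, "value": value_unit},
    )


def write_two_column(curve: ThermalCurve, path: str | Path) -> Path:
    """Write a curve as canonical header-free CSV (K, canonical value units).

    Uses repr-exact floats so read -> write -> read is the identity.
    """
    path = Path(path)
    with path.open("w") as fh:
        for t, v in zip(curve.temperatures, curve.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
    return path


def convert_value_units(
    values: np.ndarray, from_unit: str | None, kind: str
) -> np.ndarray:
    """Convert dependent-variable values to canonical units.

    DSC heat capacities are scaled to J/(mol K) (1 cal = 4.184 J); CD values
    pass through unchanged but are range-checked, since the model fits a
    normalized helicity degree and raw ellipticities are meaningless to it.
    """
    values = np.asarray(values, dtype=float)
    if kind == "cd":
        if from_unit not in _CD_UNITS:
            raise ConfigError(
                f"CD data must be dimensionless normalized helicity, got unit {from_unit!r}"
            )
        if values.size and (
            values.min() < -CD_RANGE_TOLERANCE or values.max() > 1.0 + CD_RANGE_TOLERANCE
        ):
            raise NotNormalizedError(
                "CD values are grossly outside [0, 1]; they should be normalized "
                f"(range found: [{values.min():g}, {values.max():g}])"
            )
        return values
    if kind == "dsc":
        unit = "J" if from_unit is None else from_unit
        if unit not in _DSC_FACTORS:
            raise ConfigError(
                f"unsupported DSC unit {from_unit!r}; choose one of "
                "J, kJ, cal, kcal per (mol*K)"
            )
        return values * _DSC_FACTORS[unit]
    raise ConfigError(f"kind must be 'cd' or 'dsc', got {kind!r}")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_PARAM_UNITS = {"t0": "K", "h": "J/mol", "hps": "J/mol", "Q": "1"}


def write_result_table(result: "FitResult", path: str | Path, format: str = "json") -> Path:
    """Export fitted parameters, percent errors, R^2, warnings and T_m.

    format="json" writes the full result (round-trips through
    :func:`read_result_table`); format="csv" writes one row per parameter
    with columns name, value, unit, percent_error plus summary rows.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(result.to_dict(), indent=2))
        return path
    if format != "csv":
        raise ConfigError(f"format must be 'json' or 'csv', got {format!r}")
    d = result.to_dict()
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "value", "unit", "percent_error"])
        for name in ("t0", "h", "hps", "Q"):
            pe = d["percent_errors"][name]
            writer.writerow(
                [name, repr(d["params"][name]), _PARAM_UNITS[name],
                 "" if pe is None else repr(pe)]
            )
        writer.writerow(["q", repr(d["params"]["q"]), "1", ""])
        writer.writerow(["r_squared", repr(d["r_squared"]), "1", ""])
        tm = d["melting_temperature"]
        writer.writerow(["melting_temperature", "" if tm is None else repr(tm), "K", ""])
        writer.writerow(["warnings", ";".join(d["warnings"]), "", ""])
    return path


def read_result_table(path: str | Path) -> "FitResult":
    """Reload a JSON result written by :func:`write_result_table`."""
    from .fitting import FitResult

    return FitResult.from_dict(json.loads(Path(path).read_text()))
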