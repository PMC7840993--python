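"""Plate-format melt-curve I/O.

Melt curves travel as CSV in one of two dialects:

* ``wide`` (canonical, mirrors common qPCR melt exports): first column
  ``Temperature``, one column per well.
* ``long``: columns ``well``, ``temperature``, ``rfu``.

Plate layouts are YAML documents mapping well ids to assay conditions
(probe, ligand, inhibitor, replicate group, role).  Result tables are
written as TSV with 6-significant-digit numeric formatting so repeated
runs are byte-identical.

Temperatures are degrees Celsius at every interface; concentration
units are carried per field as declared in the layout and never
converted silently.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from thermoshift.errors import ParseError, ValidationError

__all__ = [
    "MeltPlate",
    "WellCondition",
    "read_melt_csv",
    "write_melt_csv",
    "read_layout",
    "write_results",
]

_ROLES = {"sample", "reference", "blank"}


@dataclass
class WellCondition:
    """Assay conditions for one well of a plate layout."""

    well_id: str
    probe: str
    probe_conc: float = 1.5
    ligand: str | None = None
    ligand_conc: float | None = None
    inhibitor: str | None = None
    inhibitor_conc: float | None = None
    inhibitor_conc_unit: str = "uM"
    replicate_group: str | None = None
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(
                f"well {self.well_id!r}: unknown role {self.role!r} (expected one of {sorted(_ROLES)})"
            )
        if self.replicate_group is None:
            self.replicate_group = self.well_id
        for name in ("probe_conc", "ligand_conc", "inhibitor_conc"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"well {self.well_id!r}: {name} must be >= 0, got {value}")
        if self.role == "reference" and (self.ligand is not None or self.inhibitor is not None):
            raise ValidationError(
                f"well {self.well_id!r}: reference wells must have no ligand and no inhibitor"
            )


@dataclass
class MeltPlate:
    """A shared ascending temperature grid plus one RFU trace per well."""

    temperatures: np.ndarray
    curves: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.curves = {well: np.asarray(c, dtype=float) for well, c in self.curves.items()}
        self.validate()

    def validate(self) -> None:
        t = self.temperatures
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("temperature grid must be 1-D with at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("temperature grid must be strictly increasing")
        for well, curve in self.curves.items():
            if curve.shape != t.shape:
                raise ValidationError(
                    f"curve for well {well!r} has length {curve.size}, grid has {t.size}"
                )

    @property
    def wells(self) -> list[str]:
        return list(self.curves)

    def __len__(self) -> int:
        return len(self.curves)


def _as_text_stream(source: str | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source, "r", encoding="utf-8")


def read_melt_csv(source: str | IO[str], dialect: str = "auto") -> MeltPlate:
    """Parse a melt-curve CSV in the wide or long dialect.

    ``dialect='auto'`` sniffs the header: a first column named
    ``Temperature`` (case-insensitive) selects wide, the column triple
    ``well/temperature/rfu`` selects long.
    """
    stream = _as_text_stream(source)
    text = stream.read()
    header = [c.strip() for c in text.splitlines()[0].split(",")] if text.strip() else []
    try:
        frame = pd.read_csv(io.StringIO(text), dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"malformed melt CSV: {exc}") from exc
    if frame.empty or frame.shape[1] < 2:
        raise ParseError("melt CSV has no data columns")

    columns = [str(c).strip() for c in frame.columns]
    lowered = [c.lower() for c in columns]
    if dialect == "auto":
        dialect = "long" if set(lowered) >= {"well", "temperature", "rfu"} else "wide"

    if dialect == "wide":
        if lowered[0] != "temperature":
            raise ParseError(
                f"wide melt CSV must start with a 'Temperature' column, got {columns[0]!r}"
            )
        # pandas silently mangles duplicate headers, so check the raw header
        seen: set[str] = set()
        for c in header[1:]:
            if c in seen:
                raise ParseError(f"duplicate well column {c!r}")
            seen.add(c)
        data = _numeric(frame, columns)
        data = data.sort_values(columns[0], kind="mergesort")
        temps = data[columns[0]].to_numpy()
        _check_monotone(temps)
        curves = {c: data[c].to_numpy() for c in columns[1:]}
        return MeltPlate(temperatures=temps, curves=curves)

    if dialect == "long":
        rename = dict(zip(columns, lowered))
        frame = frame.rename(columns=rename)
        missing = {"well", "temperature", "rfu"} - set(frame.columns)
        if missing:
            raise ParseError(f"long melt CSV missing columns: {sorted(missing)}")
        frame["temperature"] = _numeric_col(frame["temperature"], "temperature")
        frame["rfu"] = _numeric_col(frame["rfu"], "rfu")
        curves: dict[str, np.ndarray] = {}
        temps_ref: np.ndarray | None = None
        for well, group in frame.groupby("well", sort=False):
            group = group.sort_values("temperature", kind="mergesort")
            temps = group["temperature"].to_numpy()
            _check_monotone(temps, well=str(well))
            if temps_ref is None:
                temps_ref = temps
            elif temps.shape != temps_ref.shape or not np.allclose(temps, temps_ref):
                raise ParseError(f"well {well!r} uses a different temperature grid")
            curves[str(well)] = group["rfu"].to_numpy()
        assert temps_ref is not None
        return MeltPlate(temperatures=temps_ref, curves=curves)

    raise ValueError(f"unknown dialect {dialect!r}")


def _numeric(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = pd.DataFrame()
    for c in columns:
        out[c] = _numeric_col(frame[c], c)
    return out


def _numeric_col(series: pd.Series, name: str) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(f"non-numeric cell in column {name!r}, row {row + 2}: {series[row]!r}")
    if converted.isna().any():
        row = int(converted.isna().idxmax())
        raise ParseError(f"empty cell in column {name!r}, row {row + 2}")
    return converted.astype(float)


def _check_monotone(temps: np.ndarray, well: str | None = None) -> None:
    diffs = np.diff(temps)
    if np.any(diffs == 0):
        t = temps[np.argmax(diffs == 0)]
        where = f" for well {well!r}" if well else ""
        raise ParseError(f"repeated temperature {t:g}{where}")


def write_melt_csv(plate: MeltPlate, destination: str | IO[str], dialect: str = "wide") -> None:
    """Write a plate back to CSV (6 significant digits)."""
    stream = destination if hasattr(destination, "write") else open(destination, "w", encoding="utf-8")
    if dialect == "wide":
        frame = pd.DataFrame({"Temperature": plate.temperatures})
        for well in plate.wells:
            frame[well] = plate.curves[well]
    elif dialect == "long":
        rows = []
        for well in plate.wells:
            for t, r in zip(plate.temperatures, plate.curves[well]):
                rows.append({"well": well, "temperature": t, "rfu": r})
        frame = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame.to_csv(stream, index=False, float_format="%.6g")


def read_layout(source: str | IO[str]) -> dict[str, WellCondition]:
    """Read a plate-layout YAML document.

    Expected shape::

        wells:
          A1: {probe: p65_1-306, role: reference}
          A2: {probe: p65_1-306, ligand: 2kB, ligand_conc: 10, replicate_group: d10}

    Unlisted fields default per :class:`WellCondition` (role ``sample``,
    replicate group = well id).
    """
    stream = _as_text_stream(source)
    try:
        doc = yaml.safe_load(stream)
    except yaml.YAMLError as exc:
        raise ParseError(f"malformed layout YAML: {exc}") from exc
    if not isinstance(doc, Mapping) or "wells" not in doc:
        raise ParseError("layout document must be a mapping with a top-level 'wells' key")
    wells = doc["wells"]
    if not isinstance(wells, Mapping) or not wells:
        raise ParseError("'wells' must be a non-empty mapping of well id -> conditions")
    layout: dict[str, WellCondition] = {}
    for well_id, fields in wells.items():
        well_id = str(well_id)
        if well_id in layout:
            raise ValidationError(f"duplicate well {well_id!r} in layout")
        fields = dict(fields or {})
        unknown = set(fields) - {
            "probe",
            "probe_conc",
            "ligand",
            "ligand_conc",
            "inhibitor",
            "inhibitor_conc",
            "inhibitor_conc_unit",
            "replicate_group",
            "role",
        }
        if unknown:
            raise ParseError(f"well {well_id!r}: unknown layout fields {sorted(unknown)}")
        if "probe" not in fields:
            raise ParseError(f"well {well_id!r}: layout entry must name a probe")
        layout[well_id] = WellCondition(well_id=well_id, **fields)
    return layout


def write_layout(layout: Mapping[str, WellCondition], destination: str | IO[str]) -> None:
    """Write a layout mapping back to YAML (inverse of :func:`read_layout`)."""
    wells: dict[str, dict] = {}
    for well_id, cond in layout.items():
        entry: dict = {"probe": cond.probe, "probe_conc": cond.probe_conc, "role": cond.role}
        if cond.ligand is not None:
            entry["ligand"] = cond.ligand
            entry["ligand_conc"] = cond.ligand_conc
        if cond.inhibitor is not None:
            entry["inhibitor"] = cond.inhibitor
            entry["inhibitor_conc"] = cond.inhibitor_conc
            entry["inhibitor_conc_unit"] = cond.inhibitor_conc_unit
        entry["replicate_group"] = cond.replicate_group
        wells[well_id] = entry
    stream = destination if hasattr(destination, "write") else open(destination, "w", encoding="utf-8")
    yaml.safe_dump({"wells": wells}, stream, sort_keys=False)


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return "nan"
        return f"{value:.6g}"
    if isinstance(value, (frozenset, set, tuple, list)):
        return ";".join(str(v) for v in sorted(value, key=str))
    return str(value)


def write_results(records: Iterable[Mapping], destination: str | IO[str]) -> None:
    """Write result rows as TSV: deterministic column order (first-seen),
    header always present, numbers at 6 significant digits."""
    records = [dict(r) for r in records]
    columns: list[str] = []
    for rec in records:
        for key in rec:
            if key not in columns:
                columns.append(key)
    stream = destination if hasattr(destination, "write") else open(destination, "w", encoding="utf-8")
    stream.write("\t".join(columns) + "\n")
    for rec in records:
        stream.write("\t".join(_format_cell(rec.get(c)) for c in columns) + "\n")


def results_to_string(records: Iterable[Mapping]) -> str:
    buffer = io.StringIO()
    write_results(records, buffer)
    return buffer.getvalue()
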