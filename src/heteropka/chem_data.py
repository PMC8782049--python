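"""Domain types, reference datasets, and CSV/JSON I/O.

The package estimates acid dissociation constants (pKa) of pyrimidines and
related nitrogen heterocycles from quantum-chemically computed energies.
This module defines the in-memory containers everything else operates on:

* :class:`Microstate` — one tautomer of one charge state of one compound,
  with its electronic energy in one phase (gas or aqueous continuum).
* :class:`CompoundRecord` — a compound together with its microstates,
  literature pKa measurements, and external-predictor (ACD) values.
* :class:`ThermoRecord` — a gas-phase deprotonation free-energy entry used
  for method validation.
* :class:`ReferenceRow` — a row of the packaged reference result tables
  (ΔE, experimental pKa, estimated pKa, residual).

Four reference tables are shipped as plain CSV under ``heteropka/data`` and
exposed through :func:`fixture_tables`:

* ``table1.csv`` — 31 compounds with literature pKa1/pKa2 values (with
  source tags) and ACD-predicted values with uncertainties,
* ``table2.csv`` — 6 gas-phase deprotonation free energies (experimental
  vs. calculated),
* ``table3.csv`` / ``table4.csv`` — per-compound ΔE_H2O descriptors with
  experimental values, model estimates, and residuals for the
  cation→neutral (pKa1) and neutral→anion (pKa2) steps.

Transcription conventions: UTF-8, comma-separated, ``.`` decimal, ASCII
minus. ``-`` marks a value that is not available; ``N/A`` marks a compound
with no dissociable proton for that step. Two formula cells carry apparent
typos from the source tables (isoxazole/oxazole both ``C3H6NO``, pyridazine
``C4H43N2``); they are stored as printed since identifiers, not formulas,
key the data.
"""

from __future__ import annotations

import csv
import io
import json
import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "HARTREE_TO_KJ_PER_MOL",
    "Phase",
    "Step",
    "Availability",
    "PROTONATED_CHARGE",
    "DEPROTONATED_CHARGE",
    "Microstate",
    "LiteraturePka",
    "ExternalPrediction",
    "CompoundRecord",
    "ThermoRecord",
    "ReferenceRow",
    "FixtureTables",
    "ParseError",
    "ValidationError",
    "slugify",
    "round_half_up",
    "load_dataset",
    "write_dataset",
    "read_microstates",
    "write_microstates",
    "read_pka",
    "write_pka",
    "read_external",
    "write_external",
    "fixture_tables",
    "calibration_pairs",
    "complete_external_pairs",
]

#: Conversion factor for energies declared in hartree (CODATA, kJ/mol).
HARTREE_TO_KJ_PER_MOL = 2625.5


class Phase(str, Enum):
    """Phase in which an electronic energy was computed."""

    GAS = "gas"
    AQUEOUS = "aqueous"


class Step(str, Enum):
    """Dissociation step: pKa1 is cation→neutral, pKa2 is neutral→anion."""

    PKA1 = "pka1"
    PKA2 = "pka2"


#: Charge of the proton-bearing (parent) species of each step.
PROTONATED_CHARGE = {Step.PKA1: 1, Step.PKA2: 0}
#: Charge of the deprotonated (product) species of each step.
DEPROTONATED_CHARGE = {Step.PKA1: 0, Step.PKA2: -1}


class Availability(Enum):
    """Why a literature pKa may be absent for a compound/step.

    ``NOT_MEASURED`` (printed ``-``) means no measurement was found; such
    compounds may still receive model predictions.  ``NO_PROTON`` (printed
    ``N/A``) means the step is chemically undefined (no dissociable proton)
    and no prediction applies.
    """

    MEASURED = "measured"
    NOT_MEASURED = "-"
    NO_PROTON = "N/A"


class ParseError(ValueError):
    """A malformed cell in an input file; names the line and column."""

    def __init__(self, message: str, *, line: int | None = None,
                 column: str | None = None, path: object = None) -> None:
        where = []
        if path is not None:
            where.append(str(path))
        if line is not None:
            where.append(f"line {line}")
        if column is not None:
            where.append(f"column '{column}'")
        prefix = ", ".join(where)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.line = line
        self.column = column


class ValidationError(ValueError):
    """A dataset-level invariant violation (e.g. duplicate microstate key)."""


_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(name: str) -> str:
    """Normalise a compound name to a lowercase hyphenated identifier."""
    return _SLUG_RE.sub("-", name.strip().lower()).strip("-")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with exact decimal half-up ties.

    Operates on the shortest decimal representation of the float (its
    ``repr``), so values that *are* printed decimals round the way a reader
    of the printed number would expect.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Microstate:
    """One tautomer of one charge state of one compound, in one phase."""

    compound_id: str
    charge: int
    tautomer_id: str
    phase: Phase
    energy: float  # kJ/mol

    def __post_init__(self) -> None:
        if self.charge not in (-1, 0, 1):
            raise ValidationError(
                f"{self.compound_id}/{self.tautomer_id}: charge must be in "
                f"{{-1, 0, +1}}, got {self.charge}")
        if not math.isfinite(self.energy):
            raise ValidationError(
                f"{self.compound_id}/{self.tautomer_id}: energy must be finite")
        object.__setattr__(self, "phase", Phase(self.phase))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.compound_id, self.charge, self.tautomer_id, self.phase.value)


#: Plausibility window for measured aqueous pKa values; enforced when
#: parsing literature tables (where a violation indicates a transcription
#: error), not on programmatic construction — model predictions and
#: synthetic ground truth may legitimately fall outside it.
PKA_PLAUSIBLE_RANGE = (-10.0, 25.0)


@dataclass(frozen=True)
class LiteraturePka:
    """One literature pKa measurement with its source tag."""

    compound_id: str
    step: Step
    value: float
    source_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "step", Step(self.step))
        if not math.isfinite(self.value):
            raise ValidationError(
                f"{self.compound_id}: literature pKa must be finite")


@dataclass(frozen=True)
class ExternalPrediction:
    """A pKa value from an external (commercial) predictor, with its ±."""

    compound_id: str
    step: Step
    value: float
    uncertainty: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "step", Step(self.step))


@dataclass
class CompoundRecord:
    """A compound with its microstates, literature values and external
    predictions.

    ``availability`` records, per step, whether an experimental value exists,
    was simply not found (``-``), or is chemically undefined (``N/A``).
    """

    compound_id: str
    name: str = ""
    formula: str = ""
    microstates: list[Microstate] = field(default_factory=list)
    literature: list[LiteraturePka] = field(default_factory=list)
    external: list[ExternalPrediction] = field(default_factory=list)
    availability: dict[Step, Availability] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.compound_id
        for step in Step:
            if step not in self.availability:
                self.availability[step] = (
                    Availability.MEASURED
                    if any(p.step == step for p in self.literature)
                    else Availability.NOT_MEASURED)

    def microstates_for(self, charge: int, phase: Phase) -> list[Microstate]:
        phase = Phase(phase)
        return [m for m in self.microstates
                if m.charge == charge and m.phase == phase]

    def literature_values(self, step: Step) -> list[float]:
        step = Step(step)
        return [p.value for p in self.literature if p.step == step]

    def external_for(self, step: Step) -> ExternalPrediction | None:
        step = Step(step)
        for p in self.external:
            if p.step == step:
                return p
        return None

    def has_step(self, step: Step, phase: Phase = Phase.AQUEOUS) -> bool:
        """True when both charge states needed by ``step`` have a microstate."""
        step = Step(step)
        return bool(self.microstates_for(PROTONATED_CHARGE[step], phase)
                    and self.microstates_for(DEPROTONATED_CHARGE[step], phase))


@dataclass(frozen=True)
class ThermoRecord:
    """Gas-phase deprotonation entry: experimental vs calculated ΔrG° (kJ/mol)."""

    compound_id: str
    exp_drG: float
    calc_drG: float
    calc_dE: float = float("nan")


@dataclass(frozen=True)
class ReferenceRow:
    """One row of a reference result table (tables 3/4 of the shipped data).

    ``calc`` is a float for numeric estimates or one of the qualitative
    strings ``"<0"`` / ``"<<0"`` for poorly characterised negative values.
    ``exp_text`` preserves the experimental value exactly as printed (for
    precision-aware comparisons); ``exp`` is its float value or None.
    """

    compound_id: str
    delta_e: float
    exp: float | None
    calc: float | str | None
    residual: float | None
    exp_text: str | None = None

    @property
    def calc_is_numeric(self) -> bool:
        return isinstance(self.calc, float)


class FixtureTables(NamedTuple):
    table1: list[CompoundRecord]
    table2: list[ThermoRecord]
    table3: list[ReferenceRow]
    table4: list[ReferenceRow]


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

_LIT_ENTRY_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*(?:\[([^\]]*)\])?\s*$")


def _parse_float(cell: str, *, line: int, column: str, path: object) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"expected a number, got {cell!r}",
                         line=line, column=column, path=path) from None


def _parse_literature_cell(cell: str, compound_id: str, step: Step, *,
                           line: int, path: object,
                           ) -> tuple[list[LiteraturePka], Availability]:
    column = step.value
    cell = cell.strip()
    if cell == "-" or cell == "":
        return [], Availability.NOT_MEASURED
    if cell.upper() == "N/A":
        return [], Availability.NO_PROTON
    entries = []
    for part in cell.split(";"):
        m = _LIT_ENTRY_RE.match(part)
        if m is None:
            raise ParseError(f"malformed literature entry {part!r}",
                             line=line, column=column, path=path)
        value = float(m.group(1))
        _check_pka_range(value, line=line, column=column, path=path)
        entries.append(LiteraturePka(compound_id, step, value,
                                     m.group(2) or ""))
    return entries, Availability.MEASURED


def _check_pka_range(value: float, *, line: int, column: str,
                     path: object) -> None:
    lo, hi = PKA_PLAUSIBLE_RANGE
    if not (lo <= value <= hi):
        raise ParseError(
            f"literature pKa {value} outside the plausible [{lo:g}, {hi:g}] "
            "window (transcription error?)",
            line=line, column=column, path=path)


def _check_unique_microstates(microstates: Iterable[Microstate]) -> None:
    seen: set[tuple] = set()
    for m in microstates:
        if m.key in seen:
            raise ValidationError(
                f"duplicate microstate key {m.key}: (compound, charge, "
                f"tautomer, phase) must be unique within a dataset")
        seen.add(m.key)


# ---------------------------------------------------------------------------
# Readers / writers for the documented CSV schemas
# ---------------------------------------------------------------------------

MICROSTATE_COLUMNS = ["compound_id", "charge", "tautomer_id", "phase",
                      "energy", "unit"]
PKA_COLUMNS = ["compound_id", "step", "value", "source"]
EXTERNAL_COLUMNS = ["compound_id", "step", "value", "uncertainty"]
_COMPOUND_COLUMNS = ["no", "name", "formula", "pka1", "acd_pka1",
                     "acd_pka1_unc", "pka2", "acd_pka2", "acd_pka2_unc"]
_THERMO_COLUMNS = ["compound", "exp_drg", "calc_drg", "calc_de"]


def _open_rows(path: Path) -> tuple[list[str], list[tuple[int, dict]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError("empty file (no header row)", path=path)
        rows = [(i, row) for i, row in enumerate(reader, start=2)]
    return list(reader.fieldnames), rows


def read_microstates(path: str | Path) -> list[Microstate]:
    """Read a ``microstates.csv`` file; converts hartree energies to kJ/mol."""
    path = Path(path)
    header, rows = _open_rows(path)
    out = []
    for line, row in rows:
        unit = (row.get("unit") or "kj/mol").strip().lower()
        energy = _parse_float(row["energy"], line=line, column="energy", path=path)
        if unit in ("hartree", "au", "a.u."):
            energy *= HARTREE_TO_KJ_PER_MOL
        elif unit not in ("kj/mol", "kjmol", "kj"):
            raise ParseError(f"unknown energy unit {unit!r}",
                             line=line, column="unit", path=path)
        charge = row["charge"].strip()
        try:
            charge_i = int(charge)
        except ValueError:
            raise ParseError(f"expected an integer charge, got {charge!r}",
                             line=line, column="charge", path=path) from None
        try:
            phase = Phase(row["phase"].strip().lower())
        except ValueError:
            raise ParseError(f"unknown phase {row['phase']!r}",
                             line=line, column="phase", path=path) from None
        out.append(Microstate(row["compound_id"].strip(), charge_i,
                              row["tautomer_id"].strip(), phase, energy))
    _check_unique_microstates(out)
    return out


def write_microstates(microstates: Sequence[Microstate], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MICROSTATE_COLUMNS)
        for m in microstates:
            w.writerow([m.compound_id, m.charge, m.tautomer_id,
                        m.phase.value, repr(m.energy), "kj/mol"])


def read_pka(path: str | Path,
             validate_range: bool = False) -> list[LiteraturePka]:
    """Read a ``pka.csv`` file.

    ``validate_range`` additionally enforces the measured-value plausibility
    window; leave it off for files holding simulated ground truth, which may
    legitimately extend beyond the measurable range.
    """
    path = Path(path)
    _, rows = _open_rows(path)
    out = []
    for line, row in rows:
        value = _parse_float(row["value"], line=line, column="value", path=path)
        if validate_range:
            _check_pka_range(value, line=line, column="value", path=path)
        try:
            step = Step(row["step"].strip().lower())
        except ValueError:
            raise ParseError(f"unknown step {row['step']!r}",
                             line=line, column="step", path=path) from None
        out.append(LiteraturePka(row["compound_id"].strip(), step, value,
                                 (row.get("source") or "").strip()))
    return out


def write_pka(values: Sequence[LiteraturePka], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PKA_COLUMNS)
        for p in values:
            w.writerow([p.compound_id, p.step.value, repr(p.value), p.source_tag])


def read_external(path: str | Path) -> list[ExternalPrediction]:
    path = Path(path)
    _, rows = _open_rows(path)
    out = []
    for line, row in rows:
        value = _parse_float(row["value"], line=line, column="value", path=path)
        unc_cell = (row.get("uncertainty") or "").strip()
        unc = (float("nan") if unc_cell in ("", "-")
               else _parse_float(unc_cell, line=line, column="uncertainty",
                                 path=path))
        try:
            step = Step(row["step"].strip().lower())
        except ValueError:
            raise ParseError(f"unknown step {row['step']!r}",
                             line=line, column="step", path=path) from None
        out.append(ExternalPrediction(row["compound_id"].strip(), step, value, unc))
    return out


def write_external(values: Sequence[ExternalPrediction], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EXTERNAL_COLUMNS)
        for p in values:
            unc = "-" if math.isnan(p.uncertainty) else repr(p.uncertainty)
            w.writerow([p.compound_id, p.step.value, repr(p.value), unc])


# ---------------------------------------------------------------------------
# Dataset-level load/write with schema dispatch
# ---------------------------------------------------------------------------

def _load_compound_table(path: Path) -> list[CompoundRecord]:
    _, rows = _open_rows(path)
    records = []
    seen_ids: set[str] = set()
    for line, row in rows:
        name = row["name"].strip()
        cid = slugify(name)
        if cid in seen_ids:
            raise ValidationError(f"duplicate compound {cid!r} at line {line}")
        seen_ids.add(cid)
        lit: list[LiteraturePka] = []
        availability: dict[Step, Availability] = {}
        external: list[ExternalPrediction] = []
        for step, lit_col, acd_col, unc_col in (
                (Step.PKA1, "pka1", "acd_pka1", "acd_pka1_unc"),
                (Step.PKA2, "pka2", "acd_pka2", "acd_pka2_unc")):
            entries, avail = _parse_literature_cell(
                row[lit_col], cid, step, line=line, path=path)
            lit.extend(entries)
            availability[step] = avail
            acd = (row.get(acd_col) or "-").strip()
            if acd not in ("-", ""):
                unc_cell = (row.get(unc_col) or "").strip()
                unc = (float("nan") if unc_cell in ("", "-")
                       else _parse_float(unc_cell, line=line, column=unc_col,
                                         path=path))
                external.append(ExternalPrediction(
                    cid, step,
                    _parse_float(acd, line=line, column=acd_col, path=path),
                    unc))
        records.append(CompoundRecord(cid, name, row["formula"].strip(),
                                      [], lit, external, availability))
    return records


def _load_thermo_table(path: Path) -> list[ThermoRecord]:
    _, rows = _open_rows(path)
    out = []
    for line, row in rows:
        out.append(ThermoRecord(
            slugify(row["compound"]),
            _parse_float(row["exp_drg"], line=line, column="exp_drg", path=path),
            _parse_float(row["calc_drg"], line=line, column="calc_drg", path=path),
            _parse_float(row.get("calc_de", "nan") or "nan",
                         line=line, column="calc_de", path=path)))
    return out


def _microstates_to_records(microstates: Sequence[Microstate]) -> list[CompoundRecord]:
    by_id: dict[str, list[Microstate]] = {}
    for m in microstates:
        by_id.setdefault(m.compound_id, []).append(m)
    return [CompoundRecord(cid, microstates=ms)
            for cid, ms in sorted(by_id.items())]


def load_dataset(path: str | Path, format: str = "csv"):
    """Load a dataset, dispatching on the file's schema.

    CSV headers are matched against the documented schemas: the compound
    summary table (→ ``CompoundRecord`` list), the microstates table
    (→ ``CompoundRecord`` list grouped by compound), and the gas-phase
    thermochemistry table (→ ``ThermoRecord`` list).  ``format="csv"`` may
    also point at a directory previously written by :func:`write_dataset`.
    ``format="json"`` reads the JSON mirror of the compound schema.
    """
    path = Path(path)
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return _records_from_jsonable(json.load(fh))
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    if path.is_dir():
        return _load_dataset_dir(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header_line = fh.readline()
    header = [h.strip() for h in next(csv.reader(io.StringIO(header_line)), [])]
    if set(_THERMO_COLUMNS) <= set(header):
        return _load_thermo_table(path)
    if set(MICROSTATE_COLUMNS) <= set(header):
        return _microstates_to_records(read_microstates(path))
    if set(_COMPOUND_COLUMNS) <= set(header):
        return _load_compound_table(path)
    raise ParseError(f"unrecognised column schema {header!r}", path=path)


def _load_dataset_dir(path: Path) -> list[CompoundRecord]:
    records = {r.compound_id: r
               for r in _microstates_to_records(
                   read_microstates(path / "microstates.csv")
                   if (path / "microstates.csv").exists() else [])}
    if (path / "pka.csv").exists():
        for p in read_pka(path / "pka.csv"):
            records.setdefault(p.compound_id,
                               CompoundRecord(p.compound_id)).literature.append(p)
    if (path / "external.csv").exists():
        for p in read_external(path / "external.csv"):
            records.setdefault(p.compound_id,
                               CompoundRecord(p.compound_id)).external.append(p)
    out = []
    for cid in sorted(records):
        rec = records[cid]
        # recompute availability now that literature is attached
        rec.availability = {}
        rec.__post_init__()
        out.append(rec)
    return out


def write_dataset(records: Sequence[CompoundRecord], path: str | Path,
                  format: str = "json") -> None:
    """Write a dataset; ``json`` to one file, ``csv`` to a directory of the
    three documented schema files (microstates/pka/external)."""
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_records_to_jsonable(records), fh, indent=1)
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    path.mkdir(parents=True, exist_ok=True)
    write_microstates([m for r in records for m in r.microstates],
                      path / "microstates.csv")
    write_pka([p for r in records for p in r.literature], path / "pka.csv")
    write_external([p for r in records for p in r.external],
                   path / "external.csv")


def _records_to_jsonable(records: Sequence[CompoundRecord]) -> list[dict]:
    out = []
    for r in records:
        out.append({
            "compound_id": r.compound_id,
            "name": r.name,
            "formula": r.formula,
            "availability": {s.value: a.value for s, a in r.availability.items()},
            "microstates": [
                {"compound_id": m.compound_id, "charge": m.charge,
                 "tautomer_id": m.tautomer_id, "phase": m.phase.value,
                 "energy": m.energy} for m in r.microstates],
            "literature": [
                {"compound_id": p.compound_id, "step": p.step.value,
                 "value": p.value, "source_tag": p.source_tag}
                for p in r.literature],
            "external": [
                {"compound_id": p.compound_id, "step": p.step.value,
                 "value": p.value,
                 "uncertainty": None if math.isnan(p.uncertainty)
                 else p.uncertainty} for p in r.external],
        })
    return out


def _records_from_jsonable(data: list[dict]) -> list[CompoundRecord]:
    records = []
    for d in data:
        microstates = [Microstate(m["compound_id"], m["charge"],
                                  m["tautomer_id"], Phase(m["phase"]),
                                  m["energy"]) for m in d.get("microstates", [])]
        literature = [LiteraturePka(p["compound_id"], Step(p["step"]),
                                    p["value"], p.get("source_tag", ""))
                      for p in d.get("literature", [])]
        external = [ExternalPrediction(
            p["compound_id"], Step(p["step"]), p["value"],
            float("nan") if p.get("uncertainty") is None else p["uncertainty"])
            for p in d.get("external", [])]
        availability = {Step(s): Availability(a)
                        for s, a in d.get("availability", {}).items()}
        records.append(CompoundRecord(d["compound_id"], d.get("name", ""),
                                      d.get("formula", ""), microstates,
                                      literature, external, availability))
    _check_unique_microstates(m for r in records for m in r.microstates)
    return records


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("heteropka").joinpath("data", name)))


def _load_reference_table(path: Path, exp_col: str, calc_col: str,
                          ) -> list[ReferenceRow]:
    _, rows = _open_rows(path)
    out = []
    for line, row in rows:
        exp_text = row[exp_col].strip()
        exp = None if exp_text == "-" else _parse_float(
            exp_text, line=line, column=exp_col, path=path)
        calc_text = row[calc_col].strip()
        calc: float | str | None
        if calc_text == "-":
            calc = None
        elif calc_text in ("<0", "<<0"):
            calc = calc_text
        else:
            calc = _parse_float(calc_text, line=line, column=calc_col, path=path)
        res_text = row["residual"].strip()
        residual = None if res_text == "-" else _parse_float(
            res_text, line=line, column="residual", path=path)
        out.append(ReferenceRow(
            slugify(row["compound"]),
            _parse_float(row["delta_e"], line=line, column="delta_e", path=path),
            exp, calc, residual, None if exp is None else exp_text))
    return out


def fixture_tables() -> FixtureTables:
    """Load the four packaged reference tables."""
    table1 = _load_compound_table(_data_path("table1.csv"))
    table2 = _load_thermo_table(_data_path("table2.csv"))
    table3 = _load_reference_table(_data_path("table3.csv"),
                                   "exp_pka1", "calc_pka1")
    table4 = _load_reference_table(_data_path("table4.csv"),
                                   "exp_pka2", "calc_pka2")
    return FixtureTables(table1, table2, table3, table4)


def calibration_pairs(rows: Sequence[ReferenceRow]) -> list[tuple[float, float]]:
    """(ΔE, experimental pKa) pairs eligible for model calibration.

    A row enters the calibration set when its experimental value is numeric
    *and* its estimate is numeric — compounds whose estimated value falls in
    the poorly characterised negative range (qualitative ``<0`` / ``<<0``
    marks) are excluded from fitting but still appear in prediction reports.
    """
    return [(r.delta_e, r.exp) for r in rows
            if r.exp is not None and r.calc_is_numeric]


def complete_external_pairs(records: Sequence[CompoundRecord], step: Step,
                            consolidate=None) -> list[tuple[float, float]]:
    """(external prediction, experimental pKa) pairs for compounds that have
    both.  ``consolidate`` collapses multiple literature values; defaults to
    the package's consolidation rule (imported lazily to avoid a cycle)."""
    if consolidate is None:
        from .consolidation import consolidate as consolidate_fn
        consolidate = consolidate_fn
    step = Step(step)
    pairs = []
    for r in records:
        ext = r.external_for(step)
        values = r.literature_values(step)
        if ext is None or not values:
            continue
        pairs.append((ext.value, consolidate(values, ndigits=None)))
    return pairs
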