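"""Long-format CSV I/O for 96-well ELISA plate data.

One interchange dialect is used throughout: a UTF-8 CSV with header

    plate_id,batch,run_date,operator,well,role,sample_id,conc,od

and one row per well.  ``role`` is one of ``standard``, ``control``,
``unknown``, ``blank``; ``conc`` is the nominal standard concentration in
pg/mL (empty for wells without a known concentration); ``od`` the measured
optical density.  ``batch`` is a free-form grouping label — a kit lot for
lot-level correction or the plate id itself for per-plate correction; the
model code never assumes which granularity was chosen.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, DuplicateWellError, FormatError

__all__ = [
    "Well",
    "Plate",
    "ROLES",
    "read_plates",
    "write_plates",
    "group_by_batch",
    "standard_points",
    "write_results",
    "RESULT_COLUMNS",
]

ROLES = ("standard", "control", "unknown", "blank")
_WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")
PLATE_COLUMNS = ("plate_id", "batch", "run_date", "operator", "well", "role", "sample_id", "conc", "od")
RESULT_COLUMNS = (
    "plate_id", "batch", "sample_id", "n_wells", "mean_od", "cv_pct",
    "raw_conc", "adjusted_conc", "S", "flags",
)


@dataclass(frozen=True)
class Well:
    """One measured well: an optical density with its role and grouping.

    ``sample_id`` keys replicate wells of the same sample/standard level;
    ``conc`` holds the nominal concentration (pg/mL) for standards and is
    ``None`` otherwise.
    """

    well: str
    role: str
    sample_id: str
    od: float
    conc: float | None = None

    def __post_init__(self):
        if not _WELL_RE.match(self.well):
            raise DataError(f"invalid well address {self.well!r}")
        if self.role not in ROLES:
            raise DataError(f"invalid role {self.role!r}; expected one of {ROLES}")
        if self.role == "standard":
            if self.conc is None or not (self.conc > 0):
                raise DataError(f"standard well {self.well} requires a positive concentration")
        if self.conc is not None and self.conc < 0:
            raise DataError(f"negative concentration in well {self.well}")


@dataclass
class Plate:
    """A dated, operator-attributed set of wells sharing a batch label."""

    plate_id: str
    batch: str
    run_date: str
    operator: str
    wells: list[Well] = field(default_factory=list)

    def standards(self) -> list[Well]:
        return [w for w in self.wells if w.role == "standard"]


def read_plates(path: str | Path) -> list[Plate]:
    """Read the long-format plate CSV into plates, preserving file order.

    Raises :class:`FormatError` for a missing column or unparsable numeric
    field (the message names the column / row number) and
    :class:`DuplicateWellError` when a (plate_id, well) address repeats.
    """
    path = Path(path)
    plates: dict[str, Plate] = {}
    seen: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in PLATE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            pid = row["plate_id"]
            key = (pid, row["well"])
            if key in seen:
                raise DuplicateWellError(f"duplicate well {row['well']} on plate {pid} (row {lineno})")
            seen.add(key)
            conc_txt = (row["conc"] or "").strip()
            try:
                conc = float(conc_txt) if conc_txt else None
            except ValueError:
                raise FormatError(f"unparsable conc {conc_txt!r} at row {lineno}") from None
            try:
                od = float(row["od"])
            except (TypeError, ValueError):
                raise FormatError(f"unparsable od {row['od']!r} at row {lineno}") from None
            try:
                well = Well(well=row["well"], role=row["role"], sample_id=row["sample_id"], od=od, conc=conc)
            except DataError as exc:
                raise FormatError(f"{exc} (row {lineno})") from None
            plate = plates.get(pid)
            if plate is None:
                plate = Plate(plate_id=pid, batch=row["batch"], run_date=row["run_date"],
                              operator=row["operator"])
                plates[pid] = plate
            elif plate.batch != row["batch"]:
                raise FormatError(f"plate {pid} has inconsistent batch labels (row {lineno})")
            plate.wells.append(well)
    return list(plates.values())


def write_plates(plates: Iterable[Plate], path: str | Path) -> None:
    """Write plates in the same dialect ``read_plates`` consumes (lossless)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PLATE_COLUMNS)
        for plate in plates:
            for well in plate.wells:
                w.writerow([
                    plate.plate_id, plate.batch, plate.run_date, plate.operator,
                    well.well, well.role, well.sample_id,
                    "" if well.conc is None else repr(well.conc), repr(well.od),
                ])


def group_by_batch(plates: Iterable[Plate]) -> dict[str, list[Plate]]:
    """Group plates by their batch label, preserving first-seen label order."""
    out: dict[str, list[Plate]] = {}
    for p in plates:
        out.setdefault(p.batch, []).append(p)
    return out


def standard_points(plates: Iterable[Plate]):
    """Collect (log-conc, od) pairs and well labels from all standard wells.

    Blank wells and zero-concentration standards never reach this point
    (zero concentration is rejected at the :class:`Well` level); returns
    ``(x, od, labels)`` with ``x`` in natural-log pg/mL.
    """
    xs: list[float] = []
    ods: list[float] = []
    labels: list[str] = []
    for p in plates:
        for w in p.standards():
            xs.append(math.log(w.conc))
            ods.append(w.od)
            labels.append(f"{p.plate_id}:{w.well}")
    if not xs:
        raise DataError("no standard wells found")
    return np.array(xs), np.array(ods), labels


def write_results(results: Sequence, path: str | Path) -> None:
    """Write quantification results as CSV.

    Columns are fixed (`RESULT_COLUMNS`); concentrations are in pg/mL, floats
    rendered with full precision (>= 6 significant digits), and flags joined
    with semicolons.
    """

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for r in results:
            w.writerow([
                r.plate_id, r.batch, r.sample_id, r.n_wells,
                fmt(r.mean_od), fmt(r.cv_pct), fmt(r.raw_conc), fmt(r.adjusted_conc),
                fmt(r.S), ";".join(sorted(r.flags)),
            ])


def read_results(path: str | Path):
    """Read a results CSV back into a list of row dicts (strings parsed)."""
    rows = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in RESULT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        for row in reader:
            parsed: dict = dict(row)
            parsed["n_wells"] = int(row["n_wells"])
            for col in ("mean_od", "cv_pct", "raw_conc", "adjusted_conc", "S"):
                parsed[col] = float(row[col]) if row[col] else None
            parsed["flags"] = set(t for t in row["flags"].split(";") if t)
            rows.append(parsed)
    return rows
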