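"""Longitudinal quality-control monitoring for shift-corrected ELISAs.

Three layers of QC are supported:

* inter-assay variability of laboratory controls (percent CV of a control's
  OD and of its raw vs shift-adjusted concentration across plates),
* per-lot summaries of the per-plate shift factors (mean, min, max, CV) in
  the style of a lot-comparison table, and
* outlier flagging of individual standard curves by a leave-one-out z-score
  on their shift factors — a reproducible stand-in for the informal
  "tag for review" judgement used at the bench.

Rounding conventions are pinned to bench reporting practice: CVs to integer
percent (half-up), fold ratios to one decimal, shift factors to four decimals
in the emitted report.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedCVError, UndefinedFoldError
from .plate_io import Plate
from .quantify import QuantResult
from .shift_model import BatchShift

__all__ = [
    "ControlSeries",
    "QCReport",
    "cv_percent",
    "fold_vs_group_mean",
    "flag_outlier_curves",
    "control_series_from",
    "build_report",
    "write_qc_report",
]


def _round_half_up(v: float, decimals: int = 0) -> float:
    scale = 10 ** decimals
    return math.floor(v * scale + 0.5) / scale


def cv_percent(mean: float, sd: float) -> int:
    """Coefficient of variation, 100·sd/mean, rounded half-up to integer %."""
    if not (mean > 0):
        raise UndefinedCVError(f"CV undefined for mean {mean}")
    if sd < 0:
        raise DataError("sd must be non-negative")
    return int(_round_half_up(100.0 * sd / mean))


def fold_vs_group_mean(s: float, others: Sequence[float]) -> float:
    """Ratio of one shift factor to the mean of its peers, 1-decimal.

    Raises :class:`UndefinedFoldError` (carrying the absolute difference)
    when the group mean is zero.
    """
    others = np.asarray(list(others), dtype=float)
    if others.size == 0:
        raise DataError("empty comparison group")
    m = float(others.mean())
    if m == 0:
        raise UndefinedFoldError(f"group mean is zero; absolute difference {abs(s)}", abs(s))
    return _round_half_up(s / m, 1)


def flag_outlier_curves(shifts: Sequence[BatchShift], k: float = 3.0) -> list[BatchShift]:
    """Leave-one-out outlier flagging of per-plate shift factors within a lot.

    Plate *i* is flagged when ``|S_i - mean(S_-i)| > k * sd(S_-i)`` with the
    sample standard deviation over the remaining plates.  Requires >= 3
    curves.  All-equal shifts flag nothing.
    """
    shifts = list(shifts)
    if len(shifts) < 3:
        raise DataError("outlier flagging needs at least 3 curves in the lot")
    values = np.array([s.S for s in shifts], dtype=float)
    flagged = []
    for i, s in enumerate(shifts):
        rest = np.delete(values, i)
        sd = float(rest.std(ddof=1))
        if sd == 0:
            continue
        if abs(s.S - float(rest.mean())) > k * sd:
            flagged.append(s)
    return flagged


@dataclass
class ControlSeries:
    """One control sample's longitudinal record across plates, date-sorted.

    ``entries`` has columns run_date, plate_id, batch, mean_od, raw_conc,
    adjusted_conc.
    """

    control_id: str
    entries: pd.DataFrame

    def __post_init__(self):
        self.entries = self.entries.sort_values("run_date", kind="stable").reset_index(drop=True)


def control_series_from(plates: Iterable[Plate], results: Sequence[QuantResult],
                        role: str = "control") -> list[ControlSeries]:
    """Assemble per-control longitudinal series from plates plus results.

    The plate data supply the run dates and which sample_ids are controls;
    the quantification results supply ODs and concentrations.
    """
    dates = {p.plate_id: p.run_date for p in plates}
    control_ids: list[str] = []
    for p in plates:
        for w in p.wells:
            if w.role == role and w.sample_id not in control_ids:
                control_ids.append(w.sample_id)
    series = []
    for cid in control_ids:
        rows = [
            {"run_date": dates.get(r.plate_id, ""), "plate_id": r.plate_id, "batch": r.batch,
             "mean_od": r.mean_od, "raw_conc": r.raw_conc, "adjusted_conc": r.adjusted_conc}
            for r in results if r.sample_id == cid
        ]
        if rows:
            series.append(ControlSeries(control_id=cid, entries=pd.DataFrame(rows)))
    return series


@dataclass
class QCReport:
    """Per-lot shift summaries, per-control summaries and flagged curves.

    ``lots``: lot, mean_S, min_S, max_S, n, cv_S_pct.
    ``controls``: control_id, n, mean_od, sd_od, cv_od_pct, mean_raw_conc,
    cv_raw_pct, mean_adj_conc, cv_adj_pct.
    ``flagged``: lot, batch, S, reason.
    """

    lots: pd.DataFrame
    controls: pd.DataFrame
    flagged: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_report(shifts_by_lot: Mapping[str, Sequence[BatchShift]],
                 controls: Sequence[ControlSeries],
                 k: float = 3.0) -> QCReport:
    """Summarize per-plate shift factors by lot and control series over time.

    ``shifts_by_lot`` maps a lot label to the per-plate (or per-batch) shift
    factors belonging to it.  Lots with >= 3 curves are screened for outliers
    with :func:`flag_outlier_curves`.
    """
    lot_rows = []
    flag_rows = []
    for lot, shifts in shifts_by_lot.items():
        values = np.array([s.S for s in shifts], dtype=float)
        mean_s = float(values.mean())
        row = {
            "lot": lot,
            "mean_S": round(mean_s, 4),
            "min_S": round(float(values.min()), 4),
            "max_S": round(float(values.max()), 4),
            "n": int(values.size),
        }
        if values.size > 1 and mean_s != 0:
            row["cv_S_pct"] = cv_percent(abs(mean_s), float(values.std(ddof=1)))
        else:
            row["cv_S_pct"] = None
        lot_rows.append(row)
        if len(shifts) >= 3:
            for s in flag_outlier_curves(shifts, k=k):
                rest = [o.S for o in shifts if o is not s]
                try:
                    fold = fold_vs_group_mean(s.S, rest)
                    reason = f"S {round(s.S, 4)} is {fold}-fold the lot mean"
                except UndefinedFoldError:
                    reason = f"S {round(s.S, 4)} deviates from a zero lot mean"
                flag_rows.append({"lot": lot, "batch": s.batch, "S": round(s.S, 4),
                                  "reason": reason})

    control_rows = []
    for series in controls:
        e = series.entries
        od = e["mean_od"].to_numpy(dtype=float)
        raw = e["raw_conc"].to_numpy(dtype=float)
        adj = e["adjusted_conc"].to_numpy(dtype=float)
        row = {"control_id": series.control_id, "n": int(len(e)),
               "mean_od": float(od.mean()), "sd_od": float(od.std(ddof=1)) if len(od) > 1 else 0.0}
        row["cv_od_pct"] = cv_percent(row["mean_od"], row["sd_od"]) if row["mean_od"] > 0 else None
        for name, arr in (("raw", raw), ("adj", adj)):
            ok = np.isfinite(arr)
            if ok.sum() == 0:
                row[f"mean_{name}_conc"] = None
                row[f"cv_{name}_pct"] = None
                continue
            vals = arr[ok]
            m = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            row[f"mean_{name}_conc"] = m
            row[f"cv_{name}_pct"] = cv_percent(m, sd) if m > 0 else None
        control_rows.append(row)

    return QCReport(
        lots=pd.DataFrame(lot_rows),
        controls=pd.DataFrame(control_rows),
        flagged=pd.DataFrame(flag_rows, columns=["lot", "batch", "S", "reason"]),
    )


def write_qc_report(report: QCReport, path: str | Path) -> None:
    """Emit the QC report as one CSV with a leading ``section`` column."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["section", "label", "mean_S", "min_S", "max_S", "n", "cv_S_pct",
                    "mean_od", "sd_od", "cv_od_pct", "mean_raw_conc", "cv_raw_pct",
                    "mean_adj_conc", "cv_adj_pct", "detail"])

        def fmt(v):
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                return ""
            return repr(v) if isinstance(v, float) else str(v)

        for _, r in report.lots.iterrows():
            w.writerow(["lot", r["lot"], fmt(r["mean_S"]), fmt(r["min_S"]), fmt(r["max_S"]),
                        fmt(r["n"]), fmt(r["cv_S_pct"]), "", "", "", "", "", "", "", ""])
        for _, r in report.controls.iterrows():
            w.writerow(["control", r["control_id"], "", "", "", fmt(r["n"]), "",
                        fmt(r["mean_od"]), fmt(r["sd_od"]), fmt(r["cv_od_pct"]),
                        fmt(r["mean_raw_conc"]), fmt(r["cv_raw_pct"]),
                        fmt(r["mean_adj_conc"]), fmt(r["cv_adj_pct"]), ""])
        for _, r in report.flagged.iterrows():
            w.writerow(["flagged", r["batch"], fmt(r["S"]), "", "", "", "",
                        "", "", "", "", "", "", "", f"lot {r['lot']}: {r['reason']}"])
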