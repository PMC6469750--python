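"""Inverse prediction of sample concentrations with batch-shift adjustment.

Unknown and control ODs are first read off the batch's own standard curve
(the reference curve with midpoint ``xmid + S``), giving the *raw*
log-concentration; the batch's shift factor is then subtracted:

    adjusted_log_conc = raw_log_conc - S

which places every batch's results on the reference platform.  Reported
concentrations are ``exp(x)`` in pg/mL; log values are carried internally.

ODs outside the open asymptote interval cannot be inverted and are censored
with a ``below_range``/``above_range`` flag.  Results outside the standard
range (LLOQ/ULOQ, the lowest/highest standard on the plate) keep their value
but are flagged ``below_lloq``/``above_uloq``.  Replicate CVs above the
acceptance gate (default 15%) are flagged ``high_cv`` but still reported —
censoring is a laboratory decision, not an automated one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, RangeError, UndefinedCVError
from .logistic_core import inverse_logistic
from .plate_io import Plate, Well
from .shift_model import ShiftModel

__all__ = [
    "QuantResult",
    "aggregate_replicates",
    "estimate_concentration",
    "apply_range_gates",
    "quantify_plates",
    "CV_GATE_PCT",
]

CV_GATE_PCT = 15.0  # replicate-well acceptance gate


@dataclass(frozen=True)
class QuantResult:
    """Aggregated quantification of one sample on one plate."""

    plate_id: str
    batch: str
    sample_id: str
    n_wells: int
    mean_od: float
    cv_pct: float
    S: float
    raw_log_conc: float | None = None
    adjusted_log_conc: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def raw_conc(self) -> float | None:
        """Raw concentration in pg/mL (batch's own curve)."""
        return None if self.raw_log_conc is None else math.exp(self.raw_log_conc)

    @property
    def adjusted_conc(self) -> float | None:
        """Shift-adjusted concentration in pg/mL (reference platform)."""
        return None if self.adjusted_log_conc is None else math.exp(self.adjusted_log_conc)


def aggregate_replicates(wells: Sequence[Well] | Sequence[float]) -> tuple[float, float]:
    """Mean OD and percent CV (sample sd, n-1) of replicate wells.

    A single well has CV 0 by convention.  Raises
    :class:`UndefinedCVError` when the mean OD is zero.
    """
    ods = np.array([w.od if isinstance(w, Well) else float(w) for w in wells], dtype=float)
    if ods.size == 0:
        raise DataError("no replicate wells to aggregate")
    mean = float(ods.mean())
    if mean == 0:
        raise UndefinedCVError("mean OD is zero; CV undefined")
    cv = 0.0 if ods.size == 1 else float(100.0 * ods.std(ddof=1) / mean)
    return mean, cv


def estimate_concentration(mean_od: float, model: ShiftModel, batch: str) -> dict:
    """Invert one aggregated OD on the batch's shifted curve and adjust.

    Returns a dict with ``raw_log_conc``, ``adjusted_log_conc``, ``S`` and
    ``flags``; on an out-of-asymptote OD the concentrations are ``None`` and
    the corresponding range flag is set.
    """
    s = model.S(batch)  # raises UnknownBatchError for a foreign label
    shifted = model.batch_params(batch)
    try:
        raw = inverse_logistic(mean_od, shifted)
    except RangeError as exc:
        return {"raw_log_conc": None, "adjusted_log_conc": None, "S": s,
                "flags": frozenset({exc.tag})}
    return {"raw_log_conc": raw, "adjusted_log_conc": raw - s, "S": s, "flags": frozenset()}


def apply_range_gates(result: QuantResult, standards_range: tuple[float, float]) -> QuantResult:
    """Flag adjusted concentrations outside the standard range (log space).

    ``standards_range`` is ``(x_lo, x_hi)`` — natural-log LLOQ/ULOQ taken from
    the batch's standard levels.  Values are retained (flag, don't censor);
    asymptote violations were already censored upstream.
    """
    if result.adjusted_log_conc is None:
        return result
    x_lo, x_hi = standards_range
    flags = set(result.flags)
    if result.adjusted_log_conc < x_lo:
        flags.add("below_lloq")
    elif result.adjusted_log_conc > x_hi:
        flags.add("above_uloq")
    return replace(result, flags=frozenset(flags))


def _plate_standard_range(plate: Plate) -> tuple[float, float] | None:
    concs = [w.conc for w in plate.standards()]
    if not concs:
        return None
    return math.log(min(concs)), math.log(max(concs))


def quantify_plates(plates: Iterable[Plate], model: ShiftModel,
                    roles: tuple[str, ...] = ("control", "unknown"),
                    cv_gate_pct: float = CV_GATE_PCT) -> list[QuantResult]:
    """Quantify every replicate group of the given roles on every plate.

    Wells are grouped by ``sample_id`` within a plate; each group yields one
    :class:`QuantResult` with the mean OD inverted on the plate's batch curve,
    the shift adjustment applied, and CV / range flags set.
    """
    out: list[QuantResult] = []
    for plate in plates:
        groups: dict[str, list[Well]] = {}
        for w in plate.wells:
            if w.role in roles:
                groups.setdefault(w.sample_id, []).append(w)
        srange = _plate_standard_range(plate)
        for sample_id, wells in groups.items():
            mean_od, cv = aggregate_replicates(wells)
            est = estimate_concentration(mean_od, model, plate.batch)
            flags = set(est["flags"])
            if cv > cv_gate_pct:
                flags.add("high_cv")
            res = QuantResult(
                plate_id=plate.plate_id, batch=plate.batch, sample_id=sample_id,
                n_wells=len(wells), mean_od=mean_od, cv_pct=cv, S=est["S"],
                raw_log_conc=est["raw_log_conc"], adjusted_log_conc=est["adjusted_log_conc"],
                flags=frozenset(flags),
            )
            if srange is not None:
                res = apply_range_gates(res, srange)
            out.append(res)
    return out
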