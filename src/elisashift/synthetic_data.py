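"""Simulated ELISA plates with known curves, shift factors and noise.

The generator realizes the study design the shift model targets: every batch
(kit lot) shares one true logistic curve, but its standards' *real* contents
differ from their nominal labels by a log-fold ``S``, so a standard labelled
``c`` pg/mL actually behaves like ``c * exp(-S)``.  Standard wells therefore
read ``od = f(x_label; xmid + S_batch) + eps`` with additive homoscedastic
Gaussian noise ``eps ~ N(0, od_noise_sd**2)``.

Control and unknown samples are real specimens, not kit standards: their
chemistry does not depend on the lot, so their wells are generated from the
*reference* curve at the sample's true log concentration (plus noise).  This
is what makes their raw read-outs drift across shifted batches while the
adjusted ones remain stable — the phenomenon the correction exists for.

Default parameter values follow a published reference curve for a plasma
biomarker ELISA (lower asymptote -0.01 OD, upper 3.20 OD, midpoint 1300
pg/mL, inverse slope 1/1.30, symmetric), 8 two-fold standard dilutions in
triplicate, and OD noise sd 0.02.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .logistic_core import CurveParams, logistic
from .plate_io import Plate, Well, group_by_batch
from .shift_model import fit_joint, fit_shift_model

__all__ = ["SimSpec", "default_true_params", "simulate", "recovery_experiment", "load_simspec"]

_ROWS = "ABCDEFGH"


def default_true_params() -> CurveParams:
    """Reference-scale true curve: OD -0.01..3.20, midpoint 1300 pg/mL."""
    return CurveParams(a=-0.01, d=3.20, xmid=math.log(1300.0), scal=1 / 1.30, g=1.0)


def _default_levels() -> tuple[float, ...]:
    # 8 two-fold serial dilutions from 8000 pg/mL, highest first
    return tuple(8000.0 / 2 ** i for i in range(8))


@dataclass(frozen=True)
class SimSpec:
    """Study-condition description for the simulator.

    ``batch_shifts`` maps batch labels to their true shift factors; the first
    batch with ``S == 0`` is the reference.  ``plates_per_batch`` is a single
    count or a per-batch mapping.  ``controls`` lists ``(sample_id,
    true_conc_pg_ml)`` pairs included in triplicate on every plate.
    """

    true_params: CurveParams = field(default_factory=default_true_params)
    batch_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"lot1": 0.0, "lot2": 0.07, "lot3": 0.55,
                                 "lot4": 0.65, "lot5": 0.70})
    standard_levels: Sequence[float] = field(default_factory=_default_levels)
    n_replicates: int = 3
    plates_per_batch: int | Mapping[str, int] = 4
    od_noise_sd: float = 0.02
    controls: Sequence[tuple[str, float]] = (("BMC", 500.0),)
    seed: int = 20190417

    def __post_init__(self):
        levels = list(self.standard_levels)
        if not levels or any(not (c > 0) for c in levels):
            raise ValidationError("standard levels must be strictly positive")
        if any(b >= a_ for a_, b in zip(levels, levels[1:])):
            raise ValidationError("standard levels must be strictly decreasing")
        if not self.batch_shifts:
            raise ValidationError("at least one batch required")
        if self.reference_batch is None:
            raise ValidationError("one batch must have true S = 0 (the reference)")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.od_noise_sd < 0:
            raise ValidationError("od_noise_sd must be >= 0")
        for label in self.batch_shifts:
            if self._plates_for(label) < 1:
                raise ValidationError(f"batch {label!r} needs at least one plate")

    @property
    def reference_batch(self) -> str | None:
        for label, s in self.batch_shifts.items():
            if s == 0.0:
                return label
        return None

    def _plates_for(self, batch: str) -> int:
        if isinstance(self.plates_per_batch, Mapping):
            return int(self.plates_per_batch.get(batch, 0))
        return int(self.plates_per_batch)


def simulate(spec: SimSpec, seed: int | None = None) -> list[Plate]:
    """Generate plates for every batch of the spec; reproducible under a seed.

    Standards occupy rows A-H of the first ``n_replicates`` columns; each
    control gets triplicate wells in the following columns.  Wells carry the
    NOMINAL standard concentrations, so a nonzero shift models mislabelled
    standards.  Run dates advance one day per plate from 2017-10-01.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    p = spec.true_params
    levels = list(spec.standard_levels)
    if len(levels) > len(_ROWS):
        raise ValidationError(f"at most {len(_ROWS)} standard levels fit one plate column layout")
    start = datetime.date(2017, 10, 1)
    plates: list[Plate] = []
    plate_no = 0
    for batch, s_true in spec.batch_shifts.items():
        shifted = p.shifted(s_true)
        for _ in range(spec._plates_for(batch)):
            plate_no += 1
            plate = Plate(plate_id=f"P{plate_no:03d}", batch=batch,
                          run_date=(start + datetime.timedelta(days=plate_no - 1)).isoformat(),
                          operator="sim")
            for j, conc in enumerate(levels):
                x = math.log(conc)
                for k in range(spec.n_replicates):
                    od = float(logistic(x, shifted)) + float(rng.normal(0.0, spec.od_noise_sd))
                    plate.wells.append(Well(well=f"{_ROWS[j]}{k + 1}", role="standard",
                                            sample_id=f"S{j + 1}", od=od, conc=conc))
            # controls respond through the true (reference) chemistry
            for ci, (cid, true_conc) in enumerate(spec.controls):
                x = math.log(true_conc)
                col = spec.n_replicates + 1 + ci
                for k in range(3):
                    od = float(logistic(x, p)) + float(rng.normal(0.0, spec.od_noise_sd))
                    plate.wells.append(Well(well=f"{_ROWS[k]}{col}", role="control",
                                            sample_id=cid, od=od))
            plates.append(plate)
    return plates


def recovery_experiment(spec: SimSpec,
                        mode: Literal["fixed_reference", "joint"] = "fixed_reference",
                        model: Literal["4pl", "5pl"] = "4pl",
                        seed: int | None = None) -> pd.DataFrame:
    """Simulate, fit, and pair estimated shift factors with their truth.

    Returns a DataFrame with columns batch, true_S, est_S, se_S, n_plates.
    """
    if len(spec.batch_shifts) < 2:
        raise ValidationError("recovery experiment needs at least 2 batches")
    plates = simulate(spec, seed=seed)
    ref = spec.reference_batch
    if mode == "joint":
        fitted = fit_joint(group_by_batch(plates), ref, model=model)
    else:
        fitted = fit_shift_model(plates, ref, model=model, mode="fixed_reference")
    rows = []
    for shift in fitted.shifts:
        rows.append({"batch": shift.batch, "true_S": float(spec.batch_shifts[shift.batch]),
                     "est_S": shift.S, "se_S": shift.se_S, "n_plates": shift.n_curves})
    return pd.DataFrame(rows)


def load_simspec(path: str | Path) -> SimSpec:
    """Read a SimSpec from a small YAML config file.

    Recognized keys mirror the dataclass fields; ``true_params`` is a mapping
    with a, d, xmid, scal, g (or ``midpoint_conc`` in pg/mL instead of xmid).
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    kwargs: dict = {}
    if "true_params" in raw:
        tp = dict(raw["true_params"])
        if "midpoint_conc" in tp:
            tp["xmid"] = math.log(float(tp.pop("midpoint_conc")))
        kwargs["true_params"] = CurveParams(**{k: float(v) for k, v in tp.items()})
    for key in ("batch_shifts", "n_replicates", "plates_per_batch", "od_noise_sd", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "standard_levels" in raw:
        kwargs["standard_levels"] = tuple(float(v) for v in raw["standard_levels"])
    if "controls" in raw:
        kwargs["controls"] = tuple((str(cid), float(c)) for cid, c in raw["controls"])
    unknown = set(raw) - {"true_params", "batch_shifts", "standard_levels", "n_replicates",
                          "plates_per_batch", "od_noise_sd", "controls", "seed"}
    if unknown:
        raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
    try:
        return SimSpec(**kwargs)
    except TypeError as exc:
        raise ValidationError(str(exc)) from None
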