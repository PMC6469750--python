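"""Reference-curve and shift-factor estimation for ELISA batch effects.

Lot-to-lot (or plate-to-plate) differences in standard curves are modelled as
a fixed batch effect: every batch shares the logistic shape parameters
``(a, d, scal, g)`` with the reference, but its effective midpoint is
``xmid + S_i``.  The shift factor ``S_i`` is the natural-log fold difference
between a batch's nominal standard concentrations and the reference batch's
(assumed accurate) concentrations: relabelling a batch's standards by a factor
``N`` moves its ``S`` by exactly ``ln N``.  The reference batch has ``S = 0``
by construction (identifiability).

Two estimation modes are provided:

* ``fixed_reference`` (default, the operational workflow): fit the reference
  curve once by pooled least squares over all designated reference plates,
  then estimate each batch's ``S`` by a one-dimensional least-squares fit with
  every other parameter frozen at the reference values.
* ``joint``: simultaneous least squares over the shared curve parameters and
  all non-reference shift factors.

Standard errors for ``S`` come from the usual linearized nonlinear-LS
curvature at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DataError, FormatError, UnknownBatchError
from .logistic_core import CurveParams, FitResult, fit_curve, logistic
from .plate_io import Plate, group_by_batch, standard_points

__all__ = [
    "BatchShift",
    "ShiftModel",
    "fit_reference",
    "estimate_shift",
    "fit_joint",
    "fit_shift_model",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BatchShift:
    """A batch label with its estimated shift factor.

    ``S`` is a natural-log fold; the batch's effective curve midpoint is
    ``reference xmid + S``.  ``se_S`` is the linearized standard error
    (``None`` for the pinned reference batch).
    """

    batch: str
    S: float
    n_curves: int
    se_S: float | None = None


@dataclass
class ShiftModel:
    """A fitted reference curve plus one shift factor per batch."""

    reference: CurveParams
    shifts: list[BatchShift]
    model: Literal["4pl", "5pl"]
    reference_batch: str
    rss: float
    mode: Literal["joint", "fixed_reference"] = "fixed_reference"

    def __post_init__(self):
        labels = [s.batch for s in self.shifts]
        if len(labels) != len(set(labels)):
            raise DataError("duplicate batch labels in shift model")
        ref = self.shift_for(self.reference_batch)
        if ref.S != 0.0:
            raise DataError("reference batch must have S = 0")

    def shift_for(self, batch: str) -> BatchShift:
        for s in self.shifts:
            if s.batch == batch:
                return s
        raise UnknownBatchError(batch)

    def S(self, batch: str) -> float:
        return self.shift_for(batch).S

    def batch_params(self, batch: str) -> CurveParams:
        """The batch's standard curve: reference with midpoint ``xmid + S``."""
        return self.reference.shifted(self.S(batch))


def _check_levels(plates: Sequence[Plate], minimum: int, what: str) -> None:
    levels = {w.conc for p in plates for w in p.standards()}
    if len(levels) < minimum:
        raise DataError(f"{what}: needs >= {minimum} distinct standard levels, got {len(levels)}")


def fit_reference(plates: Sequence[Plate], model: Literal["4pl", "5pl"] = "4pl") -> FitResult:
    """Pooled least-squares fit of one shared curve over all standard wells.

    All wells of all supplied plates enter a single fit (no per-plate
    parameters); replicate wells are used individually, not averaged.
    """
    plates = list(plates)
    if not plates:
        raise DataError("no plates supplied for the reference fit")
    _check_levels(plates, 4 if model == "4pl" else 5, "reference fit")
    x, od, labels = standard_points(plates)
    return fit_curve((x, od), model=model, labels=labels)


def estimate_shift(plates: Sequence[Plate] | Plate, reference: CurveParams,
                   batch: str | None = None) -> BatchShift:
    """Estimate one batch's shift factor against a fitted reference curve.

    One-dimensional least squares in ``S`` only, all other parameters frozen:
    minimizes ``sum(od - f(x; xmid + S))**2`` over the batch's standard wells.
    A coarse grid over S in [-6, 6] seeds a trust-region refinement, so far
    shifts do not strand the fit in a flat asymptote region.  ``se_S`` is
    ``sqrt(rss/(n-1) / sum(df/dS)^2)`` at the optimum.
    """
    if isinstance(plates, Plate):
        plates = [plates]
    plates = list(plates)
    _check_levels(plates, 4, f"batch {batch or plates[0].batch!r}")
    label = batch if batch is not None else plates[0].batch
    x, od, _ = standard_points(plates)

    lo, hi = reference.od_range
    if od.max() <= lo or od.min() >= hi:
        raise DataError(
            f"batch {label!r}: all ODs outside the reference asymptote interval; shift not estimable"
        )

    def resid(s):
        return logistic(x, reference.shifted(float(s[0]))) - od

    grid = np.linspace(-6.0, 6.0, 61)
    costs = [float(np.sum(resid([s]) ** 2)) for s in grid]
    s0 = float(grid[int(np.argmin(costs))])
    sol = least_squares(resid, [s0], method="trf", ftol=1e-12, xtol=1e-13, gtol=1e-13)
    if not sol.success:
        raise ConvergenceError(f"shift estimation failed for batch {label!r}")
    s_hat = float(sol.x[0])
    rss = float(np.sum(sol.fun ** 2))
    # curvature-based SE: J = d(model)/dS, sigma^2 = rss/(n - 1)
    jtj = float(np.sum(sol.jac ** 2))
    n = x.size
    se = math.sqrt(rss / max(n - 1, 1) / jtj) if jtj > 0 else None
    return BatchShift(batch=label, S=s_hat, n_curves=len(plates), se_S=se)


def fit_joint(batches: Mapping[str, Sequence[Plate]], reference_batch: str,
              model: Literal["4pl", "5pl"] = "4pl") -> ShiftModel:
    """Simultaneous fit of shared curve parameters and all shift factors.

    Parameters are ``(a, d, xmid, scal[, log g])`` plus one ``S_i`` per
    non-reference batch; the reference batch's shift is pinned at 0.
    Started from the fixed-reference solution.
    """
    if reference_batch not in batches:
        raise UnknownBatchError(reference_batch)
    if len(batches) < 2:
        raise DataError("joint fit needs at least 2 batches")
    for label, plates in batches.items():
        _check_levels(list(plates), 4 if model == "4pl" else 5, f"batch {label!r}")

    ref_fit = fit_reference(list(batches[reference_batch]), model=model)
    others = [b for b in batches if b != reference_batch]
    s_start = [estimate_shift(list(batches[b]), ref_fit.params, batch=b).S for b in others]

    data = {b: standard_points(list(batches[b]))[:2] for b in batches}
    p = ref_fit.params
    theta0 = [p.a, p.d, p.xmid, p.scal]
    n_shape = 4
    if model == "5pl":
        theta0.append(math.log(p.g))
        n_shape = 5
    theta0.extend(s_start)
    theta0 = np.array(theta0)
    lower = np.full(theta0.shape, -np.inf)
    upper = np.full(theta0.shape, np.inf)
    if model == "5pl":
        lower[4], upper[4] = math.log(0.1), math.log(10.0)

    def unpack(theta):
        g = math.exp(theta[4]) if model == "5pl" else 1.0
        base = CurveParams(a=theta[0], d=theta[1], xmid=theta[2], scal=theta[3], g=g)
        s_map = {reference_batch: 0.0}
        s_map.update({b: float(v) for b, v in zip(others, theta[n_shape:])})
        return base, s_map

    def resid(theta):
        base, s_map = unpack(theta)
        parts = [logistic(x, base.shifted(s_map[b])) - od for b, (x, od) in data.items()]
        return np.concatenate(parts)

    sol = least_squares(resid, theta0, bounds=(lower, upper), method="trf",
                        ftol=1e-12, xtol=1e-13, gtol=1e-13, max_nfev=2000)
    if not sol.success:
        raise ConvergenceError("joint shift-model fit failed to converge")
    base, s_map = unpack(sol.x)
    rss = float(np.sum(sol.fun ** 2))

    # per-batch SE from the joint covariance (linearized)
    n_obs = sol.fun.size
    dof = max(n_obs - sol.x.size, 1)
    sigma2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        ses = {b: math.sqrt(max(cov[n_shape + i, n_shape + i], 0.0)) for i, b in enumerate(others)}
    except np.linalg.LinAlgError:
        ses = {b: None for b in others}

    shifts = []
    for b, plates in batches.items():
        if b == reference_batch:
            shifts.append(BatchShift(batch=b, S=0.0, n_curves=len(plates), se_S=None))
        else:
            shifts.append(BatchShift(batch=b, S=s_map[b], n_curves=len(plates), se_S=ses.get(b)))
    return ShiftModel(reference=base, shifts=shifts, model=model,
                      reference_batch=reference_batch, rss=rss, mode="joint")


def fit_shift_model(plates: Iterable[Plate], reference_batch: str,
                    model: Literal["4pl", "5pl"] = "4pl",
                    mode: Literal["fixed_reference", "joint"] = "fixed_reference") -> ShiftModel:
    """Fit the full model from a flat plate collection (convenience wrapper)."""
    batches = group_by_batch(plates)
    if reference_batch not in batches:
        raise UnknownBatchError(reference_batch)
    if mode == "joint":
        return fit_joint(batches, reference_batch, model=model)
    ref_fit = fit_reference(batches[reference_batch], model=model)
    shifts = [BatchShift(batch=reference_batch, S=0.0,
                         n_curves=len(batches[reference_batch]), se_S=None)]
    rss = ref_fit.rss
    for label, group in batches.items():
        if label == reference_batch:
            continue
        shifts.append(estimate_shift(group, ref_fit.params, batch=label))
    # keep first-seen batch order
    order = {b: i for i, b in enumerate(batches)}
    shifts.sort(key=lambda s: order[s.batch])
    return ShiftModel(reference=ref_fit.params, shifts=shifts, model=model,
                      reference_batch=reference_batch, rss=rss, mode="fixed_reference")


# ---------------------------------------------------------------------------
# persistence: flat key-value text, bit-exact float round-trip via repr()

_MODEL_HEADER = "# elisashift model v1"


def save_model(m: ShiftModel, path: str | Path) -> None:
    lines = [
        _MODEL_HEADER,
        f"model = {m.model}",
        f"mode = {m.mode}",
        f"reference_batch = {m.reference_batch}",
        f"a = {m.reference.a!r}",
        f"d = {m.reference.d!r}",
        f"xmid = {m.reference.xmid!r}",
        f"scal = {m.reference.scal!r}",
        f"g = {m.reference.g!r}",
        f"rss = {m.rss!r}",
    ]
    for s in m.shifts:
        se = "NA" if s.se_S is None else repr(s.se_S)
        lines.append(f"batch\t{s.batch}\t{s.S!r}\t{se}\t{s.n_curves}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> ShiftModel:
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or text[0].strip() != _MODEL_HEADER:
        raise FormatError(f"{path}: not an elisashift model file")
    kv: dict[str, str] = {}
    shifts: list[BatchShift] = []
    for line in text[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("batch\t"):
            try:
                _, batch, s, se, n = line.split("\t")
            except ValueError:
                raise FormatError(f"malformed batch line: {line!r}") from None
            shifts.append(BatchShift(batch=batch, S=float(s), n_curves=int(n),
                                     se_S=None if se == "NA" else float(se)))
        elif " = " in line:
            k, v = line.split(" = ", 1)
            kv[k.strip()] = v.strip()
        else:
            raise FormatError(f"malformed model line: {line!r}")
    try:
        reference = CurveParams(a=float(kv["a"]), d=float(kv["d"]), xmid=float(kv["xmid"]),
                                scal=float(kv["scal"]), g=float(kv["g"]))
        return ShiftModel(reference=reference, shifts=shifts, model=kv["model"],
                          reference_batch=kv["reference_batch"], rss=float(kv["rss"]),
                          mode=kv["mode"])
    except KeyError as exc:
        raise FormatError(f"model file missing key {exc}") from None
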