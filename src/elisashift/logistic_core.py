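"""Four- and five-parameter logistic (4PL/5PL) calibration curves.

The 5PL relates log analyte concentration ``x`` (natural log of pg/mL) to the
assay response ``Y`` (optical density):

    Y = a + (d - a) / (1 + exp((xmid - x) / scal))**g

``a`` and ``d`` are the lower and upper response asymptotes, ``xmid`` the
log-concentration at the inflexion point, ``scal`` the inverse slope there
(positive for curves that increase with concentration) and ``g`` the asymmetry
factor.  With ``g = 1`` the curve is the symmetric 4PL.  An equivalent
"exponential" (non-log) parameterization uses the plain concentration
``x' = exp(x)`` with midpoint concentration ``C = exp(xmid)`` and slope
``B = -1/scal``; plate-reader software commonly reports that form.

This module evaluates, inverts and least-squares-fits these curves on
individual replicate wells.  All logs are natural logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DataError, DegenerateDataError, RangeError

__all__ = [
    "CurveParams",
    "ExpFormParams",
    "FitResult",
    "logistic",
    "inverse_logistic",
    "initial_params",
    "fit_curve",
    "to_exp_form",
    "from_exp_form",
]

# Multi-start restarts use a fixed seed so fits are reproducible run to run.
_MULTISTART_SEED = 20190417
_G_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class CurveParams:
    """Logistic curve parameters in the log-concentration form.

    Attributes
    ----------
    a, d : float
        Lower and upper OD asymptotes (``d != a``).
    xmid : float
        Log-concentration (natural log pg/mL) of the inflexion point.
    scal : float
        Inverse slope at the inflexion; nonzero.  Positive for increasing curves.
    g : float
        Asymmetry factor, positive; ``g = 1`` gives the 4PL.
    """

    a: float
    d: float
    xmid: float
    scal: float
    g: float = 1.0

    def __post_init__(self):
        if not math.isfinite(self.a) or not math.isfinite(self.d):
            raise DataError("asymptotes must be finite")
        if self.d == self.a:
            raise DataError("degenerate curve: d == a")
        if self.scal == 0 or not math.isfinite(self.scal):
            raise DataError("scal must be finite and nonzero")
        if not (self.g > 0) or not math.isfinite(self.g):
            raise DataError("asymmetry g must be positive and finite")

    @property
    def od_range(self) -> tuple[float, float]:
        """Open interval of attainable ODs, (min asymptote, max asymptote)."""
        return (min(self.a, self.d), max(self.a, self.d))

    def shifted(self, s: float) -> "CurveParams":
        """Return the same curve with the midpoint moved to ``xmid + s``."""
        return replace(self, xmid=self.xmid + s)


@dataclass(frozen=True)
class ExpFormParams:
    """Exponential-form parameters: ``Y = A + (D - A)/(1 + (x'/C)**B)**g``.

    ``C = exp(xmid)`` is the midpoint concentration in pg/mL and ``B = -1/scal``.
    ``A``/``D`` keep the lower/upper roles of ``a``/``d``.
    """

    A: float
    D: float
    C: float
    B: float
    g: float = 1.0

    def __post_init__(self):
        if not (self.C > 0):
            raise DataError("midpoint concentration C must be positive")


@dataclass(frozen=True)
class FitResult:
    params: CurveParams
    rss: float
    n_points: int
    converged: bool
    n_iter: int


def logistic(x, p: CurveParams):
    """Evaluate the logistic curve at log-concentration ``x``.

    Vectorized over ``x``; numerically stable far into both asymptotes
    (uses log1p-style evaluation instead of a raw exponential).
    """
    x = np.asarray(x, dtype=float)
    t = (p.xmid - x) / p.scal
    # (1 + e^t)^-g computed as exp(-g * log(1 + e^t)) via logaddexp
    y = p.a + (p.d - p.a) * np.exp(-p.g * np.logaddexp(0.0, t))
    return y if y.ndim else float(y)


def inverse_logistic(y: float, p: CurveParams) -> float:
    """Closed-form inverse: the log-concentration whose response is ``y``.

    ``y`` must lie strictly between the asymptotes.  Outside that interval a
    :class:`RangeError` is raised, tagged ``below_range`` when the OD sits on
    the low-concentration side and ``above_range`` on the high side.
    """
    lo, hi = p.od_range
    if not (lo < y < hi):
        # which side is "low concentration" depends on curve orientation
        increasing = (p.d > p.a) == (p.scal > 0)
        low_side_od = lo if increasing else hi
        if y == low_side_od or (y < lo if increasing else y > hi):
            raise RangeError(f"OD {y} at or below the low-concentration asymptote", "below_range")
        raise RangeError(f"OD {y} at or above the high-concentration asymptote", "above_range")
    ratio = (p.d - p.a) / (y - p.a)
    return p.xmid - p.scal * math.log(ratio ** (1.0 / p.g) - 1.0)


def _as_points(standards: Iterable[tuple[float, float]] | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(standards, tuple) and len(standards) == 2 and np.ndim(standards[0]) == 1:
        x, od = (np.asarray(v, dtype=float) for v in standards)
    else:
        arr = np.asarray(list(standards), dtype=float)
        if arr.size == 0:
            raise DataError("no standard points supplied")
        x, od = arr[:, 0], arr[:, 1]
    if x.shape != od.shape:
        raise DataError("x and od must have equal length")
    return x, od


def initial_params(standards, model: Literal["4pl", "5pl"] = "4pl") -> CurveParams:
    """Self-starting heuristic for the logistic fit.

    Asymptotes are set 5% of the OD range beyond the observed extremes, the
    midpoint by linear interpolation of ``x`` at the half-height OD, and the
    slope from a straight-line fit through the central points.  ``g`` starts
    at 1 (symmetric).
    """
    x, od = _as_points(standards)
    if np.unique(x).size < 4:
        raise DataError("need at least 4 distinct log-concentrations for a start estimate")
    rng_od = float(od.max() - od.min())
    if rng_od == 0:
        raise DegenerateDataError("all optical densities are equal; no curve to fit")
    a = float(od.min() - 0.05 * rng_od)
    d = float(od.max() + 0.05 * rng_od)

    # average replicate wells per level for a clean monotone profile
    levels = np.unique(x)
    prof = np.array([od[x == lv].mean() for lv in levels])
    half = 0.5 * (a + d)
    xmid = float(np.interp(half, prof, levels)) if prof[0] < prof[-1] else float(
        np.interp(half, prof[::-1], levels[::-1])
    )
    # central slope from the points nearest the half-height
    order = np.argsort(np.abs(prof - half))
    core = np.sort(order[: max(3, len(levels) // 2)])
    slope = float(np.polyfit(levels[core], prof[core], 1)[0])
    if slope == 0:
        slope = (prof[-1] - prof[0]) / (levels[-1] - levels[0])
    # 4PL slope at inflexion is (d - a)/(4*scal)
    scal = float((d - a) / (4.0 * slope))
    return CurveParams(a=a, d=d, xmid=xmid, scal=scal, g=1.0)


def _pack(p: CurveParams, model: str) -> np.ndarray:
    v = [p.a, p.d, p.xmid, p.scal]
    if model == "5pl":
        v.append(math.log(p.g))
    return np.array(v, dtype=float)


def _unpack(v: np.ndarray, model: str) -> CurveParams:
    g = math.exp(v[4]) if model == "5pl" else 1.0
    return CurveParams(a=float(v[0]), d=float(v[1]), xmid=float(v[2]), scal=float(v[3]), g=g)


def fit_curve(
    standards,
    model: Literal["4pl", "5pl"] = "4pl",
    labels: Sequence[str] | None = None,
) -> FitResult:
    """Least-squares fit of a 4PL or 5PL curve to individual replicate wells.

    Unweighted ordinary least squares on the OD residuals, trust-region
    reflective with the asymmetry factor log-parameterized and bounded in
    [0.1, 10].  On failure the heuristic start is perturbed log-normally
    (factor 1.2) for up to 10 seeded restarts; if all fail a
    :class:`ConvergenceError` carrying the best attempt is raised.
    """
    x, od = _as_points(standards)
    bad = ~np.isfinite(od) | ~np.isfinite(x)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        name = labels[i] if labels is not None else f"point {i}"
        raise DataError(f"non-finite reading at {name}")
    n_distinct = np.unique(x).size
    need = 4 if model == "4pl" else 5
    if n_distinct < need:
        raise DataError(f"{model} fit needs >= {need} distinct standard levels, got {n_distinct}")

    p0 = initial_params((x, od), model)
    start = _pack(p0, model)
    lower = np.full(start.shape, -np.inf)
    upper = np.full(start.shape, np.inf)
    if model == "5pl":
        lower[4], upper[4] = math.log(_G_BOUNDS[0]), math.log(_G_BOUNDS[1])

    def resid(v):
        return logistic(x, _unpack(v, model)) - od

    rng = np.random.default_rng(_MULTISTART_SEED)
    best = None
    for attempt in range(11):
        v0 = start if attempt == 0 else start * rng.lognormal(0.0, math.log(1.2), start.shape)
        v0 = np.clip(v0, lower, upper)
        try:
            sol = least_squares(
                resid, v0, bounds=(lower, upper), method="trf",
                ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=500 * len(v0),
            )
        except (ValueError, DataError):
            continue
        rss = float(np.sum(sol.fun ** 2))
        res = FitResult(
            params=_unpack(sol.x, model), rss=rss, n_points=int(x.size),
            converged=bool(sol.success and math.isfinite(rss)), n_iter=int(sol.nfev),
        )
        if best is None or res.rss < best.rss:
            best = res
        if res.converged:
            return res
    raise ConvergenceError("logistic fit failed to converge after multi-start", best=best)


def to_exp_form(p: CurveParams) -> ExpFormParams:
    """Map log-form parameters to the exponential (plain-concentration) form."""
    return ExpFormParams(A=p.a, D=p.d, C=math.exp(p.xmid), B=-1.0 / p.scal, g=p.g)


def from_exp_form(e: ExpFormParams) -> CurveParams:
    """Inverse of :func:`to_exp_form`; requires ``C > 0``."""
    if not (e.C > 0):
        raise DataError("midpoint concentration C must be positive")
    return CurveParams(a=e.A, d=e.D, xmid=math.log(e.C), scal=-1.0 / e.B, g=e.g)
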