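"""Hill-equation dose-response analysis of normalized permeabilization.

Replicate normalized responses are summarized per dose (sample mean and
n-1 standard deviation) and the four-parameter Hill model

    f(d) = bottom + (top - bottom) * d^n / (EC50^n + d^n)

is fitted by least squares to extract EC50 with a standard error.  By
default ``bottom`` is fixed at 0 because the normalized response is
blank-anchored by construction; it can be freed for assays with negative
responses (e.g. samples that suppress events below the blank).

Optimization is initialized from a deterministic coarse grid over
(log EC50, n) — with the linear parameters solved exactly at each grid
point — so fits are reproducible and insensitive to local minima, then
polished with a trust-region least-squares solver.  Zero doses cannot sit
on a log-dose axis and are excluded from the fit (they anchor the blank
instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DosePoint",
    "HillFitResult",
    "hill_curve",
    "summarize_doses",
    "fit_hill",
    "detection_limit",
]


@dataclass(frozen=True)
class DosePoint:
    """Replicate normalized responses at one dose.

    ``degenerate`` flags a single-replicate point, whose standard
    deviation is reported as 0 but carries no spread information.
    """

    dose_molpct: float
    replicates: tuple[float, ...]
    mean: float
    sd: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.dose_molpct < 0:
            raise ValueError("dose must be non-negative")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if len(self.replicates) < 1:
            raise ValueError("a dose point needs at least one replicate")


@dataclass(frozen=True)
class HillFitResult:
    ec50_molpct: float
    hill_n: float
    top: float
    bottom: float
    ec50_se_molpct: float
    converged: bool

    def predict(self, dose_molpct) -> np.ndarray:
        return hill_curve(
            np.asarray(dose_molpct, dtype=float),
            self.ec50_molpct,
            self.hill_n,
            self.top,
            self.bottom,
        )


def hill_curve(dose, ec50: float, hill_n: float, top: float, bottom: float):
    """Evaluate the Hill model; dose may be scalar or array, zeros allowed."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        r = np.where(d > 0, (d / ec50) ** hill_n, 0.0)
    return bottom + (top - bottom) * r / (1.0 + r)


def summarize_doses(
    raw: Sequence[tuple[float, Sequence[float]]]
) -> list[DosePoint]:
    """Per-dose sample mean and standard deviation, sorted by dose.

    Standard deviation uses the n-1 denominator; a single replicate yields
    sd 0 with the ``degenerate`` flag set.
    """
    if not raw:
        raise ValueError("no dose points supplied")
    points = []
    for dose, reps in raw:
        reps = tuple(float(r) for r in reps)
        if not reps:
            raise ValueError(f"dose {dose} has no replicates")
        mean = float(np.mean(reps))
        if len(reps) == 1:
            points.append(DosePoint(dose, reps, mean, 0.0, degenerate=True))
        else:
            sd = float(np.std(reps, ddof=1))
            points.append(DosePoint(dose, reps, mean, sd))
    return sorted(points, key=lambda p: p.dose_molpct)


def _solve_linear(r: np.ndarray, y: np.ndarray, w: np.ndarray, fix_bottom: float | None):
    """Exact LSQ for the parameters the Hill model is linear in.

    ``r`` is the saturation term d^n/(EC50^n + d^n).  Returns (top, bottom,
    sse).
    """
    sw = np.sqrt(w)
    if fix_bottom is None:
        A = np.column_stack([r, 1.0 - r]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        top, bottom = float(coef[0]), float(coef[1])
    else:
        bottom = fix_bottom
        num = np.sum(w * r * (y - bottom * (1.0 - r)))
        den = np.sum(w * r * r)
        top = float(num / den) if den > 0 else bottom
    resid = y - (bottom + (top - bottom) * r)
    return top, bottom, float(np.sum(w * resid**2))


def fit_hill(
    points: Sequence[DosePoint],
    fix_bottom: float | None = 0.0,
    weighted: bool = False,
) -> HillFitResult:
    """Least-squares Hill fit of per-dose mean responses.

    Requires at least three distinct positive doses.  Unweighted by
    default; ``weighted=True`` applies 1/sd^2 weights (doses with sd 0
    fall back to the median weight).  The EC50 standard error comes from
    the fit covariance via the delta method on log EC50; non-convergence
    or a singular covariance is reported through ``converged``, never
    silently.
    """
    pts = [p for p in points if p.dose_molpct > 0]
    doses = np.array([p.dose_molpct for p in pts])
    y = np.array([p.mean for p in pts])
    if len(np.unique(doses)) < 3:
        raise ValueError("need >= 3 distinct positive doses to fit the Hill model")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.allclose(y, y[0]):
        raise ValueError("all responses equal: dose-response is degenerate")

    if weighted:
        sds = np.array([p.sd for p in pts])
        good = sds > 0
        if not np.any(good):
            raise ValueError("weighted fit requested but all sds are zero")
        fallback = float(np.median(sds[good]))
        sds = np.where(good, sds, fallback)
        w = 1.0 / sds**2
    else:
        w = np.ones_like(y)

    logd = np.log(doses)

    # deterministic coarse grid over (log EC50, n); linear params solved exactly
    span = math.log(10.0)
    grid_log_ec50 = np.linspace(logd.min() - span, logd.max() + span, 25)
    grid_n = np.array([0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0])
    best = None
    for le in grid_log_ec50:
        for n in grid_n:
            r = 1.0 / (1.0 + np.exp(-n * (logd - le)))
            top, bottom, sse = _solve_linear(r, y, w, fix_bottom)
            if best is None or sse < best[0]:
                best = (sse, le, n, top, bottom)
    _, le0, n0, top0, bottom0 = best

    free_bottom = fix_bottom is None
    x0 = [le0, math.log(n0), top0] + ([bottom0] if free_bottom else [])
    sw = np.sqrt(w)

    def residuals(x):
        le, ln, top = x[0], x[1], x[2]
        bottom = x[3] if free_bottom else fix_bottom
        n = math.exp(ln)
        r = 1.0 / (1.0 + np.exp(-n * (logd - le)))
        return sw * (bottom + (top - bottom) * r - y)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)

    le, ln, top = sol.x[0], sol.x[1], sol.x[2]
    bottom = float(sol.x[3]) if free_bottom else float(fix_bottom)
    ec50 = math.exp(le)
    hill_n = math.exp(ln)

    converged = bool(sol.success) and ec50 > 0 and hill_n > 0
    ec50_se = math.nan
    dof = len(y) - len(sol.x)
    if converged and dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (2.0 * sol.cost / dof)
            se_le = math.sqrt(max(cov[0, 0], 0.0))
            ec50_se = ec50 * se_le  # delta method on log EC50
        except np.linalg.LinAlgError:
            converged = False

    return HillFitResult(
        ec50_molpct=ec50,
        hill_n=hill_n,
        top=float(top),
        bottom=bottom,
        ec50_se_molpct=ec50_se,
        converged=converged,
    )


def detection_limit(
    points: Sequence[DosePoint], blank_sd: float
) -> float | None:
    """Smallest tested dose whose mean response exceeds 3x the blank sd.

    Returns None when no dose qualifies.  This is the classical 3-sigma
    limit of detection on the normalized-response scale.
    """
    if blank_sd < 0:
        raise ValueError("blank_sd must be non-negative")
    if not points:
        raise ValueError("no dose points supplied")
    for p in sorted(points, key=lambda p: p.dose_molpct):
        if p.dose_molpct > 0 and p.mean > 3.0 * blank_sd:
            return p.dose_molpct
    return None
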