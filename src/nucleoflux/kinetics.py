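"""Promoter-activity estimators.

Two estimates of promoter output are computed from an expression series:

* the discrete difference d(F/OD)_n = (F/OD)_n - (F/OD)_{n-1}, a simple
  per-interval proxy for promoter activity; negative values are retained in
  the raw profile and set to zero in the clipped profile (as used for
  graphic display);
* the synthesis rate q(t) = F'(t) / OD(t): corrected fluorescence and
  corrected OD are each smoothed with a least-squares cubic B-spline, and
  the analytic derivative of the fluorescence spline is divided by the OD
  spline.  Interior knots are placed at data quantiles and adjusted so the
  Schoenberg–Whitney admissibility conditions hold, trading the smoothness
  of cross-validated knot optimisation for speed and simplicity while still
  suppressing measurement noise.

The reporter is treated as stable (no maturation or degradation term), so
q(t) is the per-biomass rate at which reporter fluorescence is produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_lsq_spline

from nucleoflux.correction import ExpressionSeries
from nucleoflux.errors import KineticsError, ValidationError

SPLINE_DEGREE = 3
DEFAULT_MARGIN_MIN = 30.0


@dataclass
class ActivityProfile:
    """Discrete promoter-activity profile of one well.

    ``time_min`` runs from the second expression time point onward; entry n
    holds the change of F/OD over the interval ending at that time.  A
    difference is valid (``mask``) only when both flanking expression
    points are unmasked.
    """

    well_id: str
    time_min: np.ndarray
    d_fod_raw: np.ndarray
    d_fod_clipped: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return self.time_min.size


@dataclass
class SynthesisProfile:
    """Spline-based synthesis-rate profile of one well.

    ``q`` is dF/dt divided by OD (fluorescence units / min / absorbance),
    evaluated on ``eval_times`` which exclude a margin at both ends where
    cubic-spline derivatives are boundary-dominated.
    """

    well_id: str
    eval_times: np.ndarray
    q: np.ndarray
    knots: np.ndarray
    spline_degree: int = SPLINE_DEGREE

    def __len__(self) -> int:
        return self.eval_times.size


def promoter_activity(expr: ExpressionSeries) -> ActivityProfile:
    """Discrete promoter activity d(F/OD) of one well.

    Raw signed differences are kept; the clipped profile sets negative
    values to zero.  Masked expression points invalidate both adjacent
    differences.  An expression series without two consecutive valid
    points yields an empty profile with a warning.
    """
    fod = expr.fod
    mask = expr.mask[1:] & expr.mask[:-1]
    if not mask.any():
        warnings.warn(f"well {expr.well_id}: no two consecutive unmasked "
                      "points; empty activity profile", stacklevel=2)
        z = np.empty(0)
        return ActivityProfile(expr.well_id, z, z.copy(), z.copy(),
                               np.empty(0, dtype=bool))
    d_raw = np.where(mask, fod[1:] - fod[:-1], np.nan)
    d_clip = np.where(mask, np.maximum(d_raw, 0.0), np.nan)
    return ActivityProfile(expr.well_id, expr.time_min[1:], d_raw, d_clip,
                           mask)


def schoenberg_whitney_ok(x: np.ndarray, knots: np.ndarray,
                          degree: int = SPLINE_DEGREE) -> bool:
    """Check Schoenberg–Whitney admissibility of a knot vector for data x.

    Requires a strictly increasing assignment of data points to basis
    functions: for each basis i there is a distinct x with
    t[i] < x < t[i+degree+1] (non-strict at the clamped global boundary
    knots, where the end basis functions attain their support limit).
    This is the rank condition for the least-squares B-spline design
    matrix.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    n_basis = t.size - degree - 1
    if n_basis < degree + 1 or x.size < n_basis:
        return False
    j = 0
    for i in range(n_basis):
        lo, hi = t[i], t[i + degree + 1]
        lo_ok = (lambda v: v >= lo) if lo == t[0] else (lambda v: v > lo)
        hi_ok = (lambda v: v <= hi) if hi == t[-1] else (lambda v: v < hi)
        while j < x.size and not lo_ok(x[j]):
            j += 1
        if j >= x.size or not hi_ok(x[j]):
            return False
        j += 1
    return True


def select_knots(time_min: np.ndarray, n_interior: int,
                 degree: int = SPLINE_DEGREE) -> np.ndarray:
    """Build an admissible clamped knot vector with quantile-placed knots.

    Interior knots are placed at the data quantiles of ``time_min`` —
    concretely at midpoints between the data points flanking each quantile
    cut, so every inter-knot interval contains at least one observation —
    and boundary knots are repeated ``degree + 1`` times at the data
    extremes.  If duplicate cuts arise (more requested knots than distinct
    gaps), the duplicates are dropped, which is the minimal adjustment
    that restores Schoenberg–Whitney admissibility.
    """
    x = np.asarray(time_min, dtype=float)
    if x.ndim != 1 or not np.all(np.diff(x) > 0):
        raise ValidationError("time grid must be 1-D strictly increasing")
    if n_interior < 0:
        raise ValidationError("n_interior must be >= 0")
    n = x.size
    if n < n_interior + degree + 1:
        raise KineticsError(
            f"need at least {n_interior + degree + 1} data points for a "
            f"degree-{degree} fit with {n_interior} interior knots; got {n}")
    cuts = np.unique(np.clip(
        np.round(np.arange(1, n_interior + 1) * n / (n_interior + 1)).astype(int),
        1, n - 1))
    interior = 0.5 * (x[cuts - 1] + x[cuts])
    t = np.concatenate([np.full(degree + 1, x[0]), interior,
                        np.full(degree + 1, x[-1])])
    if not schoenberg_whitney_ok(x, t, degree):
        raise KineticsError("selected knots are not Schoenberg–Whitney "
                            "admissible for the data")
    return t


def fit_lsq_cubic_spline(time_min: np.ndarray, y: np.ndarray,
                         knots: np.ndarray) -> BSpline:
    """Least-squares cubic B-spline over the given clamped knot vector.

    Exactly reproduces data sampled from any cubic polynomial (residual at
    machine precision).  Inadmissible knots raise a :class:`KineticsError`.
    """
    x = np.asarray(time_min, dtype=float)
    y = np.asarray(y, dtype=float)
    if not schoenberg_whitney_ok(x, knots):
        raise KineticsError("knot vector violates the Schoenberg–Whitney "
                            "conditions for this data (singular design)")
    try:
        return make_lsq_spline(x, y, np.asarray(knots, dtype=float),
                               k=SPLINE_DEGREE)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise KineticsError(f"singular spline design: {exc}") from exc


def default_n_interior(n_points: int) -> int:
    """Default interior-knot count: one knot per ~12 data points, >= 4."""
    return max(4, n_points // 12)


def synthesis_rate(expr: ExpressionSeries, n_interior: int | None = None,
                   margin_min: float = DEFAULT_MARGIN_MIN) -> SynthesisProfile:
    """Spline-derivative estimate of the per-biomass synthesis rate.

    Corrected fluorescence and corrected OD are each fit with a
    least-squares cubic spline on the unmasked points; the rate is
    q(t) = F_spline'(t) / OD_spline(t) on the data times that lie at least
    ``margin_min`` minutes inside the unmasked span (spline derivatives
    are unreliable at the boundaries).  The OD spline is floored at the
    expression series' ``od_epsilon``.
    """
    valid = expr.mask & np.isfinite(expr.f_corr) & np.isfinite(expr.od_corr)
    x = expr.time_min[valid]
    if x.size < 10:
        raise KineticsError(
            f"well {expr.well_id}: need >= 10 unmasked points for the "
            f"synthesis-rate fit, got {x.size}")
    if n_interior is None:
        n_interior = default_n_interior(x.size)
    knots = select_knots(x, n_interior)
    f_spl = fit_lsq_cubic_spline(x, expr.f_corr[valid], knots)
    od_spl = fit_lsq_cubic_spline(x, expr.od_corr[valid], knots)

    keep = (x >= x[0] + margin_min) & (x <= x[-1] - margin_min)
    eval_times = x[keep]
    if eval_times.size == 0:
        raise KineticsError(
            f"well {expr.well_id}: margin {margin_min} min leaves no "
            "interior evaluation points")
    od_eval = od_spl(eval_times)
    if np.all(od_eval <= 0):
        raise KineticsError(
            f"well {expr.well_id}: OD spline is non-positive over the whole "
            "evaluation window")
    q = f_spl.derivative()(eval_times) / np.maximum(od_eval, expr.od_epsilon)
    return SynthesisProfile(expr.well_id, eval_times, q, knots)


def activity_table(profiles: dict[str, ActivityProfile]) -> pd.DataFrame:
    frames = []
    for wid in sorted(profiles):
        p = profiles[wid]
        frames.append(pd.DataFrame({
            "well_id": wid, "time_min": p.time_min,
            "d_fod_raw": p.d_fod_raw, "d_fod_clipped": p.d_fod_clipped,
            "mask": p.mask}))
    cols = ["well_id", "time_min", "d_fod_raw", "d_fod_clipped", "mask"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def synthesis_table(profiles: dict[str, SynthesisProfile]) -> pd.DataFrame:
    frames = []
    for wid in sorted(profiles):
        p = profiles[wid]
        frames.append(pd.DataFrame({
            "well_id": wid, "time_min": p.eval_times, "q": p.q}))
    if not frames:
        return pd.DataFrame(columns=["well_id", "time_min", "q"])
    return pd.concat(frames, ignore_index=True)
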