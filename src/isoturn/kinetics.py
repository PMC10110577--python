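"""Exponential-decay turnover fitting and quality filters.

The time course of the monoisotopic RIA follows a one-compartment,
deterministic depletion model

    I_0(t) = I_0_asymp + (I_0(0) - I_0_asymp) * exp(-k t)

with a single free parameter, the turnover rate k (day^-1).  Both anchors
are computed, not fitted: I_0(0) is the natural monoisotopic RIA and
I_0_asymp is the plateau value at full labeling, p_X = p_W.  Goodness of
fit is summarized by R^2, the Pearson correlation between observed and
fitted values, and the residual standard error; the 95% confidence
interval for k is the asymptotic t-interval from the linearized Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .chem import DEFAULT_P_H, IsotopomerVector
from .enrichment import (
    PAIR_METHODS,
    estimate_enrichment_from_pair,
    estimate_enrichment_full_profile,
    reconstruct_monoisotopic_ria,
)

__all__ = [
    "TurnoverFit",
    "asymptotic_ria",
    "fit_exponential_decay",
    "fit_all_methods",
    "apply_filters",
    "r2_band",
    "R2_BANDS",
    "METHOD_ORDER",
]

#: Candidate RIA-construction methods, in tie-break preference order.
METHOD_ORDER = ("full_profile", "A1/A0", "A2/A0", "A2/A1")

#: R^2 band labels used to detail fit quality.
R2_BANDS = ("<0.8", "[0.8,0.9)", "[0.9,0.95)", ">=0.95")

K_BOUNDS = (0.0, 10.0)  # day^-1


@dataclass
class TurnoverFit:
    """One exponential-decay fit of a peptide RIA time course."""

    k: float
    i0_zero: float
    i0_asymp: float
    r_squared: float
    pearson: float
    rse: float
    ci: tuple[float, float]
    se_k: float
    method: str
    n_points: int
    flagged: bool = False
    band: str | None = None
    slow_turnover_pass: bool | None = None


def asymptotic_ria(
    i0_zero: float, n_eh: float, p_w: float, p_h: float = DEFAULT_P_H
) -> float:
    """Plateau monoisotopic RIA at full labeling (p_X = p_W)."""
    return reconstruct_monoisotopic_ria(p_w, i0_zero, n_eh, p_h)


def _model(k: float, t: np.ndarray, i0_zero: float, i0_asymp: float) -> np.ndarray:
    return i0_asymp + (i0_zero - i0_asymp) * np.exp(-k * t)


def _initial_k(t: np.ndarray, y: np.ndarray, i0_zero: float, i0_asymp: float) -> float:
    """Log-linearization of the first informative points for a start value."""
    span = i0_zero - i0_asymp
    z = (y - i0_asymp) / span
    ok = (z > 1e-9) & (z < 1.0) & (t > 0)
    if not np.any(ok):
        return 0.1
    k0 = float(np.median(-np.log(z[ok]) / t[ok]))
    return min(max(k0, 1e-4), K_BOUNDS[1])


def fit_exponential_decay(
    t,
    i0,
    i0_zero: float,
    i0_asymp: float,
    method: str = "full_profile",
) -> TurnoverFit:
    """Least-squares fit of the single-parameter decay model.

    Requires at least two distinct time points and I_0(0) > I_0_asymp.
    Returns k with R^2, Pearson correlation, residual standard error and a
    95% asymptotic t-interval (SE from the linearized Jacobian).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(i0, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and RIA series must be 1-D and equal length")
    if np.unique(t).size < 2:
        raise ValueError("need at least two distinct time points")
    if not i0_zero > i0_asymp:
        raise ValueError("I_0(0) must exceed I_0_asymp")

    k0 = _initial_k(t, y, i0_zero, i0_asymp)
    res = optimize.least_squares(
        lambda k: _model(k[0], t, i0_zero, i0_asymp) - y,
        x0=[k0],
        bounds=([K_BOUNDS[0]], [K_BOUNDS[1]]),
    )
    k = float(res.x[0])
    # the zero-rate boundary has a vanishing gradient; take it exactly when
    # it is at least as good as the optimizer's solution
    ss_at_zero = float(((y - i0_zero) ** 2).sum())
    ss_at_k = float(((y - _model(k, t, i0_zero, i0_asymp)) ** 2).sum())
    if ss_at_zero <= ss_at_k:
        k = 0.0
    fitted = _model(k, t, i0_zero, i0_asymp)
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # a zero-variance series carries no decay information: R^2 is
    # undefined, and such fits must never win the best-method selection
    # (very slow turnover is accepted through the RSE criterion instead)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 1e-30 else -np.inf
    if np.std(fitted) > 0 and np.std(y) > 0:
        pearson = float(np.corrcoef(y, fitted)[0, 1])
    else:
        pearson = 0.0
    n = t.size
    dof = max(n - 1, 1)
    rse = math.sqrt(ss_res / dof)
    # SE(k) from the 1-D Jacobian of the model wrt k
    jac = -(i0_zero - i0_asymp) * t * np.exp(-k * t)
    jtj = float(jac @ jac)
    se_k = math.sqrt(ss_res / dof / jtj) if jtj > 0 else float("inf")
    tq = stats.t.ppf(0.975, dof)
    ci = (max(k - tq * se_k, 0.0), k + tq * se_k)
    flagged = k <= K_BOUNDS[0] + 1e-12 or k >= K_BOUNDS[1] - 1e-9 or not res.success
    return TurnoverFit(
        k=k, i0_zero=i0_zero, i0_asymp=i0_asymp, r_squared=r2,
        pearson=pearson, rse=rse, ci=ci, se_k=se_k, method=method,
        n_points=int(n), flagged=flagged,
    )


def build_i0_series(
    method: str,
    times,
    abundances,
    natural: IsotopomerVector,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
    p_w: float = 0.046,
    drop_boundary: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstructed I_0 series for one RIA-construction method.

    ``abundances`` is an (n_times, 6) array of raw A_0..A_5.  Time points
    with invalid enrichment estimates are dropped, not imputed.
    """
    times = np.asarray(times, dtype=float)
    ab = np.asarray(abundances, dtype=float)
    i0_0 = natural.values[0]
    ts, ys = [], []
    pair_by_name = {v: k for k, v in PAIR_METHODS.items()}
    for t, row in zip(times, ab):
        if method == "full_profile":
            est = estimate_enrichment_full_profile(
                row, natural, n_eh, p_h, p_w, time_point=t
            )
        else:
            i, j = pair_by_name[method]
            est = estimate_enrichment_from_pair(
                row[i], row[j], (i, j), natural, n_eh, p_h, p_w, time_point=t
            )
        if not est.valid or (drop_boundary and est.at_boundary):
            continue
        ts.append(t)
        ys.append(reconstruct_monoisotopic_ria(est.p_x, i0_0, n_eh, p_h))
    return np.asarray(ts), np.asarray(ys)


def fit_all_methods(
    times,
    abundances,
    natural: IsotopomerVector,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
    p_w: float = 0.046,
    min_timepoints: int = 2,
    methods=METHOD_ORDER,
) -> tuple[TurnoverFit | None, dict[str, TurnoverFit]]:
    """Fit every RIA-construction method and select the best by R^2.

    Ties prefer the earlier entry of ``methods`` (full profile first, then
    A1/A0, A2/A0, A2/A1).  Methods with fewer than ``min_timepoints`` valid
    points are skipped.  Returns (best fit or None, per-method fits).
    """
    i0_zero = float(natural.values[0])
    i0_asymp = asymptotic_ria(i0_zero, n_eh, p_w, p_h)
    fits: dict[str, TurnoverFit] = {}
    for method in methods:
        ts, ys = build_i0_series(
            method, times, abundances, natural, n_eh, p_h, p_w
        )
        if ts.size < min_timepoints or np.unique(ts).size < 2:
            continue
        try:
            fits[method] = fit_exponential_decay(
                ts, ys, i0_zero, i0_asymp, method=method
            )
        except ValueError:
            continue
    best = None
    for method in methods:  # order encodes the tie-break preference
        fit = fits.get(method)
        if fit is None:
            continue
        if best is None or fit.r_squared > best.r_squared + 1e-12:
            best = fit
    return best, fits


def r2_band(r_squared: float) -> str:
    """Band label for an R^2 value (boundaries are inclusive on the right)."""
    if r_squared >= 0.95:
        return ">=0.95"
    if r_squared >= 0.9:
        return "[0.9,0.95)"
    if r_squared >= 0.8:
        return "[0.8,0.9)"
    return "<0.8"


def apply_filters(
    fits,
    min_timepoints: int = 4,
    r2_threshold: float = 0.8,
    k_range: tuple[float, float] | None = None,
    rse_slow: float = 0.05,
    slow_k: float = 0.01,
):
    """Quality-filter a collection of fits and label R^2 bands.

    A fit passes when it has at least ``min_timepoints`` points and either
    R^2 >= ``r2_threshold`` or — for very slow turnover (k < ``slow_k``
    day^-1, where R^2 is not a meaningful measure) — residual standard
    error <= ``rse_slow``.  ``k_range`` optionally restricts to rates
    resolvable between the shortest and longest labeling durations.
    Returns (accepted fits, all fits with bands annotated).
    """
    accepted = []
    for fit in fits:
        fit.band = r2_band(fit.r_squared)
        fit.slow_turnover_pass = fit.k < slow_k and fit.rse <= rse_slow
        if fit.n_points < min_timepoints:
            continue
        if k_range is not None and not (k_range[0] <= fit.k <= k_range[1]):
            continue
        if fit.r_squared >= r2_threshold or fit.slow_turnover_pass:
            accepted.append(fit)
    return accepted, list(fits)
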