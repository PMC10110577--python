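"""Deuterium-enrichment estimation from mass-isotopomer abundances.

The enrichment p_X(t) of a peptide can be read off a single pair of raw
isotopomer abundances because the normalization coefficient cancels in the
ratio: A_i(t)/A_j(t) = I_i(t)/I_j(t).  The estimate is the argmin of the
absolute difference between the theoretical and experimental ratio over
p_X in [0, p_W].  The traditional route normalizes the monoisotope over
the full six-peak profile and inverts the monoisotope depletion law in
closed form.  Either way, the monoisotopic RIA is then reconstructed as

    I0_tilde(t) = I_0(0) * (1 - p_X(t)/(1-p_H))**N_EH

and handed to the kinetics module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .chem import (
    DEFAULT_P_H,
    IsotopomerVector,
    b_coefficient,
    labeled_isotopomer_rias,
)

__all__ = [
    "EnrichmentEstimate",
    "PAIR_METHODS",
    "theoretical_ratio",
    "ratio_a2_a1_closed_form",
    "estimate_enrichment_from_pair",
    "estimate_enrichment_full_profile",
    "reconstruct_monoisotopic_ria",
]

#: Ratio methods using the first three isotopomers, keyed by (i, j) pair.
PAIR_METHODS = {(1, 0): "A1/A0", (2, 0): "A2/A0", (2, 1): "A2/A1"}

#: Additional pairs available through the same I_i/I_j identity but not
#: used by default (the first three peaks are usually the most abundant).
EXTRA_PAIRS = {(3, 0): "A3/A0", (4, 0): "A4/A0"}

_GRID_POINTS = 50  # coarse pre-scan guarding the bracketed minimizer
_XATOL = 1e-9


@dataclass
class EnrichmentEstimate:
    """One p_X estimate at one labeling time point."""

    p_x: float
    method: str
    objective_residual: float
    time_point: float = float("nan")
    at_boundary: bool = False
    valid: bool = True


def theoretical_ratio(
    pair: tuple[int, int],
    p_x: float,
    natural: IsotopomerVector,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
) -> float:
    """Theoretical A_i/A_j = I_i(p_X)/I_j(p_X) for an isotopomer pair."""
    if pair not in PAIR_METHODS and pair not in EXTRA_PAIRS:
        raise ValueError(f"unsupported isotopomer pair {pair}")
    i, j = pair
    rias = labeled_isotopomer_rias(natural, p_x, n_eh, p_h)
    denom = rias[j]
    if denom <= 0:
        raise ZeroDivisionError(f"I_{j}(p_X={p_x}) vanished; ratio undefined")
    return rias[i] / denom


def ratio_a2_a1_closed_form(
    p_x: float,
    natural: IsotopomerVector,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
) -> float:
    """Closed-form A2/A1 ratio (cross-check path for the generic identity).

    A2/A1 = {I2(0)/I0(0) - I1(0)/I0(0)*b1(0)
             + (N_EH+1)/(N_EH-1) * (b2(0) - b2(t))} * I0(t)/I1(t) + b1(t)
    """
    if n_eh <= 1:
        raise ValueError("closed form requires N_EH > 1")
    nat = natural.values
    b1_0 = b_coefficient(1, n_eh, 0.0, p_h)
    b2_0 = b_coefficient(2, n_eh, 0.0, p_h)
    b1_t = b_coefficient(1, n_eh, p_x, p_h)
    b2_t = b_coefficient(2, n_eh, p_x, p_h)
    rias = labeled_isotopomer_rias(natural, p_x, n_eh, p_h)
    bracket = (
        nat[2] / nat[0]
        - nat[1] / nat[0] * b1_0
        + (n_eh + 1.0) / (n_eh - 1.0) * (b2_0 - b2_t)
    )
    return bracket * rias[0] / rias[1] + b1_t


def _argmin_scalar(objective, p_w: float) -> tuple[float, float]:
    """Coarse grid pre-scan + bounded Brent refinement on [0, p_w]."""
    grid = np.linspace(0.0, p_w, _GRID_POINTS)
    vals = np.array([objective(p) for p in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, _GRID_POINTS - 1)]
    if lo == hi:
        return float(grid[k]), float(vals[k])
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": _XATOL},
    )
    best_p, best_v = float(res.x), float(res.fun)
    if vals[k] < best_v:  # keep the grid point if refinement stalled
        best_p, best_v = float(grid[k]), float(vals[k])
    return best_p, best_v


def estimate_enrichment_from_pair(
    a_i: float,
    a_j: float,
    pair: tuple[int, int],
    natural: IsotopomerVector,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
    p_w: float = 0.046,
    time_point: float = float("nan"),
) -> EnrichmentEstimate:
    """Estimate p_X from raw abundances of one isotopomer pair.

    Minimizes |I_i(p)/I_j(p) - A_i/A_j| over p in [0, p_W].  Experimental
    ratios outside the achievable range land on a boundary and are flagged
    (``at_boundary``); non-positive abundances yield an invalid estimate.
    """
    method = PAIR_METHODS.get(pair) or EXTRA_PAIRS.get(pair)
    if method is None:
        raise ValueError(f"unsupported isotopomer pair {pair}")
    if not (a_i > 0 and a_j > 0) or not np.isfinite(a_i / a_j):
        return EnrichmentEstimate(
            0.0, method, float("inf"), time_point, valid=False
        )
    target = a_i / a_j

    def objective(p: float) -> float:
        return abs(theoretical_ratio(pair, p, natural, n_eh, p_h) - target)

    p_hat, resid = _argmin_scalar(objective, p_w)
    boundary = (p_hat < 1e-12 or p_hat > p_w - 1e-12) and resid > 1e-9
    return EnrichmentEstimate(p_hat, method, resid, time_point, at_boundary=boundary)


def estimate_enrichment_full_profile(
    abundances,
    natural: IsotopomerVector,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
    p_w: float = 0.046,
    time_point: float = float("nan"),
) -> EnrichmentEstimate:
    """Estimate p_X from the complete six-peak profile.

    The monoisotopic RIA is the normalized monoisotope, I_0(t) =
    A_0/sum(A_0..A_5); the depletion law then inverts in closed form:
    p_X = (1-p_H) * (1 - (I_0(t)/I_0(0))**(1/N_EH)), clipped to [0, p_W].

    Because only six peaks are observed, the observed normalization omits
    the isotopomer tail, which grows with labeling; the closed form is
    therefore iterated with the model's six-peak sum at the current
    enrichment (a fixed point reached in a few steps) so that noiseless
    profiles invert exactly.  A super-natural monoisotope (I_0(t) >
    I_0(0)) clips to 0 and is flagged.
    """
    a = np.asarray(abundances, dtype=float)
    total = a.sum()
    if total <= 0 or np.any(a < 0):
        return EnrichmentEstimate(
            0.0, "full_profile", float("inf"), time_point, valid=False
        )
    i0_obs = a[0] / total
    i0_0 = natural.values[0]  # head of the full-normalized natural profile

    def closed_form(p: float) -> tuple[float, bool]:
        s6 = labeled_isotopomer_rias(natural, p, n_eh, p_h).values.sum()
        ratio = i0_obs * s6 / i0_0
        if ratio >= 1.0:
            return 0.0, ratio > 1.0 + 1e-12
        return (1.0 - p_h) * (1.0 - ratio ** (1.0 / n_eh)), False

    p_hat, super_natural = closed_form(0.0)
    for _ in range(40):  # truncation-tail fixed point
        p_next, super_natural = closed_form(min(p_hat, 0.5))
        if abs(p_next - p_hat) < 1e-13:
            p_hat = p_next
            break
        p_hat = p_next
    boundary = super_natural
    if p_hat > p_w:
        p_hat = p_w
        boundary = True
    model = labeled_isotopomer_rias(natural, p_hat, n_eh, p_h).values
    resid = abs(model[0] / model.sum() - i0_obs)
    return EnrichmentEstimate(
        p_hat, "full_profile", resid, time_point, at_boundary=boundary
    )


def reconstruct_monoisotopic_ria(
    p_x: float,
    i0_natural: float,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
) -> float:
    """Monoisotopic RIA at enrichment p_X: I_0(0)*(1 - p_X/(1-p_H))**N_EH."""
    if p_x < 0 or p_h + p_x >= 1:
        raise ValueError(f"enrichment {p_x} outside physical domain")
    return float(i0_natural * (1.0 - p_x / (1.0 - p_h)) ** n_eh)
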