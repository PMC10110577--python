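"""Peptide elemental composition and mass-isotopomer distributions.

A peptide labeled in vivo with heavy water carries two populations of
hydrogens: ``N_EH`` exchangeable sites whose deuterium probability rises
from the natural abundance ``p_H`` to ``p_H + p_X(t)`` as label is
incorporated, and the remaining hydrogens (plus all other elements) which
stay at natural abundance.  This module computes

* the natural (unlabeled) aggregated isotope distribution of a peptide, by
  per-element polynomial expansion and cross-element convolution;
* the analytic time-course dynamics of the first six mass isotopomers
  ``I_0(t) .. I_5(t)`` as functions of the enrichment ``p_X``, via the
  forward coefficients ``b_n`` and the inverse-series coefficients ``c_n``;
* a first-principles convolution oracle for the labeled distribution, used
  to verify the analytic forms.

Aggregated isotopomers are indexed by nominal mass shift (+0..+5); fine
structure inside a peak is summed.  Charge affects m/z only, never the
abundance vector.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from pyteomics import mass as _pyt_mass
from scipy.special import binom as _binom

__all__ = [
    "PeptideComposition",
    "IsotopomerVector",
    "LabelingParameters",
    "N_PEAKS",
    "DEFAULT_P_H",
    "load_element_table",
    "load_neh_table",
    "composition_from_sequence",
    "natural_isotope_distribution",
    "b_coefficient",
    "c_coefficient",
    "labeled_isotopomer_rias",
    "oracle_labeled_distribution",
]

#: Number of aggregated isotopomer peaks tracked everywhere (+0..+5).
N_PEAKS = 6

#: Natural deuterium abundance (fraction of all hydrogen).
DEFAULT_P_H = 0.000115

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PeptideComposition:
    """Elemental composition of one peptide species.

    ``n_exchangeable`` is N_EH, the number of hydrogens accessible to
    deuterium from body water — the sum of per-residue values, so it is
    generally non-integer.
    """

    sequence: str
    charge: int
    element_counts: Mapping[str, int]
    n_exchangeable: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be positive, got {self.charge}")
        if self.n_exchangeable < 0:
            raise ValueError("n_exchangeable must be non-negative")
        n_h = self.element_counts.get("H", 0)
        if n_h < self.n_exchangeable:
            raise ValueError(
                f"n_exchangeable ({self.n_exchangeable}) exceeds hydrogen "
                f"count ({n_h})"
            )


@dataclass
class IsotopomerVector:
    """Six relative (or raw) abundances of mass isotopomers +0..+5."""

    values: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PEAKS,):
            raise ValueError(f"expected {N_PEAKS} isotopomer values")
        if np.any(self.values < -1e-12):
            raise ValueError("isotopomer abundances must be non-negative")
        self.values = np.clip(self.values, 0.0, None)
        if self.normalized and self.values.sum() > 1 + 1e-9:
            raise ValueError("normalized isotopomer vector sums above 1")

    def normalize(self) -> "IsotopomerVector":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero vector")
        return IsotopomerVector(self.values / total, normalized=True)

    def __getitem__(self, k: int) -> float:
        return float(self.values[k])


@dataclass(frozen=True)
class LabelingParameters:
    """Experiment-level labeling constants and sampling times (days)."""

    p_w: float
    p_h: float = DEFAULT_P_H
    time_points: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 < self.p_h < self.p_w < 1):
            raise ValueError(
                f"need 0 < p_H ({self.p_h}) < p_W ({self.p_w}) < 1"
            )
        tp = tuple(float(t) for t in self.time_points)
        if any(t < 0 for t in tp):
            raise ValueError("time points must be non-negative")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "time_points", tp)


# ---------------------------------------------------------------------------
# configuration tables


def _data_path(name: str):
    return resources.files("isoturn.data").joinpath(name)


def load_element_table(path=None) -> dict[str, np.ndarray]:
    """Load per-element isotope abundances as vectors over mass shift.

    The CSV schema is ``element,mass_shift,abundance`` with ``#`` comment
    lines; each element's abundances must sum to 1 (to 1e-6).
    """
    src = path if path is not None else _data_path("elements.csv")
    table: dict[str, dict[int, float]] = {}
    with open(src, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header, *body = rows
    if [c.strip() for c in header] != ["element", "mass_shift", "abundance"]:
        raise ValueError(f"unexpected element-table header: {header}")
    for el, shift, ab in body:
        table.setdefault(el, {})[int(shift)] = float(ab)
    out = {}
    for el, shifts in table.items():
        vec = np.zeros(max(shifts) + 1)
        for s, a in shifts.items():
            vec[s] = a
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"abundances for {el} sum to {vec.sum():g}, not 1")
        out[el] = vec
    return out


def load_neh_table(path=None) -> dict[str, float]:
    """Load the per-residue exchangeable-hydrogen (N_EH) table."""
    src = path if path is not None else _data_path("neh.csv")
    with open(src, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header, *body = rows
    if [c.strip() for c in header] != ["residue", "neh"]:
        raise ValueError(f"unexpected N_EH table header: {header}")
    return {res.strip(): float(v) for res, v in body}


# ---------------------------------------------------------------------------
# composition


def composition_from_sequence(
    sequence: str,
    charge: int = 1,
    neh_table: Mapping[str, float] | None = None,
    residue_formulas: Mapping[str, Mapping[str, int]] | None = None,
) -> PeptideComposition:
    """Build a :class:`PeptideComposition` from a canonical residue string.

    Element counts are the sum of residue formulas plus one water;
    ``n_exchangeable`` is the sum of the per-residue N_EH values.
    ``residue_formulas`` defaults to the standard residue compositions
    shipped with pyteomics.
    """
    if neh_table is None:
        neh_table = load_neh_table()
    for pos, aa in enumerate(sequence):
        if aa not in _CANONICAL:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos} in {sequence!r}"
            )
        if aa not in neh_table:
            raise ValueError(f"N_EH table has no entry for residue {aa!r}")
    counts: dict[str, int] = {}
    if residue_formulas is None:
        comp = _pyt_mass.Composition(parsed_sequence=sequence)
        comp += _pyt_mass.Composition(formula="H2O")
        counts = {el: int(n) for el, n in comp.items()}
    else:
        for aa in sequence:
            for el, n in residue_formulas[aa].items():
                counts[el] = counts.get(el, 0) + int(n)
        counts["H"] = counts.get("H", 0) + 2
        counts["O"] = counts.get("O", 0) + 1
    neh = float(sum(neh_table[aa] for aa in sequence))
    return PeptideComposition(sequence, charge, counts, neh)


# ---------------------------------------------------------------------------
# natural distribution (polynomial expansion + convolution)


def _poly_power(base: np.ndarray, n: int, n_keep: int | None = None) -> np.ndarray:
    """base(z)**n by repeated squaring; optionally truncate to n_keep terms."""
    result = np.array([1.0])
    b = np.asarray(base, dtype=float)
    while n:
        if n & 1:
            result = np.convolve(result, b)
            if n_keep is not None:
                result = result[:n_keep]
        b = np.convolve(b, b)
        if n_keep is not None:
            b = b[:n_keep]
        n >>= 1
    return result


def _aggregated_distribution(
    counts: Mapping[str, int],
    elements: Mapping[str, np.ndarray],
    substitutions: Mapping[str, tuple[int, np.ndarray]] | None = None,
    n_peaks: int = N_PEAKS,
) -> np.ndarray:
    """Full-distribution convolution over elements, truncated to n_peaks.

    ``substitutions`` maps an element symbol to ``(n_atoms, atom_poly)``:
    that many atoms of the element use ``atom_poly`` instead of the natural
    single-atom polynomial (used for exchangeable hydrogens).  The
    untruncated distribution sums to 1; truncation happens at the end, so
    the returned vector is a genuine head of the normalized distribution.
    """
    substitutions = substitutions or {}
    # Polynomials in z (z tracks nominal mass shift); keep enough terms that
    # the first n_peaks coefficients are exact.
    keep = n_peaks
    poly = np.array([1.0])
    for el, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for element {el}")
        if n == 0:
            continue
        if el not in elements:
            raise ValueError(f"element {el} missing from isotope table")
        n_sub, sub_poly = substitutions.get(el, (0, None))
        if n_sub > n:
            raise ValueError(f"more substituted {el} atoms than present")
        poly = np.convolve(poly, _poly_power(elements[el], n - n_sub, keep))[:keep]
        if n_sub:
            poly = np.convolve(poly, _poly_power(sub_poly, n_sub, keep))[:keep]
    out = np.zeros(n_peaks)
    out[: len(poly)] = poly[:n_peaks]
    return out


def natural_isotope_distribution(
    composition: PeptideComposition,
    n_peaks: int = N_PEAKS,
    elements: Mapping[str, np.ndarray] | None = None,
) -> IsotopomerVector:
    """First ``n_peaks`` aggregated natural isotopomer abundances.

    Computed by per-element polynomial expansion and cross-element
    convolution of the full distribution (which sums to 1), then truncated.
    """
    if elements is None:
        elements = load_element_table()
    vec = _aggregated_distribution(composition.element_counts, elements, n_peaks=n_peaks)
    return IsotopomerVector(vec, normalized=True)


# ---------------------------------------------------------------------------
# analytic labeled dynamics


def _check_enrichment_domain(p_x: float, p_h: float) -> None:
    if p_x < 0:
        raise ValueError(f"enrichment p_X must be non-negative, got {p_x}")
    if p_h < 0:
        raise ValueError(f"p_H must be non-negative, got {p_h}")
    if p_h + p_x >= 1:
        raise ValueError(f"p_H + p_X must be below 1, got {p_h + p_x}")


def b_coefficient(n: int, n_eh: float, p_x: float, p_h: float) -> float:
    """Forward coefficient b_n = C(N_EH, n) * ((p_X+p_H)/(1-p_H-p_X))**n.

    The binomial coefficient is generalized to non-integer N_EH through the
    gamma function.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    _check_enrichment_domain(p_x, p_h)
    ratio = (p_x + p_h) / (1.0 - p_h - p_x)
    return float(_binom(n_eh, n) * ratio**n)


def c_coefficient(n: int, n_eh: float, p_h: float) -> float:
    """Inverse-series coefficient c_n = C(N_EH+n-1, n) * (p_H/(1-p_H))**n."""
    if n < 0:
        raise ValueError("n must be >= 0")
    _check_enrichment_domain(0.0, p_h)
    return float(_binom(n_eh + n - 1, n) * (p_h / (1.0 - p_h)) ** n)


def labeled_isotopomer_rias(
    natural: IsotopomerVector,
    p_x: float,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
) -> IsotopomerVector:
    """Analytic RIAs I_0(t)..I_5(t) at enrichment ``p_x``.

    The monoisotope follows I_0(t) = I_0(0) * (1 - p_X/(1-p_H))**N_EH; the
    heavier isotopomers follow the exact series recursion: the natural
    profile is deflated by the alternating c_n coefficients to strip the
    natural contribution of the exchangeable sites, then re-inflated with
    the b_n(t) coefficients at the labeled deuterium probability.  Each
    I_k reuses the lower-index intermediates.
    """
    _check_enrichment_domain(p_x, p_h)
    nat = natural.values
    if nat[0] <= 0:
        raise ValueError("natural monoisotopic abundance must be positive")
    n = N_PEAKS
    b = np.array([b_coefficient(j, n_eh, p_x, p_h) for j in range(n)])
    d = np.array([(-1) ** j * c_coefficient(j, n_eh, p_h) for j in range(n)])
    i0_t = nat[0] * (1.0 - p_x / (1.0 - p_h)) ** n_eh
    # G_k = I_0(t) * (deconvolved natural)_k / (deconvolved natural)_0
    g = np.zeros(n)
    out = np.zeros(n)
    g[0] = i0_t
    out[0] = i0_t
    for k in range(1, n):
        r_k = sum(d[j] * nat[k - j] / nat[0] for j in range(k + 1))
        g[k] = i0_t * r_k
        out[k] = g[k] + sum(b[j] * g[k - j] for j in range(1, k + 1))
    out = np.clip(out, 0.0, None)
    return IsotopomerVector(out, normalized=True)


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_labeled_distribution(
    composition: PeptideComposition,
    p_x: float,
    p_h: float = DEFAULT_P_H,
    n_peaks: int = N_PEAKS,
    elements: Mapping[str, np.ndarray] | None = None,
) -> IsotopomerVector:
    """Labeled distribution by first-principles convolution.

    N_EH hydrogens carry heavy-isotope probability ``p_h + p_x``; all other
    atoms keep natural abundances.  Defined only for integer N_EH, since a
    convolution needs a whole number of substituted atoms.
    """
    n_eh = composition.n_exchangeable
    if abs(n_eh - round(n_eh)) > 1e-9:
        raise ValueError(
            f"convolution oracle requires integer N_EH, got {n_eh}"
        )
    _check_enrichment_domain(p_x, p_h)
    if elements is None:
        elements = load_element_table()
    q = p_h + p_x
    sub = {"H": (int(round(n_eh)), np.array([1.0 - q, q]))}
    vec = _aggregated_distribution(
        composition.element_counts, elements, substitutions=sub, n_peaks=n_peaks
    )
    return IsotopomerVector(vec, normalized=True)
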