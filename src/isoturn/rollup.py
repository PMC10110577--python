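"""Protein-level aggregation of peptide turnover rates.

A protein's turnover rate is the median of the rates of its accepted
peptides; the confidence interval comes from the standard deviation of
those peptide rates (a t-interval on the mean-of-peptides scale).  The
normalized-difference metric (k_pep - k_prot)/sqrt(k_pep^2 + k_prot^2)
compares a single peptide against its protein consensus and is bounded in
(-1, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ProteinRate", "aggregate_protein", "peptide_protein_metric"]


@dataclass
class ProteinRate:
    protein: str
    k_prot: float
    ci: tuple[float, float]
    n_peptides: int
    peptide_rates: list = field(default_factory=list)
    degenerate_ci: bool = False


def aggregate_protein(protein: str, peptide_rates) -> ProteinRate:
    """Aggregate accepted peptide rates into one protein rate.

    k_prot is the median peptide rate; the 95% CI is
    k_prot +/- t_{0.975, n-1} * sd(rates)/sqrt(n).  A single-peptide
    protein has no spread, so its CI collapses to the point and is flagged.
    """
    rates = [float(k) for k in peptide_rates]
    if len(rates) == 0:
        raise ValueError(f"protein {protein!r} has no accepted peptide rates")
    k_prot = float(np.median(rates))
    n = len(rates)
    if n == 1:
        return ProteinRate(protein, k_prot, (k_prot, k_prot), 1, rates, degenerate_ci=True)
    sd = float(np.std(rates, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return ProteinRate(
        protein, k_prot, (max(k_prot - half, 0.0), k_prot + half), n, rates
    )


def peptide_protein_metric(k_pep: float, k_prot: float) -> float:
    """Normalized rate difference (k_pep - k_prot)/sqrt(k_pep^2 + k_prot^2)."""
    denom = math.hypot(k_pep, k_prot)
    if denom == 0:
        raise ValueError("metric undefined when both rates are zero")
    return (k_pep - k_prot) / denom
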