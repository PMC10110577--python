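"""End-to-end analysis: quantification table -> peptide, protein, QC tables.

For every (protein, peptide, charge) time course the pipeline builds four
candidate monoisotopic-RIA series — the traditional full-profile
normalization and the three pair-ratio reconstructions — fits the decay
model to each, keeps the best fit by R^2, applies the quality filters,
aggregates accepted peptides per protein, and scores spectral accuracy of
each observed profile against the unlabeled/fully-labeled composite model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_P_H,
    composition_from_sequence,
    labeled_isotopomer_rias,
    natural_isotope_distribution,
)
from .kinetics import METHOD_ORDER, apply_filters, fit_all_methods
from .rollup import aggregate_protein
from .spectra import fit_theta, spectral_accuracy_report

__all__ = ["analyze_quant", "PEPTIDE_COLUMNS", "PROTEIN_COLUMNS", "QC_COLUMNS"]

logger = logging.getLogger("isoturn")

PEPTIDE_COLUMNS = [
    "protein", "peptide", "charge", "method", "k", "ci_low", "ci_high",
    "r_squared", "pearson", "rse", "n_points", "band", "accepted",
]
PROTEIN_COLUMNS = ["protein", "k_prot", "ci_low", "ci_high", "n_peptides"]
QC_COLUMNS = ["protein", "peptide", "charge", "time", "theta", "ssd", "ln_ssd"]


def analyze_quant(
    quant: pd.DataFrame,
    p_w: float = 0.046,
    p_h: float = DEFAULT_P_H,
    neh_table=None,
    min_timepoints: int = 4,
    r2_threshold: float = 0.8,
    k_range=None,
    rse_slow: float = 0.05,
    min_peptides: int = 1,
    methods=METHOD_ORDER,
):
    """Run the full pipeline on a quantification table.

    Returns ``(peptides, proteins, qc)`` DataFrames.  ``peptides`` holds
    the best fit per peptide (all candidate methods were fitted; the one
    with the highest R^2 is kept, ties preferring the full profile).
    Peptides shared between protein groups are excluded from the protein
    rollup.  ``min_peptides`` sets the smallest number of accepted
    peptides a reported protein needs.
    """
    peptide_rows, qc_fits, qc_meta, best_fits, owners = [], [], [], [], []
    shared = (
        quant.groupby(["peptide", "charge"])["protein"].nunique()
    )
    shared_keys = set(shared[shared > 1].index)
    for (protein, peptide, charge), grp in quant.groupby(
        ["protein", "peptide", "charge"], sort=True
    ):
        grp = grp.sort_values("time")
        times = grp["time"].to_numpy(dtype=float)
        ab = grp[["A0", "A1", "A2", "A3", "A4", "A5"]].to_numpy(dtype=float)
        try:
            comp = composition_from_sequence(peptide, int(charge), neh_table)
        except ValueError as exc:
            logger.warning("skipping %s/%s: %s", protein, peptide, exc)
            continue
        natural = natural_isotope_distribution(comp)
        best, _ = fit_all_methods(
            times, ab, natural, comp.n_exchangeable, p_h, p_w,
            min_timepoints=2, methods=methods,
        )
        if best is None:
            continue
        best_fits.append(best)
        owners.append((protein, peptide, charge))
        # spectral accuracy against the theta-composite model
        s_unlab = natural.values / natural.values.sum()
        plateau = labeled_isotopomer_rias(natural, p_w, comp.n_exchangeable, p_h)
        s_lab = plateau.values / plateau.values.sum()
        for t, row in zip(times, ab):
            total = row.sum()
            if total <= 0:
                continue
            qc_fits.append(fit_theta(row / total, s_unlab, s_lab))
            qc_meta.append((protein, peptide, charge, t))

    accepted, labeled = apply_filters(
        best_fits,
        min_timepoints=min_timepoints,
        r2_threshold=r2_threshold,
        k_range=k_range,
        rse_slow=rse_slow,
    )
    accepted_ids = {id(f) for f in accepted}
    for (protein, peptide, charge), fit in zip(owners, labeled):
        peptide_rows.append(
            [protein, peptide, charge, fit.method, fit.k, fit.ci[0],
             fit.ci[1], fit.r_squared, fit.pearson, fit.rse, fit.n_points,
             fit.band, id(fit) in accepted_ids]
        )
    peptides = pd.DataFrame(peptide_rows, columns=PEPTIDE_COLUMNS)

    protein_rows = []
    acc = peptides[peptides["accepted"]]
    for protein, grp in acc.groupby("protein"):
        keep = [
            k for (pep, ch), k in zip(zip(grp["peptide"], grp["charge"]), grp["k"])
            if (pep, ch) not in shared_keys
        ]
        if len(keep) < max(min_peptides, 1):
            logger.info("protein %s omitted: %d accepted peptide(s)", protein, len(keep))
            continue
        pr = aggregate_protein(protein, keep)
        protein_rows.append(
            [pr.protein, pr.k_prot, pr.ci[0], pr.ci[1], pr.n_peptides]
        )
    proteins = pd.DataFrame(protein_rows, columns=PROTEIN_COLUMNS)

    qc = spectral_accuracy_report(qc_fits)
    meta = pd.DataFrame(qc_meta, columns=["protein", "peptide", "charge", "time"])
    qc = pd.concat([meta, qc[["theta", "ssd", "ln_ssd"]]], axis=1)
    return peptides, proteins, qc[QC_COLUMNS]
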