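"""Synthetic isotopomer time courses with known ground truth.

The generator runs the forward model of the analysis chain: the
monoisotopic RIA decays exponentially from its natural value toward the
full-labeling plateau with the peptide's true rate k, the implied
enrichment p_X(t) follows from inverting the depletion law, and the full
six-peak profile at each time point comes from the analytic isotopomer
dynamics.  Profiles are scaled to raw abundances, optionally perturbed by
multiplicative lognormal noise (abundance measurement fluctuation) and by
additive constant contamination on chosen channels (the minimal model of
a co-eluting interference such as a "prior ion" on the monoisotope).

Defaults mirror a murine liver heavy-water study: body-water enrichment
p_W = 4.6%, sampling at 0, 1, 3, 7, 14 and 21 days, rates within the
window resolvable between the shortest and longest labeling durations.
The precursor is one-compartment and instantaneous: body water is at p_W
from t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_P_H,
    IsotopomerVector,
    composition_from_sequence,
    labeled_isotopomer_rias,
    natural_isotope_distribution,
)
from .kinetics import asymptotic_ria

__all__ = [
    "PeptideSpec",
    "Contamination",
    "SimulationConfig",
    "default_config",
    "simulate_time_course",
    "simulate_composite_population",
]

QUANT_COLUMNS = [
    "protein", "peptide", "charge", "time", "experiment",
    "A0", "A1", "A2", "A3", "A4", "A5",
]

TRUTH_COLUMNS = [
    "protein", "peptide", "charge", "time", "k_true", "n_eh",
    "p_x_true", "i0_true",
]


@dataclass(frozen=True)
class PeptideSpec:
    sequence: str
    protein: str = "SIMPROT1"
    charge: int = 2
    k_true: float = 0.135
    base_abundance: float = 1.0e6
    n_eh: float | None = None  # override the table-derived N_EH


@dataclass(frozen=True)
class Contamination:
    """Additive constant interference on one isotopomer channel.

    ``amplitude`` is a fraction of the peptide's base peak (its natural
    monoisotope abundance); ``time_points`` of None affects every point.
    """

    channel: int
    amplitude: float
    time_points: tuple | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.channel <= 5:
            raise ValueError("contamination channel must be in 0..5")
        if self.amplitude < 0:
            raise ValueError("contamination amplitude must be >= 0")


@dataclass
class SimulationConfig:
    peptides: list = field(default_factory=list)
    time_points: tuple = (0.0, 1.0, 3.0, 7.0, 14.0, 21.0)
    p_w: float = 0.046
    p_h: float = DEFAULT_P_H
    noise_cv: float = 0.0
    noise_model: str = "lognormal"  # or "gaussian" (additive)
    contamination: list = field(default_factory=list)
    seed: int = 0


#: A small liver-like cohort: three simulated proteins spanning slow to
#: fast turnover, each quantified by several realistic-length tryptic
#: peptides (typical sizes give tens of exchangeable hydrogens and hence
#: a deep monoisotope depletion span).
_DEFAULT_PEPTIDES = [
    PeptideSpec("GTTITSVLPKPALVASR", "SIMPROT_FAST", 2, 0.135),
    PeptideSpec("NLDKEYLPIGGLAEFCK", "SIMPROT_FAST", 2, 0.135),
    PeptideSpec("LVEALCAEHQINLIK", "SIMPROT_FAST", 3, 0.135),
    PeptideSpec("AGFAGDDAPRAVFPSIVGR", "SIMPROT_MED", 2, 0.28),
    PeptideSpec("SYELPDGQVITIGNER", "SIMPROT_MED", 2, 0.28),
    PeptideSpec("VAPEEHPVLLTEAPLNPK", "SIMPROT_MED", 2, 0.28),
    PeptideSpec("YPIEHGIVTNWDDMEK", "SIMPROT_SLOW", 2, 0.03),
    PeptideSpec("DLYANTVLSGGTTMYPGIADR", "SIMPROT_SLOW", 2, 0.03),
]


def default_config(seed: int = 0, noise_cv: float = 0.03) -> SimulationConfig:
    """Study-condition defaults: 4.6% body water, six time points, 3% CV."""
    return SimulationConfig(
        peptides=list(_DEFAULT_PEPTIDES), noise_cv=noise_cv, seed=seed
    )


def _noise_factors(rng, cv: float, shape, model: str):
    if cv <= 0:
        return np.ones(shape)
    if model == "lognormal":
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=shape)
    if model == "gaussian":
        return np.clip(1.0 + rng.normal(0.0, cv, size=shape), 0.0, None)
    raise ValueError(f"unknown noise model {model!r}")


def simulate_time_course(cfg: SimulationConfig):
    """Generate a quantification table and its ground truth.

    Returns ``(quant, truth)`` DataFrames.  ``quant`` carries raw A_0..A_5
    per (peptide, time); ``truth`` carries the generating k, N_EH, p_X(t)
    and noiseless I_0(t).  Identical configs (including seed) produce
    identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    quant_rows, truth_rows = [], []
    times = np.asarray(cfg.time_points, dtype=float)
    for spec in cfg.peptides:
        comp = composition_from_sequence(spec.sequence, spec.charge)
        n_eh = spec.n_eh if spec.n_eh is not None else comp.n_exchangeable
        natural = natural_isotope_distribution(comp)
        i0_zero = natural.values[0]
        i0_asymp = asymptotic_ria(i0_zero, n_eh, cfg.p_w, cfg.p_h)
        base_peak = spec.base_abundance * i0_zero
        noise = _noise_factors(
            rng, cfg.noise_cv, (times.size, 6), cfg.noise_model
        )
        for ti, t in enumerate(times):
            i0_t = i0_asymp + (i0_zero - i0_asymp) * np.exp(-spec.k_true * t)
            ratio = i0_t / i0_zero
            if ratio <= 0:
                raise ValueError("depletion model produced non-positive RIA")
            p_x = (1.0 - cfg.p_h) * (1.0 - ratio ** (1.0 / n_eh))
            if p_x > cfg.p_w + 1e-12:
                raise ValueError(
                    f"config implies p_X(t)={p_x:.4g} above p_W={cfg.p_w}"
                )
            profile = labeled_isotopomer_rias(natural, p_x, n_eh, cfg.p_h)
            ab = spec.base_abundance * profile.values * noise[ti]
            for cont in cfg.contamination:
                affected = (
                    cont.time_points is None or t in cont.time_points
                )
                if affected:
                    ab[cont.channel] += cont.amplitude * base_peak
            quant_rows.append(
                [spec.protein, spec.sequence, spec.charge, t, "sim"]
                + list(ab)
            )
            truth_rows.append(
                [spec.protein, spec.sequence, spec.charge, t,
                 spec.k_true, n_eh, p_x, i0_t]
            )
    quant = pd.DataFrame(quant_rows, columns=QUANT_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return quant, truth


def simulate_composite_population(
    n_spectra: int,
    s_unlabeled,
    s_labeled,
    seed: int = 0,
    perturbation: float = 0.0,
):
    """Random composite spectra for spectral-accuracy tests.

    Draws theta uniformly on [0, 1] (the endpoints 0 and 1 are always
    included), mixes the endpoint spectra, and optionally adds a uniform
    perturbation of the given amplitude on one random channel per
    spectrum.  Returns ``(thetas, spectra)`` with spectra of shape (n, 6).
    """
    if n_spectra < 2:
        raise ValueError("need at least two spectra to include both endpoints")
    rng = np.random.default_rng(seed)
    unlab = np.asarray(
        s_unlabeled.values if isinstance(s_unlabeled, IsotopomerVector) else s_unlabeled,
        dtype=float,
    )
    lab = np.asarray(
        s_labeled.values if isinstance(s_labeled, IsotopomerVector) else s_labeled,
        dtype=float,
    )
    thetas = rng.uniform(0.0, 1.0, size=n_spectra)
    thetas[0], thetas[1] = 0.0, 1.0
    spectra = thetas[:, None] * unlab[None, :] + (1.0 - thetas[:, None]) * lab[None, :]
    if perturbation > 0:
        channels = rng.integers(0, 6, size=n_spectra)
        bumps = rng.uniform(0.0, perturbation, size=n_spectra)
        spectra[np.arange(n_spectra), channels] += bumps
    return thetas, spectra
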