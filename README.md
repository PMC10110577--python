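# isoturn

Protein turnover rates from heavy-water (²H₂O) metabolic labeling LC-MS
data, using either complete six-peak isotope profiles or *partial
profiles* — any single pair of mass isotopomers.

## The problem

When an animal drinks heavy water, deuterium enters non-essential amino
acids and, from there, newly synthesized proteins. A peptide's mass
isotopomer distribution shifts as label accumulates: the relative isotope
abundance (RIA) of the monoisotope, I₀(t), depletes from its natural
value toward a plateau set by the body-water enrichment. The time course

    I₀(t) = I₀^asymp + (I₀(0) − I₀^asymp) · e^(−kt)

yields the turnover rate k (day⁻¹) of the protein the peptide came from
(half-life = ln 2 / k). Traditionally I₀(t) is taken as the normalized
monoisotope of the full six-peak profile, A₀/ΣAᵢ. In complex proteomes,
co-eluting contaminants frequently corrupt one or more of the six
channels, and 55–65% of quantified peptides end up with fits too poor to
use (R² < 0.8).

isoturn implements the partial-profile alternative: the deuterium
enrichment p_X(t) of a peptide is estimated from a *single pair* of raw
isotopomer abundances, since Aᵢ/Aⱼ = Iᵢ/Iⱼ (the normalization cancels).
The analytic dynamics of all six isotopomers as functions of p_X — built
from the coefficients

    b_n = C(N_EH, n) · ((p_X + p_H)/(1 − p_H − p_X))ⁿ
    c_n = C(N_EH + n − 1, n) · (p_H/(1 − p_H))ⁿ

where N_EH is the number of body-water-exchangeable hydrogens, p_H the
natural deuterium abundance, p_W the body-water enrichment — give the
theoretical ratio for any pair; p_X is the argmin of
|theoretical − observed| over [0, p_W]. The monoisotopic RIA is then
reconstructed as

    Ĩ₀(t) = I₀(0) · (1 − p_X(t)/(1 − p_H))^N_EH

and fit with the decay model. A contaminant confined to one channel
leaves every pair that avoids that channel unbiased, so the best of
{full profile, A₁/A₀, A₂/A₀, A₂/A₁} (highest R²) rescues peptides the
traditional approach loses.

Also included: spectral-accuracy scoring (least-squares mixing fraction θ
between unlabeled and plateau spectra; the residual SSD flags distorted
profiles), quality filters (≥4 time points; R² bands at 0.8/0.9/0.95; an
RSE ≤ 0.05 path for very slow turnover, k < 0.01 day⁻¹, where R² is
uninformative), protein rollup (median of peptide rates with a t-interval
CI), and a simulator that forward-generates isotopomer time courses with
known ground truth, noise, and channel-specific contamination.

## Worked example

`python examples/enrichment_from_pairs.py` — a peptide profile is
forward-simulated at p_X = 0.030 and inverted by every estimator, clean
and with a 50% contaminant on the monoisotope:

```
clean profile:
  A1/A0        p_X = 0.030000
  A2/A0        p_X = 0.030000
  A2/A1        p_X = 0.030000
  full_profile p_X = 0.030000

monoisotope contaminated (+50% on A0):
  A1/A0        p_X = 0.009674
  A2/A0        p_X = 0.018492
  A2/A1        p_X = 0.030000
  full_profile p_X = 0.018488
```

Estimators touching the corrupted A₀ are biased low (the inflated
monoisotope mimics less label); A₂/A₁ is exact because the contaminated
channel never enters its ratio.

`python examples/fit_turnover.py` runs the whole pipeline on a simulated
liver-like cohort (three proteins, eight peptides, 3% abundance noise):

```
protein        k_prot [95% CI]        n_peptides
SIMPROT_FAST  0.1358 [0.1226, 0.1491]  3
SIMPROT_MED   0.2807 [0.2568, 0.3047]  3
SIMPROT_SLOW  0.0314 [0.0168, 0.0460]  2
```

against generating rates of 0.135, 0.28 and 0.03 day⁻¹. The other
examples (`isotope_dynamics.py`, `spectral_accuracy.py`) show the
six-isotopomer dynamics and the composite-spectrum QC.

## Command line

```sh
isoturn simulate --seed 1 --noise-cv 0.03 --output-dir run/
isoturn fit run/quant.csv --output-dir run/
isoturn validate --seed 1
```

`fit` reads a quantification CSV (`protein,peptide,charge,time,
experiment,A0..A5`) and writes `peptide_rates.csv`, `protein_rates.csv`
and `spectral_qc.csv` with run parameters echoed in `#` header lines.
The per-residue N_EH table and the element isotope table are plain CSV
configs (`src/isoturn/data/`), overridable via `--neh-table` or a YAML
config.

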