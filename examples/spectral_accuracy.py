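"""Spectral accuracy via the unlabeled/labeled composite-spectrum model.

An observed isotope profile during labeling is modeled as a mixture
theta * S_unlabeled + (1 - theta) * S_labeled of the natural spectrum and
the full-labeling plateau spectrum.  The least-squares theta has a closed
form; the residual SSD measures how far the observation sits from any
such mixture — distorted (contaminated) profiles score large SSD.
"""

import numpy as np

from isoturn import (
    composition_from_sequence,
    fit_theta,
    labeled_isotopomer_rias,
    natural_isotope_distribution,
    simulate_composite_population,
)

comp = composition_from_sequence("GTTITSVLPKPALVASR", 2)
nat = natural_isotope_distribution(comp)
unlabeled = nat.values / nat.values.sum()
plateau = labeled_isotopomer_rias(nat, 0.046, comp.n_exchangeable)
labeled = plateau.values / plateau.values.sum()

mix = 0.4 * unlabeled + 0.6 * labeled
fit = fit_theta(mix, unlabeled, labeled)
print(f"noiseless 40/60 mixture: theta = {fit.theta:.4f}, SSD = {fit.ssd:.2e}")

distorted = mix.copy()
distorted[3] += 0.05
fit_d = fit_theta(distorted, unlabeled, labeled)
print(f"with +0.05 on channel 3: theta = {fit_d.theta:.4f}, SSD = {fit_d.ssd:.2e}")

_, clean = simulate_composite_population(500, unlabeled, labeled, seed=1)
_, dirty = simulate_composite_population(500, unlabeled, labeled, seed=1,
                                         perturbation=0.02)
ln_clean = np.median([np.log(max(fit_theta(s, unlabeled, labeled).ssd, 1e-12))
                      for s in clean])
ln_dirty = np.median([np.log(max(fit_theta(s, unlabeled, labeled).ssd, 1e-12))
                      for s in dirty])
print(f"\nmedian ln(SSD): clean population {ln_clean:.1f}, "
      f"perturbed population {ln_dirty:.1f}")
print("the separation mirrors how poor spectral accuracy flags profiles "
      "that need the pair-ratio treatment.")
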