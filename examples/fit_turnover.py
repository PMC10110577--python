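"""Full pipeline: simulate a labeled cohort, fit turnover rates, roll up.

Simulates a small liver-like cohort (three proteins spanning slow to fast
turnover, 3% abundance noise, sampling at 0-21 days), runs the complete
analysis — enrichment estimation by all four methods, best-fit selection,
quality filters, protein aggregation — and compares the recovered rates
with the generating truth.
"""

import numpy as np

from isoturn import analyze_quant, default_config, simulate_time_course

cfg = default_config(seed=42, noise_cv=0.03)
quant, truth = simulate_time_course(cfg)
print(f"simulated {quant['peptide'].nunique()} peptides, "
      f"{quant['protein'].nunique()} proteins, "
      f"{quant['time'].nunique()} labeling durations\n")

peptides, proteins, qc = analyze_quant(quant, p_w=cfg.p_w, p_h=cfg.p_h)

truth_k = truth.groupby("peptide")["k_true"].first()
print("peptide                 method        k_fit   k_true     R2")
for _, row in peptides.iterrows():
    print(f"{row['peptide']:22s}  {row['method']:12s}"
          f"{row['k']:7.4f}  {truth_k[row['peptide']]:7.3f}  {row['r_squared']:.4f}")

print("\nprotein        k_prot [95% CI]        n_peptides")
for _, row in proteins.iterrows():
    print(f"{row['protein']:13s} {row['k_prot']:.4f} "
          f"[{row['ci_low']:.4f}, {row['ci_high']:.4f}]  {row['n_peptides']}")

merged = peptides.merge(truth_k, on="peptide")
rel = np.abs(merged["k"] - merged["k_true"]) / merged["k_true"]
print(f"\nmax relative rate error across peptides: {rel.max():.3f}")
print("rates are in day^-1; half-life = ln(2)/k days.")
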