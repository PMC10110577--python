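# Methods

## Model

A peptide's aggregated mass-isotopomer distribution is tracked over the
first six peaks (+0…+5 nominal mass shifts from the monoisotope; fine
structure within a peak is summed; charge affects m/z only). Two hydrogen
populations are distinguished: N_EH exchangeable sites whose deuterium
probability rises from the natural abundance p_H to p_H + p_X(t) during
labeling, and all remaining atoms at natural abundance. Body water is
assumed at its plateau enrichment p_W from t = 0 (one-compartment,
instantaneous precursor); a two-compartment precursor model and
stochastic decay models are out of scope.

Under this model the monoisotopic RIA depletes as
I₀(t) = I₀(0)·(1 − p_X(t)/(1 − p_H))^N_EH, and the protein-turnover time
course follows the single-parameter exponential decay
I₀(t) = I₀^asymp + (I₀(0) − I₀^asymp)·e^(−kt), with both anchors
computed, not fitted: I₀(0) is the theoretical natural monoisotopic RIA
and I₀^asymp its value at p_X = p_W.

### Analytic isotopomer dynamics

The labeled distribution is the natural distribution with the
exchangeable-site binomial replaced at the higher deuterium probability.
Writing b_n(t) = C(N_EH, n)·((p_X+p_H)/(1−p_H−p_X))ⁿ for the forward
(labeled) expansion and c_n = C(N_EH+n−1, n)·(p_H/(1−p_H))ⁿ for the
inverse series of the natural expansion, each labeled RIA I_k(t) is
obtained by (i) deconvolving the natural profile with the alternating
c_n coefficients — stripping the natural contribution of the
exchangeable sites — and (ii) reconvolving with b_n(t), reusing the
lower-index intermediates. Binomial coefficients generalize to
non-integer N_EH through the gamma function, and the monoisotope law
holds with a real exponent. The recursion is verified against a
first-principles convolution oracle (N_EH hydrogens at probability
p_H + p_X, everything else natural; defined only for integer N_EH) to
better than 1e-9 across a broad composition × enrichment grid — in
practice agreement is at machine precision. The closed-form A₂/A₁ ratio,
whose bracket carries an (N_EH+1)/(N_EH−1) factor on b₂(0) − b₂(t), is
provided as an independent cross-check path and agrees with the generic
I₂/I₁ ratio to machine precision.

### Enrichment estimation

Pair estimators minimize |Iᵢ(p)/Iⱼ(p) − Aᵢ/Aⱼ| over p ∈ [0, p_W] with a
50-point coarse pre-scan followed by bounded Brent refinement (absolute
tolerance 1e-9); the pre-scan guards against any non-monotone objective,
and the result matches a 1e-5-step grid search within one step. Ratios
default to the first three isotopomers (usually the most abundant);
A₃/A₀ and A₄/A₀ are available through the same identity but disabled by
default. Out-of-range experimental ratios clip to the nearest bound and
carry a flag rather than erroring; flagged points may be dropped
(configurable, default keep).

The full-profile estimator inverts the monoisotope depletion law in
closed form from I₀(t) = A₀/ΣA₀..₅. Because only six peaks are observed,
that normalization omits the isotopomer tail, which grows with labeling
(see "six-peak coverage" below); the closed form is therefore iterated
with the model's six-peak sum at the current enrichment — a fixed point
reached in a few steps — so that noiseless profiles invert exactly
(< 1e-12) for any peptide size.

### Kinetics, GOF, confidence intervals

k is fit by bounded 1-D nonlinear least squares (k ∈ [0, 10] day⁻¹,
start from log-linearization of the informative points); the k = 0
boundary is taken exactly whenever it fits at least as well, since its
gradient vanishes. GOF: R² = 1 − SS_res/SS_tot, the Pearson correlation
between observed and fitted values, and the residual standard error
RSE = √(SS_res/(n−1)). A zero-variance RIA series carries no decay
information, so its R² is stored as −inf (banded "<0.8") and can never
win the best-method selection; genuine zero-turnover peptides are
accepted through the RSE path instead. The 95% CI is the asymptotic
t-interval k ± t₀.₉₇₅,ₙ₋₁·SE(k) with SE from the linearized Jacobian and
residual variance — a standard construction adopted here and documented
as this package's choice. R² may be negative for terrible fits and is
stored as-is.

Per peptide, four candidate RIA series are built (full profile, A₁/A₀,
A₂/A₀, A₂/A₁), each fitted, and the best selected by highest R² with
ties preferring the full profile, then A₁/A₀, A₂/A₀, A₂/A₁. Selection is
per fit (a per-time-point mode is not provided). Time points with
invalid estimates are dropped per method, never imputed.

Filters: at least four labeling durations; R² ≥ 0.8 to accept, with
bands {<0.8, [0.8,0.9), [0.9,0.95), ≥0.95} (right edges inclusive); very
slow turnover (k < 0.01 day⁻¹) is accepted via RSE ≤ 0.05 because R² is
not meaningful when the depletion span is tiny; an optional k-range
restriction (e.g. 0.05–0.6 day⁻¹) limits rates to those resolvable
between the shortest and longest labeling durations.

### Spectral accuracy

The observed profile is modeled as θ·S_unlabeled + (1−θ)·S_labeled with
S_labeled the plateau spectrum at p_X = p_W (configurable). Both spectra
and the observation are normalized over the same six peaks. The model is
linear in θ, so the least-squares θ is the projection onto the segment
between the endpoint spectra, clipped to [0,1]; identical endpoints are
flagged degenerate. ln(SSD) is floored at ln(1e-12). Note the two
representations used in this package are distinct approximations of a
labeling sample: the composite spectrum mixes unlabeled and
plateau-labeled molecules, while the enrichment dynamics assume a uniform
intermediate enrichment. Profiles generated under the uniform model sit
close to, but not exactly on, the composite segment (SSD up to ~1e-3 on
clean simulated data); contamination moves profiles much farther away,
which is what the score is for.

### Protein rollup

k_prot is the median of accepted peptide rates; the 95% CI is
k_prot ± t₀.₉₇₅,ₙ₋₁·sd(rates)/√n (a t-interval on the mean-of-peptides
scale, adopted as this package's construction). Single-peptide proteins
get a degenerate, flagged CI. Peptides mapping to more than one protein
group are excluded from rollup by default. Minimum-peptide thresholds
are parameters, not hardcoded.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| p_H | 0.000115 | natural deuterium abundance (fraction) |
| p_W | 0.046 | body-water deuterium enrichment (fraction) |
| time points | 0, 1, 3, 7, 14, 21 d | labeling durations |
| N_EH table | Commerford-derived per-residue values | exchangeable hydrogens; shipped as editable CSV, never asserted as truth |
| element isotopes | IUPAC/NIST abundances | editable CSV |
| min time points | 4 | acceptance filter |
| R² threshold | 0.8 | acceptance filter |
| slow-turnover RSE | 0.05 at k < 0.01 d⁻¹ | alternate acceptance path |
| k bounds | [0, 10] d⁻¹ | fit domain |

## Simulator

The generator runs the forward model: I₀(t) from the decay law, p_X(t)
by closed-form inversion, the six-peak profile from the analytic
dynamics, scaled to raw abundances. Noise is multiplicative lognormal
per channel with given CV (mean-preserving; additive Gaussian available
behind a flag), emulating abundance measurement fluctuation.
Contamination is an additive constant on selected channels, expressed as
a fraction of the peptide's natural base peak — the minimal model of a
co-eluting interference such as a "prior ion" under the monoisotope.
Default cohort: eight realistic-length tryptic peptides (15–21 residues,
N_EH ≈ 20–34) across three proteins at 0.03, 0.135 and 0.28 day⁻¹ —
slow, fast-exemplar and liver-median-like conditions. Identical configs
(including seed) produce identical tables.

What the simulator does **not** emulate: chromatographic peak shapes and
elution-window effects, retention-time drift, peptide misidentification,
correlated channel noise, precursor enrichment kinetics, and razor/shared
peptide ambiguity beyond exact sequence sharing. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
noise and interference models, not robustness to everything real LC-MS
data contains.

## Numerical notes and edge cases

- Six-peak coverage: the untruncated distribution sums to 1; the
  six-peak head covers ≥ 99% of the natural distribution for peptides
  below ~1800 Da, but labeled coverage is governed by N_EH, not mass —
  at p_X = 0.05 an alanine-rich 975 Da peptide (N_EH ≈ 26) drops to
  ~0.988 and 1700 Da tryptic peptides (N_EH ≈ 28–32) to 0.94–0.96. The
  truncation-corrected full-profile inversion absorbs this loss; pair
  ratios are unaffected (both members share the normalization).
- Problem sizes in the validation runs (oracle grid of 20 compositions ×
  6 enrichments; 200 contaminated and 500 noisy replicates; 1000 mixture
  draws) were chosen to estimate each quantity to well under its
  acceptance margin on a single CPU in seconds to tens of seconds.
- Super-natural monoisotopes (I₀(t) > I₀(0)) clip to p_X = 0 with a
  flag; non-positive abundances invalidate the single estimate, not the
  series.
- All rates are day⁻¹, times days, isotopomer indices 0-based.

## Known limitations

- The composite-spectrum θ and the uniform-enrichment p_X are different
  coordinates for labeling progress; SSD against the composite model is
  a QC score, not a likelihood.
- CI coverage is nominal for a single chosen method; selecting the best
  of four fits by R² and then quoting that fit's CI is slightly
  optimistic (measured ≈ 0.90 vs 0.93 at nominal 0.95 under 3% noise).
- Post-translational modifications, non-canonical residues and isotope
  fine structure are out of scope; the N_EH table is tissue- and
  protocol-dependent and should be overridden when better values exist.
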