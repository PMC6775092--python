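# Methods

## Scope and data model

`spindyn` starts from quantified peak intensities, not spectra. Spectral
processing, peak picking and resonance assignment are upstream of the
package; intrinsic H/D exchange rates are likewise consumed as an input
table (they are routinely predicted from sequence by dedicated servers,
and re-implementing that predictor with its large substituent-parameter
set is out of scope). Residue numbering is taken verbatim from the input
and may be non-positive, as happens with N-terminal cloning artifacts
(e.g. Gly at −1, Ser at 0).

## Relaxation-rate extraction

Inversion-recovery series are fit with the three-parameter form
I(t) = I∞ − (I∞ − I₀)·exp(−R₁t). The third parameter makes the fit robust
to imperfect inversion; with perfect inversion it reduces to the
two-parameter form at no cost. Spin-lock decays use the two-parameter
I(t) = I₀·exp(−R₁ρt). Duplicate delays enter as independent observations,
and when no per-point errors are supplied the spread of the duplicates
seeds a flat error estimate. Errors come from the fit covariance matrix.

R₂ is computed from R₁ρ and R₁ through the tilt angle θ = arctan(ω₁/Ω) of
the effective field. The spin-lock carrier position is configuration, not
inference: with no offsets supplied, on-resonance (θ = 90°, R₂ = R₁ρ) is
assumed and a warning is logged. A combination implying negative R₂ is
rejected rather than silently clipped.

The heteronuclear NOE is the saturated/reference intensity ratio with the
error propagated from the spectral noise level; NOE < 0.65 flags
significantly increased internal mobility.

## Diffusion tensor and model-free analysis

Rigid-core residues for the tensor fit are selected in two passes:
residues with NOE < 0.65 are removed, the mean R₂/R₁ is computed once over
the survivors, and residues deviating from that mean by more than 10% are
removed. Fewer than 10 survivors refuses the fit. Both an isotropic and an
axially symmetric tensor are fit to the observed ratios (predicted with
internal motion suppressed, S² = 1) and returned with their χ² for model
comparison. The axial fit parametrizes (log D_iso, log D∥/D⊥, θ, φ) and is
restarted from four axis orientations to avoid local minima. A
near-parallel NH-vector distribution triggers an orientation-reliability
warning.

Spectral densities use the Woessner three-exponential form with
τ_A = 1/(6D⊥), τ_B = 1/(5D⊥ + D∥), τ_C = 1/(2D⊥ + 4D∥) and amplitudes
A₁ = ((3cos²α−1)/2)², A₂ = 3cos²α·sin²α, A₃ = (3/4)sin⁴α for an NH vector
at angle α to the unique axis. Physical constants default to
r_NH = 1.02 Å and Δσ(¹⁵N) = −160 ppm (widely used defaults of
rotational-diffusion analysis software; both configurable). Correlation
times are exact arithmetic on the tensor eigenvalues; note that
eigenvalues rounded to three significant figures (1.39/1.30 × 10⁷ /s)
carry ~0.1 ns of uncertainty into τ_C, and quoted reference values for
this tensor (12.6 ns) differ from the recomputed 12.53 ns for exactly
that reason — the τ_C test tolerance is widened to ±0.1 ns accordingly.

Model-free models 1–5 (S²; S²,τe; S²,Rex; S²,τe,Rex; S²_f,S²,τe) are fit
per residue by bounded least squares, with τe carried in ns internally so
all free parameters are of order one, and with a small multi-start grid
per model. Selection uses the corrected Akaike information criterion;
with single-field data (n = 3 observables) the AICc small-sample
correction is undefined for k ≥ 2, so plain AIC is used for all models of
such residues — a deliberate deviation from χ²-ladder selection schemes,
chosen because it needs no simulated χ² tables and is reproducible.
Parameter errors come from 200 seeded Monte-Carlo redraws of the data
within their errors (count configurable). Error estimates entering the
fit are floored at 10⁻⁶ of the observable: noise-free synthetic data
otherwise produce near-zero covariance errors and pathological weighting.
Rex is assumed to scale with the square of the static field when records
from several fields are combined.

## CPMG dispersion

R₂,eff(ν) = −ln(I(ν)/I₀)/T_CPMG on constant-time schedules whose
frequencies must satisfy T·ν = even positive integer (whole echo blocks);
schedules are validated, never silently rounded, though the validation
tolerance (10⁻⁴ relative) admits values that round-tripped through
6-significant-figure report tables. Point-wise errors pool the standard
deviation over duplicated frequencies and are floored at 2% of R₂,eff,
the conventional allowance for off-resonance and other systematic
imperfections; profiles without duplicates fall back to the floor with a
warning, and non-positive R₂,eff points take the floor of the median
positive value.

The two-site engine propagates transverse magnetization through the
echo train with the complex 2×2 evolution matrix
L = [[−k_AB, k_BA], [k_AB, −k_BA + iΔω]]; ideal 180° pulses act as
complex conjugation, so one two-pulse unit (δ/2 − 180 − δ − 180 − δ/2) is
the complex-linear map E(δ/2)·conj(E(δ))·E(δ/2), applied T·ν times via
vectorized closed-form 2×2 exponentials and binary matrix powering. The
intrinsic rate R₂,₀ (assumed equal in both states — the standard choice
for sparse data) commutes with everything and enters additively. R₂,eff
is computed from the magnitude of the summed complex magnetization of
both states at the end of the interval. The propagator was cross-checked
during development against a naive step-by-step `scipy.linalg.expm`
propagation (agreement ~10⁻¹³).

The Carver–Richards closed form is implemented independently as a fast
initial-guess engine and as a test oracle. Its agreement with exact
propagation is ~0.1% in fast exchange but degrades with growing minor
population and slow exchange (measured: ~1.4% worst-case at p_B = 5%,
~4% at p_B = 20%, always worst at the lowest ν where the train has the
fewest echoes). The engine-equivalence test therefore sweeps the
dilute-minor-state regime (p_B = 0.5–2%, k_ex = 500–4000/s, |Δϖ| up to
5 ppm with Δω_rad ≤ k_ex), where worst-case disagreement is below 1%.

The global fit shares (k_ex, p_B) across all residues, one |Δϖ_N| in ppm
per residue across fields, and one R₂,₀ per residue per field. The sign
of Δϖ_N is not identifiable from CPMG alone and is stored as a magnitude.
Initial guesses come from a (k_ex, p_B) grid (100/300/1000/3000 /s ×
0.5/2/10%) with per-residue |Δϖ| scanned against Carver–Richards and
R₂,₀ profiled out analytically; the best grid start seeds a full
least-squares refinement against the Bloch–McConnell engine. Parameter
errors are taken from the covariance matrix (inverse of JᵀJ of the
σ-weighted residuals) at the optimum; a p_B error spanning zero flags the
fit unidentifiable. The significance screen keeps residues whose
dispersion amplitude is at least 3× the median σ (inclusive boundary) and
whose per-residue fast-exchange fit beats a flat model in an F-test at
p < 0.01 — a documented surrogate, since no universal criterion exists
for "measurable and significant" dispersion; both thresholds are
configurable and every exclusion is logged with its triggering rule.

## H/D exchange

Exchange rates are fit with the two-parameter mono-exponential on the
seven-point time course (0.3–17.9 h), with t = 0 at reconstitution and
the first point treated as data, not baseline. A series whose first
intensity is below 3× the noise level is `too_fast` (the threshold is a
documented choice for "exchanged before the first experiment"); a fitted
rate whose 95% confidence interval includes zero yields `lower_bound`,
reporting the CI upper limit on k_ex — hence a lower bound on
PF = k_int/k_ex. Protection bands are half-open and monotone:
PF < 10² unobservable, 10² ≤ PF < 2×10³ moderate, PF ≥ 2×10³ high. For
quantified records PF·p_open = 1 holds exactly by construction.

## Restraints and geometry

NOE classes follow the standard sequence-separation convention
(i = j intraresidual, |i−j| = 1 sequential, 1 < |i−j| < 5 medium,
|i−j| ≥ 5 long); ambiguous restraints form their own class and never
enter the separation classes. Hydrogen bonds contribute exactly two
restraints each (HN–acceptor 1.5–2.3 Å, N–acceptor 2.5–3.5 Å). Karplus
coefficients default to the quantitative-HNHA calibration
(A, B, C) = (6.51, −1.76, 1.60) Hz, configurable. Couplings within
max(1.0 Hz, 2·σ_J) of 7.0 Hz are excluded as rotamerically averaged (the
guard band is a documented surrogate for "sufficiently different");
otherwise the restraint centers on the β-region Karplus solution (nearest
−120°) for J > 7 Hz or the α-region solution (nearest −60°) for J < 7 Hz
— the branch choice is by J magnitude, since slow-exchange-free large
couplings are characteristic of extended backbone — with ±30° tolerance.

Backbone torsions use the standard four-atom dihedral; chain breaks and
missing atoms yield absent values. PPII runs require both Φ and Ψ within
±25° of (−75°, +120°) in at least half of the ensemble models over at
least 3 consecutive residues (window and run length configurable; the
window reflects the ≈ in "canonical" PPII geometry). Ensemble RMSD
superposes all models on their mean over the selected atoms (backbone =
N, CA, C, O — a common convention that can shift results by a few
hundredths of an Å relative to three-atom conventions), recomputes the
mean, and iterates to < 10⁻⁴ Å; reported as mean ± sd of per-model RMSD
to the converged mean.

The ideal-geometry backbone builder places N, CA, C, O atoms by natural
extension (NeRF) with standard bond lengths/angles and ω = 180°, and
realizes a requested (Φ, Ψ) script to well under 0.1°.

## Synthetic data: what it emulates and what it does not

Generators reproduce the acquisition schedules (11-point inversion
recovery 80–1200 ms and 10-point spin lock 10–100 ms, 3 duplicates each;
17-point T = 48 ms, 41.7–2000 Hz at 600 MHz and 14-point T = 40 ms,
50–1000 Hz at 800 MHz CPMG schedules with duplicates at the
lowest/median/highest frequency; the seven H/D time points) and the
documented parameter regimes (oblate tensor 1.39/1.30 × 10⁷ /s, i.e.
τ_iso = 12.3 ns; k_ex = 847/s, p_B = 1.63% with |Δϖ| uniform 0.5–6 ppm
and R₂,₀ uniform 8–20/s over 57 residues; protection factors spanning
10–3×10⁴). Only the extreme frequencies of the CPMG schedules are
documented; intermediate points are log-spaced and snapped to the nearest
valid whole-block frequency. The noise model is i.i.d. Gaussian on
intensities (or on R₂,eff at the 2% floor); real data additionally carry
correlated baseline and offset errors, peak overlap, and
heteroscedastic noise, so passing closed-loop tests demonstrates
correctness of the estimators under their stated model, not robustness
to every experimental artifact. The H/D "too fast" stratum pairs low
protection (PF ~ 10) with realistically fast intrinsic rates
(500–2000/h) so that the signal is gone before the first time point.
All generators are bit-deterministic under (seed, parameters).

## Problem sizes and numerical choices

The shipped closed-loop suites use 10–57 residues, chosen to match the
57-residue dispersion analysis and to keep the full test suite fast
(~1 min); the global dispersion fit on the full 57-residue two-field
dataset takes ~10 s through the vectorized propagator. Optimizers are
`scipy.optimize.least_squares` (trust-region reflective) with tight
tolerances (10⁻¹²–10⁻¹⁵) and explicit parameter scaling; ties and
boundary cases (inclusive screen boundary, half-open PF bands, altloc
ties resolved to first-encountered highest occupancy) are fixed
conventions stated at their definition sites.

## Known limitations

- Fully anisotropic (rhombic) diffusion tensors and reduced
  spectral-density mapping are not implemented.
- Three-site exchange, ¹H/multi-quantum dispersion, off-resonance and
  finite-width pulse effects are out of scope; 180° pulses are ideal.
- The tensor fit assumes rigid-limit ratios for the filtered core; small
  residual internal motion (S² ≈ 0.85–0.95 with short τe) biases the
  fitted correlation times downward by a few percent on realistic
  synthetic data — visible, and documented here, rather than corrected.
- EX1/EX2 discrimination is outside the PF ≈ 1/p_open interpretation
  used for H/D exchange; no pD corrections are applied.
- Quantities that depend on the unreleased experimental spectra (e.g.
  mean rates over a particular construct, the RMSD of fitted shift
  differences to a random-coil table) are supported as operations but
  are not reproduced as numbers by tests.
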