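# Methods

## The physical problem

A redox site buried in a protein (the motivating system is the heme of a
small electron-shuttling cytochrome) exchanges one electron with a partner.
In the Marcus picture the activation barrier of the half reaction
(ΔG₀ = 0) is fixed by a single reorganization energy, ΔG† = λ/4.  Two
observables, however, probe λ differently:

* **Stokes-shift reorganization energy** — half the separation of the mean
  vertical energy gaps of the two redox ensembles,
  λ^St = (⟨X⟩_Red − ⟨X⟩_Ox)/2;
* **variance reorganization energy** — the gap-fluctuation strength in one
  ensemble, λ_i = ⟨δX²⟩_i/(2k_BT), averaged as λ = (λ_Ox + λ_Red)/2.

Linear response plus full sampling forces λ^St = λ.  When they separate,
the barrier follows the three-parameter form ΔG† = λ^r/4 with
λ^r = (λ^St)²/λ, and the ratio κ_G = λ/λ^St > 1 measures how much the
barrier drops below the Marcus estimate *without* spending reaction free
energy.  This package implements the analysis showing that an electronically
**polarizable** active site — one whose ground state mixes with many excited
states through the bath electric field — drives κ_G up while barely moving
λ^St.

## Model

### Quantum centre

The site is a manifold of M+1 electronic states (default M = 100) per redox
form, each form carrying a total charge Q (−1 oxidized, −2 reduced).  Bath
electrostatics enter through the potential at the metal centre φ_Fe and the
bath field **E**_b (dipolar truncation of the bath-potential expansion):

    H_jj = E_j + Q φ_Fe − μ_jj·E_b
    H_jk = −ξ μ_jk·E_b        (j ≠ k)

in eV with charges in e, dipoles in e·Å, fields in V/Å.  The matrix is
diagonalized per frame; the gap coordinate is X = E_g^Red − E_g^Ox plus an
optional vacuum offset (default 0; it cancels from every reorganization
quantity).  The dimensionless factor ξ scales only the transition
(off-diagonal) dipoles, so ξ = 0 is the non-polarizable fixed-charge limit
while permanent dipoles, when present, remain coupled.  The permanent-dipole
diagonal term can be disabled via `include_permanent=False`; it is kept by
default because a field-coupled permanent dipole is part of the fixed-charge
electrostatics, not of the polarizability.

The sum-over-states polarizability of state k,
α_k = 2ξ² Σ_{m≠k} μ_km μ_km / (E_m − E_k), is reported as a tensor
(converted to Å³ with e²/4πε₀ = 14.3996 eV·Å) and as the isotropic scalar
trace/3; printed scalar values are interpreted as isotropic averages.  It
obeys α(ξ) = ξ²α(1) exactly, and the quadratic Stark shift −½E·α_k·E agrees
with exact diagonalization to second order in the field.

### Synthetic bath

Real inputs would be a long (hundreds of ns) MD trajectory of the solvated
protein and semi-empirical excited-state manifolds.  Both are replaced by
generators so the full analysis runs in minutes:

* φ_p and φ_w (protein and water potentials) are sums of stationary
  Ornstein–Uhlenbeck modes with the exact AR(1) discretization
  x_{i+1} = m + (x_i − m)e^{−dt/τ} + σ√(1 − e^{−2dt/τ}) η_i, so means,
  variances and autocorrelations are exact at any dt;
* the slowest protein and water modes are driven by jointly Gaussian
  innovations with correlation ρ_pw (strongly negative by default),
  reproducing the interfacial-water compensation that concentrates at low
  frequency;
* each Cartesian field component is an independent OU sum with identical
  statistics in both ensembles (zero mean), so the field contributes
  fluctuation but no Stokes shift;
* the Ox and Red ensembles differ by their means, applied on top of
  seed-reproducible noise; per-component seeds derive from the base seed
  plus CRC32("ensemble:component"), a scheme that is frozen so the two
  ensembles are independent yet reproducible.

`linear_response_spec` inverts the construction: given targets
(λ^St, λ) it returns a spec whose classical gap X = Δq·φ_fe has variance
2k_BTλ in each ensemble and mean separation 2λ^St (means placed at ∓λ^St
with the protein/water carrying opposite-signed shares, +1.5×/−0.5×).  The
protein:water:cross variance ratio is fixed at 2.28 : 3.39 : −4.0
(normalized to 1.67), the decomposition observed for the oxidized ensemble
of the motivating system; 85% of each component's variance sits in the
slowest mode and the cross-correlation of the slow pair closes the budget
(ρ ≈ −0.85).  With λ^St = λ the bath satisfies the fluctuation–dissipation
relation (a Marcus bath); other choices deliberately violate it.

State manifolds are generated with excitation energies from a shifted
exponential, E_m = gap_scale·(0.25 + Exp(1)) (gap_scale default 2 eV, the
scale of low-lying heme excitations), i.i.d. symmetric transition dipoles
and zero permanent dipoles, rescaled once so the ground-state isotropic
polarizability at ξ = 1 hits a target exactly.

### Reference study conditions

The reference system (`polarsite.pipeline`) fixes, once:
α_Ox = 85 / α_Red = 54 Å³ at ξ = 1 (Δα = −31 Å³), M = 100;
bath targets λ^St = 1.24 eV, λ = 1.675 eV at ξ = 0; relaxation times
(0.2, 2, 20) ps at dt = 0.25 ps; field σ = 0.3 V/Å per component with
τ = 2 ps; T = 300 K (the generator's configurable default).  The
polarizability targets and λ^St are the magnitudes characteristic of heme
-protein electron transfer; the field amplitude is in the range of interior
protein fields and makes the Stark-induced gap variance comparable to the
fixed-charge variance at ξ = 1.  The default trajectory length is 2×10⁴
frames (5 ns of synthetic time), the problem size at which all pipeline
statistics in the tests are quoted.

Mechanism, in these conditions: the ground-state Stark shifts
−½ξ²α_{Ox/Red}E² fluctuate with E², adding variance ∝ ξ⁴ to X (both
ensembles), while their difference −½ξ²Δα⟨E²⟩ is a common constant that
cancels from λ^St.  Hence λ − λ^St and κ_G rise steeply along ξ ∈ {0, 1, 2}
while λ^St is nearly flat.

## Estimators and numerical choices

* **Variances** are population (1/N) moments; convergence is exposed by
  batch-means standard errors over 10 contiguous blocks rather than i.i.d.
  formulas, since the gap is strongly autocorrelated.
* **Free-energy surfaces** F_i = −k_BT ln P_i use a shared uniform grid over
  the joint sample range; empty bins are NaN (never −∞); parabolas are fit
  by count-weighted least squares over bins with ≥ 10 samples (unweighted
  log-scale fits are dominated by noisy tails); the transition state is the
  fitted-parabola crossing between the two vertices.
* **Autocorrelation** uses the biased (1/N) FFT estimator: it guarantees
  non-negative spectral mass; c[0] equals the population variance exactly.
* **Loss spectra**: C_X(ω) is the one-sided cosine transform counted twice
  (full Fourier transform of the even extension), so a single Debye mode
  gives χ″(ω) = 2λωτ/(1+ω²τ²) with peak value λ at ω = 1/τ and sum rule
  (1/π)∫χ″/ω dω = λ.  The transform integrates the piecewise-linear
  interpolant of C_X(t) analytically (Filon-type), keeping the relative
  quadrature error ~(dt/τ)² at all frequencies where plain trapezoid
  integration fails once ω·dt ≳ 1.  The measured correlation is truncated
  at the first lag statistically indistinguishable from zero (|ρ| below
  twice its Bartlett standard error) and extended by an analytic
  single-exponential tail fitted to the closing half of the resolved window
  (`tail="fit"`, default; `"truncate"` and `"none"` are available).
  Frequencies are reported as ν with ω = 2πν.
* **Debye fits** are bound-constrained (amplitudes ≥ 0) nonlinear least
  squares with deterministic multi-start over log-spaced relaxation-time
  initializations; modes are returned sorted by τ.
* **Gaussianity**: Γ(t) = [⟨δX²(t)δX²(0)⟩ − ⟨δX²⟩² − 2C_X(t)²]/⟨δX²⟩²
  vanishes under Wick factorization; series shorter than 10⁴ frames are
  flagged unreliable, constant series return NaN with a warning.
* **Rounding**: comparisons against printed one-decimal κ_G values use
  half-up decimal rounding (numpy's bankers rounding would differ on ties).
* **Eigen-solver**: full symmetric diagonalization (`eigvalsh`), batched
  over frames in fixed-size chunks purely for speed; results are
  chunking-independent and frames are statelessly permutable.  Degenerate
  ground states are allowed (the minimum eigenvalue remains well defined);
  degenerate state pairs with nonzero transition dipoles make the
  sum-over-states polarizability undefined and raise an error naming the
  pair.

## What the synthetic data does and does not show

The generators reproduce the *statistical* structure the analysis assumes:
Gaussian multi-timescale bath fluctuations, protein–water anticorrelation,
linear-response mean shifts, and manifolds with realistic polarizability
magnitudes.  Passing tests therefore validate the estimators and the
mechanism (polarizability separates λ from λ^St and suppresses the shared
slow band of χ″) — they do not validate force fields, sampling of a real
protein's rugged landscape, conformational gating, non-Gaussian bath
statistics, or the absolute reorganization energies of any particular
protein.  Induction (bath-polarizability) corrections, redox potentials
(ΔG₀ ≠ 0 barriers) and electronic couplings are deliberately out of scope.

## Known limitations

* The cross-correlation construction is exact only when the paired slow
  modes share a relaxation time (as the default specs do); unequal times
  give an innovation—not stationary—correlation of ρ.
* `barriers` supports ΔG₀ = 0 only and raises otherwise.
* Per-component reorganization energies constrain but do not determine the
  mode-by-mode variance partition; the 85% slow-mode fraction is a stated
  default, not an inference.
* The Debye-fit error report is a residual norm; no parameter covariance is
  returned.
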