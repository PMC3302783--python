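# Methods

This note documents the models behind `ionsite`, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Alchemical free energies

The interaction free energy ΔG_int of a bound ion is the free-energy change
of the coupled transformation "bound ion → bulk water" taken with the
binding sign convention. Two estimators consume per-window sample series:

**Thermodynamic integration.** ΔG = ∫₀¹ ⟨∂U/∂λ⟩_λ dλ is evaluated with a
seven-point Gauss–Legendre rule mapped to [0, 1] by λ = (x+1)/2,
w = w_GL/2. The rule is exact for polynomial integrands up to degree 13;
for smooth non-polynomial integrands (such as the harmonic benchmark's
rational integrand) its intrinsic error is ~10⁻⁵ on the kcal/mol scale —
far below any statistical error of interest. Node means are combined as
Σ wᵢ·meanᵢ with error √(Σ wᵢ² semᵢ²), treating nodes as independent
simulations.

**Free-energy perturbation.** Per window (λ_lo, λ_hi),
ΔG_w = −k_BT ln⟨exp(−ΔU/k_BT)⟩, computed through log-sum-exp so large |ΔU|
cannot overflow. The default schedule is 20 uniform windows — denser than
the 7 TI nodes, mirroring the usual practice of spacing FEP windows more
closely; it is configurable. A backward pass traverses λ 1→0, so its path
value is −ΔG(0→1); because exponential averaging is nonlinear, samples
cannot be sign-flipped — orientation is an explicit estimate-level step
(`oriented_forward`) before forward/backward averaging. TI needs no such
step: both passes integrate the same ⟨∂U/∂λ⟩.

**Errors and convergence.** Statistical errors use block averaging:
contiguous non-overlapping blocks (default 50 ps, converted to sample
counts; a trailing partial block is dropped), SEM = sd(block means)/√n.
For FEP the block SEM of exp(−ΔU/k_BT) is pushed through the logarithm by
the delta method (err = k_BT·sem/mean) and combined in quadrature across
windows — a pragmatic recipe, adequate away from the strongly skewed
regime. Inside `ti_integrate`, a node too short for two complete blocks
falls back to the naive sd/√n so that degenerate fixtures remain
computable; `block_error` itself refuses < 2 blocks. Convergence is
declared when the running average over the final 20% of samples stays
within 0.5 kcal/mol of its end value; hysteresis |ΔG_f − ΔG_b| is flagged
when it exceeds 2·√(e_f² + e_b²). Both thresholds are conventions chosen
here — flattening running averages and "no significant forward/backward
difference" are the qualitative criteria they encode.

Constants: k_B = 0.0019872041 kcal/mol/K; default T = 300 K.

## Standard-state entropy correction

ΔG_tr = −k_BT ln[(2πe)^{3/2} σx σy σz / V₀], V₀ = 1660 Å³, models the bound
ion as a 3-D Gaussian: (2πe)^{3/2}σxσyσz is the Gaussian's effective volume
and the correction vanishes when it equals the standard-state volume. From
raw positions, σ are by default the square roots of the covariance
eigenvalues (principal-axis frame), which makes ΔG_tr rotation-invariant;
lab-frame per-axis σ are available since the formula is often quoted that
way. Positions are centred on their mean with no detrending — a drifting
"bound" ion violates the model and should be caught upstream. No error bar
is attached to ΔG_tr, matching how such corrections are usually tabulated.
ΔG_b = ΔG_int + ΔG_tr is exact bookkeeping; the ΔG_int error passes
through, and ΔΔG comparisons combine errors in quadrature.

## Coordination shells

For each candidate ligand oxygen the per-frame ion–oxygen Euclidean
distance is summarised as mean ± sd (sample sd, n−1; reported as NaN for a
single frame). Shell membership is mean ≤ cutoff with a 3.0 Å default: Na⁺–O
coordination distances cluster at 2.1–2.4 Å while non-coordinating oxygens
sit at ≥ 3.5 Å, so 3.0 Å separates the two groups with maximal margin. A
water candidate is scored against the nearest water oxygen in each frame
(bulk water exchanges, so no fixed atom stays coordinated). No
minimum-image correction is applied: the analysis targets pocket-scale
distances far below any box dimension and inputs are assumed pre-wrapped.
Displacement analysis (mean/max distance of an atom from its reference
position) performs no superposition; inputs are assumed pre-aligned.
Report tables display one decimal, rounding halves away from zero.

## Kinetics

Initial rates are the OLS slope over the longest initial prefix (≥ 3
points) whose linear fit reaches R² ≥ 0.98, falling back (flagged) to the
first three points. Note the inherent secant bias: for a saturating curve
A(1−e^{−kt}) sampled out to kt ≈ 0.5, the whole curve can satisfy the R²
criterion and the slope then underestimates the true t→0 rate A·k by
~20%; tightening R² trades this bias for noise sensitivity.

Saturation fits minimise residuals of the unnormalised response
I = Imax·Sⁿ/(Sⁿ + K₀.₅ⁿ) with Imax free (fitting a pre-normalised curve
would be circular). Multi-start initialisation covers K₀.₅ at the geometric
quartiles of the concentration grid and n ∈ {0.5, 1, 2, 3}; bounds keep
n ∈ [0.05, 10]. Standard errors are asymptotic (Jacobian-based) — they
describe the single-dataset fit, not between-experiment scatter. A fit is
reported non-converged when K₀.₅ exceeds the highest tested concentration
or any parameter error is unbounded: non-saturating data cannot constrain
the plateau, the situation seen with strongly Na⁺-affinity-impaired
mutants.

## Synthetic data: what it does and does not show

The generators define the test conditions for the whole pipeline:

- **Harmonic alchemy** (`gen_harmonic_ti`/`gen_harmonic_fep`): U(λ,x) =
  ½k(λ)x², k(λ) = (1−λ)k₀+λk₁, so ⟨∂U/∂λ⟩ = (k₁−k₀)k_BT/2k(λ) and
  ΔG = n_dof·(k_BT/2)·ln(k₁/k₀) exactly. Defaults k₀ = 1, k₁ = e² give
  ΔG = k_BT. Temporal correlation is AR(1) on the coordinate (mean-preserving,
  unit marginal variance) — the simplest process that makes block averaging
  non-trivial; 10⁴ samples per node at 0.1 ps spacing emulate a 1 ns
  production window with 50 ps blocks (20 blocks/node).
- **Bound-ion clouds**: exact axis-aligned Gaussians — the entropy
  formula's own model, so these tests validate implementation, not the
  Gaussian assumption itself.
- **Coordination trajectories**: ligand oxygens on fixed random directions
  with Gaussian radial jitter about chosen means; waters re-drawn each
  frame so nearest-water identity exchanges. 1000 frames at 1 ps emulate a
  1 ns analysis window.
- **Kinetics**: Hill curves with additive Gaussian noise (default truth
  K₀.₅ = 3.9 mM, n = 2.3, Imax = 7.5 — a wild-type-like Na⁺ dependence —
  at 5% of Imax noise on 8 concentrations spanning 0.1–300 mM); saturating
  exponential uptake curves.

Passing on these fixtures shows the estimators are correct and calibrated
under their stated assumptions (stationarity, Gaussian confinement,
short-memory noise). It does not show robustness to real-data pathologies:
slow conformational drift, non-Gaussian tails in ΔU, anharmonic or
multi-well ion binding, or heteroscedastic assay noise.

## Problem sizes and determinism

Validation workloads are sized for desk-scale runs: 10⁴ samples/node for
TI recovery, 10⁵ samples for single-window FEP and entropy sampling, 200
replicates for SEM-coverage calibration (±1 SEM should cover truth ≈ 68%
of the time; the check accepts 60–75%) and 200 replicate Hill fits. Every
stochastic path flows from one `numpy.random.Generator` per call, seeded
explicitly; identical seeds reproduce byte-identical datasets.

## Known limitations

- No BAR/MBAR estimators; TI and FEP only, with nodes treated as
  independent when combining errors.
- The PDB/XYZ layer handles pocket-scale analysis, not general topology
  (no bonds, elements, or binary trajectory formats); altloc handling keeps
  ''/'A' and warns.
- Hill fits pool replicates rather than weighting them; experiment-level
  s.e.m. is out of reach without raw replicates.
- The entropy correction covers translational confinement only — no
  rotational or conformational terms.
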