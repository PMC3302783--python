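# ionsite

Ion binding-site energetics and transporter kinetics in Python.

`ionsite` implements the computational workflow used to locate and validate
ion-binding sites in membrane transporters — such as the third Na⁺ site of
the archaeal aspartate transporter Glt_Ph and its human glutamate-transporter
homologues — from three directions at once:

1. **Alchemical binding free energies.** The interaction (translocation)
   free energy ΔG_int of a bound ion is estimated from per-λ-window sample
   series by thermodynamic integration,
   ΔG = ∫₀¹ ⟨∂U/∂λ⟩ dλ, evaluated with a seven-point Gauss–Legendre
   quadrature, and independently by free-energy perturbation (Zwanzig
   exponential averaging) over windows tiling [0, 1]. Forward and backward
   transformations are averaged; their discrepancy (hysteresis) is flagged
   when it exceeds twice the combined statistical error. Errors come from
   block averaging (50 ps blocks by default) and convergence is diagnosed
   from the flatness of running averages.
2. **Standard-state correction and composition.** The total binding free
   energy is ΔG_b = ΔG_int + ΔG_tr, where
   ΔG_tr = −k_BT·ln[(2πe)^{3/2}σxσyσz/V₀] accounts for the translational
   entropy lost on confinement, with V₀ = 1660 Å³ the 1 M standard-state
   volume and σ the rms fluctuations of the bound ion. Site-vs-site and
   wild-type-vs-mutant comparisons are plain ΔΔG differences with errors in
   quadrature.
3. **Coordination shells and kinetics.** Trajectories (multi-model PDB or
   XYZ) are reduced to per-ligand ion–oxygen mean ± sd distance tables with
   cutoff-based shell classification; uptake time courses yield initial
   rates from their linear portion; and concentration–response data are fit
   to the Hill equation I/I_max = [S]ⁿ/([S]ⁿ + K₀.₅ⁿ) (Michaelis–Menten for
   n = 1) by multi-start nonlinear least squares.

Because raw MD trajectories and laboratory traces are rarely published, a
first-class synthetic-data module generates every input class with exact
ground truth (a harmonic oscillator with closed-form ΔG, Gaussian bound-ion
clouds, jittered coordination geometries, noisy Hill curves), which is how
the whole pipeline is tested.

## Worked example

```python
from ionsite import (HarmonicAlchemySpec, LambdaSchedule, combine_forward_backward,
                     gen_harmonic_ti, ti_integrate)

schedule = LambdaSchedule.gauss7()
spec = HarmonicAlchemySpec(samples_per_node=10_000, ar1_phi=0.5, seed=0)
fwd, bwd, true_dg = gen_harmonic_ti(spec, schedule)
ti = combine_forward_backward(ti_integrate(fwd, schedule), ti_integrate(bwd, schedule))
print(f"exact {true_dg:+.4f}   TI {ti.value:+.4f} ± {ti.error:.4f}   "
      f"hysteresis {ti.hysteresis:.4f}")
```

prints

```
exact +0.5962   TI +0.5954 ± 0.0033   hysteresis 0.0014
```

i.e. on a benchmark whose exact answer is k_BT = 0.5962 kcal/mol, the TI
estimate lands within one block-averaged standard error and the
forward/backward passes agree (no hysteresis flag). The
`examples/` directory contains one narrative script per capability
(free-energy pipeline, entropy correction, coordination shell, kinetics);
each builds a small input, runs the method and explains its printout.

A thin CLI mirrors the library for shell use:

```bash
ionsite simulate ti --out work --seed 0
ionsite ti work/ti_forward.tsv work/ti_backward.tsv
ionsite coord traj.pdb --ion A:900:NA --ligands ligands.yaml --cutoff 3.0
ionsite kinetics fit saturation.csv --model hill
```

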