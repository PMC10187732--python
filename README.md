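# hpcg — HP/HP+ heteropolymer phase-behavior toolkit

`hpcg` simulates and analyzes coarse-grained heteropolymers built from
hydrophobic (H) and polar (P) monomers, a minimal model for intrinsically
disordered proteins (IDPs) and their liquid–liquid phase separation. It is
aimed at researchers studying how the *strength* versus the *localization*
of attractive interactions controls single-chain ensembles, chain–chain
association, and condensate formation.

## The model

Bead-spring chains (σ = 0.5 nm, m = 100 g/mol, harmonic bonds
k_b = 2000 kcal/(mol nm²), r₀ = 0.38 nm) interact through an
Ashbaugh–Hatch scaled Lennard-Jones potential in which a pair hydropathy
λ_ij scales only the attractive branch:

    U(r) = U_LJ(r) + (1 − λ_ij) ε    for r ≤ 2^{1/6} σ
         = λ_ij U_LJ(r)              for 2^{1/6} σ < r ≤ 4σ

with ε = 0.2 kcal/mol (well depth ≈ 0.34 k_BT at 300 K). λ_PP = 0 always;
two variants differ in the H–P cross term:

* **HP**: λ_HP = 0 — strong *localized* attraction (H–H contacts only);
* **HP+**: λ_HP = λ_H/2 — weak *distributed* attraction (H–P too).

Chains of length N = 20 are generated over a grid of polar fraction
X_P ∈ {0, 0.05, …, 1}. For each sequence the H hydropathy is set to
λ_H = a/(1 − X_P), and the scaling factor *a* is calibrated so the
single-chain ⟨R_g⟩ matches the purely hydrophobic reference (X_P = 0,
λ_H = 1). On top of this calibrated, single-chain-matched footing the
package quantifies:

* single-chain ensembles — ⟨R_g⟩, P(R_g), shape anisotropy ⟨κ²⟩,
  nonbonded energy U_nb, end-to-end relaxation τ_e, intrachain scaling ν;
* two-chain interactions — umbrella-sampled potential of mean force w(r)
  with a WHAM combiner, an independent Mayer-sampling oracle, and the
  second virial coefficient B22 = −2π∫[e^{−w/kT} − 1] r² dr;
* phase behavior — direct-coexistence slab simulations, z-concentration
  profiles with tanh coexistence fits, slab/cluster/homogeneous
  classification, H–H g(r), chain cluster-size distributions P(N_c), and
  the composition threshold X_P* above which no bulk condensate forms.

Dynamics are Langevin (BAOAB, dt = 10 fs, γ = 0.1 g/(mol fs), 300 K) with
numba-compiled kernels; given a seed, runs are bit-reproducible.

## Worked example

Calibrate an HP-model sequence with 25% polar monomers against the
hydrophobic reference and inspect its ensemble:

```python
from hpcg import (generate_sequence, build_single_chain, run_langevin)
from hpcg.calibrate import reference_Rg, match_rg
from hpcg.forcefield import default_forcefield, scaled_lambda_H
from hpcg.chain_obs import chain_ensemble_stats

ref = reference_Rg("HP", seed=11, n_steps=2_000_000)
print(f"reference <Rg> = {ref[0]:.3f} +/- {ref[1]:.3f} nm")

seq = generate_sequence(20, 0.25, seed=101)          # HHPHPHPHHHHHPHHHPHHH
cal = match_rg(seq, "HP", ref, seed=11, n_steps=1_000_000)
print(f"a = {cal.a:.3f}  lambda_H = {cal.lambda_H:.3f}  "
      f"<Rg> = {cal.achieved_Rg:.3f} nm  rel. dev. = {cal.rel_dev:.1%}")

ff = default_forcefield("HP", scaled_lambda_H(cal.a, 0.25))
traj = run_langevin(build_single_chain(seq, seed=1), ff, 2_000_000,
                    sample_every=2_000, seed=1).discard(0.1)
stats = chain_ensemble_stats(traj, ff=ff)
print(f"kappa2 = {stats.kappa2:.3f}   U_nb = {stats.U_nb_mean:.2f} kcal/mol")
```

Output from this exact snippet:

```
reference <Rg> = 0.936 +/- 0.009 nm
a = 1.125  lambda_H = 1.500  <Rg> = 0.962 nm  rel. dev. = 2.8%
kappa2 = 0.405   U_nb = -3.82 kcal/mol
```

Read: matching ⟨R_g⟩ for this sequence requires amplifying the H–H
attraction beyond composition compensation (a > 1, the HP-model
signature), and the calibrated chain's shape (κ² ≈ 0.40, close to the
random-walk value) stays close to the reference —
the central single-chain observation the package is built to probe.

The same stages are scriptable from the shell via the `hpc` command
(`generate`, `simulate`, `tune`, `stats`, `coex`, `b22`, `cluster`,
`scan`, `report`); `hpc report --config campaign.yaml --seed 1 --out out/`
runs the whole pipeline and stamps every artifact with the config hash.
Full-size coexistence campaigns (500 chains, 10 × 10 × 75 nm, 1 μs per
state point) take hours per composition on one core; the test suite and
the examples use scaled-down geometries (see `docs/methods.md`).

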