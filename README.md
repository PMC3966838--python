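# qsfr

Quantitative Stability/Flexibility Relationships (QSFR) for protein
structures via the Distance Constraint Model (DCM): body-bar constraint
networks, exact pebble-game rigidity analysis, free-energy landscapes and
melting curves, per-bond flexibility profiling, and cluster-weighted
statistical comparison of structural ensembles (wild type vs mutants).

## The problem

How a mutation redistributes rigidity and flexibility through a protein is
not predictable from local chemistry: hydrogen-bond networks are long-range
mechanical objects, and a stabilizing substitution can rigidify its own
neighborhood while loosening loops on the far side of the molecule.  This
package implements the machinery to quantify that redistribution.

## The model

Each atom is a rigid body with 6 degrees of freedom; interactions are edges
carrying *bars* (5 for rotatable covalent bonds and H-bonds, 6 for locked
bonds, +1 for a packing torsion).  A **(6,6) body-bar pebble game** decides
exactly which constraints are independent and decomposes the network into
rigid clusters, flexible regions (with H hinges and A independent DOFs) and
over-constrained regions (with B redundant bars among L locked bonds).

A macrostate is a count pair (N_hb, N_nat): hydrogen bonds present and
torsions in the native (packed) state.  Constraint topologies are sampled
uniformly within each macrostate and the pebble game, run with constraints
placed in order of ascending component entropy, yields the averaged
q-values that attenuate the conformational entropy:

    S_conf = R [ Σ_t γ_t q̄_t p_t + δ_nat q̄_nat N_nat + δ_dis q̄_dis (N_tor − N_nat) ]

    G(N_hb, N_nat; T) = U + u_sol (N_hb^max − N_hb) + v_nat N_nat
                        − T (S_conf + S_mix)

Boltzmann weighting of the macrostate grid gives the heat capacity from
enthalpy fluctuations, C_p = Var[H]/(R T²), the melting temperature T_m at
its peak, and the native basin over which the mechanical metrics are
averaged.  The three phenomenological parameters {u_sol, v_nat, δ_nat} are
fit to experimental heat-capacity curves.

Per rotatable bond, the **Flexibility Index** is the ensemble average of
f = h − l (h = A/H in its flexible region, l = B/L in its over-constrained
region) and the **Cooperativity Correlation** matrix records which backbone
bond pairs are co-flexible (+h), co-rigid (−l) or uncoupled (0).

Ensembles of frames are clustered on CA+CB RMSD; the most populated
clusters contribute representative structures, and mutant-vs-wild-type
differences are scored per residue with the cluster-weighted Z-score

    Z = (x̄_m − x̄_w) / sqrt((σ_m² + σ_w²)/N_rep),

positive for increased flexibility in the mutant, classified at |Z| > 2.33
(moderate, one-sided p = 0.01) and |Z| > 3.33 (large, p = 0.0005).

## Worked example

A 12-residue ideal α-helix from the built-in generator, analyzed end to
end:

```python
import numpy as np
from qsfr import (DCMParams, build_network, detect_hbonds, analyze,
                  build_tables, heat_capacity, native_basin, qsfr_profiles)
from qsfr.synthetic import PeptideEnsembleSpec, make_peptide_ensemble

ens = make_peptide_ensemble(PeptideEnsembleSpec(n_residues=12, fold="helix"))
frame = ens.frame(0)
frame.bonds = ens.frames.bonds

hbonds = detect_hbonds(frame)                  # geometric criteria + energies
network = build_network(frame, hbonds)         # body-bar constraint network
print(f"{network.n_bodies} atoms, {network.n_hb_max} H-bonds, "
      f"{network.n_tor} rotatable torsions")

rigidity = analyze(network)                    # pebble game, all H-bonds on
print(f"internal DOFs F = {rigidity.F}, redundant bars B = {rigidity.B}")

params = DCMParams()                           # u_sol=-2.71, v_nat=-0.89, δ_nat=1.89
tables = build_tables(network, params, n_samples=50, seed=0)
curve = heat_capacity(tables, params, np.arange(100.0, 600.0, 2.0))
print(f"T_m = {curve.tm:.0f} K")

basin = native_basin(tables, params, curve.tm)
fi, cc = qsfr_profiles(network, tables, params, curve.tm, basin,
                       n_samples=25, seed=1)
print(fi.by_residue().head(4).to_string(index=False))
```

prints

```
71 atoms, 8 H-bonds, 23 rotatable torsions
internal DOFs F = 3, redundant bars B = 20
T_m = 296 K
chain  res_id        fi
    A       1  0.161276
    A       2 -0.860462
    A       3 -0.894106
    A       4 -0.911722
```

With every i→i+4 hydrogen bond formed the helix interior is over-constrained
(negative FI: more redundant constraints than hinge freedom), while the
chain termini keep residual flexibility (residue 1 has FI > 0) — the
canonical fraying pattern.  The melting temperature of such a short,
solvent-free model helix is low, as expected.

The command line mirrors the library:

```sh
qsfr simulate --config helix.yaml --out wt.pdb
qsfr compare --wt wt.pdb --mut mut.pdb --config run.yaml --out report/
```

producing Z-score tables, classification counts, H-bond-network diffs and a
JSON run manifest.

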