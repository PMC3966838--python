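"""Validation studies: each function runs one self-contained check of the
package against an independent oracle or closed form, at desk scale.

These are the studies the test suite and the reproduction script execute:
pebble game vs rigidity-matrix ranks, the preferential-order entropy bound,
the engineered half-independent q_nat case, Z-threshold tail probabilities,
the two-state heat-capacity closed form, parameter recovery from synthetic
C_p data, the planted-mutation comparison and the occupancy class mapping.
"""

from __future__ import annotations

import warnings

import numpy as np

from .compare import (
    occupancy_class,
    odds_reciprocal,
    tail_probability,
    hbond_occupancy,
)
from .network import ConstraintNetwork
from .oracle import rank_analysis
from .pebble import analyze, preferential_order
from .pipeline import RunConfig, compare_ensembles
from .synthetic import (
    PeptideEnsembleSpec,
    SyntheticCpSpec,
    ToyFrameworkSpec,
    make_cp_curve,
    make_half_independent_network,
    make_peptide_ensemble,
    make_toy_framework,
    make_two_state_network,
)
from .thermo import (
    DCMParams,
    Macrostate,
    R_KCAL,
    build_tables,
    fit_parameters,
    heat_capacity,
    sample_topologies,
)

__all__ = [
    "random_framework",
    "pebble_oracle_study",
    "entropy_bound_study",
    "q_nat_half_study",
    "z_threshold_study",
    "two_state_study",
    "parameter_recovery_study",
    "planted_mutation_study",
    "occupancy_class_study",
]


def random_framework(rng: np.random.Generator) -> ConstraintNetwork:
    """A random small body-bar framework (parallel edges allowed)."""
    n = int(rng.integers(2, 9))
    m = int(rng.integers(1, n * (n - 1) // 2 + 3))
    edges = []
    while len(edges) < m:
        i, j = rng.integers(0, n, 2)
        if i != j:
            edges.append((min(i, j), max(i, j)))
    spec = ToyFrameworkSpec(
        n_bodies=n,
        topology=edges,
        bars_per_edge=int(rng.integers(1, 7)),
        gamma=("uniform", 0.1, 2.0),
        seed=int(rng.integers(0, 2**31)),
    )
    return make_toy_framework(spec)


def pebble_oracle_study(n_frameworks: int = 500, seed: int = 0) -> dict:
    """Pebble game vs randomized rigidity-matrix rank oracle.

    Compares internal DOFs F, redundant bar count B and the rigid-cluster
    partition on random frameworks of at most 8 bodies.
    """
    rng = np.random.default_rng(seed)
    matches = 0
    for k in range(n_frameworks):
        net = random_framework(rng)
        pg = analyze(net)
        orc = rank_analysis(net, seed=int(rng.integers(0, 2**31)))
        if pg.F == orc.F and pg.B == orc.B and orc.same_partition(pg.cluster_of):
            matches += 1
    return {
        "agreement_pct": 100.0 * matches / n_frameworks,
        "n": n_frameworks,
    }


def entropy_bound_study(
    n_networks: int = 30, n_orders: int = 100, seed: int = 0
) -> dict:
    """Preferential placement must never exceed random placements in the
    entropy-weighted independent set (the lowest-upper-bound property)."""
    rng = np.random.default_rng(seed)
    violations = 0
    comparisons = 0
    for _ in range(n_networks):
        net = random_framework(rng)
        topo = net.full_topology()
        gammas = np.array([c.entropy for c in topo.constraints])
        pref = analyze(topo, preferential_order(topo), want_regions=False)
        s_pref = float(gammas @ pref.q)
        for _ in range(n_orders):
            order = rng.permutation(len(topo.constraints))
            res = analyze(topo, list(order), want_regions=False)
            comparisons += 1
            if s_pref > float(gammas @ res.q) + 1e-12:
                violations += 1
    return {"violations": violations, "n": comparisons}


def q_nat_half_study(n_samples: int = 50, seed: int = 0) -> dict:
    """Engineered topology where exactly half the native torsions are
    independent in every sampled network, so qbar_nat = 0.5."""
    net = make_half_independent_network()
    sample = sample_topologies(
        net, Macrostate(0, 2), n_samples=n_samples, seed=seed
    )
    return {"q_nat": sample.qbar_nat, "n": n_samples}


def z_threshold_study() -> dict:
    """One-sided normal tails at the moderate/large Z thresholds."""
    return {
        "p_at_2.33": tail_probability(2.33),
        "odds_reciprocal_at_3.33": odds_reciprocal(3.33),
    }


def two_state_study(grid_step: float = 1.0) -> dict:
    """Two-macrostate toy: C_p peak at T = dH/dS, height dH^2/(4 R T_m^2).

    The single-torsion network has exactly two macrostates; a large
    enthalpy/entropy gap keeps the finite-gap corrections to the two-state
    closed form well inside the tolerances.
    """
    net = make_two_state_network()
    params = DCMParams(u_sol=-2.71, v_nat=-42.0, delta_nat=1.0, delta_dis=61.0)
    d_h = abs(params.v_nat)
    d_s = R_KCAL * (params.delta_dis - params.delta_nat)
    tm_theory = d_h / d_s
    grid = np.arange(tm_theory - 60.0, tm_theory + 60.0, grid_step)
    curve = heat_capacity(net, params, grid, n_samples=5, seed=1)
    peak_theory = d_h**2 / (4.0 * R_KCAL * tm_theory**2)
    return {
        "tm_theory": tm_theory,
        "tm_measured": curve.tm,
        "tm_error_K": abs(curve.tm - tm_theory),
        "grid_step": grid_step,
        "peak_theory": peak_theory,
        "peak_measured": float(curve.cp.max()),
        "peak_ratio": float(curve.cp.max()) / peak_theory,
    }


def parameter_recovery_study(seed: int = 0, n_samples: int = 48) -> dict:
    """Fit {u_sol, v_nat, delta_nat} to a synthetic C_p curve (2% peak
    noise) generated by the model itself on a small helix network."""
    ens = make_peptide_ensemble(PeptideEnsembleSpec(10, "helix", 1))
    frame = ens.frame(0)
    frame.bonds = ens.frames.bonds
    from .network import build_network, detect_hbonds

    net = build_network(frame, detect_hbonds(frame))
    true = DCMParams()
    tables = build_tables(net, true, n_samples=n_samples, seed=seed + 3)
    grid = tuple(np.arange(100.0, 601.0, 1.0))
    clean = heat_capacity(tables, true, np.array(grid))
    spec = SyntheticCpSpec(
        true, grid, noise_sd=0.02 * float(clean.cp.max()), seed=seed + 7
    )
    curve = make_cp_curve(spec, net, tables=tables)
    x0 = DCMParams(true.u_sol * 1.25, true.v_nat * 0.75, 1.70)
    # synthetic curves live on the model's absolute scale, so no nuisance
    # baseline/amplitude alignment is fitted here
    fit = fit_parameters(
        tables, curve, x0=x0, align="none", n_restarts=5, seed=seed + 1
    )
    p = fit.params
    errs = {
        "u_sol_error_pct": 100.0 * abs(p.u_sol - true.u_sol) / abs(true.u_sol),
        "v_nat_error_pct": 100.0 * abs(p.v_nat - true.v_nat) / abs(true.v_nat),
        "delta_nat_error_pct": 100.0
        * abs(p.delta_nat - true.delta_nat)
        / abs(true.delta_nat),
    }
    return {
        "true_tm": clean.tm,
        "fit_tm": fit.tm,
        "tm_error_K": abs(fit.tm - clean.tm),
        "max_param_error_pct": max(errs.values()),
        **errs,
    }


def planted_mutation_study(seed: int = 0) -> dict:
    """Wild-type vs mutant helices differing by one designed H-bond.

    The suppressed bond (donor residue 14, acceptor residue 10) should raise
    |Z| above the moderate threshold inside the perturbed region (residues
    10-14) while distal residues (1-6, more than a helical turn away) stay
    insignificant; the classification counts must follow the 2.33/3.33
    rules exactly and the H-bond network diff must report the lost bond.
    """
    n_res = 14
    suppressed = n_res - 5  # last designed bond: donor 14 -> acceptor 10
    wt = make_peptide_ensemble(
        PeptideEnsembleSpec(
            n_res, "helix", n_frames=30, perturbation_scale=0.12,
            hbond_toggle_rate=0.1, seed=1000 + seed,
        )
    )
    mut = make_peptide_ensemble(
        PeptideEnsembleSpec(
            n_res, "helix", n_frames=30, perturbation_scale=0.12,
            hbond_toggle_rate=0.1, seed=2000 + seed,
            suppressed_bonds=(suppressed,),
        )
    )
    cfg = RunConfig(
        n_representatives=8,
        target_clusters=8,
        n_samples=24,
        basin_samples=12,
        stride_nat=2,
        seed=seed,
        t_start=60.0,
        t_stop=700.0,
        t_step=5.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = compare_ensembles(wt, mut, cfg)
    z = report.zprofile
    res_ids = z["label"].str.split(":").str[1].astype(int)
    site = (res_ids >= 10) & (res_ids <= n_res)
    distal = res_ids <= 6
    zabs = z["z"].abs()

    # classification counts recomputed independently from the raw Z values
    zv = z["z"].to_numpy()
    expect = {
        "large rigidity increase": int(np.sum(zv < -3.33)),
        "moderate rigidity increase": int(np.sum((zv < -2.33) & (zv >= -3.33))),
        "none": int(np.sum(np.abs(zv) <= 2.33)),
        "moderate flexibility increase": int(np.sum((zv > 2.33) & (zv <= 3.33))),
        "large flexibility increase": int(np.sum(zv > 3.33)),
    }
    lost_keys = [k for k, _ in report.hbn["lost"]]
    return {
        "max_abs_z_site": float(zabs[site].max()),
        "max_abs_z_distal": float(zabs[distal].max()),
        "median_abs_z_distal": float(zabs[distal].median()),
        "classes_follow_thresholds": expect == report.classification["counts"],
        "suppressed_bond_lost_in_hbn": ("A:14:N", "A:10:O") in lost_keys,
        "n_rep": len(report.wt.representatives),
    }


def occupancy_class_study(n_frames: int = 40) -> dict:
    """Designed occupancies 0.95/0.8/0.6/0.45 must map onto the display
    classes >0.9, (0.7,0.9], (0.5,0.7] and excluded."""
    designed = {0: 0.95, 1: 0.8, 2: 0.6, 3: 0.45}
    ens = make_peptide_ensemble(
        PeptideEnsembleSpec(
            8, "helix", n_frames=n_frames, designed_occupancies=designed
        )
    )
    net = hbond_occupancy(ens)
    frame = ens.frame(0)

    def label(i):
        return f"{frame.chain_id[i]}:{int(frame.res_id[i])}:{frame.atom_name[i]}"

    expected = {0.95: ">0.9", 0.8: "(0.7,0.9]", 0.6: "(0.5,0.7]", 0.45: "excluded"}
    results = {}
    correct = 0
    for k, (donor, acceptor) in enumerate(ens.designed_hbonds):
        row = net.table[
            (net.table["donor_label"] == label(donor))
            & (net.table["acceptor_label"] == label(acceptor))
        ]
        occ = float(row["occupancy"].iloc[0]) if len(row) else 0.0
        cls = occupancy_class(occ)
        results[designed[k]] = {"occupancy": occ, "class": cls}
        if cls == expected[designed[k]]:
            correct += 1
    return {
        "mapping_correct_pct": 100.0 * correct / len(designed),
        "details": results,
    }
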