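"""Ensemble comparison machinery: clustering, weighted statistics,
Z-scores, distances, occupancies, RMSD/RMSF."""

import numpy as np
import pandas as pd
import pytest
import biotite.structure as struc
from hypothesis import given, settings, strategies as st

from qsfr.compare import (
    StructureEnsemble,
    classify_changes,
    cluster_frames,
    distance_to_mutation,
    hbn_diff,
    hbond_occupancy,
    occupancy_class,
    odds_reciprocal,
    rmsd_rmsf,
    tail_probability,
    weighted_stats,
    z_class,
    zscore_profile,
)
from qsfr.synthetic import PeptideEnsembleSpec, make_peptide_ensemble


def _stack_from_coords(base_ens, coords):
    stack = struc.stack([base_ens.frame(0)] * len(coords))
    stack.coord = np.array(coords)
    stack.bonds = base_ens.frames.bonds
    return StructureEnsemble(frames=stack)


class TestWeightedStats:
    def test_equal_weights_reduce_to_plain_mean_sd(self, rng):
        v = rng.normal(size=20)
        mean, sd = weighted_stats(v, np.ones(20))
        assert mean == pytest.approx(v.mean())
        assert sd == pytest.approx(v.std())

    def test_hand_computed_example(self):
        mean, sd = weighted_stats([1.0, 3.0], [3.0, 1.0])
        assert mean == pytest.approx(1.5)
        assert sd == pytest.approx(np.sqrt(0.75))

    def test_single_representative_has_zero_sd(self):
        assert weighted_stats([2.5], [7.0]) == (2.5, 0.0)


class TestZScores:
    def test_identical_distributions_give_zero(self):
        v = np.array([[1.0, 2.0], [1.2, 2.2], [0.8, 1.8]])
        w = [2.0, 1.0, 1.0]
        z = zscore_profile(v, w, v, w)
        assert np.all(z["z"] == 0.0)
        assert set(z["class"]) == {"none"}

    def test_worked_arithmetic_example(self):
        # mean diff 0.2, both SDs 0.1, n_rep 10 -> Z ~ 4.47, large
        wt = np.array([[0.0], [0.1], [0.2]])  # mean 0.1, sd ~0.0816
        # construct exact: use two reps with sd 0.1
        wt = np.array([[0.1 - 0.1], [0.1 + 0.1]])
        mut = wt + 0.2
        z = zscore_profile(wt, [1, 1], mut, [1, 1], n_rep=10)
        assert z["z"].iloc[0] == pytest.approx(0.2 / np.sqrt(0.002))
        assert z["class"].iloc[0] == "large flexibility increase"

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_swapping_ensembles_flips_the_sign(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        w = rng.uniform(0.5, 2.0, 4)
        z1 = zscore_profile(a, w, b, w)["z"].to_numpy()
        z2 = zscore_profile(b, w, a, w)["z"].to_numpy()
        np.testing.assert_allclose(z1, -z2, atol=1e-10)

    def test_zero_sd_sentinels(self):
        same = np.array([[1.0], [1.0]])
        higher = np.array([[2.0], [2.0]])
        z_eq = zscore_profile(same, [1, 1], same, [1, 1])["z"].iloc[0]
        z_inf = zscore_profile(same, [1, 1], higher, [1, 1])["z"].iloc[0]
        assert z_eq == 0.0
        assert z_inf == np.inf


class TestClassification:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (2.0, "none"),
            (-2.5, "moderate rigidity increase"),
            (3.4, "large flexibility increase"),
            (-3.34, "large rigidity increase"),
            (2.34, "moderate flexibility increase"),
        ],
    )
    def test_threshold_classes(self, z, expected):
        assert z_class(z) == expected

    def test_counts_and_skew(self):
        df = pd.DataFrame({"z": [0.0, 2.5, 3.5, -2.5, 1.0]})
        df["class"] = df["z"].map(z_class)
        out = classify_changes(df)
        assert out["counts"]["moderate flexibility increase"] == 1
        assert out["counts"]["large flexibility increase"] == 1
        assert out["counts"]["moderate rigidity increase"] == 1
        assert out["n_significant"] == 3
        assert out["skew"] == pytest.approx(
            abs(2 / 3 - 1 / 3) * 100.0
        )

    def test_tail_probabilities_match_the_thresholds(self):
        assert round(tail_probability(2.33), 2) == 0.01
        assert tail_probability(3.33) < 5e-4
        assert odds_reciprocal(3.33) > 2300


class TestDistances:
    def test_distance_examples(self, helix12):
        frame, _ = helix12
        # mutation at residue 1; changed at residues 1, 5
        df, summary = distance_to_mutation(frame, [1, 5], [1])
        assert df[df["residue"] == 1]["distance"].iloc[0] == 0.0
        assert summary["mean_distance"] >= 0.0

    def test_collinear_mean(self):
        arr = struc.AtomArray(3)
        arr.atom_name = np.array(["CA", "CA", "CA"])
        arr.element = np.array(["C", "C", "C"])
        arr.res_id = np.array([1, 2, 3])
        arr.res_name = np.array(["GLY"] * 3)
        arr.chain_id = np.array(["A"] * 3)
        arr.hetero = np.zeros(3, bool)
        arr.coord = np.array([[0.0, 0, 0], [5.0, 0, 0], [12.0, 0, 0]])
        df, summary = distance_to_mutation(arr, [2, 3], [1])
        assert summary["mean_distance"] == pytest.approx(8.5)

    def test_equidistant_tie_uses_the_common_distance(self):
        arr = struc.AtomArray(3)
        arr.atom_name = np.array(["CA"] * 3)
        arr.element = np.array(["C"] * 3)
        arr.res_id = np.array([1, 2, 3])
        arr.res_name = np.array(["GLY"] * 3)
        arr.chain_id = np.array(["A"] * 3)
        arr.hetero = np.zeros(3, bool)
        arr.coord = np.array([[-4.0, 0, 0], [0.0, 0, 0], [4.0, 0, 0]])
        df, _ = distance_to_mutation(arr, [2], [1, 3])
        assert df["distance"].iloc[0] == pytest.approx(4.0)


@pytest.fixture(scope="module")
def scheduled():
    spec = PeptideEnsembleSpec(
        8, "helix", n_frames=20,
        designed_occupancies={0: 1.0, 1: 0.8, 2: 0.4, 3: 1.0},
    )
    return make_peptide_ensemble(spec)


class TestOccupancy:
    @pytest.mark.parametrize(
        "occ, expected",
        [(1.0, ">0.9"), (0.95, ">0.9"), (0.8, "(0.7,0.9]"), (0.6, "(0.5,0.7]"),
         (0.45, "excluded"), (0.5, "excluded")],
    )
    def test_class_boundaries(self, occ, expected):
        assert occupancy_class(occ) == expected

    def test_always_present_bond_has_unit_occupancy(self, scheduled):
        net = hbond_occupancy(scheduled)
        assert (net.table["occupancy"] == 1.0).sum() >= 2
        assert net.table["occupancy"].between(0, 1).all()

    def test_low_occupancy_bonds_are_excluded_from_report(self, scheduled):
        net = hbond_occupancy(scheduled)
        assert (net.table["occupancy"] <= 0.5).any()
        assert (net.reported["occupancy"] > 0.5).all()

    def test_diff_of_identical_networks_is_empty(self, scheduled):
        net = hbond_occupancy(scheduled)
        diff = hbn_diff(net, net)
        assert diff["gained"] == [] and diff["lost"] == []
        assert (diff["per_residue_delta"]["delta_hbond_count"] == 0).all()

    def test_bond_dropping_below_floor_is_reported_lost(self):
        wt = make_peptide_ensemble(
            PeptideEnsembleSpec(8, "helix", 20, designed_occupancies={0: 0.8})
        )
        mut = make_peptide_ensemble(
            PeptideEnsembleSpec(8, "helix", 20, designed_occupancies={0: 0.4})
        )
        diff = hbn_diff(hbond_occupancy(wt), hbond_occupancy(mut))
        lost_keys = [k for k, _ in diff["lost"]]
        assert ("A:5:N", "A:1:O") in lost_keys


class TestRmsdRmsf:
    def test_identical_frames_are_zero(self):
        ens = make_peptide_ensemble(PeptideEnsembleSpec(6, "helix", 4))
        rmsd, rmsf = rmsd_rmsf(ens)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-5)
        np.testing.assert_allclose(rmsf["rmsf"], 0.0, atol=1e-5)

    def test_rigid_rotation_is_invisible_after_superposition(self, rng):
        ens = make_peptide_ensemble(PeptideEnsembleSpec(6, "helix", 1))
        base = ens.frames.coord[0]
        coords = [base]
        for _ in range(3):
            q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            coords.append(base @ q.T + rng.normal(size=3))
        ens2 = _stack_from_coords(ens, coords)
        rmsd, _ = rmsd_rmsf(ens2)
        np.testing.assert_allclose(rmsd, 0.0, atol=1e-5)

    def test_noisy_residue_has_rmsf_s_sqrt3(self, rng):
        """Isotropic Gaussian noise of SD s on one residue's CA gives an
        RMSF near s*sqrt(3); the rest of the chain anchors the superposition
        (which still absorbs a small part of the single-atom displacement,
        hence the tolerance band)."""
        ens = make_peptide_ensemble(PeptideEnsembleSpec(20, "helix", 1))
        base = ens.frames.coord[0]
        ca = np.where(ens.frames.atom_name == "CA")[0]
        target = ca[9]
        s = 0.2
        coords = []
        for _ in range(500):
            frame = base.copy()
            frame[target] += rng.normal(0, s, 3)
            coords.append(frame)
        ens2 = _stack_from_coords(ens, coords)
        _, rmsf = rmsd_rmsf(ens2)
        noisy = rmsf[rmsf["res_id"] == 10]["rmsf"].iloc[0]
        assert noisy == pytest.approx(s * np.sqrt(3), rel=0.15)
        assert rmsf[rmsf["res_id"] != 10]["rmsf"].max() < 0.5 * noisy


class TestClustering:
    def test_identical_frames_collapse_to_one_cluster(self):
        ens = make_peptide_ensemble(PeptideEnsembleSpec(6, "helix", 5))
        with pytest.warns(UserWarning):
            model = cluster_frames(ens, target_n_clusters=3)
        assert model.n_clusters == 1
        assert model.weights[0] == 5

    def test_planted_conformers_are_recovered(self, rng):
        """Three well-separated conformations with small intra-cluster noise
        come back as three clusters matching the generating labels."""
        folds = ["helix", "hairpin", "coil"]
        bases = [
            make_peptide_ensemble(PeptideEnsembleSpec(8, f, 1)).frames.coord[0]
            for f in folds
        ]
        ref = make_peptide_ensemble(PeptideEnsembleSpec(8, "helix", 1))
        coords, labels = [], []
        for k, base in enumerate(bases):
            for _ in range(4):
                coords.append(base + rng.normal(0, 0.05, base.shape))
                labels.append(k)
        ens = _stack_from_coords(ref, coords)
        model = cluster_frames(ens, target_n_clusters=3)
        assert model.n_clusters == 3
        # same generating label <=> same cluster
        for i in range(len(labels)):
            for j in range(len(labels)):
                same = labels[i] == labels[j]
                assert (model.assignments[i] == model.assignments[j]) == same
        assert model.top_fraction(10) <= 1.0
        assert model.weights.sum() == len(labels)

    def test_representatives_belong_to_their_cluster(self, rng):
        ens = make_peptide_ensemble(
            PeptideEnsembleSpec(6, "helix", 12, perturbation_scale=0.3, seed=2)
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model = cluster_frames(ens, target_n_clusters=4)
        for c, rep in enumerate(model.representatives):
            assert model.assignments[rep] == c
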