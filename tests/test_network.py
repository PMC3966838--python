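"""Structure -> constraint network mapping: H-bond detection, bar typing,
torsion inventory, component entropies."""

import numpy as np
import pytest
import biotite.structure as struc

from qsfr.network import (
    COVALENT_LOCKED,
    COVALENT_ROTATABLE,
    MissingHydrogensError,
    assign_component_entropies,
    build_network,
    detect_hbonds,
    read_network_tsv,
    write_network_tsv,
)


def _mini_structure(atoms, bonds):
    """atoms: list of (name, element, res_id, res_name, xyz)."""
    arr = struc.AtomArray(len(atoms))
    arr.atom_name = np.array([a[0] for a in atoms])
    arr.element = np.array([a[1] for a in atoms])
    arr.res_id = np.array([a[2] for a in atoms])
    arr.res_name = np.array([a[3] for a in atoms])
    arr.chain_id = np.full(len(atoms), "A")
    arr.hetero = np.zeros(len(atoms), bool)
    arr.coord = np.array([a[4] for a in atoms], float)
    arr.bonds = struc.BondList(
        len(atoms), np.array(bonds, dtype=np.uint32).reshape(-1, 3)
    )
    return arr


class TestDetectHbonds:
    def test_ideal_helix_yields_every_designed_bond(self, helix12):
        frame, ens = helix12
        found = {(h.donor, h.acceptor) for h in detect_hbonds(frame)}
        assert found == set(ens.designed_hbonds)

    def test_pair_beyond_distance_cutoff_is_rejected(self):
        s = _mini_structure(
            [
                ("N", "N", 1, "GLY", (0.0, 0.0, 0.0)),
                ("H", "H", 1, "GLY", (1.0, 0.0, 0.0)),
                ("C", "C", 1, "GLY", (-1.4, 0.4, 0.0)),
                ("O", "O", 5, "GLY", (5.0, 0.0, 0.0)),
            ],
            [(0, 1, 1), (0, 2, 1)],
        )
        assert detect_hbonds(s) == []
        # same geometry at 3.0 A is accepted
        s.coord[3] = (3.0, 0.0, 0.0)
        bonds = detect_hbonds(s)
        assert len(bonds) == 1 and bonds[0].energy < 0

    def test_charged_pair_is_flagged_as_salt_bridge(self):
        s = _mini_structure(
            [
                ("NZ", "N", 1, "LYS", (0.0, 0.0, 0.0)),
                ("HZ1", "H", 1, "LYS", (1.0, 0.0, 0.0)),
                ("CE", "C", 1, "LYS", (-1.5, 0.0, 0.0)),
                ("OE1", "O", 9, "GLU", (3.0, 0.0, 0.0)),
            ],
            [(0, 1, 1), (0, 2, 1)],
        )
        bonds = detect_hbonds(s)
        assert len(bonds) == 1
        assert bonds[0].is_salt_bridge

    def test_detection_is_rotation_invariant(self, helix12, rng):
        frame, _ = helix12
        ref = detect_hbonds(frame)
        rotated = frame.copy()
        rotated.bonds = frame.bonds
        # random proper rotation + translation
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rotated.coord = frame.coord @ q.T + np.array([5.0, -3.0, 11.0])
        rot = detect_hbonds(rotated)
        assert [(h.donor, h.acceptor) for h in rot] == [
            (h.donor, h.acceptor) for h in ref
        ]
        # float32 coordinate storage limits the attainable precision
        np.testing.assert_allclose(
            [h.energy for h in rot], [h.energy for h in ref], atol=1e-4
        )

    def test_structure_without_hydrogens_requires_explicit_flag(self, helix12):
        frame, _ = helix12
        heavy = frame[frame.element != "H"]
        with pytest.raises(MissingHydrogensError):
            detect_hbonds(heavy)
        bonds = detect_hbonds(heavy, allow_heavy_only=True)
        assert len(bonds) >= 8  # designed bonds still found on heavy atoms


class TestBuildNetwork:
    def test_four_atom_chain_has_single_central_torsion(self):
        s = _mini_structure(
            [
                ("C1", "C", 1, "LIG", (0.0, 0.0, 0.0)),
                ("C2", "C", 1, "LIG", (1.5, 0.0, 0.0)),
                ("C3", "C", 1, "LIG", (2.3, 1.3, 0.0)),
                ("C4", "C", 1, "LIG", (3.8, 1.3, 0.0)),
            ],
            [(0, 1, 1), (1, 2, 1), (2, 3, 1)],
        )
        net = build_network(s, hbonds=[])
        assert len(net.constraints) == 3
        assert net.n_tor == 1
        rotatable = net.constraints[net.torsions[0]]
        assert {rotatable.i, rotatable.j} == {1, 2}

    def test_double_bond_is_locked_with_no_torsion(self):
        s = _mini_structure(
            [
                ("C1", "C", 1, "LIG", (0.0, 0.0, 0.0)),
                ("C2", "C", 1, "LIG", (1.33, 0.0, 0.0)),
            ],
            [(0, 1, 2)],
        )
        net = build_network(s, hbonds=[])
        assert len(net.constraints) == 1
        assert net.constraints[0].bars == 6
        assert net.n_tor == 0

    def test_helix_torsion_inventory_matches_enumeration(self, helix12_network):
        """phi for residues 2..12 and psi for 1..12 are rotatable; peptide,
        carbonyl, N-H and terminal CA-CB bonds are locked."""
        net, hbonds = helix12_network
        assert net.n_hb_max == len(hbonds)
        labels = set(net.torsion_labels())
        expected = {f"A:{r}:phi" for r in range(2, 13)} | {
            f"A:{r}:psi" for r in range(1, 13)
        }
        assert labels == expected

    def test_bar_classes_follow_the_body_bar_convention(self, helix12_network):
        net, _ = helix12_network
        for c in net.constraints:
            assert (c.kind, c.bars) in {
                (COVALENT_ROTATABLE, 5),
                (COVALENT_LOCKED, 6),
            }
        assert all(c.bars == 5 for c in net.hbonds)

    def test_torsion_inventory_independent_of_hbonds(self, helix12):
        frame, _ = helix12
        with_hb = build_network(frame)
        without = build_network(frame, hbonds=[])
        assert with_hb.torsion_labels() == without.torsion_labels()

    def test_edge_list_tsv_round_trip(self, helix12_network, tmp_path):
        net, _ = helix12_network
        prefix = str(tmp_path / "net")
        write_network_tsv(net, prefix)
        back = read_network_tsv(prefix)
        assert back.n_bodies == net.n_bodies
        assert back.n_hb_max == net.n_hb_max
        assert back.torsions == net.torsions
        assert [c.bars for c in back.constraints] == [
            c.bars for c in net.constraints
        ]


class TestComponentEntropies:
    def test_stronger_bond_gets_lower_entropy(self):
        g = assign_component_entropies([-8.0, -1.0])
        assert g[0] < g[1]

    def test_equal_energies_get_equal_entropy(self):
        g = assign_component_entropies([-4.0, -4.0])
        assert g[0] == g[1]

    def test_energy_grid_maps_to_strictly_increasing_gammas(self):
        g = assign_component_entropies([-8.0, -6.0, -4.0, -2.0])
        assert np.all(np.diff(g) > 0)
        assert np.all(g > 0)
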