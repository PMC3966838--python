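"""DCM thermodynamics: q-value sampling, entropies, free energy, heat
capacity, basins and parameter fitting."""

import numpy as np
import pytest

from qsfr.network import Constraint, ConstraintNetwork, GENERIC, HBOND
from qsfr.synthetic import (
    PeptideEnsembleSpec,
    SyntheticCpSpec,
    make_cp_curve,
    make_half_independent_network,
    make_peptide_ensemble,
    make_two_state_network,
)
from qsfr.thermo import (
    CpCurve,
    DCMParams,
    LandscapeError,
    Macrostate,
    R_KCAL,
    TopologySample,
    _boltzmann_weights,
    build_tables,
    conformational_entropy,
    fit_parameters,
    free_energy,
    heat_capacity,
    mixing_entropy,
    native_basin,
    sample_topologies,
)

TWO_STATE_PARAMS = DCMParams(v_nat=-42.0, delta_nat=1.0, delta_dis=61.0)


def _chain_with_torsions(n=4):
    cons = [
        Constraint(i, i + 1, 5, "covalent-rotatable", label=f"A:{i + 1}:tor")
        for i in range(n - 1)
    ]
    return ConstraintNetwork(n, cons, torsions=list(range(n - 1)))


class TestSampling:
    def test_covalent_chain_has_no_hbond_energy(self):
        net = _chain_with_torsions()
        s = sample_topologies(net, Macrostate(0, 0), n_samples=10, seed=0)
        assert s.u_mean == 0.0
        assert 0.0 <= s.qbar_dis <= 1.0

    def test_engineered_half_independent_gives_q_nat_half(self):
        net = make_half_independent_network()
        s = sample_topologies(net, Macrostate(0, 2), n_samples=30, seed=1)
        assert s.qbar_nat == 0.5

    def test_fully_redundant_hbonds_give_q_zero(self):
        # locked clique: every H-bond lands inside one rigid body
        cons = [
            Constraint(i, j, 6, GENERIC)
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        hb = [
            Constraint(0, 2, 5, HBOND, entropy=0.5, energy=-5.0),
            Constraint(1, 3, 5, HBOND, entropy=0.6, energy=-4.0),
        ]
        net = ConstraintNetwork(4, cons, hbonds=hb)
        s = sample_topologies(net, Macrostate(2, 0), n_samples=10, seed=2)
        assert np.all(s.qbar_hb == 0.0)

    def test_impossible_macrostate_raises(self):
        net = _chain_with_torsions()
        with pytest.raises(ValueError):
            sample_topologies(net, Macrostate(1, 0))


class TestEntropies:
    def test_all_redundant_network_has_zero_s_conf(self):
        net = _chain_with_torsions()
        s = TopologySample(
            Macrostate(0, 0), 1, 0, np.zeros(0), np.zeros(0), 0.0, 0.0, 0.0
        )
        assert conformational_entropy(s, net, Macrostate(0, 0)) == 0.0

    def test_worked_case_two_r_delta_nat(self):
        # N_nat = 4, qbar_nat = 0.5, no H-bonds -> S_conf = 2 R delta_nat
        net = _chain_with_torsions(5)
        params = DCMParams()
        s = TopologySample(
            Macrostate(0, 4), 1, 0, np.zeros(0), np.zeros(0), 0.5, 0.0, 0.0
        )
        expected = R_KCAL * 2.0 * params.delta_nat
        assert conformational_entropy(s, net, Macrostate(0, 4), params) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize(
        "nmax, nhb, ntor, nnat, expected_ln",
        [(4, 0, 0, 0, 0.0), (4, 2, 0, 0, np.log(6.0))],
    )
    def test_mixing_entropy_values(self, nmax, nhb, ntor, nnat, expected_ln):
        hb = [
            Constraint(0, k + 1, 5, HBOND, entropy=0.5, energy=-1.0)
            for k in range(nmax)
        ]
        net = ConstraintNetwork(nmax + 1, [], hbonds=hb)
        m = Macrostate(nhb, nnat)
        assert mixing_entropy(net, m) == pytest.approx(R_KCAL * expected_ln)

    def test_mixing_entropy_is_binomially_symmetric(self, helix12_network):
        net, _ = helix12_network
        for nhb in range(net.n_hb_max + 1):
            a = mixing_entropy(net, Macrostate(nhb, 0))
            b = mixing_entropy(net, Macrostate(net.n_hb_max - nhb, 0))
            assert a == pytest.approx(b)

    def test_preferential_entropy_not_above_random_orders(self, rng):
        """Lowest-upper-bound property on random toy networks."""
        from qsfr.pebble import analyze
        from qsfr.validation import random_framework

        for _ in range(5):
            net = random_framework(rng)
            topo = net.full_topology()
            gammas = np.array([c.entropy for c in topo.constraints])
            s_pref = float(gammas @ analyze(topo, want_regions=False).q)
            for _ in range(20):
                order = list(rng.permutation(len(topo.constraints)))
                s = float(gammas @ analyze(topo, order, want_regions=False).q)
                assert s_pref <= s + 1e-12


class TestFreeEnergy:
    def test_zero_temperature_leaves_only_enthalpy(self):
        net = make_two_state_network()
        s = sample_topologies(net, Macrostate(0, 1), 5, 0, TWO_STATE_PARAMS)
        cell = free_energy(net, Macrostate(0, 1), s, TWO_STATE_PARAMS, 0.0)
        assert cell.G == cell.enthalpy

    def test_g_is_linear_in_temperature(self):
        net = make_two_state_network()
        m = Macrostate(0, 1)
        s = sample_topologies(net, m, 5, 0, TWO_STATE_PARAMS)
        c1 = free_energy(net, m, s, TWO_STATE_PARAMS, 300.0)
        c2 = free_energy(net, m, s, TWO_STATE_PARAMS, 400.0)
        slope = (c2.G - c1.G) / 100.0
        assert slope == pytest.approx(-(c1.s_conf + c1.s_mix))


class TestHeatCapacity:
    def test_two_state_closed_form(self):
        p = TWO_STATE_PARAMS
        tm = abs(p.v_nat) / (R_KCAL * (p.delta_dis - p.delta_nat))
        grid = np.arange(tm - 60, tm + 60, 1.0)
        curve = heat_capacity(make_two_state_network(), p, grid, n_samples=5)
        assert abs(curve.tm - tm) <= 1.0
        peak = abs(p.v_nat) ** 2 / (4 * R_KCAL * tm**2)
        assert curve.cp.max() == pytest.approx(peak, rel=0.01)

    def test_doubling_enthalpy_and_entropy_keeps_tm(self):
        p2 = DCMParams(v_nat=-84.0, delta_nat=2.0, delta_dis=122.0)
        tm = abs(p2.v_nat) / (R_KCAL * (p2.delta_dis - p2.delta_nat))
        assert tm == pytest.approx(
            abs(TWO_STATE_PARAMS.v_nat)
            / (R_KCAL * (TWO_STATE_PARAMS.delta_dis - TWO_STATE_PARAMS.delta_nat))
        )
        grid = np.arange(tm - 60, tm + 60, 1.0)
        curve = heat_capacity(make_two_state_network(), p2, grid, n_samples=5)
        assert abs(curve.tm - tm) <= 1.0

    def test_degenerate_landscape_raises(self):
        # v_nat = 0 and delta_nat ~ delta_dis: both states identical in G
        net = make_two_state_network()
        p = DCMParams(v_nat=-1e-12, delta_nat=2.1249, delta_dis=2.125)
        with pytest.raises(LandscapeError):
            heat_capacity(net, p, np.arange(200.0, 400.0, 5.0), n_samples=5)

    def test_weights_normalize_and_cp_nonnegative(self, helix12_network):
        net, _ = helix12_network
        tables = build_tables(net, DCMParams(), n_samples=8, seed=0, stride_nat=3)
        G = tables.gibbs(DCMParams(), 300.0)
        w = _boltzmann_weights(G, 300.0)
        assert w.sum() == pytest.approx(1.0)
        curve = heat_capacity(tables, DCMParams(), np.arange(60.0, 700.0, 10.0))
        assert np.all(curve.cp >= 0.0)


class TestNativeBasin:
    def _tables(self):
        """Hand-crafted bimodal landscape over a 5x6 grid."""
        net = ConstraintNetwork(
            2, [], hbonds=[
                Constraint(0, 1, 5, HBOND, entropy=0.5, energy=-1.0)
                for _ in range(4)
            ],
            torsions=[],
        )
        from qsfr.thermo import TopologyTables

        n_hb = np.arange(5)
        n_nat = np.arange(6)
        u = np.zeros((5, 6))
        # two wells: (0 hb, 0 nat) and (4 hb, 5 nat); barrier between
        for i in range(5):
            for j in range(6):
                u[i, j] = 0.5 * ((i - 4) ** 2 + (j - 5) ** 2) * 0.2
        u[0, 0] = 0.5  # second, shallower well at the disordered corner
        u[1, 1] = 3.0
        net.torsions = []
        return TopologyTables(
            network=net,
            n_hb_values=n_hb,
            n_nat_values=n_nat,
            u_mean=u,
            c_hb=np.zeros((5, 6)),
            qbar_nat=np.zeros((5, 6)),
            qbar_dis=np.zeros((5, 6)),
            s_mix=np.zeros((5, 6)),
            n_samples=1,
            seed=0,
        )

    def test_bimodal_landscape_selects_high_n_nat_minimum(self):
        tables = self._tables()
        p = DCMParams(u_sol=0.0, v_nat=-1e-9)
        basin = native_basin(tables, p, 300.0, dg_cut=1.0)
        assert Macrostate(4, 5) in basin
        assert Macrostate(0, 0) not in basin

    def test_zero_cut_returns_exactly_the_minimum_cell(self):
        tables = self._tables()
        p = DCMParams(u_sol=0.0, v_nat=-1e-9)
        basin = native_basin(tables, p, 300.0, dg_cut=0.0)
        assert basin == [Macrostate(4, 5)]

    def test_infinite_cut_returns_all_macrostates(self):
        tables = self._tables()
        p = DCMParams(u_sol=0.0, v_nat=-1e-9)
        basin = native_basin(tables, p, 300.0, dg_cut=np.inf)
        assert len(basin) == 30

    def test_unimodal_landscape_warns(self):
        tables = self._tables()
        tables.u_mean[0, 0] = 10.0  # remove the second well
        p = DCMParams(u_sol=0.0, v_nat=-1e-9)
        with pytest.warns(UserWarning):
            native_basin(tables, p, 300.0, dg_cut=0.5)


@pytest.fixture(scope="module")
def helix_tables():
    ens = make_peptide_ensemble(PeptideEnsembleSpec(8, "helix", 1))
    frame = ens.frame(0)
    frame.bonds = ens.frames.bonds
    from qsfr.network import build_network, detect_hbonds

    net = build_network(frame, detect_hbonds(frame))
    tables = build_tables(net, DCMParams(), n_samples=32, seed=11)
    return net, tables


class TestFitting:

    def test_noise_free_self_consistency(self, helix_tables):
        net, tables = helix_tables
        true = DCMParams()
        grid = tuple(np.arange(120.0, 451.0, 2.0))
        curve = make_cp_curve(
            SyntheticCpSpec(true, grid, 0.0, 0), net, tables=tables
        )
        fit = fit_parameters(
            tables,
            curve,
            x0=DCMParams(-3.2, -0.7, 1.7),
            align="none",
            n_restarts=2,
            seed=0,
        )
        assert fit.params.u_sol == pytest.approx(true.u_sol, rel=1e-2)
        assert fit.params.v_nat == pytest.approx(true.v_nat, rel=1e-2)
        assert fit.params.delta_nat == pytest.approx(true.delta_nat, rel=1e-2)

    def test_u_sol_v_nat_objective_valley_is_correlated(self, helix_tables):
        """Perturbing u_sol and v_nat together along the compensating
        direction costs much less than perturbing them in opposition."""
        net, tables = helix_tables
        true = DCMParams()
        grid = np.arange(120.0, 451.0, 2.0)
        data = heat_capacity(tables, true, grid)

        def cost(u_scale, v_scale):
            p = DCMParams(true.u_sol * u_scale, true.v_nat * v_scale, 1.89)
            model = heat_capacity(tables, p, grid)
            r = data.cp - model.cp
            return float(r @ r)

        along = cost(1.05, 1.1)  # both magnitudes up together (compensating)
        against = cost(1.05, 0.9)
        assert along < against

    def test_fit_always_reports_parameters_and_diagnostics(self, helix_tables):
        _, tables = helix_tables
        grid = np.arange(120.0, 451.0, 10.0)
        data = heat_capacity(tables, DCMParams(), grid)
        fit = fit_parameters(tables, data, n_restarts=1, seed=0)
        assert np.isfinite(fit.cost)
        assert isinstance(fit.params, DCMParams)
        assert fit.message


def test_cp_curve_tsv_round_trip(tmp_path):
    curve = CpCurve(np.array([300.0, 310.0, 320.0]), np.array([1.0, 2.0, 1.5]))
    path = tmp_path / "cp.tsv"
    curve.to_tsv(path)
    back = CpCurve.from_tsv(path)
    np.testing.assert_allclose(back.temperature, curve.temperature)
    np.testing.assert_allclose(back.cp, curve.cp)
    assert back.tm == 310.0
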