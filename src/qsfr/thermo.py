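"""Distance-constraint-model thermodynamics.

A macrostate is a pair (N_hb, N_nat): the number of intramolecular H-bonds
present and the number of torsions in the native (packed) state.  Constraint
topologies within a macrostate are sampled uniformly, each analyzed by the
pebble game under preferential (entropy-ascending) placement, and the
averaged q-values attenuate the additive entropy sum:

    S_conf = R [ sum_t gamma_t qbar_t p_t
                 + delta_nat qbar_nat N_nat
                 + delta_dis qbar_dis (N_tor - N_nat) ]

    G(N_hb, N_nat; T) = U + u_sol (N_hb^max - N_hb) + v_nat N_nat
                        - T (S_conf + S_mix)

with S_mix the log-binomial mixing entropy of distributing the present
H-bonds and native torsions.  Boltzmann weighting of the macrostate grid
yields the heat capacity via enthalpy fluctuations, the melting temperature
T_m at the C_p peak, and the native basin over which the mechanical metrics
are averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .network import ConstraintNetwork
from .pebble import analyze, preferential_order

__all__ = [
    "R_KCAL",
    "DCMParams",
    "Macrostate",
    "TopologySample",
    "TopologyTables",
    "CpCurve",
    "LandscapeCell",
    "LandscapeError",
    "sample_topologies",
    "conformational_entropy",
    "mixing_entropy",
    "free_energy",
    "build_tables",
    "heat_capacity",
    "native_basin",
    "basin_weights",
    "fit_parameters",
]

#: gas constant in kcal/mol/K
R_KCAL = 0.0019872041


class LandscapeError(RuntimeError):
    """Degenerate free-energy landscape (no usable heat-capacity peak)."""


@dataclass(frozen=True)
class DCMParams:
    """Phenomenological DCM parameters.

    ``u_sol`` (kcal/mol): average H-bond energy to solvent gained when an
    intramolecular H-bond breaks.  ``v_nat`` (kcal/mol): energy of a
    native-like (packed) torsion.  ``delta_nat`` / ``delta_dis``
    (dimensionless, units of R): entropy of a native-like and disordered
    torsion.  Only {u_sol, v_nat, delta_nat} are fitted; delta_dis is held
    fixed.  Defaults are the package's reference parameterization for
    antibody Fv fragments.
    """

    u_sol: float = -2.71
    v_nat: float = -0.89
    delta_nat: float = 1.89
    delta_dis: float = 2.125

    def __post_init__(self):
        if not (self.delta_dis > self.delta_nat):
            raise ValueError("delta_dis must exceed delta_nat")
        for v in (self.u_sol, self.v_nat, self.delta_nat, self.delta_dis):
            if not math.isfinite(v):
                raise ValueError("DCM parameters must be finite")


@dataclass(frozen=True)
class Macrostate:
    n_hb: int
    n_nat: int


@dataclass
class TopologySample:
    """Monte-Carlo averages over constraint topologies of one macrostate."""

    macrostate: Macrostate
    n_samples: int
    seed: int
    qbar_hb: np.ndarray  # conditional P(independent | present), per candidate
    hb_present_count: np.ndarray
    qbar_nat: float
    qbar_dis: float
    u_mean: float  # mean intramolecular H-bond energy (kcal/mol)


def _validate_macrostate(network: ConstraintNetwork, m: Macrostate) -> None:
    if not (0 <= m.n_hb <= network.n_hb_max):
        raise ValueError(
            f"N_hb={m.n_hb} outside [0, {network.n_hb_max}] for this network"
        )
    if not (0 <= m.n_nat <= network.n_tor):
        raise ValueError(
            f"N_nat={m.n_nat} outside [0, {network.n_tor}] for this network"
        )


def sample_topologies(
    network: ConstraintNetwork,
    m: Macrostate,
    n_samples: int = 200,
    seed: int = 0,
    params: DCMParams | None = None,
) -> TopologySample:
    """Uniformly sample constraint topologies of macrostate ``m``.

    All constraint networks carry equal weight within a macrostate: each
    sample draws N_hb of the candidate H-bonds and N_nat of the torsion
    inventory without replacement, runs the pebble game under preferential
    order and records which constraints are independent.
    """
    _validate_macrostate(network, m)
    params = params or DCMParams()
    rng = np.random.default_rng(seed)
    nmax, ntor = network.n_hb_max, network.n_tor

    hb_indep = np.zeros(nmax)
    hb_count = np.zeros(nmax)
    nat_indep = nat_count = 0
    dis_indep = dis_count = 0
    u_total = 0.0
    for _ in range(n_samples):
        present = (
            rng.choice(nmax, size=m.n_hb, replace=False) if nmax else np.empty(0, int)
        )
        native = (
            rng.choice(ntor, size=m.n_nat, replace=False) if ntor else np.empty(0, int)
        )
        topo = network.realize(present, native, params.delta_nat, params.delta_dis)
        res = analyze(topo, preferential_order(topo), want_regions=False)
        native_set = set(int(t) for t in native)
        for k, c in enumerate(topo.constraints):
            hb = topo.hb_index[k]
            tor = topo.tor_index[k]
            if hb >= 0:
                hb_count[hb] += 1
                hb_indep[hb] += res.q[k]
                u_total += c.energy
            elif tor >= 0:
                if tor in native_set:
                    nat_count += 1
                    nat_indep += res.q[k]
                else:
                    dis_count += 1
                    dis_indep += res.q[k]

    with np.errstate(invalid="ignore", divide="ignore"):
        qbar_hb = np.where(hb_count > 0, hb_indep / np.maximum(hb_count, 1), np.nan)
    # bonds never drawn fall back to the mean over observed bonds
    if np.any(np.isnan(qbar_hb)):
        observed = qbar_hb[~np.isnan(qbar_hb)]
        fill = float(observed.mean()) if observed.size else 0.0
        qbar_hb = np.where(np.isnan(qbar_hb), fill, qbar_hb)
    return TopologySample(
        macrostate=m,
        n_samples=n_samples,
        seed=seed,
        qbar_hb=qbar_hb,
        hb_present_count=hb_count,
        qbar_nat=nat_indep / nat_count if nat_count else 0.0,
        qbar_dis=dis_indep / dis_count if dis_count else 0.0,
        u_mean=u_total / n_samples,
    )


def conformational_entropy(
    sample: TopologySample,
    network: ConstraintNetwork,
    m: Macrostate,
    params: DCMParams | None = None,
) -> float:
    """Nonadditive conformational entropy of a macrostate (kcal/mol/K).

    The q-values are the conditional probabilities for constraints to be
    independent when present; under uniform sampling each candidate H-bond is
    present with probability p_t = N_hb / N_hb^max.
    """
    params = params or DCMParams()
    gammas = np.array([c.entropy for c in network.hbonds])
    p_t = m.n_hb / network.n_hb_max if network.n_hb_max else 0.0
    c_hb = float(np.sum(gammas * sample.qbar_hb * p_t)) if network.n_hb_max else 0.0
    return R_KCAL * (
        c_hb
        + params.delta_nat * sample.qbar_nat * m.n_nat
        + params.delta_dis * sample.qbar_dis * (network.n_tor - m.n_nat)
    )


def mixing_entropy(network: ConstraintNetwork, m: Macrostate) -> float:
    """Log-binomial mixing entropy (kcal/mol/K), computed stably."""
    _validate_macrostate(network, m)

    def lnbinom(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return R_KCAL * float(
        lnbinom(network.n_hb_max, m.n_hb) + lnbinom(network.n_tor, m.n_nat)
    )


@dataclass(frozen=True)
class LandscapeCell:
    enthalpy: float
    s_conf: float
    s_mix: float
    G: float


def free_energy(
    network: ConstraintNetwork,
    m: Macrostate,
    sample: TopologySample,
    params: DCMParams,
    T: float,
) -> LandscapeCell:
    """One cell of the free-energy landscape at temperature T (kcal/mol)."""
    H = (
        sample.u_mean
        + params.u_sol * (network.n_hb_max - m.n_hb)
        + params.v_nat * m.n_nat
    )
    s_conf = conformational_entropy(sample, network, m, params)
    s_mix = mixing_entropy(network, m)
    return LandscapeCell(H, s_conf, s_mix, H - T * (s_conf + s_mix))


# ---------------------------------------------------------------------------
# macrostate-grid tables
# ---------------------------------------------------------------------------


@dataclass
class TopologyTables:
    """Parameter-independent Monte-Carlo tables over the macrostate grid.

    The sampled q-bars and mean H-bond energies depend on the network and the
    entropy *ranking* of constraint classes only, not on the numerical DCM
    parameters, so the tables are computed once and reused across parameter
    evaluations (notably during C_p fitting).
    """

    network: ConstraintNetwork
    n_hb_values: np.ndarray
    n_nat_values: np.ndarray
    u_mean: np.ndarray  # (n_hb_cells, n_nat_cells)
    c_hb: np.ndarray  # sum_t gamma_t qbar_t p_t
    qbar_nat: np.ndarray
    qbar_dis: np.ndarray
    s_mix: np.ndarray
    n_samples: int
    seed: int

    def enthalpy(self, params: DCMParams) -> np.ndarray:
        nhb = self.n_hb_values[:, None]
        nnat = self.n_nat_values[None, :]
        return (
            self.u_mean
            + params.u_sol * (self.network.n_hb_max - nhb)
            + params.v_nat * nnat
        )

    def s_conf(self, params: DCMParams) -> np.ndarray:
        nnat = self.n_nat_values[None, :]
        return R_KCAL * (
            self.c_hb
            + params.delta_nat * self.qbar_nat * nnat
            + params.delta_dis * self.qbar_dis * (self.network.n_tor - nnat)
        )

    def gibbs(self, params: DCMParams, T: float) -> np.ndarray:
        return self.enthalpy(params) - T * (self.s_conf(params) + self.s_mix)

    def macrostate(self, i: int, j: int) -> Macrostate:
        return Macrostate(int(self.n_hb_values[i]), int(self.n_nat_values[j]))


def build_tables(
    network: ConstraintNetwork,
    params: DCMParams | None = None,
    *,
    n_samples: int = 200,
    seed: int = 0,
    stride_hb: int = 1,
    stride_nat: int = 1,
) -> TopologyTables:
    """Sample every macrostate of the (optionally decimated) grid."""
    params = params or DCMParams()
    n_hb_values = np.arange(0, network.n_hb_max + 1, stride_hb)
    if n_hb_values[-1] != network.n_hb_max:
        n_hb_values = np.append(n_hb_values, network.n_hb_max)
    n_nat_values = np.arange(0, network.n_tor + 1, stride_nat)
    if network.n_tor and n_nat_values[-1] != network.n_tor:
        n_nat_values = np.append(n_nat_values, network.n_tor)

    shape = (len(n_hb_values), len(n_nat_values))
    u_mean = np.zeros(shape)
    c_hb = np.zeros(shape)
    qnat = np.zeros(shape)
    qdis = np.zeros(shape)
    smix = np.zeros(shape)
    children = np.random.SeedSequence(seed).spawn(shape[0] * shape[1])
    gammas = np.array([c.entropy for c in network.hbonds])
    idx = 0
    for i, nhb in enumerate(n_hb_values):
        for j, nnat in enumerate(n_nat_values):
            m = Macrostate(int(nhb), int(nnat))
            cell_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            s = sample_topologies(network, m, n_samples, cell_seed, params)
            u_mean[i, j] = s.u_mean
            p_t = m.n_hb / network.n_hb_max if network.n_hb_max else 0.0
            c_hb[i, j] = float(np.sum(gammas * s.qbar_hb * p_t)) if len(gammas) else 0.0
            qnat[i, j] = s.qbar_nat
            qdis[i, j] = s.qbar_dis
            smix[i, j] = mixing_entropy(network, m)
    return TopologyTables(
        network=network,
        n_hb_values=n_hb_values,
        n_nat_values=n_nat_values,
        u_mean=u_mean,
        c_hb=c_hb,
        qbar_nat=qnat,
        qbar_dis=qdis,
        s_mix=smix,
        n_samples=n_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# heat capacity and basins
# ---------------------------------------------------------------------------


@dataclass
class CpCurve:
    """Heat-capacity curve with its peak (melting) temperature."""

    temperature: np.ndarray
    cp: np.ndarray
    tm: float = field(default=float("nan"))
    true_params: DCMParams | None = None  # recorded by the synthetic generator

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, float)
        self.cp = np.asarray(self.cp, float)
        if math.isnan(self.tm) and len(self.cp):
            self.tm = float(self.temperature[int(np.argmax(self.cp))])

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.temperature, self.cp]),
            delimiter="\t",
            header="temperature_K\tcp",
            comments="",
        )

    @classmethod
    def from_tsv(cls, path) -> "CpCurve":
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(data[:, 0], data[:, 1])


def _boltzmann_weights(G: np.ndarray, T: float) -> np.ndarray:
    x = -G / (R_KCAL * T)
    x = x - x.max()
    w = np.exp(x)
    return w / w.sum()


def heat_capacity(
    network: ConstraintNetwork | TopologyTables,
    params: DCMParams,
    T_grid,
    *,
    n_samples: int = 200,
    seed: int = 0,
    stride_hb: int = 1,
    stride_nat: int = 1,
    tables: TopologyTables | None = None,
) -> CpCurve:
    """Heat capacity C_p(T) from enthalpy fluctuations over the macrostate
    grid, with T_m at the interior maximum.

    Raises :class:`LandscapeError` if the curve is flat (degenerate
    landscape) or the maximum sits on the grid boundary.
    """
    if isinstance(network, TopologyTables):
        tables = network
    elif tables is None:
        tables = build_tables(
            network,
            params,
            n_samples=n_samples,
            seed=seed,
            stride_hb=stride_hb,
            stride_nat=stride_nat,
        )
    T_grid = np.asarray(T_grid, float)
    H = tables.enthalpy(params)
    S = tables.s_conf(params) + tables.s_mix
    cp = np.empty_like(T_grid)
    for k, T in enumerate(T_grid):
        w = _boltzmann_weights(H - T * S, T)
        hbar = float(np.sum(w * H))
        var = float(np.sum(w * (H - hbar) ** 2))
        cp[k] = var / (R_KCAL * T * T)
    if np.ptp(cp) <= 1e-12 * max(1.0, float(np.abs(cp).max())):
        raise LandscapeError("flat heat-capacity curve: degenerate landscape")
    imax = int(np.argmax(cp))
    if imax in (0, len(cp) - 1):
        raise LandscapeError(
            "heat-capacity maximum on the temperature-grid boundary; widen grid"
        )
    return CpCurve(T_grid, cp, tm=float(T_grid[imax]))


def _local_minima(G: np.ndarray) -> list[tuple[int, int]]:
    n, m = G.shape
    minima = []
    for i in range(n):
        for j in range(m):
            g = G[i, j]
            neigh = []
            if i > 0:
                neigh.append(G[i - 1, j])
            if i < n - 1:
                neigh.append(G[i + 1, j])
            if j > 0:
                neigh.append(G[i, j - 1])
            if j < m - 1:
                neigh.append(G[i, j + 1])
            if all(g <= x for x in neigh):
                minima.append((i, j))
    return minima


def native_basin(
    tables: TopologyTables,
    params: DCMParams,
    T: float,
    dg_cut: float | None = None,
) -> list[Macrostate]:
    """Macrostates of the native basin at temperature T.

    The basin is the 4-connected set of grid cells within ``dg_cut``
    (default 3RT) of the local free-energy minimum with the larger N_nat.
    A unimodal landscape returns the whole low-G region with a warning.
    """
    if dg_cut is None:
        dg_cut = 3.0 * R_KCAL * T
    G = tables.gibbs(params, T)
    minima = _local_minima(G)
    if len(minima) <= 1:
        warnings.warn("unimodal landscape: returning whole low-G region", stacklevel=2)
    # native seed: local minimum with largest N_nat, ties by lower G
    seed_cell = max(minima, key=lambda ij: (tables.n_nat_values[ij[1]], -G[ij]))
    gmin = G[seed_cell]
    n, m = G.shape
    inside = G <= gmin + dg_cut
    visited = np.zeros_like(inside, dtype=bool)
    stack = [seed_cell]
    visited[seed_cell] = True
    cells = []
    while stack:
        i, j = stack.pop()
        cells.append((i, j))
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < n and 0 <= b < m and inside[a, b] and not visited[a, b]:
                visited[a, b] = True
                stack.append((a, b))
    return [tables.macrostate(i, j) for i, j in sorted(cells)]


def basin_weights(
    tables: TopologyTables,
    params: DCMParams,
    T: float,
    basin: list[Macrostate],
) -> np.ndarray:
    """Boltzmann weights of the basin macrostates at temperature T."""
    G = tables.gibbs(params, T)
    hb_pos = {int(v): i for i, v in enumerate(tables.n_hb_values)}
    nat_pos = {int(v): j for j, v in enumerate(tables.n_nat_values)}
    g = np.array([G[hb_pos[m.n_hb], nat_pos[m.n_nat]] for m in basin])
    x = -(g - g.min()) / (R_KCAL * T)
    w = np.exp(x)
    return w / w.sum()


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: DCMParams
    cost: float
    tm: float
    amplitude: float
    baseline: tuple[float, float]
    success: bool
    message: str


def _aligned_residuals(model_cp, data: CpCurve, align: str):
    """Residuals after nuisance alignment of the model curve to the data.

    ``align``: "baseline" fits amplitude plus a linear baseline (DSC data),
    "amplitude" a scale factor only, "none" compares on absolute scale
    (synthetic curves generated by the model itself).
    """
    if align == "baseline":
        design = np.column_stack(
            [model_cp, np.ones_like(model_cp), data.temperature]
        )
    elif align == "amplitude":
        design = model_cp[:, None]
    elif align == "none":
        return data.cp - model_cp, np.array([1.0])
    else:
        raise ValueError(f"unknown alignment {align!r}")
    coef, *_ = np.linalg.lstsq(design, data.cp, rcond=None)
    return data.cp - design @ coef, coef


def fit_parameters(
    tables: TopologyTables | ConstraintNetwork,
    data: CpCurve,
    *,
    x0: DCMParams | None = None,
    align: str = "baseline",
    n_restarts: int = 5,
    seed: int = 0,
    bounds: tuple | None = None,
    n_samples: int = 200,
    table_seed: int = 0,
) -> FitResult:
    """Fit {u_sol, v_nat, delta_nat} to a heat-capacity curve.

    Least-squares over the three phenomenological parameters with delta_dis
    held fixed; at each evaluation the model curve is aligned to the data by
    the nuisance model of ``align`` ("baseline": amplitude + linear baseline,
    for experimental DSC traces; "amplitude"; "none": absolute scale, for
    curves generated by the model itself).  The u_sol/v_nat valley is
    correlated and can host secondary branches, so widely dispersed restarts
    are used and the lowest-cost solution kept.  Non-convergence returns the
    best-so-far parameters with ``success=False``.
    """
    if isinstance(tables, ConstraintNetwork):
        tables = build_tables(tables, x0, n_samples=n_samples, seed=table_seed)
    x0 = x0 or DCMParams()
    delta_dis = x0.delta_dis
    if bounds is None:
        gmax = max((c.entropy for c in tables.network.hbonds), default=1.2)
        bounds = (
            [-20.0, -20.0, gmax + 0.05],
            [-1e-3, -1e-3, delta_dis - 1e-3],
        )

    def residuals(x):
        params = DCMParams(x[0], x[1], x[2], delta_dis)
        try:
            curve = heat_capacity(tables, params, data.temperature)
            model_cp = curve.cp
        except LandscapeError:
            # degenerate region of parameter space: uniform-weight curve
            model_cp = np.zeros_like(data.temperature)
        res, _ = _aligned_residuals(model_cp, data, align)
        return res

    rng = np.random.default_rng(seed)
    start = np.array([x0.u_sol, x0.v_nat, x0.delta_nat])
    best = None
    for r in range(max(1, n_restarts)):
        guess = start if r == 0 else start * rng.uniform(0.6, 1.6, 3)
        guess = np.clip(guess, bounds[0], bounds[1])
        sol = least_squares(residuals, guess, bounds=bounds, xtol=1e-10, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    params = DCMParams(best.x[0], best.x[1], best.x[2], delta_dis)
    try:
        curve = heat_capacity(tables, params, data.temperature)
        model_cp, tm = curve.cp, curve.tm
    except LandscapeError:
        model_cp, tm = np.zeros_like(data.temperature), float("nan")
    _, coef = _aligned_residuals(model_cp, data, align)
    amplitude = float(coef[0])
    base = (
        (float(coef[1]), float(coef[2])) if align == "baseline" else (0.0, 0.0)
    )
    return FitResult(
        params=params,
        cost=float(best.cost),
        tm=tm,
        amplitude=amplitude,
        baseline=base,
        success=bool(best.success),
        message=str(best.message),
    )
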