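"""Synthetic inputs: toy frameworks, peptide-like ensembles, C_p curves.

Everything downstream is testable without external data: toy body-bar
frameworks have analytically known degree-of-freedom counts; idealized
peptide ensembles place backbone donors and acceptors so that designed
H-bonds pass the geometric detection criteria exactly; synthetic
heat-capacity curves are generated by the DCM itself at known parameters so
that parameter recovery can be validated end to end.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import yaml

from .network import (
    Constraint,
    ConstraintNetwork,
    COVALENT_ROTATABLE,
    GENERIC,
)
from .compare import StructureEnsemble
from .thermo import (
    CpCurve,
    DCMParams,
    TopologyTables,
    build_tables,
    heat_capacity,
)

__all__ = [
    "ToyFrameworkSpec",
    "PeptideEnsembleSpec",
    "SyntheticCpSpec",
    "make_toy_framework",
    "make_peptide_ensemble",
    "make_cp_curve",
    "make_two_state_network",
    "make_half_independent_network",
    "load_spec",
]


# ---------------------------------------------------------------------------
# toy body-bar frameworks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyFrameworkSpec:
    """A small body-bar framework with known generic rigidity.

    ``gamma`` sets the per-edge component entropies: a scalar, an explicit
    sequence, or ``("uniform", lo, hi)`` for seeded random draws.
    """

    n_bodies: int
    topology: str | tuple = "chain"  # chain | ring | clique | edge list
    bars_per_edge: int = 5
    gamma: float | tuple | list = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bodies < 1:
            raise ValueError("need at least one body")
        if not (1 <= self.bars_per_edge <= 6):
            raise ValueError("bars_per_edge must be in [1, 6]")


def _toy_edges(spec: ToyFrameworkSpec) -> list[tuple[int, int]]:
    n = spec.n_bodies
    topo = spec.topology
    if topo == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if topo == "ring":
        if n < 3:
            raise ValueError("ring needs >= 3 bodies")
        return [(i, (i + 1) % n) for i in range(n)]
    if topo == "clique":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    if isinstance(topo, (list, tuple)):
        edges = []
        for e in topo:
            i, j = int(e[0]), int(e[1])
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid edge {e}")
            edges.append((i, j))
        return edges
    raise ValueError(f"unknown topology {topo!r}")


def make_toy_framework(spec: ToyFrameworkSpec) -> ConstraintNetwork:
    """Build the toy framework as a network of generic bar edges."""
    edges = _toy_edges(spec)
    rng = np.random.default_rng(spec.seed)
    g = spec.gamma
    if isinstance(g, tuple) and len(g) == 3 and g[0] == "uniform":
        gammas = rng.uniform(g[1], g[2], size=len(edges))
    elif np.isscalar(g):
        gammas = np.full(len(edges), float(g))
    else:
        gammas = np.asarray(g, float)
        if len(gammas) != len(edges):
            raise ValueError("gamma sequence length does not match edge count")
    constraints = [
        Constraint(i, j, spec.bars_per_edge, GENERIC, entropy=float(gammas[k]))
        for k, (i, j) in enumerate(edges)
    ]
    return ConstraintNetwork(n_bodies=spec.n_bodies, constraints=constraints)


def make_two_state_network() -> ConstraintNetwork:
    """Two bodies joined by one rotatable bond carrying one torsion.

    The macrostate grid is exactly {N_nat = 0, 1}: a two-level system whose
    C_p peak has the closed form T_m = dH/dS, peak height dH^2/(4 R T_m^2).
    """
    c = Constraint(0, 1, 5, COVALENT_ROTATABLE, label="toy:1:tor")
    return ConstraintNetwork(n_bodies=2, constraints=[c], torsions=[0])


def make_half_independent_network() -> ConstraintNetwork:
    """Engineered network where exactly half the native torsions are
    pebble-game independent in every topology (so qbar_nat = 0.5).

    Bond B-C carries an extra low-entropy bar that locks it before torsion
    placement; bond A-B stays free, so of the two native torsion constraints
    exactly one absorbs a pebble.
    """
    cons = [
        Constraint(0, 1, 5, COVALENT_ROTATABLE, label="toy:1:tor"),
        Constraint(1, 2, 5, COVALENT_ROTATABLE, label="toy:2:tor"),
        Constraint(1, 2, 1, GENERIC, entropy=0.5, label="lock"),
    ]
    return ConstraintNetwork(n_bodies=3, constraints=cons, torsions=[0, 1])


# ---------------------------------------------------------------------------
# idealized peptide ensembles
# ---------------------------------------------------------------------------

_FOLD_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
    "coil": (-70.0, 150.0),
}

# internal coordinates (lengths in A, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H, _B_CA_CB = (
    1.458,
    1.525,
    1.329,
    1.231,
    1.010,
    1.530,
)
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O, _A_C_N_H, _A_N_CA_CB = (
    121.7,
    111.2,
    116.2,
    120.8,
    119.5,
    110.5,
)


def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom D from reference atoms A, B, C (natural extension)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class PeptideEnsembleSpec:
    """Idealized peptide ensemble standing in for MD-derived frames.

    The helix fold uses canonical alpha-helical phi/psi so every i -> i+4
    backbone N-H...O=C pair satisfies the H-bond detection criteria in
    unperturbed frames.  Frames differ by isotropic Gaussian coordinate noise
    of scale ``perturbation_scale`` and by designed-bond toggling: with
    probability ``hbond_toggle_rate`` per frame a designed bond is broken by
    displacing its acceptor beyond the distance cutoff (detection stays the
    single source of truth).  ``suppressed_bonds`` lists designed bonds
    broken in *every* frame (a planted mutation); ``designed_occupancies``
    pins individual designed bonds to exact occupancy fractions via a
    deterministic schedule.
    """

    n_residues: int
    fold: str = "helix"
    n_frames: int = 1
    perturbation_scale: float = 0.0
    hbond_toggle_rate: float = 0.0
    seed: int = 0
    suppressed_bonds: tuple = ()
    designed_occupancies: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if self.n_frames < 1:
            raise ValueError("need at least 1 frame")
        if self.perturbation_scale < 0:
            raise ValueError("perturbation_scale must be >= 0")
        if not (0.0 <= self.hbond_toggle_rate <= 1.0):
            raise ValueError("hbond_toggle_rate must be in [0, 1]")
        if self.fold not in ("helix", "hairpin", "coil"):
            raise ValueError(f"unknown fold {self.fold!r}")


def _residue_dihedrals(spec: PeptideEnsembleSpec) -> list[tuple[float, float]]:
    n = spec.n_residues
    if spec.fold in ("helix", "coil"):
        return [_FOLD_DIHEDRALS["helix" if spec.fold == "helix" else "coil"]] * n
    # hairpin: two strands around a type-I' two-residue turn
    half = (n - 2) // 2
    dihedrals = [_FOLD_DIHEDRALS["strand"]] * half
    dihedrals += [(60.0, 30.0), (90.0, 0.0)]
    dihedrals += [_FOLD_DIHEDRALS["strand"]] * (n - len(dihedrals))
    return dihedrals


def _build_backbone(spec: PeptideEnsembleSpec):
    """Base coordinates, annotations and bonds for one idealized chain."""
    n = spec.n_residues
    dihedrals = _residue_dihedrals(spec)
    pos: dict[tuple[int, str], np.ndarray] = {}
    # seed residue 1
    pos[(1, "N")] = np.zeros(3)
    pos[(1, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    pos[(1, "C")] = pos[(1, "CA")] + _B_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(1, n + 1):
        phi, psi = dihedrals[i - 1]
        if i > 1:
            pos[(i, "N")] = _nerf(
                pos[(i - 1, "N")],
                pos[(i - 1, "CA")],
                pos[(i - 1, "C")],
                _B_C_N,
                _A_CA_C_N,
                dihedrals[i - 2][1],  # psi of previous residue
            )
            pos[(i, "CA")] = _nerf(
                pos[(i - 1, "CA")],
                pos[(i - 1, "C")],
                pos[(i, "N")],
                _B_N_CA,
                _A_C_N_CA,
                180.0,  # omega
            )
            pos[(i, "C")] = _nerf(
                pos[(i - 1, "C")],
                pos[(i, "N")],
                pos[(i, "CA")],
                _B_CA_C,
                _A_N_CA_C,
                phi,
            )
            pos[(i, "H")] = _nerf(
                pos[(i - 1, "CA")],
                pos[(i - 1, "C")],
                pos[(i, "N")],
                _B_N_H,
                _A_C_N_H,
                0.0,  # anti to CA(i), in the peptide plane
            )
            # carbonyl O of the previous residue, anti to this N
            pos[(i - 1, "O")] = _nerf(
                pos[(i, "N")],
                pos[(i - 1, "CA")],
                pos[(i - 1, "C")],
                _B_C_O,
                _A_CA_C_O,
                180.0,
            )
        pos[(i, "CB")] = _nerf(
            pos[(i, "C")],
            pos[(i, "N")],
            pos[(i, "CA")],
            _B_CA_CB,
            _A_N_CA_CB,
            122.6,
        )
    # C-terminal carbonyl O
    pos[(n, "O")] = _nerf(
        pos[(n, "N")],
        pos[(n, "CA")],
        pos[(n, "C")],
        _B_C_O,
        _A_CA_C_O,
        dihedrals[n - 1][1] + 180.0,
    )

    atom_order = ["N", "CA", "C", "O", "CB", "H"]
    names, res_ids, coords = [], [], []
    index: dict[tuple[int, str], int] = {}
    for i in range(1, n + 1):
        for name in atom_order:
            if (i, name) not in pos:
                continue
            index[(i, name)] = len(names)
            names.append(name)
            res_ids.append(i)
            coords.append(pos[(i, name)])

    bonds = []
    for i in range(1, n + 1):
        bonds.append((index[(i, "N")], index[(i, "CA")], 1))
        bonds.append((index[(i, "CA")], index[(i, "C")], 1))
        bonds.append((index[(i, "C")], index[(i, "O")], 2))
        bonds.append((index[(i, "CA")], index[(i, "CB")], 1))
        if (i, "H") in index:
            bonds.append((index[(i, "N")], index[(i, "H")], 1))
        if i < n:
            bonds.append((index[(i, "C")], index[(i + 1, "N")], 1))
    return np.array(coords), names, res_ids, bonds, index


def make_peptide_ensemble(spec: PeptideEnsembleSpec) -> StructureEnsemble:
    """Generate the frame stack with designed H-bonds and perturbations."""
    base, names, res_ids, bonds, index = _build_backbone(spec)
    n_atoms = len(names)

    # designed backbone H-bonds: helix i -> i+4; other folds have none
    designed = []
    if spec.fold == "helix":
        for i in range(5, spec.n_residues + 1):
            designed.append((index[(i, "N")], index[(i - 4, "O")]))

    rng = np.random.default_rng(spec.seed)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        frame = base.copy()
        if spec.perturbation_scale > 0:
            frame = frame + rng.normal(0.0, spec.perturbation_scale, frame.shape)
        for k, (donor, acceptor) in enumerate(designed):
            if k in spec.designed_occupancies:
                occ = spec.designed_occupancies[k]
                present_frames = int(round(occ * spec.n_frames))
                broken = f >= present_frames
            elif k in spec.suppressed_bonds:
                broken = True
            elif spec.hbond_toggle_rate > 0:
                broken = bool(rng.random() < spec.hbond_toggle_rate)
            else:
                broken = False
            if broken:
                direction = frame[acceptor] - frame[donor]
                direction /= np.linalg.norm(direction)
                frame[acceptor] = frame[acceptor] + 2.5 * direction
        coords[f] = frame

    arr = struc.AtomArray(n_atoms)
    arr.coord = coords[0]
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = np.array(res_ids)
    arr.res_name = np.full(n_atoms, "ALA")
    arr.atom_name = np.array(names)
    arr.element = np.array([n[0] for n in names])
    arr.hetero = np.zeros(n_atoms, bool)
    stack = struc.stack([arr] * spec.n_frames)
    stack.coord = coords
    stack.bonds = struc.BondList(
        n_atoms, np.array(bonds, dtype=np.uint32).reshape(-1, 3)
    )
    return StructureEnsemble(frames=stack, designed_hbonds=designed)


# ---------------------------------------------------------------------------
# synthetic heat-capacity curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCpSpec:
    """A C_p(T) curve generated by the DCM at known parameters."""

    true_params: DCMParams
    temperature_grid: tuple
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.temperature_grid, float)
        if len(grid) < 3 or np.any(np.diff(grid) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_cp_curve(
    spec: SyntheticCpSpec,
    network: ConstraintNetwork,
    *,
    tables: TopologyTables | None = None,
    n_samples: int = 200,
    table_seed: int = 0,
) -> CpCurve:
    """DCM heat capacity under the true parameters plus additive Gaussian
    noise; the true parameters are recorded on the curve for recovery tests.
    Degenerate landscapes (no interior C_p peak) raise
    :class:`~qsfr.thermo.LandscapeError`.
    """
    grid = np.asarray(spec.temperature_grid, float)
    if tables is None:
        tables = build_tables(
            network, spec.true_params, n_samples=n_samples, seed=table_seed
        )
    clean = heat_capacity(tables, spec.true_params, grid)
    rng = np.random.default_rng(spec.seed)
    noisy = clean.cp + rng.normal(0.0, spec.noise_sd, size=len(grid))
    curve = CpCurve(grid, noisy)
    curve.true_params = spec.true_params
    return curve


# ---------------------------------------------------------------------------
# config-file specs
# ---------------------------------------------------------------------------


def load_spec(path):
    """Load a generator spec from a YAML/JSON config file.

    The mapping must contain ``kind`` (toy_framework | peptide_ensemble |
    cp_curve); remaining keys are the dataclass fields.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    kind = data.pop("kind")
    if kind == "toy_framework":
        if isinstance(data.get("topology"), list):
            data["topology"] = [tuple(e) for e in data["topology"]]
        return ToyFrameworkSpec(**data)
    if kind == "peptide_ensemble":
        if "suppressed_bonds" in data:
            data["suppressed_bonds"] = tuple(data["suppressed_bonds"])
        return PeptideEnsembleSpec(**data)
    if kind == "cp_curve":
        data["true_params"] = DCMParams(**data["true_params"])
        data["temperature_grid"] = tuple(data["temperature_grid"])
        return SyntheticCpSpec(**data)
    raise ValueError(f"unknown spec kind {kind!r}")
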