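"""Constraint networks: mapping molecular structures onto body-bar graphs.

Every atom is treated as a rigid body with six degrees of freedom, and every
interaction (covalent bond, hydrogen bond, torsional packing constraint)
becomes an edge carrying a number of *bars*, each bar removing one relative
degree of freedom.  The resulting :class:`ConstraintNetwork` is the substrate
for the pebble-game rigidity analysis and for the distance-constraint-model
thermodynamics built on top of it.

Bar conventions (standard body-bar accounting, one residual hinge degree of
freedom per rotatable bond):

* rotatable covalent bond  -> 5 bars
* locked covalent bond     -> 6 bars (double/partial-double, peptide bonds,
  ring bonds and bonds to terminal groups)
* hydrogen bond / salt bridge -> 5 bars, tagged with a component entropy
* torsion (packing) constraint -> +1 bar across the central rotatable bond
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Constraint",
    "ConstraintNetwork",
    "Topology",
    "HBond",
    "MissingHydrogensError",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "ensure_bonds",
    "detect_hbonds",
    "assign_component_entropies",
    "build_network",
    "write_network_tsv",
    "read_network_tsv",
]

# constraint classes
COVALENT_LOCKED = "covalent-locked"
COVALENT_ROTATABLE = "covalent-rotatable"
HBOND = "hbond"
TORSION_NATIVE = "torsion-native"
TORSION_DISORDERED = "torsion-disordered"
GENERIC = "generic"

#: constraint kinds that define the mechanical network (everything except the
#: disordered-torsion probes, which only count residual hinge DOFs)
MECHANICAL_KINDS = frozenset(
    {COVALENT_LOCKED, COVALENT_ROTATABLE, HBOND, TORSION_NATIVE, GENERIC}
)


class MissingHydrogensError(ValueError):
    """Structure lacks hydrogens and heavy-atom-only inference was not allowed."""


@dataclass(frozen=True)
class Constraint:
    """A bar-typed edge between two bodies.

    ``entropy`` is the component entropy in units of R (0 for covalent
    constraints, gamma_t for H-bonds, delta_nat / delta_dis for torsions);
    ``energy`` is the component enthalpy in kcal/mol.
    """

    i: int
    j: int
    bars: int
    kind: str
    entropy: float = 0.0
    energy: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not (1 <= self.bars <= 7):
            raise ValueError(f"bar count {self.bars} outside [1, 7]")
        if self.i == self.j:
            raise ValueError("self-loop constraint")

    @property
    def hinge_capable(self) -> bool:
        """True if this edge leaves exactly one residual rotational DOF."""
        return self.kind == COVALENT_ROTATABLE or (
            self.kind == GENERIC and self.bars == 5
        )


@dataclass(frozen=True)
class HBond:
    """A detected hydrogen bond (salt bridges are a special case)."""

    donor: int
    acceptor: int
    hydrogen: int | None
    energy: float
    is_salt_bridge: bool = False
    distance: float = float("nan")
    angle: float = float("nan")

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor coincide")
        if self.energy > 0:
            raise ValueError("accepted H-bond must have non-positive energy")


@dataclass
class Topology:
    """A realized constraint topology: the input to one pebble-game run.

    ``hb_index[k]`` / ``tor_index[k]`` map constraint ``k`` back to the
    candidate H-bond or torsion-inventory entry it instantiates (-1 if none).
    """

    n_bodies: int
    constraints: list[Constraint]
    hb_index: list[int] = field(default_factory=list)
    tor_index: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.hb_index:
            self.hb_index = [-1] * len(self.constraints)
        if not self.tor_index:
            self.tor_index = [-1] * len(self.constraints)
        for c in self.constraints:
            if not (0 <= c.i < self.n_bodies and 0 <= c.j < self.n_bodies):
                raise ValueError("constraint references invalid body")

    @property
    def total_bars(self) -> int:
        return sum(c.bars for c in self.constraints)


@dataclass
class ConstraintNetwork:
    """Body-bar network of a structure: covalent skeleton, candidate H-bonds
    and the rotatable-torsion inventory.

    ``constraints`` holds the always-present edges (covalent bonds, or generic
    bar edges for toy frameworks).  ``hbonds`` holds the *candidate* H-bond
    constraints whose presence fluctuates between macrostates.  ``torsions``
    indexes the rotatable entries of ``constraints`` that carry a packing
    torsion (native or disordered) in the model.
    """

    n_bodies: int
    constraints: list[Constraint]
    hbonds: list[Constraint] = field(default_factory=list)
    torsions: list[int] = field(default_factory=list)
    #: residue id per body (for profile reporting); may be empty for toys
    body_res_id: np.ndarray | None = None
    body_chain_id: np.ndarray | None = None

    @property
    def n_hb_max(self) -> int:
        return len(self.hbonds)

    @property
    def n_tor(self) -> int:
        return len(self.torsions)

    def torsion_labels(self) -> list[str]:
        return [self.constraints[k].label for k in self.torsions]

    def full_topology(self) -> Topology:
        """Topology with every candidate H-bond present and no torsion bars."""
        cons = list(self.constraints) + list(self.hbonds)
        hb_index = [-1] * len(self.constraints) + list(range(len(self.hbonds)))
        tor_index = [-1] * len(cons)
        return Topology(self.n_bodies, cons, hb_index, tor_index)

    def realize(
        self,
        present_hbonds: "np.ndarray | list[int]",
        native_torsions: "np.ndarray | list[int]",
        delta_nat: float,
        delta_dis: float,
    ) -> Topology:
        """Build the constraint topology of one microstate.

        ``present_hbonds`` selects candidate H-bonds that are formed;
        ``native_torsions`` selects the torsion-inventory entries in the
        native (packed) state, the rest being disordered.  Native torsions add
        one bar across their central bond; disordered torsions add a one-bar
        probe as well, but it is placed last under preferential ordering and
        only counts residual hinge DOFs.
        """
        if delta_dis <= delta_nat:
            raise ValueError("delta_dis must exceed delta_nat")
        native = set(int(t) for t in native_torsions)
        cons = list(self.constraints)
        hb_index = [-1] * len(cons)
        tor_index = [-1] * len(cons)
        for t in present_hbonds:
            cons.append(self.hbonds[int(t)])
            hb_index.append(int(t))
            tor_index.append(-1)
        for k, ci in enumerate(self.torsions):
            base = self.constraints[ci]
            nat = k in native
            cons.append(
                Constraint(
                    base.i,
                    base.j,
                    1,
                    TORSION_NATIVE if nat else TORSION_DISORDERED,
                    entropy=delta_nat if nat else delta_dis,
                    energy=0.0,
                    label=base.label,
                )
            )
            hb_index.append(-1)
            tor_index.append(k)
        return Topology(self.n_bodies, cons, hb_index, tor_index)


# ---------------------------------------------------------------------------
# structure I/O (biotite-backed)
# ---------------------------------------------------------------------------


def read_structure(path) -> struc.AtomArray:
    """Read a single-model PDB file into an AtomArray (first model)."""
    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    return arr


def read_ensemble(path) -> struc.AtomArrayStack:
    """Read a multi-model PDB file into an AtomArrayStack."""
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    return stack


def write_ensemble(stack, path) -> None:
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def ensure_bonds(structure: struc.AtomArray) -> struc.AtomArray:
    """Attach a covalent BondList if the structure has none.

    Standard residues are connected via reference residue names; anything
    unresolved falls back to distance-based inference.
    """
    if structure.bonds is not None and structure.bonds.get_bond_count() > 0:
        return structure
    try:
        bonds = struc.connect_via_residue_names(structure)
        if bonds.get_bond_count() == 0:
            raise ValueError
    except Exception:
        bonds = struc.connect_via_distances(structure)
    structure = structure.copy()
    structure.bonds = bonds
    return structure


# ---------------------------------------------------------------------------
# hydrogen bond detection
# ---------------------------------------------------------------------------

_BASIC_DONORS = {
    ("LYS", "NZ"),
    ("ARG", "NE"),
    ("ARG", "NH1"),
    ("ARG", "NH2"),
    ("HIS", "ND1"),
    ("HIS", "NE2"),
}
_ACIDIC_ACCEPTORS = {
    ("ASP", "OD1"),
    ("ASP", "OD2"),
    ("GLU", "OE1"),
    ("GLU", "OE2"),
}

#: distance (A) of an ideal donor-acceptor pair; the energy well bottoms here
IDEAL_DA_DISTANCE = 2.9
#: angle (deg) beyond which the angular factor saturates
SATURATION_ANGLE = 160.0


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def hbond_energy(
    distance: float,
    angle: float | None,
    *,
    well_depth: float = -8.0,
    d_max: float = 3.5,
    angle_min: float = 100.0,
) -> float:
    """Empirical distance/angle-modulated H-bond well.

    Returns ``well_depth`` at ideal geometry, decaying smoothly to zero at the
    geometric cutoffs.  Only the *ordering* of energies matters downstream (it
    sets the preferential placement order), so any smooth monotone surrogate
    is admissible; this one is the package default and is configurable.
    """
    s_d = (d_max - distance) / (d_max - IDEAL_DA_DISTANCE)
    s_d = max(0.0, min(1.0, s_d))
    if angle is None:
        s_a = 1.0
    else:
        s_a = (angle - angle_min) / (SATURATION_ANGLE - angle_min)
        s_a = max(0.0, min(1.0, s_a))
    return well_depth * s_d * s_a


def detect_hbonds(
    structure: struc.AtomArray,
    *,
    d_da_max: float = 3.5,
    d_ha_max: float = 2.5,
    angle_min: float = 100.0,
    well_depth: float = -8.0,
    allow_heavy_only: bool = False,
) -> list[HBond]:
    """Detect hydrogen bonds (and salt bridges) by geometric criteria.

    Donors are N/O/S heavy atoms with a covalently bound hydrogen; acceptors
    are O/S atoms and under-coordinated N atoms.  A pair is accepted when the
    donor-acceptor distance is <= ``d_da_max``, the hydrogen-acceptor distance
    is <= ``d_ha_max`` and the D-H-A angle is >= ``angle_min``.  Charged
    donor/acceptor pairs are flagged as salt bridges.

    If the structure has no hydrogens, detection proceeds on heavy atoms only
    (distance criterion alone) when ``allow_heavy_only`` is set, and raises
    :class:`MissingHydrogensError` otherwise.
    """
    structure = ensure_bonds(structure)
    coord = structure.coord
    element = structure.element
    n = structure.array_length()
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in structure.bonds.as_array():
        adjacency[int(i)].append(int(j))
        adjacency[int(j)].append(int(i))

    is_h = element == "H"
    has_hydrogens = bool(np.any(is_h))
    if not has_hydrogens and not allow_heavy_only:
        raise MissingHydrogensError(
            "structure has no hydrogens; pass allow_heavy_only=True to infer "
            "H-bonds from heavy-atom geometry"
        )

    heavy_neighbors = [
        [k for k in adjacency[i] if element[k] != "H"] for i in range(n)
    ]

    donor_candidates = []  # (donor, hydrogen or None)
    for i in range(n):
        if element[i] not in ("N", "O", "S"):
            continue
        hs = [k for k in adjacency[i] if element[k] == "H"]
        if hs:
            for h in hs:
                donor_candidates.append((i, h))
        elif not has_hydrogens and element[i] == "N":
            donor_candidates.append((i, None))
        elif not has_hydrogens and element[i] == "O":
            donor_candidates.append((i, None))

    acceptor_candidates = [
        i
        for i in range(n)
        if element[i] in ("O", "S")
        or (element[i] == "N" and len(adjacency[i]) < 3)
    ]

    def excluded(d: int, a: int) -> bool:
        if a == d or a in adjacency[d]:
            return True
        # 1-3 exclusion: shared covalent neighbor
        return bool(set(adjacency[d]) & set(adjacency[a]))

    found: dict[tuple[int, int], HBond] = {}
    for d, h in donor_candidates:
        for a in acceptor_candidates:
            if excluded(d, a):
                continue
            dist = float(np.linalg.norm(coord[d] - coord[a]))
            if dist > d_da_max:
                continue
            if h is not None:
                if float(np.linalg.norm(coord[h] - coord[a])) > d_ha_max:
                    continue
                ang = _angle_deg(coord[d], coord[h], coord[a])
                if ang < angle_min:
                    continue
            else:
                ang = None
            energy = hbond_energy(
                dist, ang, well_depth=well_depth, d_max=d_da_max,
                angle_min=angle_min,
            )
            salt = (
                (structure.res_name[d], structure.atom_name[d]) in _BASIC_DONORS
                and (
                    (structure.res_name[a], structure.atom_name[a])
                    in _ACIDIC_ACCEPTORS
                    or structure.atom_name[a] == "OXT"
                )
            )
            bond = HBond(
                donor=d,
                acceptor=a,
                hydrogen=h,
                energy=energy,
                is_salt_bridge=salt,
                distance=dist,
                angle=float("nan") if ang is None else ang,
            )
            key = (d, a)
            if key not in found or bond.energy < found[key].energy:
                found[key] = bond
    return sorted(found.values(), key=lambda b: (b.donor, b.acceptor))


def assign_component_entropies(
    energies,
    *,
    gamma_min: float = 0.05,
    gamma_max: float = 1.2,
    e_well: float = -8.0,
) -> np.ndarray:
    """Map H-bond energies onto component entropies gamma_t (units of R).

    Affine map of the energy onto [gamma_min, gamma_max]: the strongest bond
    (energy ``e_well``) gets gamma_min, a vanishing bond gets gamma_max.  This
    preserves the lowest-to-highest component-entropy ordering required by
    preferential pebble-game placement.
    """
    e = np.asarray(energies, dtype=float)
    frac = np.clip((e - e_well) / (0.0 - e_well), 0.0, 1.0)
    return gamma_min + (gamma_max - gamma_min) * frac


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def _is_peptide_bond(structure, i: int, j: int) -> bool:
    ni, nj = structure.atom_name[i], structure.atom_name[j]
    if {ni, nj} != {"C", "N"}:
        return False
    return (structure.res_id[i] != structure.res_id[j]) or (
        structure.chain_id[i] != structure.chain_id[j]
    )


def build_network(
    structure: struc.AtomArray,
    hbonds: list[HBond] | None = None,
    *,
    gamma_min: float = 0.05,
    gamma_max: float = 1.2,
) -> ConstraintNetwork:
    """Map a structure (plus detected H-bonds) onto a constraint network.

    Covalent bonds become 5-bar (rotatable) or 6-bar (locked) edges.  A bond
    is rotatable iff it is a single bond, not a peptide/amide bond, not part
    of a ring (a bridge in the covalent graph), and each endpoint carries at
    least one further heavy-atom neighbor (so e.g. methyl and carbonyl
    torsions are locked).  Rotatable bonds form the torsion inventory;
    backbone N-CA and CA-C bonds are labeled phi and psi.  H-bonds become
    5-bar fluctuating edges tagged with component entropies gamma_t.
    """
    structure = ensure_bonds(structure)
    if hbonds is None:
        hbonds = detect_hbonds(structure)
    n = structure.array_length()
    element = structure.element
    bond_array = structure.bonds.as_array()

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j, order in bond_array:
        g.add_edge(int(i), int(j), order=int(order))
    bridges = set(frozenset(e) for e in nx.bridges(g))

    heavy_deg = np.zeros(n, dtype=int)
    for i, j, _ in bond_array:
        i, j = int(i), int(j)
        if element[j] != "H":
            heavy_deg[i] += 1
        if element[i] != "H":
            heavy_deg[j] += 1

    isolated = [i for i in range(n) if g.degree[i] == 0]
    if isolated:
        warnings.warn(
            f"{len(isolated)} disconnected atoms included as isolated bodies",
            stacklevel=2,
        )

    constraints: list[Constraint] = []
    torsions: list[int] = []
    for i, j, order in bond_array:
        i, j = int(i), int(j)
        single = int(order) in (0, 1)  # BondType.ANY or SINGLE
        rotatable = (
            single
            and element[i] != "H"
            and element[j] != "H"
            and not _is_peptide_bond(structure, i, j)
            and frozenset((i, j)) in bridges
            and heavy_deg[i] >= 2
            and heavy_deg[j] >= 2
        )
        if rotatable:
            label = _torsion_label(structure, i, j)
            constraints.append(
                Constraint(i, j, 5, COVALENT_ROTATABLE, label=label)
            )
            torsions.append(len(constraints) - 1)
        else:
            constraints.append(Constraint(i, j, 6, COVALENT_LOCKED))

    gammas = assign_component_entropies(
        [hb.energy for hb in hbonds], gamma_min=gamma_min, gamma_max=gamma_max
    )
    hb_constraints = [
        Constraint(
            hb.donor,
            hb.acceptor,
            5,
            HBOND,
            entropy=float(gammas[k]),
            energy=hb.energy,
            label="salt-bridge" if hb.is_salt_bridge else "hbond",
        )
        for k, hb in enumerate(hbonds)
    ]
    return ConstraintNetwork(
        n_bodies=n,
        constraints=constraints,
        hbonds=hb_constraints,
        torsions=torsions,
        body_res_id=structure.res_id.copy(),
        body_chain_id=structure.chain_id.copy(),
    )


def _torsion_label(structure, i: int, j: int) -> str:
    names = {structure.atom_name[i], structure.atom_name[j]}
    res = int(structure.res_id[i])
    chain = str(structure.chain_id[i])
    if names == {"N", "CA"}:
        kind = "phi"
        res = int(structure.res_id[i if structure.atom_name[i] == "CA" else j])
    elif names == {"CA", "C"}:
        kind = "psi"
        res = int(structure.res_id[i if structure.atom_name[i] == "CA" else j])
    else:
        kind = "chi"
    return f"{chain}:{res}:{kind}"


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------


def write_network_tsv(network: ConstraintNetwork, prefix) -> None:
    """Write the edge list and torsion inventory as TSV files."""
    rows = []
    for c in network.constraints:
        rows.append((c.i, c.j, c.bars, c.kind, c.energy, c.entropy, c.label))
    for c in network.hbonds:
        rows.append((c.i, c.j, c.bars, c.kind, c.energy, c.entropy, c.label))
    df = pd.DataFrame(
        rows, columns=["body_i", "body_j", "bars", "class", "energy", "gamma", "label"]
    )
    df.to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
    tor = pd.DataFrame(
        {
            "constraint": network.torsions,
            "label": network.torsion_labels(),
        }
    )
    tor.to_csv(f"{prefix}.torsions.tsv", sep="\t", index=False)


def read_network_tsv(prefix) -> ConstraintNetwork:
    """Reconstruct a ConstraintNetwork from the TSV pair written above."""
    df = pd.read_csv(f"{prefix}.edges.tsv", sep="\t", keep_default_na=False)
    tor = pd.read_csv(f"{prefix}.torsions.tsv", sep="\t", keep_default_na=False)
    constraints: list[Constraint] = []
    hbonds: list[Constraint] = []
    for row in df.itertuples(index=False):
        c = Constraint(
            int(row.body_i),
            int(row.body_j),
            int(row.bars),
            str(row._3),
            energy=float(row.energy),
            entropy=float(row.gamma),
            label=str(row.label),
        )
        (hbonds if c.kind == HBOND else constraints).append(c)
    n = 0
    for c in constraints + hbonds:
        n = max(n, c.i + 1, c.j + 1)
    return ConstraintNetwork(
        n_bodies=n,
        constraints=constraints,
        hbonds=hbonds,
        torsions=[int(t) for t in tor["constraint"]],
    )
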