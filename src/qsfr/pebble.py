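"""(6,6) body-bar pebble game: exact generic rigidity analysis.

Each body starts with six pebbles (its six degrees of freedom).  A bar
between bodies u and v is *independent* when seven pebbles can be gathered
onto {u, v} (six cover the relative placement already fixed, the seventh is
consumed by the new bar); otherwise the bar is redundant and the failed
pebble search delineates the over-constrained (stressed) region it closes.

Placing constraints in preferential order -- ascending component entropy --
makes the resulting independent set the minimum-entropy basis of the
underlying count matroid, which is what gives the distance constraint model
its lowest-upper-bound conformational entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    ConstraintNetwork,
    Topology,
    TORSION_DISORDERED,
)

__all__ = [
    "RigidityResult",
    "FlexRegion",
    "StressRegion",
    "PebbleGame",
    "preferential_order",
    "analyze",
    "dof_count",
]

_K = 6  # pebbles per body
_L = 6  # quota: a bar needs _L + 1 pebbles on its endpoints


class PebbleGame:
    """Mutable state of a (6,6) pebble game over ``n`` bodies."""

    __slots__ = ("n", "peb", "out")

    def __init__(self, n: int):
        self.n = n
        self.peb = [_K] * n
        # directed multigraph: out[u] maps v -> number of bars oriented u->v
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]

    # -- pebble search ----------------------------------------------------

    def _pull(self, root: int, other: int):
        """Try to move one free pebble onto ``root``.

        Depth-first search along edge orientations, excluding ``root`` and
        ``other`` as donors.  On success the path is reversed and ``None`` is
        returned; on failure the set of visited bodies is returned (this is
        the rigid/over-constrained span of the failed search).
        """
        peb = self.peb
        out = self.out
        prev: dict[int, int] = {}
        seen = {root, other}
        stack = [root]
        while stack:
            x = stack.pop()
            for y in out[x]:
                if y in seen:
                    continue
                seen.add(y)
                prev[y] = x
                if peb[y] > 0:
                    peb[y] -= 1
                    cur = y
                    while cur != root:
                        p = prev[cur]
                        # reverse edge p -> cur
                        m = out[p]
                        if m[cur] == 1:
                            del m[cur]
                        else:
                            m[cur] -= 1
                        out[cur][p] = out[cur].get(p, 0) + 1
                        cur = p
                    peb[root] += 1
                    return None
                stack.append(y)
        return seen

    def _gather(self, u: int, v: int, quota: int):
        """Gather pebbles on {u, v} up to ``quota``.

        Returns ``None`` on success, else the union of the failed search
        regions from both endpoints.
        """
        peb = self.peb
        while peb[u] + peb[v] < quota:
            fail_u = self._pull(u, v)
            if fail_u is None:
                continue
            fail_v = self._pull(v, u)
            if fail_v is None:
                continue
            return fail_u | fail_v
        return None

    def insert_bar(self, u: int, v: int):
        """Insert one bar between u and v.

        Returns ``(True, None)`` if the bar is independent (it then absorbs a
        pebble), or ``(False, region)`` if redundant, where ``region`` is the
        over-constrained body set identified by the failed search.
        """
        if u == v:
            return False, {u}
        region = self._gather(u, v, _L + 1)
        if region is not None:
            return False, region
        if self.peb[u] == 0:
            u, v = v, u
        self.peb[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1
        return True, None

    def mutually_rigid(self, u: int, v: int) -> bool:
        """True if bodies u and v have no relative degree of freedom."""
        if u == v:
            return True
        return self._gather(u, v, _L + 1) is not None

    @property
    def free_pebbles(self) -> int:
        return sum(self.peb)


@dataclass(frozen=True)
class FlexRegion:
    """A flexible region: rigid clusters linked by hinge bonds.

    ``H`` counts the hinge (rotatable-but-rotating) bonds, ``A`` the
    independent disordered torsions (internal DOFs) among them.
    """

    bodies: frozenset
    hinge_bonds: tuple
    H: int
    A: int


@dataclass(frozen=True)
class StressRegion:
    """An over-constrained region: union of overlapping stressed subgraphs.

    ``B`` counts redundant bars, ``L`` the locked rotatable bonds inside.
    """

    bodies: frozenset
    locked_bonds: tuple
    B: int
    L: int


@dataclass
class RigidityResult:
    n_bodies: int
    #: per-constraint independence, as the fraction of the constraint's bars
    #: that absorbed pebbles.  For single-bar constraints (torsions) this is
    #: the binary 0/1 flag; for multi-bar constraints the per-bar fraction is
    #: what keeps the preferential-order entropy a rigorous lowest upper
    #: bound (the weighted independent bar set is a minimum-weight matroid
    #: basis under entropy-ascending placement).
    q: np.ndarray
    independent_bars: int
    redundant_bars: int
    F: int  # internal DOFs (excluding 6 global per connected component)
    n_components: int
    cluster_of: np.ndarray | None = None  # per-body rigid-cluster label
    bond_state: dict = field(default_factory=dict)  # idx -> hinge|locked|isostatic
    flexible_regions: list = field(default_factory=list)
    overconstrained_regions: list = field(default_factory=list)
    f_values: dict = field(default_factory=dict)  # idx -> f_i = h_i - l_i

    @property
    def B(self) -> int:
        return self.redundant_bars


def preferential_order(topology: Topology | ConstraintNetwork) -> list[int]:
    """Placement order: ascending component entropy, ties broken by
    ascending energy then constraint index (stable and deterministic)."""
    cons = _as_topology(topology).constraints
    return sorted(range(len(cons)), key=lambda k: (cons[k].entropy, cons[k].energy, k))


def _as_topology(obj) -> Topology:
    if isinstance(obj, ConstraintNetwork):
        return obj.full_topology()
    return obj


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def analyze(
    topology: Topology | ConstraintNetwork,
    placement_order=None,
    *,
    want_regions: bool = True,
) -> RigidityResult:
    """Run the pebble game and (optionally) the full region decomposition.

    ``placement_order`` must be a permutation of constraint indices; it
    defaults to the preferential (entropy-ascending) order.  Aggregate
    quantities (F, B, cluster partition, regions) are independent of the
    order by the matroid property; only the per-constraint q flags depend
    on it.

    The mechanical decomposition (rigid clusters, hinge states, flexible and
    over-constrained regions) is evaluated on the network *without* the
    disordered-torsion probes; the probes are then placed, in ascending
    entropy order, to count independent internal DOFs (``A``) per flexible
    region.  For topologies without explicit disordered torsions (toy
    frameworks), virtual one-bar probes across each hinge bond play that role.
    """
    topo = _as_topology(topology)
    cons = topo.constraints
    n_cons = len(cons)
    if placement_order is None:
        placement_order = preferential_order(topo)
    else:
        placement_order = list(placement_order)
        if sorted(placement_order) != list(range(n_cons)):
            raise ValueError("placement_order must be a permutation of constraints")

    n = topo.n_bodies

    # ---- q-pass: single game over all constraints in the given order -----
    game = PebbleGame(n)
    q = np.zeros(n_cons, dtype=float)
    independent = 0
    redundant = 0
    comp = _UnionFind(n)
    for k in placement_order:
        c = cons[k]
        comp.union(c.i, c.j)
        absorbed = 0
        for _ in range(c.bars):
            ok, _region = game.insert_bar(c.i, c.j)
            if ok:
                independent += 1
                absorbed += 1
            else:
                redundant += 1
        q[k] = absorbed / c.bars
    n_components = len({comp.find(b) for b in range(n)})
    F = game.free_pebbles - _K * n_components

    result = RigidityResult(
        n_bodies=n,
        q=q,
        independent_bars=independent,
        redundant_bars=redundant,
        F=F,
        n_components=n_components,
    )
    if not want_regions:
        return result

    _decompose(topo, placement_order, result)
    return result


def _decompose(topo: Topology, placement_order, result: RigidityResult) -> None:
    """Mechanical region decomposition (second game, probes last)."""
    cons = topo.constraints
    n = topo.n_bodies
    mech = [k for k in placement_order if cons[k].kind != TORSION_DISORDERED]
    probes = [k for k in placement_order if cons[k].kind == TORSION_DISORDERED]

    game = PebbleGame(n)
    stress_uf = _UnionFind(n)
    fail_events: list[tuple[set, int]] = []  # (region bodies, n redundant bars)
    for k in mech:
        c = cons[k]
        for _ in range(c.bars):
            ok, region = game.insert_bar(c.i, c.j)
            if not ok:
                fail_events.append((set(region), 1))
    for region, _nb in fail_events:
        it = iter(region)
        first = next(it)
        for b in it:
            stress_uf.union(first, b)

    # rigid clusters: transitive closure of pairwise-rigid adjacent bodies
    cluster_uf = _UnionFind(n)
    pairs = {frozenset((cons[k].i, cons[k].j)) for k in mech}
    for pair in pairs:
        u, v = tuple(pair)
        if game.mutually_rigid(u, v):
            cluster_uf.union(u, v)
    cluster_of = np.array([cluster_uf.find(b) for b in range(n)])
    # relabel clusters 0..m-1 deterministically
    labels = {}
    for b in range(n):
        r = cluster_of[b]
        if r not in labels:
            labels[r] = len(labels)
    cluster_of = np.array([labels[r] for r in cluster_of])
    result.cluster_of = cluster_of

    # hinge / locked states for hinge-capable mechanical constraints
    hinge_bonds = []
    locked_bonds = []
    for k in mech:
        c = cons[k]
        if not c.hinge_capable:
            continue
        if cluster_of[c.i] == cluster_of[c.j]:
            locked_bonds.append(k)
        else:
            hinge_bonds.append(k)
            result.bond_state[k] = "hinge"

    # over-constrained regions with B (redundant bars) and L (locked bonds)
    stress_roots = {}
    for region, nb in fail_events:
        root = stress_uf.find(next(iter(region)))
        rec = stress_roots.setdefault(root, {"bodies": set(), "B": 0})
        rec["bodies"].update(region)
        rec["B"] += nb
    region_of_locked: dict[int, int] = {}
    stress_regions = []
    for idx, (root, rec) in enumerate(sorted(stress_roots.items())):
        bodies = rec["bodies"]
        inside = [
            k
            for k in locked_bonds
            if cons[k].i in bodies and cons[k].j in bodies
        ]
        for k in inside:
            region_of_locked[k] = idx
        stress_regions.append(
            StressRegion(
                bodies=frozenset(bodies),
                locked_bonds=tuple(inside),
                B=rec["B"],
                L=len(inside),
            )
        )
    result.overconstrained_regions = stress_regions

    for k in locked_bonds:
        if k in region_of_locked and stress_regions[region_of_locked[k]].B > 0:
            result.bond_state[k] = "locked"
        else:
            result.bond_state[k] = "isostatic"

    # flexible regions: rigid clusters linked by hinge bonds
    reg_uf = _UnionFind(n)
    cluster_rep: dict[int, int] = {}
    for b in range(n):
        lab = int(cluster_of[b])
        if lab in cluster_rep:
            reg_uf.union(cluster_rep[lab], b)
        else:
            cluster_rep[lab] = b
    for k in hinge_bonds:
        reg_uf.union(cons[k].i, cons[k].j)
    region_map: dict[int, list[int]] = {}
    for k in hinge_bonds:
        region_map.setdefault(reg_uf.find(cons[k].i), []).append(k)
    bodies_of_root: dict[int, set[int]] = {}
    for b in range(n):
        root = reg_uf.find(b)
        if root in region_map:
            bodies_of_root.setdefault(root, set()).add(b)

    # probe pass: disordered torsions (or virtual probes on hinge bonds)
    probe_independent: dict[int, bool] = {}  # bond constraint idx -> independent
    if probes:
        ordered = sorted(
            probes, key=lambda k: (cons[k].entropy, cons[k].energy, k)
        )
        for k in ordered:
            c = cons[k]
            ok, _ = game.insert_bar(c.i, c.j)
            probe_independent[k] = ok
            result.bond_state.setdefault(k, "probe")
        # map probe results onto the central rotatable bonds they ride on
        by_pair: dict[frozenset, bool] = {}
        for k, ok in probe_independent.items():
            by_pair[frozenset((cons[k].i, cons[k].j))] = ok
        probe_on_bond = {
            k: by_pair.get(frozenset((cons[k].i, cons[k].j)), False)
            for k in hinge_bonds
        }
    else:
        probe_on_bond = {}
        for k in sorted(hinge_bonds):
            c = cons[k]
            ok, _ = game.insert_bar(c.i, c.j)
            probe_on_bond[k] = ok

    flex_regions = []
    region_of_hinge: dict[int, int] = {}
    for idx, (root, bonds) in enumerate(sorted(region_map.items())):
        bodies = bodies_of_root[root]
        A = sum(1 for k in bonds if probe_on_bond.get(k, False))
        for k in bonds:
            region_of_hinge[k] = idx
        flex_regions.append(
            FlexRegion(
                bodies=frozenset(bodies),
                hinge_bonds=tuple(sorted(bonds)),
                H=len(bonds),
                A=A,
            )
        )
    result.flexible_regions = flex_regions

    # flexibility index ingredients per rotatable bond
    for k in hinge_bonds:
        reg = flex_regions[region_of_hinge[k]]
        result.f_values[k] = reg.A / reg.H if reg.H else 0.0
    for k in locked_bonds:
        if k in region_of_locked:
            reg = stress_regions[region_of_locked[k]]
            result.f_values[k] = -(reg.B / reg.L) if reg.L and reg.B else 0.0
        else:
            result.f_values[k] = 0.0


def dof_count(topology: Topology | ConstraintNetwork) -> int:
    """Internal independent degrees of freedom F (excluding the 6 global
    rigid-body motions of each connected component)."""
    return analyze(topology, want_regions=False).F
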