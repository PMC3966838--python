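"""Brute-force generic rigidity via randomized rigidity-matrix ranks.

Independent cross-check for the pebble game on small frameworks: each bar of
a body-bar framework becomes a row of a rigidity matrix whose entries are the
bar's screw coordinates.  With random (generic) screws the matrix rank equals
the rank of the body-bar count matroid, so internal degrees of freedom,
redundancy and pairwise rigidity can all be read off linear algebra alone.

This module is used only as a test oracle; it never replaces the pebble game.
"""

from __future__ import annotations

import numpy as np

from .network import ConstraintNetwork, Topology

__all__ = ["rank_analysis", "RankOracleResult"]


def _as_topology(obj) -> Topology:
    if isinstance(obj, ConstraintNetwork):
        return obj.full_topology()
    return obj


def _build_rows(topo: Topology, rng: np.random.Generator) -> np.ndarray:
    rows = []
    for c in topo.constraints:
        for _ in range(c.bars):
            screw = rng.standard_normal(6)
            row = np.zeros(6 * topo.n_bodies)
            row[6 * c.i : 6 * c.i + 6] = screw
            row[6 * c.j : 6 * c.j + 6] = -screw
            rows.append(row)
    if not rows:
        return np.zeros((0, 6 * topo.n_bodies))
    return np.array(rows)


def _rank(m: np.ndarray) -> int:
    if m.size == 0:
        return 0
    return int(np.linalg.matrix_rank(m))


class RankOracleResult:
    """F, B and a rigid-cluster partition computed from matrix ranks."""

    def __init__(self, F: int, B: int, cluster_of: np.ndarray):
        self.F = F
        self.B = B
        self.cluster_of = cluster_of

    def same_partition(self, other_labels) -> bool:
        a = np.asarray(self.cluster_of)
        b = np.asarray(other_labels)
        if a.shape != b.shape:
            return False
        # label-invariant comparison
        seen: dict[tuple[int, int], bool] = {}
        remap_a: dict[int, int] = {}
        remap_b: dict[int, int] = {}
        for x, y in zip(a, b):
            ia = remap_a.setdefault(int(x), len(remap_a))
            ib = remap_b.setdefault(int(y), len(remap_b))
            if ia != ib:
                return False
        return True


def rank_analysis(
    topology: Topology | ConstraintNetwork,
    seed: int = 0,
    trials: int = 2,
) -> RankOracleResult:
    """Compute F, B and the rigid-cluster partition by randomized ranks.

    ``trials`` independent random realizations are used and the maximum rank
    taken, guarding against accidental non-generic draws.  The cluster
    partition is the transitive closure of pairwise-rigid adjacent bodies,
    where a pair is rigid iff a random extra bar between them fails to
    increase the matrix rank -- the same closure the pebble game reports.
    """
    topo = _as_topology(topology)
    n = topo.n_bodies
    total_bars = topo.total_bars

    best = None
    for t in range(trials):
        rng = np.random.default_rng((seed, t))
        rows = _build_rows(topo, rng)
        rank = _rank(rows)
        if best is None or rank > best[0]:
            best = (rank, rows, rng)
    rank, rows, rng = best

    # connected components (isolated bodies count)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in topo.constraints:
        ra, rb = find(c.i), find(c.j)
        if ra != rb:
            parent[rb] = ra
    ncomp = len({find(b) for b in range(n)})

    F = 6 * n - rank - 6 * ncomp
    B = total_bars - rank

    # pairwise rigidity on adjacent pairs
    pairs = sorted({(min(c.i, c.j), max(c.i, c.j)) for c in topo.constraints})
    cparent = list(range(n))

    def cfind(x):
        while cparent[x] != x:
            cparent[x] = cparent[cparent[x]]
            x = cparent[x]
        return x

    for u, v in pairs:
        rigid = True
        for t in range(trials):
            trng = np.random.default_rng((seed, 1000 + t))
            screw = trng.standard_normal(6)
            row = np.zeros(6 * n)
            row[6 * u : 6 * u + 6] = screw
            row[6 * v : 6 * v + 6] = -screw
            aug = np.vstack([rows, row]) if rows.size else row[None, :]
            if _rank(aug) > rank:
                rigid = False
                break
        if rigid:
            ru, rv = cfind(u), cfind(v)
            if ru != rv:
                cparent[rv] = ru

    labels = np.array([cfind(b) for b in range(n)])
    return RankOracleResult(F=F, B=B, cluster_of=labels)
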