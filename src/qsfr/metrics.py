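"""Flexibility Index and Cooperativity Correlation profiles.

Both metrics derive from the region decomposition of individual constraint
topologies.  For a rotatable bond that rotates within a flexible region,
h = A/H is the density of independent DOFs in that region; for a bond locked
inside an over-constrained region, l = B/L is the density of redundant
constraints.  The Flexibility Index is the ensemble average of f = h - l
(0 for isostatically locked bonds); the CC matrix tracks which backbone
bond pairs share a flexible region (entry +h) or an over-constrained rigid
region (entry -l), averaged the same way.

Averages run over the native-basin macrostates at T = T_m: topologies are
equal-weighted within a macrostate and Boltzmann-weighted across basin
macrostates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ConstraintNetwork
from .pebble import analyze, preferential_order
from .thermo import DCMParams, Macrostate, TopologyTables, basin_weights

__all__ = [
    "FlexibilityProfile",
    "CCMatrix",
    "qsfr_profiles",
    "flexibility_index",
    "cooperativity_correlation",
]


@dataclass
class FlexibilityProfile:
    """Per-rotatable-bond flexibility index with averaging metadata."""

    table: pd.DataFrame  # chain, res_id, bond, fi
    temperature: float
    n_macrostates: int
    n_topologies: int

    def values(self) -> np.ndarray:
        return self.table["fi"].to_numpy()

    def by_residue(self) -> pd.DataFrame:
        """Backbone-bond FI averaged per residue (phi/psi only)."""
        bb = self.table[self.table["bond"].isin(("phi", "psi"))]
        return (
            bb.groupby(["chain", "res_id"], as_index=False)["fi"]
            .mean()
            .sort_values(["chain", "res_id"], ignore_index=True)
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CCMatrix:
    """Backbone cooperativity-correlation matrix with bond labels."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def to_tsv(self, path, index_path=None) -> None:
        np.savetxt(path, self.values, delimiter="\t")
        if index_path is not None:
            pd.DataFrame({"label": self.labels}).to_csv(
                index_path, sep="\t", index=False
            )


def _parse_label(label: str) -> tuple[str, int, str]:
    chain, res, kind = label.split(":")
    return chain, int(res), kind


def qsfr_profiles(
    network: ConstraintNetwork,
    tables: TopologyTables,
    params: DCMParams,
    T: float,
    basin: list[Macrostate],
    n_samples: int = 25,
    seed: int = 0,
) -> tuple[FlexibilityProfile, CCMatrix]:
    """Compute FI and CC in one sampling pass over the native basin.

    Side-chain rotatable bonds receive FI values, but CC is restricted to the
    backbone phi/psi bonds (proline contributes a single backbone bond).
    """
    if not basin:
        raise ValueError("basin must contain at least one macrostate")
    weights = basin_weights(tables, params, T, basin)
    labels = network.torsion_labels()
    ntor = network.n_tor
    backbone = [
        k for k, lab in enumerate(labels) if _parse_label(lab)[2] in ("phi", "psi")
    ]
    bb_pos = {k: p for p, k in enumerate(backbone)}

    fi = np.zeros(ntor)
    cc = np.zeros((len(backbone), len(backbone)))
    children = np.random.SeedSequence(seed).spawn(len(basin))
    n_topologies = 0
    for m, w, child in zip(basin, weights, children):
        rng = np.random.default_rng(child)
        f_acc = np.zeros(ntor)
        cc_acc = np.zeros_like(cc)
        for _ in range(n_samples):
            present = (
                rng.choice(network.n_hb_max, size=m.n_hb, replace=False)
                if network.n_hb_max
                else np.empty(0, int)
            )
            native = (
                rng.choice(ntor, size=m.n_nat, replace=False)
                if ntor
                else np.empty(0, int)
            )
            topo = network.realize(
                present, native, params.delta_nat, params.delta_dis
            )
            res = analyze(topo, preferential_order(topo), want_regions=True)
            # rotatable-bond constraints sit at the same positions as in
            # network.constraints (realize appends, never reorders)
            for k, ci in enumerate(network.torsions):
                f_acc[k] += res.f_values.get(ci, 0.0)
            tor_at = {ci: k for k, ci in enumerate(network.torsions)}
            for region in res.flexible_regions:
                inv = [
                    bb_pos[tor_at[c]]
                    for c in region.hinge_bonds
                    if c in tor_at and tor_at[c] in bb_pos
                ]
                h = region.A / region.H if region.H else 0.0
                for a in inv:
                    for b in inv:
                        cc_acc[a, b] += h
            for region in res.overconstrained_regions:
                inv = [
                    bb_pos[tor_at[c]]
                    for c in region.locked_bonds
                    if c in tor_at and tor_at[c] in bb_pos
                ]
                l = region.B / region.L if region.L and region.B else 0.0
                for a in inv:
                    for b in inv:
                        cc_acc[a, b] -= l
            n_topologies += 1
        fi += w * f_acc / n_samples
        cc += w * cc_acc / n_samples

    rows = []
    for k, lab in enumerate(labels):
        chain, res_id, kind = _parse_label(lab)
        rows.append({"chain": chain, "res_id": res_id, "bond": kind, "fi": fi[k]})
    profile = FlexibilityProfile(
        table=pd.DataFrame(rows),
        temperature=T,
        n_macrostates=len(basin),
        n_topologies=n_topologies,
    )
    ccm = CCMatrix(values=cc, labels=[labels[k] for k in backbone])
    return profile, ccm


def flexibility_index(
    network: ConstraintNetwork,
    tables: TopologyTables,
    params: DCMParams,
    T: float,
    basin: list[Macrostate],
    n_samples: int = 25,
    seed: int = 0,
) -> FlexibilityProfile:
    """Native-basin-averaged flexibility index per rotatable bond."""
    profile, _ = qsfr_profiles(network, tables, params, T, basin, n_samples, seed)
    return profile


def cooperativity_correlation(
    network: ConstraintNetwork,
    tables: TopologyTables,
    params: DCMParams,
    T: float,
    basin: list[Macrostate],
    n_samples: int = 25,
    seed: int = 0,
) -> CCMatrix:
    """Native-basin-averaged backbone cooperativity-correlation matrix."""
    _, ccm = qsfr_profiles(network, tables, params, T, basin, n_samples, seed)
    return ccm
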