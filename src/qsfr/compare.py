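"""Ensemble machinery and wild-type vs mutant statistics.

Frames stand in for molecular-dynamics snapshots: they are clustered by
radius on CA+CB RMSD, the largest clusters contribute representative
structures weighted by cluster population, and per-representative profiles
are compared between wild type (w) and mutant (m) with the Z-score

    Z = (xbar_m - xbar_w) / sqrt((sigma_m^2 + sigma_w^2) / n_rep)

where means and standard deviations are cluster-weighted.  Positive Z means
increased flexibility in the mutant.  |Z| > 2.33 flags a moderate change
(one-sided normal tail 0.01) and |Z| > 3.33 a large change (tail 0.0005,
odds below 1 in 2300).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.stats import norm

from .network import detect_hbonds

__all__ = [
    "StructureEnsemble",
    "ClusterModel",
    "OccupancyNetwork",
    "Z_MODERATE",
    "Z_LARGE",
    "cluster_frames",
    "weighted_stats",
    "zscore_profile",
    "classify_changes",
    "z_class",
    "tail_probability",
    "odds_reciprocal",
    "distance_to_mutation",
    "hbond_occupancy",
    "occupancy_class",
    "hbn_diff",
    "rmsd_rmsf",
]

Z_MODERATE = 2.33
Z_LARGE = 3.33

CLASSES = (
    "large rigidity increase",
    "moderate rigidity increase",
    "none",
    "moderate flexibility increase",
    "large flexibility increase",
)


@dataclass
class StructureEnsemble:
    """Ordered structure frames sharing atom identity, with an optional
    atom-subset mask used for comparisons (e.g. to exclude a mobile linker)."""

    frames: struc.AtomArrayStack
    mask: np.ndarray | None = None
    #: designed H-bonds (donor, acceptor atom indices); synthetic metadata
    designed_hbonds: list = field(default_factory=list)

    def __post_init__(self):
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if len(self.mask) != self.frames.array_length():
                raise ValueError("mask length does not match atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.stack_depth()

    def frame(self, i: int) -> struc.AtomArray:
        return self.frames[i]


# ---------------------------------------------------------------------------
# superposition / RMSD helpers
# ---------------------------------------------------------------------------


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of two coordinate sets after optimal superposition."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = bc.T @ ac
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = ac - bc @ rot
    return float(np.sqrt((diff**2).sum() / len(a)))


def _comparison_coords(ensemble: StructureEnsemble) -> np.ndarray:
    frames = ensemble.frames
    sel = np.isin(frames.atom_name, ("CA", "CB"))
    if ensemble.mask is not None:
        sel &= ensemble.mask
    if not np.any(sel):
        sel = frames.element != "H"
    return frames.coord[:, sel, :]


def _rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kabsch_rmsd(coords[i], coords[j])
    return d


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Leader clustering of frames with population-weighted representatives."""

    assignments: np.ndarray  # frame -> cluster id (0 = most populated)
    representatives: np.ndarray  # cluster id -> frame index
    weights: np.ndarray  # cluster id -> population
    radius: float

    @property
    def n_clusters(self) -> int:
        return len(self.weights)

    def top_fraction(self, k: int = 10) -> float:
        return float(self.weights[:k].sum() / self.weights.sum())


def _leader_assign(d: np.ndarray, radius: float) -> np.ndarray:
    leaders: list[int] = []
    assign = np.empty(len(d), dtype=int)
    for f in range(len(d)):
        for c, lead in enumerate(leaders):
            if d[f, lead] <= radius:
                assign[f] = c
                break
        else:
            leaders.append(f)
            assign[f] = len(leaders) - 1
    return assign


def cluster_frames(
    ensemble: StructureEnsemble, target_n_clusters: int = 20
) -> ClusterModel:
    """Radius-based (leader) clustering on CA+CB RMSD.

    The radius is auto-tuned by bisection until the cluster count is within
    +-10% of ``target_n_clusters``; the closest achievable count is used if
    the target cannot be hit exactly.  Representatives are the frames nearest
    each cluster centroid (the RMSD medoid), weighted by cluster population.
    Deterministic given the frame order.
    """
    coords = _comparison_coords(ensemble)
    d = _rmsd_matrix(coords)
    n = len(coords)
    tol = max(1, int(round(0.1 * target_n_clusters)))

    if d.max() < 1e-6:  # identical frames up to float32 round-off
        if target_n_clusters > 1:
            warnings.warn("identical frames: returning a single cluster", stacklevel=2)
        assign = np.zeros(n, dtype=int)
        radius = 0.0
    else:
        lo, hi = 0.0, float(d.max())
        best = (None, None, np.inf)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            assign = _leader_assign(d, mid)
            count = assign.max() + 1
            if abs(count - target_n_clusters) < best[2]:
                best = (assign, mid, abs(count - target_n_clusters))
            if count > target_n_clusters:
                lo = mid
            elif count < target_n_clusters:
                hi = mid
            else:
                break
        assign, radius, err = best if best[0] is not None else (assign, mid, 0)
        if err > tol:
            warnings.warn(
                f"cluster count off target by {err} (target {target_n_clusters})",
                stacklevel=2,
            )

    # order clusters by population (descending), ties by first occurrence
    ids, counts = np.unique(assign, return_counts=True)
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], c))
    remap = {old: new for new, old in enumerate(order)}
    assign = np.array([remap[a] for a in assign])
    weights = np.array(sorted(counts, reverse=True))

    reps = np.empty(len(weights), dtype=int)
    for c in range(len(weights)):
        members = np.where(assign == c)[0]
        sub = d[np.ix_(members, members)]
        reps[c] = members[int(np.argmin((sub**2).sum(axis=1)))]
    return ClusterModel(
        assignments=assign, representatives=reps, weights=weights, radius=radius
    )


# ---------------------------------------------------------------------------
# weighted statistics and Z-scores
# ---------------------------------------------------------------------------


def weighted_stats(values, weights) -> tuple[float, float]:
    """Weight-normalized mean and population standard deviation."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if len(v) == 0 or np.any(w <= 0):
        raise ValueError("need >= 1 value with positive weights")
    mean = float(np.sum(w * v) / w.sum())
    var = float(np.sum(w * (v - mean) ** 2) / w.sum())
    return mean, float(np.sqrt(var))


def z_class(z: float, moderate: float = Z_MODERATE, large: float = Z_LARGE) -> str:
    """Significance class of a Z value (positive = more flexible mutant)."""
    if z > large:
        return CLASSES[4]
    if z > moderate:
        return CLASSES[3]
    if z < -large:
        return CLASSES[0]
    if z < -moderate:
        return CLASSES[1]
    return CLASSES[2]


def zscore_profile(
    wt_values,
    wt_weights,
    mut_values,
    mut_weights,
    n_rep: int = 10,
    labels=None,
    moderate: float = Z_MODERATE,
    large: float = Z_LARGE,
) -> pd.DataFrame:
    """Per-item Z-scores between wild-type and mutant representative sets.

    ``*_values`` are (n_representatives, n_items) arrays; means and SDs are
    cluster-weighted.  When both SDs vanish, equal means give Z = 0 and
    unequal means a signed infinity sentinel.
    """
    wt = np.atleast_2d(np.asarray(wt_values, float))
    mu = np.atleast_2d(np.asarray(mut_values, float))
    if wt.shape[1] != mu.shape[1]:
        raise ValueError("wild-type and mutant profiles are not aligned")
    n_items = wt.shape[1]
    rows = []
    for k in range(n_items):
        mw, sw = weighted_stats(wt[:, k], wt_weights)
        mm, sm = weighted_stats(mu[:, k], mut_weights)
        denom = np.sqrt((sm**2 + sw**2) / n_rep)
        if denom == 0.0:
            z = 0.0 if mm == mw else float(np.sign(mm - mw)) * np.inf
        else:
            z = (mm - mw) / denom
        rows.append(
            {
                "label": labels[k] if labels is not None else k,
                "mean_wt": mw,
                "sd_wt": sw,
                "mean_mut": mm,
                "sd_mut": sm,
                "z": z,
                "class": z_class(z, moderate, large),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_rep"] = n_rep
    df.attrs["z_form"] = "(mean_m - mean_w)/sqrt((sd_m^2 + sd_w^2)/n_rep)"
    df.attrs["tails"] = "one-sided"
    return df


def classify_changes(zprofile: pd.DataFrame) -> dict:
    """Per-class counts and the rigidity/flexibility skew summary."""
    counts = {c: int((zprofile["class"] == c).sum()) for c in CLASSES}
    n_rig = counts[CLASSES[0]] + counts[CLASSES[1]]
    n_flex = counts[CLASSES[3]] + counts[CLASSES[4]]
    total = n_rig + n_flex
    pct_rig = 100.0 * n_rig / total if total else 0.0
    pct_flex = 100.0 * n_flex / total if total else 0.0
    return {
        "counts": counts,
        "n_significant": total,
        "pct_increased_rigidity": pct_rig,
        "pct_increased_flexibility": pct_flex,
        "skew": abs(pct_flex - pct_rig),
    }


def tail_probability(z: float) -> float:
    """One-sided standard-normal tail P(Z > z)."""
    return float(norm.sf(z))


def odds_reciprocal(z: float) -> float:
    """Reciprocal odds 1/P(Z > z) of a change this large by chance."""
    return 1.0 / tail_probability(z)


# ---------------------------------------------------------------------------
# distance to mutation
# ---------------------------------------------------------------------------


def distance_to_mutation(
    structure: struc.AtomArray,
    changed_residues,
    mutation_sites,
    bin_width: float = 4.0,
) -> tuple[pd.DataFrame, dict]:
    """CA-CA distance from each changed residue to its nearest mutation site.

    Residues are given as (chain_id, res_id) pairs or plain res_ids.  Returns
    the per-residue table and a summary with the mean distance and a
    histogram of the distances.
    """

    def ca_coord(res):
        chain, rid = res if isinstance(res, tuple) else (None, res)
        sel = (structure.atom_name == "CA") & (structure.res_id == rid)
        if chain is not None:
            sel &= structure.chain_id == chain
        idx = np.where(sel)[0]
        if len(idx) == 0:
            return None
        return structure.coord[idx[0]]

    site_coords = []
    for site in mutation_sites:
        c = ca_coord(site)
        if c is None:
            raise ValueError(f"mutation site {site} has no CA atom")
        site_coords.append(c)
    site_coords = np.array(site_coords)

    rows = []
    for res in changed_residues:
        c = ca_coord(res)
        if c is None:
            warnings.warn(f"residue {res} has no CA atom; skipped", stacklevel=2)
            continue
        dists = np.linalg.norm(site_coords - c, axis=1)
        rows.append({"residue": res, "distance": float(dists.min())})
    df = pd.DataFrame(rows, columns=["residue", "distance"])
    if len(df):
        edges = np.arange(0.0, df["distance"].max() + bin_width, bin_width)
        if len(edges) < 2:
            edges = np.array([0.0, bin_width])
        hist, edges = np.histogram(df["distance"], bins=edges)
    else:
        hist, edges = np.array([], int), np.array([0.0, bin_width])
    summary = {
        "mean_distance": float(df["distance"].mean()) if len(df) else float("nan"),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
    }
    return df, summary


# ---------------------------------------------------------------------------
# H-bond occupancy networks
# ---------------------------------------------------------------------------


def occupancy_class(occ: float) -> str:
    if occ > 0.9:
        return ">0.9"
    if occ > 0.7:
        return "(0.7,0.9]"
    if occ > 0.5:
        return "(0.5,0.7]"
    return "excluded"


@dataclass
class OccupancyNetwork:
    """H-bond occupancies across an ensemble, keyed on donor/acceptor heavy
    atoms (hydrogens are ignored so flipping protons do not split bonds)."""

    table: pd.DataFrame  # donor, acceptor, donor_label, acceptor_label, occupancy, class
    n_frames: int
    floor: float = 0.5

    @property
    def reported(self) -> pd.DataFrame:
        """Bonds above the occupancy floor (the displayed network)."""
        return self.table[self.table["occupancy"] > self.floor].reset_index(drop=True)

    def keys(self) -> set:
        return set(
            zip(self.reported["donor_label"], self.reported["acceptor_label"])
        )


def _atom_label(frame, i: int) -> str:
    return f"{frame.chain_id[i]}:{int(frame.res_id[i])}:{frame.atom_name[i]}"


def hbond_occupancy(
    ensemble: StructureEnsemble, floor: float = 0.5, **detect_kwargs
) -> OccupancyNetwork:
    """Fraction of frames in which each donor/acceptor pair passes H-bond
    detection; bonds at or below the floor are excluded from the reported
    network."""
    from .network import ensure_bonds

    counts: dict[tuple[int, int], int] = {}
    frame0 = ensure_bonds(ensemble.frame(0))
    for f in range(ensemble.n_frames):
        frame = ensemble.frame(f)
        frame.bonds = frame0.bonds
        for hb in detect_hbonds(frame, **detect_kwargs):
            key = (hb.donor, hb.acceptor)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for (d, a), c in sorted(counts.items()):
        occ = c / ensemble.n_frames
        rows.append(
            {
                "donor": d,
                "acceptor": a,
                "donor_label": _atom_label(frame0, d),
                "acceptor_label": _atom_label(frame0, a),
                "occupancy": occ,
                "class": occupancy_class(occ),
            }
        )
    cols = ["donor", "acceptor", "donor_label", "acceptor_label", "occupancy", "class"]
    return OccupancyNetwork(
        table=pd.DataFrame(rows, columns=cols),
        n_frames=ensemble.n_frames,
        floor=floor,
    )


def hbn_diff(
    wt: OccupancyNetwork,
    mut: OccupancyNetwork,
    residue_map: dict | None = None,
) -> dict:
    """Set differences of the reported H-bond networks.

    ``residue_map`` maps mutant residue labels (``chain:res_id``) onto
    wild-type labels for the mutated positions; unmappable labels are
    reported, not silently dropped.  Returns gained/lost/retained bond sets
    with occupancy deltas and per-residue donor+acceptor count deltas.
    """

    def remap(label: str) -> tuple[str, bool]:
        chain_res, atom = label.rsplit(":", 1)
        if residue_map and chain_res in residue_map:
            return f"{residue_map[chain_res]}:{atom}", True
        return label, True

    def keyed(net: OccupancyNetwork, apply_map: bool) -> dict:
        out = {}
        for row in net.reported.itertuples(index=False):
            dl, al = row.donor_label, row.acceptor_label
            if apply_map:
                dl, _ = remap(dl)
                al, _ = remap(al)
            out[(dl, al)] = row.occupancy
        return out

    wt_keys = keyed(wt, apply_map=False)
    mut_keys = keyed(mut, apply_map=True)

    gained = sorted(set(mut_keys) - set(wt_keys))
    lost = sorted(set(wt_keys) - set(mut_keys))
    retained = sorted(set(wt_keys) & set(mut_keys))

    def residue_counts(keys) -> dict:
        counts: dict[str, int] = {}
        for d, a in keys:
            for label in (d, a):
                res = label.rsplit(":", 1)[0]
                counts[res] = counts.get(res, 0) + 1
        return counts

    wt_counts = residue_counts(wt_keys)
    mut_counts = residue_counts(mut_keys)
    residues = sorted(set(wt_counts) | set(mut_counts))
    per_residue = pd.DataFrame(
        {
            "residue": residues,
            "delta_hbond_count": [
                mut_counts.get(r, 0) - wt_counts.get(r, 0) for r in residues
            ],
        }
    )
    return {
        "gained": [(k, mut_keys[k]) for k in gained],
        "lost": [(k, wt_keys[k]) for k in lost],
        "retained": [(k, wt_keys[k], mut_keys[k]) for k in retained],
        "per_residue_delta": per_residue,
    }


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------


def rmsd_rmsf(
    ensemble: StructureEnsemble, mask: np.ndarray | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """CA RMSD of every frame to frame 1 (after superposition) and per-residue
    RMSF about the mean structure."""
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = ensemble.frames
    sel = frames.atom_name == "CA"
    if mask is None:
        mask = ensemble.mask
    if mask is not None:
        sel &= mask
    coords = frames.coord[:, sel, :]
    ref = coords[0]

    aligned = np.empty_like(coords)
    rmsd = np.empty(len(coords))
    refc = ref - ref.mean(axis=0)
    for f in range(len(coords)):
        x = coords[f] - coords[f].mean(axis=0)
        h = x.T @ refc
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        aligned[f] = x @ rot
        rmsd[f] = float(np.sqrt(((aligned[f] - refc) ** 2).sum() / refc.shape[0]))

    mean_struct = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean_struct) ** 2).sum(axis=2).mean(axis=0))
    res_ids = frames.res_id[sel]
    chain_ids = frames.chain_id[sel]
    df = pd.DataFrame({"chain": chain_ids, "res_id": res_ids, "rmsf": rmsf})
    return rmsd, df
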