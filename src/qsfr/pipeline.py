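"""End-to-end orchestration: ensembles -> networks -> DCM -> QSFR -> comparison.

The workflow mirrors the hybrid sampling strategy the model is built for:
an ensemble of frames is clustered on CA+CB RMSD, the most populated
clusters contribute representative structures, the DCM/QSFR machinery runs
on each representative, and all properties are averaged with cluster-size
weights.  Two ensembles (wild type and mutant) are compared through
cluster-weighted Z-scores on per-residue flexibility and through H-bond
occupancy network differencing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import (
    ClusterModel,
    StructureEnsemble,
    classify_changes,
    cluster_frames,
    hbn_diff,
    hbond_occupancy,
    zscore_profile,
)
from .metrics import CCMatrix, FlexibilityProfile, qsfr_profiles
from .network import build_network, detect_hbonds, ensure_bonds
from .thermo import (
    CpCurve,
    DCMParams,
    LandscapeError,
    build_tables,
    heat_capacity,
    native_basin,
)

__all__ = [
    "RunConfig",
    "RepresentativeResult",
    "EnsembleResult",
    "ComparisonReport",
    "analyze_structure",
    "analyze_ensemble",
    "compare_ensembles",
    "run_qsfr",
    "nrep_sensitivity",
]


@dataclass
class RunConfig:
    """Knobs of a pipeline run; all randomness funnels through ``seed``."""

    params: DCMParams = field(default_factory=DCMParams)
    n_representatives: int = 10
    target_clusters: int = 20
    n_samples: int = 200  # MC topologies per macrostate for the q tables
    basin_samples: int = 25  # topologies per basin macrostate for FI/CC
    stride_hb: int = 1
    stride_nat: int = 1
    seed: int = 0
    dg_cut: float | None = None  # native-basin cut, default 3RT
    t_start: float = 60.0
    t_stop: float = 700.0
    t_step: float = 4.0
    z_moderate: float = 2.33
    z_large: float = 3.33
    occupancy_floor: float = 0.5

    def t_grid(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_stop, self.t_step)

    def manifest(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


@dataclass
class RepresentativeResult:
    frame_index: int
    weight: float
    tm: float
    cp: CpCurve
    fi: FlexibilityProfile
    cc: CCMatrix
    n_hbonds: int
    n_torsions: int


@dataclass
class EnsembleResult:
    clusters: ClusterModel
    representatives: list[RepresentativeResult]
    weighted_tm: float

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.representatives], float)

    def fi_by_residue(self) -> tuple[np.ndarray, list]:
        """(n_rep, n_residues) matrix of residue-averaged backbone FI."""
        tables = [r.fi.by_residue() for r in self.representatives]
        keys = list(zip(tables[0]["chain"], tables[0]["res_id"]))
        mat = np.array([t["fi"].to_numpy() for t in tables])
        return mat, keys


@dataclass
class ComparisonReport:
    zprofile: pd.DataFrame
    classification: dict
    hbn: dict
    wt: EnsembleResult
    mut: EnsembleResult


def analyze_structure(
    frame, config: RunConfig, seed: int = 0
) -> tuple[RepresentativeResult, object]:
    """DCM/QSFR analysis of a single structure under fixed parameters."""
    frame = ensure_bonds(frame)
    hbonds = detect_hbonds(frame)
    network = build_network(frame, hbonds)
    tables = build_tables(
        network,
        config.params,
        n_samples=config.n_samples,
        seed=seed,
        stride_hb=config.stride_hb,
        stride_nat=config.stride_nat,
    )
    try:
        cp = heat_capacity(tables, config.params, config.t_grid())
    except LandscapeError:
        # peak outside the configured window (weakly bonded frames can melt
        # at very low T): retry on a maximally wide grid before giving up
        cp = heat_capacity(
            tables, config.params, np.arange(5.0, 1500.0, config.t_step)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        basin = native_basin(tables, config.params, cp.tm, config.dg_cut)
    fi, cc = qsfr_profiles(
        network,
        tables,
        config.params,
        cp.tm,
        basin,
        n_samples=config.basin_samples,
        seed=seed + 1,
    )
    rep = RepresentativeResult(
        frame_index=-1,
        weight=1.0,
        tm=cp.tm,
        cp=cp,
        fi=fi,
        cc=cc,
        n_hbonds=network.n_hb_max,
        n_torsions=network.n_tor,
    )
    return rep, network


def analyze_ensemble(ensemble: StructureEnsemble, config: RunConfig) -> EnsembleResult:
    """Cluster frames, analyze the top representatives, weight by population."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clusters = cluster_frames(ensemble, config.target_clusters)
    n_rep = min(config.n_representatives, clusters.n_clusters)
    reps: list[RepresentativeResult] = []
    frame0 = ensure_bonds(ensemble.frame(0))
    for c in range(n_rep):
        frame = ensemble.frame(int(clusters.representatives[c]))
        frame.bonds = frame0.bonds
        rep, _ = analyze_structure(frame, config, seed=config.seed + 101 * c)
        rep.frame_index = int(clusters.representatives[c])
        rep.weight = float(clusters.weights[c])
        reps.append(rep)
    weights = np.array([r.weight for r in reps])
    tms = np.array([r.tm for r in reps])
    return EnsembleResult(
        clusters=clusters,
        representatives=reps,
        weighted_tm=float(np.sum(weights * tms) / weights.sum()),
    )


def compare_ensembles(
    wt_ensemble: StructureEnsemble,
    mut_ensemble: StructureEnsemble,
    config: RunConfig,
    residue_map: dict | None = None,
) -> ComparisonReport:
    """Full wild-type vs mutant comparison.

    Z-scores are computed on residue-averaged backbone FI across the
    representative sets (positive = more flexible mutant); the H-bond
    occupancy networks of the full ensembles are differenced above the
    occupancy floor.
    """
    wt = analyze_ensemble(wt_ensemble, config)
    mut = analyze_ensemble(mut_ensemble, config)
    wt_fi, wt_keys = wt.fi_by_residue()
    mut_fi, mut_keys = mut.fi_by_residue()
    if wt_keys != mut_keys:
        raise ValueError("wild-type and mutant residues are not aligned")
    z = zscore_profile(
        wt_fi,
        wt.weights,
        mut_fi,
        mut.weights,
        n_rep=min(len(wt.representatives), len(mut.representatives)),
        labels=[f"{c}:{r}" for c, r in wt_keys],
        moderate=config.z_moderate,
        large=config.z_large,
    )
    occ_wt = hbond_occupancy(wt_ensemble, floor=config.occupancy_floor)
    occ_mut = hbond_occupancy(mut_ensemble, floor=config.occupancy_floor)
    hbn = hbn_diff(occ_wt, occ_mut, residue_map)
    return ComparisonReport(
        zprofile=z,
        classification=classify_changes(z),
        hbn=hbn,
        wt=wt,
        mut=mut,
    )


def _pairwise_similarity(vectors: list[np.ndarray]) -> np.ndarray:
    """Pairwise Pearson correlations between flattened profiles."""
    sims = []
    for a in range(len(vectors)):
        for b in range(a + 1, len(vectors)):
            x, y = vectors[a].ravel(), vectors[b].ravel()
            if np.std(x) == 0 or np.std(y) == 0:
                sims.append(1.0 if np.allclose(x, y) else 0.0)
            else:
                sims.append(float(np.corrcoef(x, y)[0, 1]))
    return np.array(sims)


def nrep_sensitivity(result: EnsembleResult, n_rep_range=None) -> pd.DataFrame:
    """Weighted T_m and pairwise FI/CC similarity versus number of
    representatives used (population-ranked)."""
    reps = result.representatives
    if n_rep_range is None:
        n_rep_range = range(2, len(reps) + 1)
    rows = []
    for n in n_rep_range:
        if n > len(reps):
            warnings.warn(
                f"n_rep={n} exceeds available representatives; truncated",
                stacklevel=2,
            )
            n = len(reps)
        sub = reps[:n]
        w = np.array([r.weight for r in sub])
        tm = float(np.sum(w * [r.tm for r in sub]) / w.sum())
        fi_sims = _pairwise_similarity([r.fi.values() for r in sub])
        cc_sims = _pairwise_similarity([r.cc.values for r in sub])
        rows.append(
            {
                "n_rep": n,
                "weighted_tm": tm,
                "fi_sim_median": float(np.median(fi_sims)) if len(fi_sims) else 1.0,
                "fi_sim_q1": float(np.percentile(fi_sims, 25)) if len(fi_sims) else 1.0,
                "fi_sim_q3": float(np.percentile(fi_sims, 75)) if len(fi_sims) else 1.0,
                "cc_sim_median": float(np.median(cc_sims)) if len(cc_sims) else 1.0,
                "cc_sim_q1": float(np.percentile(cc_sims, 25)) if len(cc_sims) else 1.0,
                "cc_sim_q3": float(np.percentile(cc_sims, 75)) if len(cc_sims) else 1.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk-facing entry point
# ---------------------------------------------------------------------------


def run_qsfr(
    wt_path,
    out_dir,
    mut_path=None,
    config: RunConfig | None = None,
    residue_map: dict | None = None,
):
    """Run the pipeline on multi-model PDB inputs and write TSV/JSON reports.

    With one input, per-representative and weighted DCM/QSFR artifacts are
    produced; with two, the full wild-type vs mutant comparison as well.
    """
    from .network import read_ensemble

    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    wt_ens = StructureEnsemble(frames=read_ensemble(wt_path))
    manifest = config.manifest()
    manifest["inputs"] = {"wt": str(wt_path), "mut": str(mut_path) if mut_path else None}

    if mut_path is None:
        result = analyze_ensemble(wt_ens, config)
        _write_ensemble_artifacts(result, out, "wt")
        manifest["weighted_tm"] = result.weighted_tm
        report = None
    else:
        mut_ens = StructureEnsemble(frames=read_ensemble(mut_path))
        report = compare_ensembles(wt_ens, mut_ens, config, residue_map)
        _write_ensemble_artifacts(report.wt, out, "wt")
        _write_ensemble_artifacts(report.mut, out, "mut")
        report.zprofile.to_csv(out / "zscores.tsv", sep="\t", index=False)
        with open(out / "classification.json", "w") as fh:
            json.dump(report.classification, fh, indent=2)
        hbn = {
            "gained": [[list(k), v] for k, v in report.hbn["gained"]],
            "lost": [[list(k), v] for k, v in report.hbn["lost"]],
        }
        with open(out / "hbn_diff.json", "w") as fh:
            json.dump(hbn, fh, indent=2)
        report.hbn["per_residue_delta"].to_csv(
            out / "hbn_per_residue.tsv", sep="\t", index=False
        )
        manifest["weighted_tm"] = {
            "wt": report.wt.weighted_tm,
            "mut": report.mut.weighted_tm,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


def _write_ensemble_artifacts(result: EnsembleResult, out: Path, tag: str) -> None:
    rows = [
        {
            "representative": k,
            "frame": r.frame_index,
            "weight": r.weight,
            "tm": r.tm,
            "n_hbonds": r.n_hbonds,
            "n_torsions": r.n_torsions,
        }
        for k, r in enumerate(result.representatives)
    ]
    pd.DataFrame(rows).to_csv(out / f"{tag}.representatives.tsv", sep="\t", index=False)
    result.representatives[0].fi.to_tsv(out / f"{tag}.fi.tsv")
    result.representatives[0].cc.to_tsv(
        out / f"{tag}.cc.tsv", out / f"{tag}.cc_labels.tsv"
    )
    result.representatives[0].cp.to_tsv(out / f"{tag}.cp.tsv")
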