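"""End-to-end orchestration: timeseries -> edge dynamics -> entropy ->
templates -> variance-component fits -> network/topology/map analyses.

A :class:`RunConfig` holds every stage parameter with defaults matching the
study where stated (band 0.017-0.1 Hz, trim 10, 60 s windows at step one
TR, SampEn m=2 eps=0.2, 16 candidate densities per tail). ``run_full``
executes the whole pipeline on a dataset directory written by
:func:`edgentropy.synth.write_dataset` (or arranged identically by the
user) and writes results plus a manifest under an output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .entropy import SampEnParams, edge_entropy
from .network_stats import (block_average, degree_centrality, fdr_bh,
                            node_entropy, null_edge_shuffle, null_rewire)
from .spatial import map_correlation_test
from .templates import (DEFAULT_DENSITIES, build_similarity,
                        group_mean_entropy, sweep_and_select)
from .tvfc import preprocess_timeseries, sliding_window_correlation
from .varcomp import (VarianceComponentModel, edgewise_variance, impute,
                      quantile_normalize)
from .cognition import first_pc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    data_dir: str = "."
    out_dir: str = "results"
    band: tuple[float, float] = (0.017, 0.1)
    trim: int = 10
    window_seconds: float = 60.0
    step_frames: int = 1
    sampen_m: int = 2
    sampen_eps: float = 0.20
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    n_perm_model: int = 200
    n_perm_network: int = 2000
    n_surrogates: int = 500
    q_fdr: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["densities"] = list(self.densities)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _load_dataset(data_dir: Path):
    subjects = pd.read_csv(data_dir / "subjects.csv")
    parcels = pd.read_csv(data_dir / "parcels.csv")
    series = {}
    for _, row in subjects.iterrows():
        df = pd.read_csv(data_dir / "timeseries" / f"{row.subject_id}.tsv",
                         sep="\t")
        series[row.subject_id] = df.to_numpy(float)
    behavior = covariates = None
    if (data_dir / "behavior.csv").exists():
        behavior = pd.read_csv(data_dir / "behavior.csv", index_col=0)
    if (data_dir / "covariates.csv").exists():
        covariates = pd.read_csv(data_dir / "covariates.csv", index_col=0)
    manifest = None
    if (data_dir / "manifest.json").exists():
        manifest = json.loads((data_dir / "manifest.json").read_text())
    return subjects, parcels, series, behavior, covariates, manifest


def compute_entropy_stacks(cfg: RunConfig):
    """Stages tvfc + entropy for every subject; returns control and patient
    subjects x edges ESE stacks plus bookkeeping."""
    from .tvfc import ParcelTimeseries

    data_dir = Path(cfg.data_dir)
    subjects, parcels, series, behavior, covariates, manifest = _load_dataset(
        data_dir)
    tr = manifest["config"]["tr"] if manifest else 0.8
    params = SampEnParams(m=cfg.sampen_m, eps=cfg.sampen_eps)
    stacks: dict[str, list[np.ndarray]] = {"control": [], "patient": []}
    ids: dict[str, list[str]] = {"control": [], "patient": []}
    edge_idx = None
    for _, row in subjects.iterrows():
        ts = ParcelTimeseries(series[row.subject_id], tr=tr,
                              subject_id=row.subject_id, group=row.group)
        ts = preprocess_timeseries(ts, band=cfg.band, trim=cfg.trim)
        ed = sliding_window_correlation(ts, window_seconds=cfg.window_seconds,
                                        step_frames=cfg.step_frames)
        ev = edge_entropy(ed, params)
        stacks[row.group].append(ev.values)
        ids[row.group].append(row.subject_id)
        edge_idx = ed.edge_idx
    return {
        "controls": np.array(stacks["control"]),
        "patients": np.array(stacks["patient"]),
        "control_ids": ids["control"], "patient_ids": ids["patient"],
        "edge_idx": edge_idx, "parcels": parcels,
        "behavior": behavior, "covariates": covariates,
        "manifest": manifest,
    }


def run_full(cfg: RunConfig) -> dict:
    """Execute every stage and write a result bundle; returns key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = compute_entropy_stacks(cfg)
    controls, patients = bundle["controls"], bundle["patients"]
    parcels = bundle["parcels"]
    mean_ese = group_mean_entropy(controls)

    behavior, covariates = bundle["behavior"], bundle["covariates"]
    if behavior is None:
        raise ValueError("dataset has no behavior table")
    behavior, covariates = impute(behavior, covariates)
    Y = quantile_normalize(behavior).to_numpy()
    X = covariates.to_numpy(float) if covariates is not None else None

    ranking, winners = sweep_and_select(
        mean_ese, patients, Y, X, densities=cfg.densities,
        n_perm=cfg.n_perm_model, seed=cfg.seed)
    ranking.to_csv(out / "cutoff_ranking.csv", index=False)

    fits = {}
    for tail, mask in winners.items():
        R = build_similarity(patients, mask)
        fit = VarianceComponentModel(
            n_perm=cfg.n_perm_model, random_state=cfg.seed).fit(Y, R, X)
        fits[tail] = fit
        pd.DataFrame({
            "edge_position": list(mask.edge_positions)}).to_csv(
                out / f"template_{tail}.csv", index=False)

    labels = parcels
    net_results = {}
    topo = {}
    for tail, mask in winners.items():
        pos = np.array(mask.edge_positions)
        vals = edgewise_variance(Y, X, patients, pos)
        edges = bundle["edge_idx"][pos]
        blocks = block_average(vals, edges, labels)
        _, p_shuffle = null_edge_shuffle(
            vals, edges, labels, n_parcels=len(parcels),
            n_perm=cfg.n_perm_network, seed=cfg.seed)
        p_rewire, rewire_diag = null_rewire(
            vals, edges, labels, n_perm=min(cfg.n_perm_network, 500),
            seed=cfg.seed)
        net_results[tail] = {
            "blocks": blocks, "p_shuffle": p_shuffle,
            "sig_shuffle": fdr_bh(p_shuffle.to_numpy(), cfg.q_fdr),
            "p_rewire": p_rewire, "rewire_diag": rewire_diag,
        }
        blocks.means.to_csv(out / f"blocks_{tail}.csv")
        p_shuffle.to_csv(out / f"blocks_{tail}_p_shuffle.csv")
        cent = degree_centrality(edges, len(parcels),
                                 n_perm=cfg.n_perm_network, seed=cfg.seed)
        topo[tail] = cent
        cent.to_csv(out / f"centrality_{tail}.csv", index=False)

    cortical = parcels.loc[parcels.cortical, "parcel_id"].to_numpy()
    ne = node_entropy(topo["HEN"], topo["LEN"], cortical)
    ne.to_csv(out / "node_entropy.csv", index=False)

    pca = first_pc(Y, measure_names=list(behavior.columns))
    pd.DataFrame({"measure": behavior.columns,
                  "loading": pca.loadings}).to_csv(out / "pca.csv",
                                                   index=False)

    manifest = {
        "config": cfg.to_dict(), "config_hash": cfg.digest(),
        "winners": {t: {"density": m.density, "n_edges": len(m)}
                    for t, m in winners.items()},
        "fits": {t: {"m_overall": f.m_overall_,
                     "mean_variance_explained": f.mean_variance_explained(),
                     "p_wald": f.p_wald_, "p_perm": f.p_perm_}
                 for t, f in fits.items()},
        "pc1_variance_fraction": pca.variance_fraction,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"winners": winners, "fits": fits, "ranking": ranking,
            "network": net_results, "topology": topo, "node_entropy": ne,
            "pca": pca, "bundle": bundle, "mean_ese": mean_ese,
            "Y": Y, "X": X}


def run_controls(patients: np.ndarray, mask_positions: np.ndarray,
                 Y: np.ndarray, X: np.ndarray | None, n_edges_total: int,
                 mode: str, n_perm: int = 200, seed: int = 0
                 ) -> VarianceComponentModel:
    """Control experiments for a fitted template.

    shuffled-edges: permute each patient's masked entropy values
    independently before building R (destroys cross-subject structure);
    random-edges: draw a random edge set of the template's size, the same
    for all patients.
    """
    rng = np.random.default_rng(seed)
    pos = np.asarray(mask_positions, int)
    if mode == "shuffled-edges":
        vals = patients[:, pos].copy()
        for i in range(vals.shape[0]):
            vals[i] = rng.permutation(vals[i])
    elif mode == "random-edges":
        pick = rng.choice(n_edges_total, size=len(pos), replace=False)
        vals = patients[:, pick]
    else:
        raise ValueError("mode must be 'shuffled-edges' or 'random-edges'")
    from .templates import similarity_matrix
    R = similarity_matrix(vals)
    return VarianceComponentModel(n_perm=n_perm, random_state=seed).fit(Y, R, X)
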