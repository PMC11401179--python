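"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the shape of a parcellated resting-state study:
multi-subject parcel timeseries whose edge dynamics carry a planted
regular/irregular contrast, behavioral tables drawn from the
variance-component model Y = XB + C + E with Vec(C) ~ N(0, Sigma_c (x) R)
at known variance fractions, annotation maps with known spatial
autocorrelation, and an 8-system parcel labeling (7 cortical networks plus
subcortex).

Edge-dynamics mechanism
-----------------------
Windowed-correlation series of *uncoupled* signal pairs are already the
"roughest" series this pipeline can produce (the sliding window imposes
their smoothness floor), so the planted contrast is built around that
ceiling:

* every baseline node carries a shared slow source whose amplitude is
  modulated by a slow raised sinusoid; loadings are exactly sign-balanced
  so the source never enters the cross-parcel mean and survives the
  global-mean regression. All baseline pairs therefore share slowly
  drifting correlation -> intermediate edge sample entropy (ESE);
* regular edges are node-disjoint pairs driven by a private AR(1) source
  whose sign on one member switches as a slow telegraph process. The
  windowed correlation is a deep square wave -> lowest ESE;
* irregular nodes are whitened and decoupled from the shared source; every
  edge incident to them is pure correlation sampling noise -> highest ESE.

The irregular set is node-induced (all edges incident to the designated
nodes) because high ESE is physically a node property here: roughness
contaminates every incident edge, so arbitrary high-ESE edge sets are not
realizable by a pairwise mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import edge_index, edges_to_positions, n_edges
from .tvfc import ParcelTimeseries

SYSTEM_LABELS = ["VIS", "SM", "DAT", "SAL", "LIM", "CC", "DMN", "SC"]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped dimensions of a synthetic dataset.

    Defaults mirror the study geometry: 53 controls, 97 patients, 116
    parcels, one ~5.5 min run at TR = 0.8 s (410 frames, which after
    trimming and the 75-frame window yields 316 windows), 7 cognitive
    measures and 5 covariates.
    """

    n_controls: int = 53
    n_patients: int = 97
    n_parcels: int = 116
    n_frames: int = 410
    tr: float = 0.8
    n_measures: int = 7
    n_covariates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_parcels", "n_frames",
                     "n_measures", "n_covariates"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass(frozen=True)
class EdgeRegularityPlan:
    """Planted regular (low-ESE) and irregular (high-ESE) edge sets.

    ``regular_timescale`` is the dwell (in frames) of the telegraph sign
    process driving regular edges; ``irregular_timescale`` the effective
    correlation time of the irregular nodes' signals (1 = white).
    """

    regular_edges: tuple[tuple[int, int], ...]
    irregular_edges: tuple[tuple[int, int], ...]
    irregular_nodes: tuple[int, ...]
    regular_timescale: float = 50.0
    irregular_timescale: float = 1.0

    def __post_init__(self) -> None:
        if set(self.regular_edges) & set(self.irregular_edges):
            raise ValueError("regular and irregular edge sets must be disjoint")
        if self.regular_timescale <= 0 or self.irregular_timescale <= 0:
            raise ValueError("timescales must be positive")
        if self.regular_timescale <= self.irregular_timescale:
            raise ValueError("regular_timescale must exceed irregular_timescale")

    def validate_for(self, n_parcels: int) -> None:
        for (i, j) in (*self.regular_edges, *self.irregular_edges):
            if not 0 <= i < j < n_parcels:
                raise ValueError(f"edge ({i}, {j}) invalid for {n_parcels} parcels")
        if self.regular_timescale < 2:
            raise ValueError(
                f"regular_timescale {self.regular_timescale} is shorter than "
                "2 frames; the telegraph process would be white"
            )


def make_plan(n_parcels: int, n_regular_pairs: int = 8,
              n_irregular_nodes: int = 3, seed: int = 0) -> EdgeRegularityPlan:
    """Build a recoverable plan: disjoint regular pairs plus a node-induced
    irregular set, on mutually exclusive nodes."""
    need = 2 * n_regular_pairs + n_irregular_nodes
    if need > n_parcels:
        raise ValueError(f"plan needs {need} distinct nodes, have {n_parcels}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_parcels)
    reg = tuple(
        (int(min(perm[2 * k], perm[2 * k + 1])),
         int(max(perm[2 * k], perm[2 * k + 1])))
        for k in range(n_regular_pairs)
    )
    w = sorted(int(n) for n in perm[2 * n_regular_pairs:
                                    2 * n_regular_pairs + n_irregular_nodes])
    wset = set(w)
    irr = tuple(
        (int(i), int(j)) for i, j in edge_index(n_parcels)
        if (int(i) in wset) != (int(j) in wset)
        or (int(i) in wset and int(j) in wset)
    )
    return EdgeRegularityPlan(regular_edges=reg, irregular_edges=irr,
                              irregular_nodes=tuple(w))


# ---------------------------------------------------------------------------
# parcel timeseries

def _ar1(rng: np.random.Generator, shape, rho: float) -> np.ndarray:
    e = rng.standard_normal(shape)
    x = np.empty_like(e)
    x[0] = e[0]
    c = np.sqrt(1.0 - rho ** 2)
    for t in range(1, e.shape[0]):
        x[t] = rho * x[t - 1] + c * e[t]
    return x

def _one_subject(rng: np.random.Generator, cfg: SyntheticConfig,
                 plan: EdgeRegularityPlan, c_bg: float, depth: float,
                 c_reg: float, wf_irr: float, slow_period: float,
                 node_rho: float) -> np.ndarray:
    T, P = cfg.n_frames, cfg.n_parcels
    t = np.arange(T)
    X = _ar1(rng, (T, P), node_rho)
    for n in plan.irregular_nodes:
        X[:, n] = (np.sqrt(1 - wf_irr) * X[:, n]
                   + np.sqrt(wf_irr) * rng.standard_normal(T))
    # shared slow source, sign-balanced so it never enters the global mean
    g = _ar1(rng, (T,), node_rho)
    lam = np.ones(P)
    lam[list(plan.irregular_nodes)] = 0.0
    sgn = np.empty(P)
    tot = 0.0
    for n in np.argsort(-lam):
        s = -1.0 if tot > 0 else 1.0
        sgn[n] = s
        tot += s * lam[n]
    phase = rng.uniform(0, 2 * np.pi)
    a = c_bg * (1 - depth + depth * 0.5
                * (1 + np.sin(2 * np.pi * t / slow_period + phase)))
    X += np.outer(a * g, lam * sgn)
    dwell = max(2, int(round(plan.regular_timescale)))
    for (i, j) in plan.regular_edges:
        src = _ar1(rng, (T,), node_rho)
        n_seg = T // dwell + 1
        tel = np.repeat(rng.choice([-1.0, 1.0], n_seg), dwell)[:T]
        X[:, i] += c_reg * tel * src
        X[:, j] += c_reg * src
    # export contract: zero mean, unit variance per parcel
    return (X - X.mean(0)) / X.std(0)


def generate_parcel_timeseries(cfg: SyntheticConfig, plan: EdgeRegularityPlan,
                               c_bg: float = 2.0, depth: float = 0.65,
                               c_reg: float = 2.2, wf_irr: float = 0.9,
                               slow_period: float = 240.0,
                               node_rho: float = 0.9) -> list[ParcelTimeseries]:
    """Per-subject frames x parcels matrices with the planted edge contrast.

    Controls come first (``ctl-000``...), then patients (``pat-000``...).
    Deterministic given ``cfg.seed``.
    """
    plan.validate_for(cfg.n_parcels)
    rng = np.random.default_rng(cfg.seed)
    out: list[ParcelTimeseries] = []
    for k in range(cfg.n_controls):
        X = _one_subject(rng, cfg, plan, c_bg, depth, c_reg, wf_irr,
                         slow_period, node_rho)
        out.append(ParcelTimeseries(X, tr=cfg.tr, subject_id=f"ctl-{k:03d}",
                                    group="control"))
    for k in range(cfg.n_patients):
        X = _one_subject(rng, cfg, plan, c_bg, depth, c_reg, wf_irr,
                         slow_period, node_rho)
        out.append(ParcelTimeseries(X, tr=cfg.tr, subject_id=f"pat-{k:03d}",
                                    group="patient"))
    return out


# ---------------------------------------------------------------------------
# covariates and behavior

def generate_covariates(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Covariate table shaped like the study's: age (years), sex (0/1),
    antipsychotic dose (chlorpromazine-equivalent mg, half-normal), mean
    framewise displacement (mm, lognormal) and phenotype (0/1)."""
    rng = np.random.default_rng(seed)
    age = rng.normal(22.65, 3.36, n_subjects)
    sex = (rng.random(n_subjects) < 0.37).astype(float)
    dose = np.abs(rng.normal(0.0, 220.0, n_subjects))
    s2 = np.log(1 + (0.06 / 0.12) ** 2)
    fd = rng.lognormal(np.log(0.12) - s2 / 2, np.sqrt(s2), n_subjects)
    phen = (rng.random(n_subjects) < 24 / 97).astype(float)
    return pd.DataFrame(
        {"age": age, "sex": sex, "dose": dose, "mean_fd": fd,
         "phenotype": phen},
        index=[f"pat-{k:03d}" for k in range(n_subjects)],
    )


@dataclass
class GenerativeBehaviorSpec:
    """Parameters of Y = XB + C + E with Vec(C) ~ N(0, Sigma_c (x) R)."""

    Sigma_c: np.ndarray
    Sigma_e: np.ndarray
    B: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.Sigma_c = np.asarray(self.Sigma_c, float)
        self.Sigma_e = np.asarray(self.Sigma_e, float)
        self.B = np.asarray(self.B, float)
        self.R = np.asarray(self.R, float)
        P = self.Sigma_c.shape[0]
        if self.Sigma_e.shape != (P, P) or self.B.shape[1] != P:
            raise ValueError("inconsistent dimensions in behavior spec")
        if self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")

    @property
    def variance_fraction(self) -> float:
        tc, te = np.trace(self.Sigma_c), np.trace(self.Sigma_e)
        return float(tc / (tc + te))


def spec_for_fraction(fraction: float, n_measures: int, R: np.ndarray,
                      n_covariates: int = 5,
                      B: np.ndarray | None = None) -> GenerativeBehaviorSpec:
    """Isotropic spec with a planted overall variance fraction."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    P = n_measures
    if B is None:
        B = np.zeros((n_covariates, P))
    return GenerativeBehaviorSpec(
        Sigma_c=fraction * np.eye(P),
        Sigma_e=(1 - fraction) * np.eye(P),
        B=B, R=np.asarray(R, float),
    )


def _psd_root(R: np.ndarray, name: str = "R") -> np.ndarray:
    w, V = np.linalg.eigh(R)
    tol = -1e-8 * max(1.0, float(np.max(np.abs(w))))
    if np.min(w) < tol:
        raise ValueError(
            f"{name} is not positive semi-definite: smallest eigenvalue "
            f"{np.min(w):.3e}"
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def generate_behavior(spec: GenerativeBehaviorSpec, X: np.ndarray,
                      seed: int = 0,
                      subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Draw Y = XB + L_R Z L_c' + E with L_R L_R' = R, L_c L_c' = Sigma_c."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    N = spec.R.shape[0]
    P = spec.Sigma_c.shape[0]
    if X.shape != (spec.B.shape[0],) and X.shape[0] != N:
        raise ValueError("covariate matrix not aligned to R")
    L_R = _psd_root(spec.R, "R")
    L_c = _psd_root(spec.Sigma_c, "Sigma_c")
    w_e = np.linalg.eigvalsh(spec.Sigma_e)
    if np.min(w_e) <= 0:
        raise ValueError(
            f"Sigma_e must be positive definite (eigenvalue {np.min(w_e):.3e})"
        )
    L_e = np.linalg.cholesky(spec.Sigma_e)
    C = L_R @ rng.standard_normal((L_R.shape[1], L_c.shape[1])) @ L_c.T
    E = rng.standard_normal((N, P)) @ L_e.T
    Y = X @ spec.B + C + E
    if subject_ids is None:
        subject_ids = [f"pat-{k:03d}" for k in range(N)]
    cols = MEASURE_NAMES[:P] if P <= len(MEASURE_NAMES) else [
        f"measure_{p}" for p in range(P)]
    return pd.DataFrame(Y, index=subject_ids, columns=cols)


MEASURE_NAMES = ["Flexibility", "INH", "WM", "Reading", "Vocabulary",
                 "EpisodicMemory", "ProcessingSpeed"]


def generate_behavior_mixture(kernels: list[tuple[np.ndarray, float]],
                              n_measures: int, X: np.ndarray,
                              B: np.ndarray | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Y with several kernel-structured components at given fractions.

    ``kernels`` is a list of (R_k, fraction_k); the residual fraction
    1 - sum(fraction_k) is i.i.d. noise. Used to plant different variance
    fractions for two similarity matrices in the same behavioral table.
    """
    fractions = [f for _, f in kernels]
    resid = 1.0 - sum(fractions)
    if resid <= 0:
        raise ValueError("kernel fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    N = kernels[0][0].shape[0]
    P = n_measures
    X = np.asarray(X, float)
    if B is None:
        B = np.zeros((X.shape[1], P))
    Y = X @ B + np.sqrt(resid) * rng.standard_normal((N, P))
    for R, f in kernels:
        L = _psd_root(R)
        Y += np.sqrt(f) * (L @ rng.standard_normal((L.shape[1], P)))
    cols = MEASURE_NAMES[:P] if P <= len(MEASURE_NAMES) else [
        f"measure_{p}" for p in range(P)]
    return pd.DataFrame(Y, index=[f"pat-{k:03d}" for k in range(N)],
                        columns=cols)


# ---------------------------------------------------------------------------
# entropy-feature shortcut (model-level experiments)

def generate_entropy_features(n_subjects: int, n_edges: int,
                              informative: np.ndarray | None = None,
                              n_latent: int = 5, signal: float = 1.0,
                              baseline: float = 0.20, noise: float = 0.05,
                              seed: int = 0) -> np.ndarray:
    """Subjects x edges entropy-like matrix with low-rank subject structure
    on the ``informative`` edges.

    A cheap stand-in for running the full timeseries pipeline when an
    experiment only needs structured similarity matrices (e.g. resampling
    power studies); values are positive and on the scale of typical ESE.
    """
    rng = np.random.default_rng(seed)
    Z = baseline + noise * rng.standard_normal((n_subjects, n_edges))
    if informative is None:
        return Z
    groups = (informative if isinstance(informative, (list, tuple))
              else [informative])
    for grp in groups:  # independent latent block per informative set
        grp = np.asarray(grp, int)
        if grp.size == 0:
            continue
        U = rng.standard_normal((n_subjects, n_latent))
        V = rng.standard_normal((n_latent, grp.size))
        Z[:, grp] += signal * noise * (U @ V) / np.sqrt(n_latent)
    return Z


# ---------------------------------------------------------------------------
# annotation maps, coordinates, labels

def generate_parcel_coords(n_parcels: int, seed: int = 0,
                           box: float = 100.0) -> np.ndarray:
    """Uniform random parcel centroids in a cube (mm-scale units)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, box, size=(n_parcels, 3))


def generate_annotation_map(coords: np.ndarray, range_param: float,
                            seed: int = 0) -> np.ndarray:
    """Gaussian field with exponential covariance exp(-d / range_param) on
    pairwise Euclidean distances; standardized to zero mean, unit variance."""
    coords = np.asarray(coords, float)
    if range_param <= 0:
        raise ValueError("range_param must be positive")
    uniq = np.unique(coords, axis=0)
    if len(uniq) < 3:
        raise ValueError("need >= 3 parcels with distinct coordinates")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    K = np.exp(-d / range_param)
    rng = np.random.default_rng(seed)
    L = _psd_root(K + 1e-10 * np.eye(len(K)), "annotation covariance")
    v = L @ rng.standard_normal(L.shape[1])
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate (constant) annotation map")
    return v / sd


def generate_network_labels(n_parcels: int) -> pd.DataFrame:
    """Assign each parcel one of the 8 systems (7 cortical resting-state
    networks + subcortex), in contiguous blocks; subcortex gets roughly the
    study's share (16 of 116)."""
    if n_parcels < 8:
        raise ValueError("need >= 8 parcels to cover all 8 systems")
    n_sc = max(1, round(n_parcels * 16 / 116))
    n_cort = n_parcels - n_sc
    base, extra = divmod(n_cort, 7)
    sizes = [base + (1 if k < extra else 0) for k in range(7)] + [n_sc]
    labels = []
    for lab, sz in zip(SYSTEM_LABELS, sizes):
        labels.extend([lab] * sz)
    return pd.DataFrame({
        "parcel_id": np.arange(n_parcels),
        "label": labels,
        "cortical": [lab != "SC" for lab in labels],
    })


# ---------------------------------------------------------------------------
# file export

def write_dataset(outdir: str | Path, cfg: SyntheticConfig,
                  plan: EdgeRegularityPlan,
                  subjects: list[ParcelTimeseries],
                  behavior: pd.DataFrame | None = None,
                  covariates: pd.DataFrame | None = None) -> Path:
    """Write timeseries TSVs, tables, parcel metadata and a manifest."""
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    parcel_cols = [f"parcel_{p}" for p in range(cfg.n_parcels)]
    for ts in subjects:
        pd.DataFrame(ts.data, columns=parcel_cols).to_csv(
            outdir / "timeseries" / f"{ts.subject_id}.tsv", sep="\t",
            index=False)
    labels = generate_network_labels(cfg.n_parcels)
    coords = generate_parcel_coords(cfg.n_parcels, seed=cfg.seed)
    meta = labels.assign(x=coords[:, 0], y=coords[:, 1], z=coords[:, 2])
    meta.to_csv(outdir / "parcels.csv", index=False)
    if behavior is not None:
        behavior.to_csv(outdir / "behavior.csv")
    if covariates is not None:
        covariates.to_csv(outdir / "covariates.csv")
    groups = pd.DataFrame({
        "subject_id": [ts.subject_id for ts in subjects],
        "group": [ts.group for ts in subjects],
    })
    groups.to_csv(outdir / "subjects.csv", index=False)
    manifest = {
        "config": {k: getattr(cfg, k) for k in (
            "n_controls", "n_patients", "n_parcels", "n_frames", "tr",
            "n_measures", "n_covariates", "seed")},
        "plan": {
            "regular_edges": [list(e) for e in plan.regular_edges],
            "irregular_edges": [list(e) for e in plan.irregular_edges],
            "irregular_nodes": list(plan.irregular_nodes),
            "regular_timescale": plan.regular_timescale,
            "irregular_timescale": plan.irregular_timescale,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def plan_edge_positions(plan: EdgeRegularityPlan,
                        n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge positions of the planted regular and irregular sets."""
    reg = edges_to_positions(np.array(plan.regular_edges), n_parcels)
    irr = edges_to_positions(np.array(plan.irregular_edges), n_parcels)
    return reg, irr
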