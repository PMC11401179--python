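"""System-level aggregation of edgewise results and graph null models.

Edgewise values on a template are averaged within and between the 8
systems (7 cortical resting-state networks + subcortex). Significance of
block means is assessed against two null models:

* edge shuffle: the template's edges are relocated uniformly among all
  possible edges, carrying their values (size- and density-matched);
* degree/strength-preserving rewire: double-edge swaps on the binary
  template preserve every node's degree exactly, and values are reassigned
  to the rewired topology by matching the original nodal-strength ranking
  (strength is preserved approximately; the distortion is reported).

All permutation p-values use the add-one estimator (1 + #) / (n + 1) and
are one-sided (greater). Node-level summaries are the binary
degree-centrality normalized by the null-mean degree of the edge-shuffle
ensemble, and Node-Entropy, the min-max-rescaled difference of the HEN and
LEN normalized degrees on cortical parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .edges import edge_index
from .synth import SYSTEM_LABELS

__all__ = ["block_average", "null_edge_shuffle", "null_rewire", "fdr_bh",
           "degree_centrality", "node_entropy", "SystemBlocks"]


@dataclass
class SystemBlocks:
    """Symmetric matrix of block means plus per-block edge counts."""

    means: pd.DataFrame
    counts: pd.DataFrame


def _block_accumulate(values: np.ndarray, edges: np.ndarray,
                      label_codes: np.ndarray, n_sys: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    li = label_codes[edges[:, 0]]
    lj = label_codes[edges[:, 1]]
    a, b = np.minimum(li, lj), np.maximum(li, lj)
    flat = a * n_sys + b
    sums = np.bincount(flat, weights=values, minlength=n_sys * n_sys)
    cnts = np.bincount(flat, minlength=n_sys * n_sys)
    S = sums.reshape(n_sys, n_sys)
    C = cnts.reshape(n_sys, n_sys)
    S, C = S + np.triu(S, 1).T, C + np.triu(C, 1).T
    return S, C


def _label_codes(labels: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(labels, pd.DataFrame):
        lab = labels["label"].to_numpy()
    else:
        lab = np.asarray(labels)
    systems = [s for s in SYSTEM_LABELS if s in set(lab)]
    extra = sorted(set(lab) - set(systems))
    systems = systems + extra
    code = {s: k for k, s in enumerate(systems)}
    return np.array([code[s] for s in lab]), systems


def block_average(edge_values: np.ndarray, mask_edges: np.ndarray,
                  labels: pd.DataFrame | np.ndarray) -> SystemBlocks:
    """Mean edge value per unordered system pair over the template edges."""
    values = np.asarray(edge_values, float)
    edges = np.asarray(mask_edges, int)
    if len(values) != len(edges):
        raise ValueError("edge_values and mask_edges must align")
    codes, systems = _label_codes(labels)
    if edges.size and edges.max() >= len(codes):
        raise ValueError("labels do not cover all parcels in the mask")
    ok = np.isfinite(values)
    S, C = _block_accumulate(values[ok], edges[ok], codes, len(systems))
    with np.errstate(invalid="ignore"):
        M = np.where(C > 0, S / np.maximum(C, 1), np.nan)
    return SystemBlocks(
        means=pd.DataFrame(M, index=systems, columns=systems),
        counts=pd.DataFrame(C.astype(int), index=systems, columns=systems),
    )


def null_edge_shuffle(edge_values: np.ndarray, mask_edges: np.ndarray,
                      labels: pd.DataFrame | np.ndarray, n_parcels: int,
                      n_perm: int = 10_000, seed: int = 0
                      ) -> tuple[SystemBlocks, pd.DataFrame]:
    """Relocate the template's edges uniformly among all possible edges
    (values attached) and compare block means; one-sided greater p-values."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = np.asarray(edge_values, float)
    edges = np.asarray(mask_edges, int)
    ok = np.isfinite(values)
    values, edges = values[ok], edges[ok]
    codes, systems = _label_codes(labels)
    n_sys = len(systems)
    emp_S, emp_C = _block_accumulate(values, edges, codes, n_sys)
    with np.errstate(invalid="ignore"):
        emp = np.where(emp_C > 0, emp_S / np.maximum(emp_C, 1), np.nan)
    all_edges = edge_index(n_parcels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((n_sys, n_sys))
    valid = np.zeros((n_sys, n_sys))
    for _ in range(n_perm):
        pick = rng.choice(len(all_edges), size=len(edges), replace=False)
        S, C = _block_accumulate(values, all_edges[pick], codes, n_sys)
        with np.errstate(invalid="ignore"):
            m = np.where(C > 0, S / np.maximum(C, 1), np.nan)
        comp = np.isfinite(m) & np.isfinite(emp)
        exceed += np.where(comp & (m >= emp), 1, 0)
        valid += comp
    p = (1 + exceed) / (np.maximum(valid, 1) + 1)
    p[~np.isfinite(emp)] = np.nan
    blocks = SystemBlocks(
        means=pd.DataFrame(emp, index=systems, columns=systems),
        counts=pd.DataFrame(emp_C.astype(int), index=systems, columns=systems))
    return blocks, pd.DataFrame(p, index=systems, columns=systems)


def null_value_permutation(edge_values: np.ndarray, mask_edges: np.ndarray,
                           labels: pd.DataFrame | np.ndarray,
                           n_perm: int = 10_000, seed: int = 0
                           ) -> pd.DataFrame:
    """Alternative null: permute values over the fixed template topology.

    Provided for comparison with :func:`null_edge_shuffle`; the two agree
    in distribution when block membership is exchangeable.
    """
    values = np.asarray(edge_values, float)
    edges = np.asarray(mask_edges, int)
    ok = np.isfinite(values)
    values, edges = values[ok], edges[ok]
    codes, systems = _label_codes(labels)
    n_sys = len(systems)
    emp_S, emp_C = _block_accumulate(values, edges, codes, n_sys)
    with np.errstate(invalid="ignore"):
        emp = np.where(emp_C > 0, emp_S / np.maximum(emp_C, 1), np.nan)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((n_sys, n_sys))
    for _ in range(n_perm):
        S, C = _block_accumulate(rng.permutation(values), edges, codes, n_sys)
        with np.errstate(invalid="ignore"):
            m = np.where(C > 0, S / np.maximum(C, 1), np.nan)
        exceed += np.where(np.isfinite(m) & np.isfinite(emp) & (m >= emp), 1, 0)
    p = (1 + exceed) / (n_perm + 1)
    p[~np.isfinite(emp)] = np.nan
    return pd.DataFrame(p, index=systems, columns=systems)


def _rewire_once(G: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    H = G.copy()
    n_swap = max(1, 10 * H.number_of_edges())
    seed = int(rng.integers(0, 2 ** 31 - 1))
    try:
        nx.double_edge_swap(H, nswap=n_swap, max_tries=50 * n_swap,
                            seed=seed)
    except nx.NetworkXException as err:
        raise ValueError(f"mask graph too constrained to rewire: {err}")
    return H


def null_rewire(edge_values: np.ndarray, mask_edges: np.ndarray,
                labels: pd.DataFrame | np.ndarray, n_perm: int = 10_000,
                seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Degree-preserving rewire null with strength-aware value reassignment.

    Each permutation performs double-edge swaps (exact degree preservation)
    and then reassigns the original values to the rewired edges: edges are
    ordered by the sum of their endpoints' original strengths and the
    sorted values are mapped onto that order, which approximately preserves
    the nodal strength sequence. Returns block p-values and diagnostics
    (mean Spearman correlation of original vs rewired strengths).
    """
    values = np.asarray(edge_values, float)
    edges = np.asarray(mask_edges, int)
    ok = np.isfinite(values)
    values, edges = values[ok], edges[ok]
    codes, systems = _label_codes(labels)
    n_sys = len(systems)
    n_parcels = len(codes)
    emp_S, emp_C = _block_accumulate(values, edges, codes, n_sys)
    with np.errstate(invalid="ignore"):
        emp = np.where(emp_C > 0, emp_S / np.maximum(emp_C, 1), np.nan)
    G = nx.Graph()
    G.add_nodes_from(range(n_parcels))
    G.add_edges_from(map(tuple, edges))
    strength = np.zeros(n_parcels)
    np.add.at(strength, edges[:, 0], values)
    np.add.at(strength, edges[:, 1], values)
    sorted_vals = np.sort(values)[::-1]
    rng = np.random.default_rng(seed)
    exceed = np.zeros((n_sys, n_sys))
    spearmans = []
    from scipy.stats import spearmanr
    for it in range(n_perm):
        H = _rewire_once(G, rng)
        new_edges = np.array(H.edges(), dtype=int)
        endpoint_strength = strength[new_edges[:, 0]] + strength[new_edges[:, 1]]
        order = np.argsort(-endpoint_strength)
        new_vals = np.empty(len(values))
        new_vals[order] = sorted_vals
        S, C = _block_accumulate(new_vals, new_edges, codes, n_sys)
        with np.errstate(invalid="ignore"):
            m = np.where(C > 0, S / np.maximum(C, 1), np.nan)
        exceed += np.where(np.isfinite(m) & np.isfinite(emp) & (m >= emp), 1, 0)
        if it < 50:  # strength-distortion diagnostic on a subsample
            s_new = np.zeros(n_parcels)
            np.add.at(s_new, new_edges[:, 0], new_vals)
            np.add.at(s_new, new_edges[:, 1], new_vals)
            on = strength != 0
            if on.sum() > 2:
                spearmans.append(spearmanr(strength[on], s_new[on]).statistic)
    p = (1 + exceed) / (n_perm + 1)
    p[~np.isfinite(emp)] = np.nan
    diag = {"strength_spearman_mean": float(np.mean(spearmans))
            if spearmans else np.nan}
    return pd.DataFrame(p, index=systems, columns=systems), diag


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs propagate as not-significant."""
    p = np.asarray(pvals, float).ravel()
    out = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return out.reshape(np.asarray(pvals).shape)


def degree_centrality(mask_edges: np.ndarray, n_parcels: int,
                      n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Binary degree per node, normalized by the mean degree of size- and
    density-matched random networks (uniform edge relocation)."""
    edges = np.asarray(mask_edges, int)
    if len(edges) == 0:
        raise ValueError("empty template")
    deg = np.zeros(n_parcels)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    all_edges = edge_index(n_parcels)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros(n_parcels)
    exceed = np.zeros(n_parcels)
    for _ in range(n_perm):
        pick = rng.choice(len(all_edges), size=len(edges), replace=False)
        nd = np.zeros(n_parcels)
        np.add.at(nd, all_edges[pick, 0], 1)
        np.add.at(nd, all_edges[pick, 1], 1)
        null_sum += nd
        exceed += nd >= deg
    null_mean = null_sum / n_perm
    return pd.DataFrame({
        "parcel_id": np.arange(n_parcels),
        "degree": deg.astype(int),
        "null_mean": null_mean,
        "normalized": deg / null_mean,
        "p": (1 + exceed) / (n_perm + 1),
    })


def node_entropy(cent_hen: pd.DataFrame, cent_len: pd.DataFrame,
                 cortical_ids: np.ndarray) -> pd.DataFrame:
    """Min-max-rescaled HEN - LEN normalized-degree difference on cortex."""
    ids = np.asarray(cortical_ids, int)
    h = cent_hen.set_index("parcel_id").loc[ids, "normalized"].to_numpy()
    l = cent_len.set_index("parcel_id").loc[ids, "normalized"].to_numpy()
    diff = h - l
    lo, hi = diff.min(), diff.max()
    if hi == lo:
        raise ValueError(
            "degenerate Node-Entropy: HEN-LEN difference is constant")
    return pd.DataFrame({"parcel_id": ids,
                         "node_entropy": (diff - lo) / (hi - lo)})
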