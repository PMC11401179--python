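"""High-/low-entropy network templates and patient similarity matrices.

Templates are built by proportional thresholding of the edge-sample-entropy
vector averaged across the template group (healthy controls): at density d
the HEN template keeps the floor(d * E) edges with the largest group-mean
ESE, the LEN template the smallest. Each template is used as a binary mask
to extract patients' ESE values, which are correlated across patients to
form the similarity matrix R driving the variance-component model.

The operating density per tail is chosen by sweeping a grid of candidate
densities and ranking each candidate on four criteria: mean variance
explained (higher better), p-Wald (lower better), p-Perm (lower better)
and concordance |p-Perm - p-Wald| (smaller better). The winner is the
candidate with the best average rank; ties break toward the sparser
template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .varcomp import VarianceComponentModel

logger = logging.getLogger(__name__)

DEFAULT_DENSITIES = tuple(np.round(np.linspace(0.01, 0.16, 16), 4))


@dataclass(frozen=True)
class TemplateMask:
    """Binary edge template at a stated density, tail-labeled."""

    tail: str  # "HEN" | "LEN"
    density: float
    edge_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.tail not in ("HEN", "LEN"):
            raise ValueError("tail must be 'HEN' or 'LEN'")
        if len(self.edge_positions) < 1:
            raise ValueError("template must contain at least one edge")

    def __len__(self) -> int:
        return len(self.edge_positions)


def group_mean_entropy(vectors: list[np.ndarray] | np.ndarray,
                       max_undefined_frac: float = 0.5) -> np.ndarray:
    """Elementwise mean ESE across the template group, skipping undefined
    (NaN) values; edges undefined in more than half the group are dropped
    (NaN) and logged."""
    stack = np.asarray(vectors, float)
    if stack.ndim != 2 or stack.shape[0] < 2:
        raise ValueError("need >= 2 subjects with identical edge indexing")
    undef = np.isnan(stack).mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    drop = undef > max_undefined_frac
    if drop.any():
        logger.info("dropping %d edges undefined in > %d%% of the group",
                    int(drop.sum()), int(100 * max_undefined_frac))
        mean[drop] = np.nan
    return mean


def proportional_threshold(mean_ese: np.ndarray, density: float,
                           tail: str) -> TemplateMask:
    """Keep the floor(density * E) largest (HEN) or smallest (LEN) edges.

    Undefined edges are excluded before thresholding. Ties at the cutoff
    break by canonical edge order (lower position first).
    """
    mean_ese = np.asarray(mean_ese, float)
    E = mean_ese.size
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    k = int(np.floor(density * E))
    if k < 1:
        raise ValueError(f"density {density} keeps zero of {E} edges")
    valid = np.flatnonzero(np.isfinite(mean_ese))
    if len(valid) < k:
        raise ValueError("not enough defined edges for requested density")
    vals = mean_ese[valid]
    if tail == "HEN":
        order = np.lexsort((valid, -vals))  # descending value, then position
    elif tail == "LEN":
        order = np.lexsort((valid, vals))
    else:
        raise ValueError("tail must be 'HEN' or 'LEN'")
    chosen = np.sort(valid[order[:k]])
    return TemplateMask(tail=tail, density=float(density),
                        edge_positions=tuple(int(e) for e in chosen))


def similarity_matrix(masked_values: np.ndarray) -> np.ndarray:
    """Pearson correlation across subjects of masked entropy vectors.

    ``masked_values`` is subjects x masked-edges. NaNs trigger
    pairwise-complete correlation (logged). The diagonal is set to 1.
    """
    V = np.asarray(masked_values, float)
    n = V.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects for a similarity matrix")
    if np.isnan(V).any():
        logger.info("similarity: %d NaN entries; using pairwise-complete "
                    "correlation", int(np.isnan(V).sum()))
        R = pd.DataFrame(V.T).corr(min_periods=2).to_numpy()
    else:
        sd = V.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(f"subject {bad} has zero variance over the mask")
        R = np.corrcoef(V)
    np.fill_diagonal(R, 1.0)
    return R


def build_similarity(patients: list[np.ndarray] | np.ndarray,
                     mask: TemplateMask) -> np.ndarray:
    """Similarity matrix of patients restricted to a template's edges."""
    stack = np.asarray(patients, float)
    return similarity_matrix(stack[:, list(mask.edge_positions)])


def sweep_and_select(mean_ese: np.ndarray, patients: np.ndarray,
                     Y: np.ndarray, X: np.ndarray | None = None,
                     densities: tuple[float, ...] = DEFAULT_DENSITIES,
                     n_perm: int = 200, seed: int = 0,
                     ) -> tuple[pd.DataFrame, dict[str, TemplateMask]]:
    """Rank candidate densities per tail and pick the operating template.

    Returns the full ranking table (one row per candidate; 16 densities per
    tail -> 32 rows) and the winning mask per tail.
    """
    densities = tuple(densities)
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")
    rows = []
    masks: dict[tuple[str, float], TemplateMask] = {}
    for tail in ("HEN", "LEN"):
        for d in densities:
            mask = proportional_threshold(mean_ese, d, tail)
            masks[(tail, d)] = mask
            try:
                R = build_similarity(patients, mask)
                fit = VarianceComponentModel(
                    n_perm=n_perm, random_state=seed).fit(Y, R, X)
                rows.append({
                    "tail": tail, "density": d, "n_edges": len(mask),
                    "mean_variance_explained": fit.mean_variance_explained(),
                    "p_wald": fit.p_wald_, "p_perm": fit.p_perm_,
                    "concordance": abs(fit.p_perm_ - fit.p_wald_),
                    "failed": False,
                })
            except ValueError as err:
                logger.warning("candidate %s@%g failed: %s", tail, d, err)
                rows.append({
                    "tail": tail, "density": d, "n_edges": len(mask),
                    "mean_variance_explained": np.nan, "p_wald": np.nan,
                    "p_perm": np.nan, "concordance": np.nan, "failed": True,
                })
    table = pd.DataFrame(rows)
    winners: dict[str, TemplateMask] = {}
    for tail in ("HEN", "LEN"):
        sub = table[(table["tail"] == tail) & (~table["failed"])].copy()
        if sub.empty:
            raise ValueError(f"all candidate densities failed for {tail}")
        # rank: 1 = worst; higher rank is better on every criterion
        sub["rank_mve"] = sub.mean_variance_explained.rank(ascending=True)
        sub["rank_wald"] = sub.p_wald.rank(ascending=False)
        sub["rank_perm"] = sub.p_perm.rank(ascending=False)
        sub["rank_conc"] = sub.concordance.rank(ascending=False)
        sub["avg_rank"] = sub[[
            "rank_mve", "rank_wald", "rank_perm", "rank_conc"]].mean(axis=1)
        best = sub.sort_values(
            ["avg_rank", "density"], ascending=[False, True]).iloc[0]
        winners[tail] = masks[(tail, float(best.density))]
        table.loc[sub.index, ["rank_mve", "rank_wald", "rank_perm",
                              "rank_conc", "avg_rank"]] = sub[[
            "rank_mve", "rank_wald", "rank_perm", "rank_conc",
            "avg_rank"]].to_numpy()
    return table, winners
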