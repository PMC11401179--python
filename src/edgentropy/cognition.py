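"""Integration structure of the cognitive battery: first principal
component and bootstrap contrasts of its loadings between measure groups."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "first_pc", "loading_contrast"]


@dataclass
class PCAResult:
    """First principal component of the measure correlation matrix."""

    loadings: np.ndarray          # unit-norm, oriented so the sum is positive
    variance_fraction: float      # lambda_1 / P
    measure_names: list[str] | None = None


def first_pc(Y: np.ndarray, measure_names: list[str] | None = None) -> PCAResult:
    """Leading eigenvector of the correlation matrix of Y (N x P).

    The component is oriented so that the loading sum is positive; with an
    all-positive correlation structure this gives all-positive loadings.
    """
    Y = np.asarray(Y, float)
    N, P = Y.shape
    if N <= P:
        raise ValueError("need more subjects than measures")
    C = np.corrcoef(Y.T)
    w, V = np.linalg.eigh(C)
    v1 = V[:, -1]
    if v1.sum() < 0:
        v1 = -v1
    return PCAResult(loadings=v1, variance_fraction=float(w[-1] / P),
                     measure_names=measure_names)


def loading_contrast(Y: np.ndarray, group_a: np.ndarray, group_b: np.ndarray,
                     n_boot: int = 2000, alpha: float = 0.05,
                     seed: int = 0) -> dict:
    """Percentile bootstrap CI for mean(loadings_A) - mean(loadings_B).

    Subjects are resampled with replacement; each replicate's first PC is
    re-oriented (positive loading sum) before the contrast so sign flips
    cannot bimodalize the bootstrap distribution.
    """
    Y = np.asarray(Y, float)
    a = np.asarray(group_a, int)
    b = np.asarray(group_b, int)
    if len(a) == 0 or len(b) == 0 or set(a) & set(b):
        raise ValueError("groups must be disjoint and nonempty")
    base = first_pc(Y)
    observed = float(base.loadings[a].mean() - base.loadings[b].mean())
    rng = np.random.default_rng(seed)
    N = Y.shape[0]
    boots = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, N, N)
        pc = first_pc(Y[idx])
        boots[k] = pc.loadings[a].mean() - pc.loadings[b].mean()
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return {
        "difference": observed, "ci_lo": float(lo), "ci_hi": float(hi),
        "excludes_zero": bool(lo > 0 or hi < 0), "n_boot": n_boot,
        "pc1_variance_fraction": base.variance_fraction,
    }
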