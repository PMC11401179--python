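"""Sample entropy (SampEn) of edge timeseries.

SampEn(m, eps) of a signal x of length N is -ln(U^{m+1} / U^m), where U^m
is the average over template vectors of the fraction of other templates
within Chebyshev distance r = eps * sigma_x (sigma_x the population SD of
x). Matching is boundary-inclusive: a distance exactly equal to r counts
(Heaviside convention Theta(0) = 1). Both the m- and (m+1)-length match
counts run over the same N - m template vectors, excluding self-matches,
with denominator N - m - 1.

A constant signal has sigma = 0, hence r = 0 and all distances 0, so every
template matches and SampEn is 0. When no (m+1)-length (or m-length) match
exists the statistic is undefined and NaN is returned rather than +inf;
downstream template construction skips flagged edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .tvfc import EdgeDynamics

__all__ = ["SampEnParams", "sample_entropy", "edge_entropy", "EdgeSampleEntropy",
           "EntropyVector"]


@dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension m and tolerance scale eps (r = eps * sigma)."""

    m: int = 2
    eps: float = 0.20

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.eps <= 0:
            raise ValueError("tolerance scale eps must be > 0")


@dataclass
class EntropyVector:
    """Per-edge SampEn values for one subject (NaN = undefined)."""

    values: np.ndarray
    subject_id: str = "sub-0"
    group: str = "control"
    params: SampEnParams = SampEnParams()

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Off-diagonal match counts at embedding lengths m and m+1."""
    N = x.size
    nv = N - m  # number of template vectors at both lengths
    A = np.abs(x[:, None] - x[None, :])
    D = A[:nv, :nv].copy()
    for k in range(1, m):
        np.maximum(D, A[k:k + nv, k:k + nv], out=D)
    cm = int((D <= r).sum()) - nv  # diagonal always matches; remove it
    np.maximum(D, A[m:m + nv, m:m + nv], out=D)
    cm1 = int((D <= r).sum()) - nv
    return cm, cm1


def sample_entropy(x: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """SampEn of a 1-D signal; NaN when undefined (zero match count)."""
    x = np.asarray(x, dtype=float).ravel()
    N = x.size
    if N <= params.m + 1:
        raise ValueError(f"signal length {N} too short for m={params.m}")
    r = params.eps * x.std()  # population (1/N) standard deviation
    cm, cm1 = _match_counts(x, params.m, r)
    if cm == 0 or cm1 == 0:
        return float("nan")
    # U^{m+1}/U^m reduces to the count ratio (same normalization both lengths)
    return float(-np.log(cm1 / cm))


def edge_entropy(ed: EdgeDynamics,
                 params: SampEnParams = SampEnParams()) -> EntropyVector:
    """SampEn of every edge column of an :class:`EdgeDynamics` matrix."""
    est = EdgeSampleEntropy(m=params.m, eps=params.eps)
    vals = est.transform(ed.data)
    return EntropyVector(values=vals, subject_id=ed.subject_id,
                         group=ed.group, params=params)


class EdgeSampleEntropy(TransformerMixin, BaseEstimator):
    """Column-wise SampEn transformer (windows x edges -> edges)."""

    def __init__(self, m: int = 2, eps: float = 0.20):
        self.m = m
        self.eps = eps

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a windows x edges matrix")
        params = SampEnParams(m=self.m, eps=self.eps)
        if X.shape[0] <= params.m + 1:
            raise ValueError(
                f"{X.shape[0]} windows too short for m={params.m}"
            )
        out = np.empty(X.shape[1])
        for e in range(X.shape[1]):
            out[e] = sample_entropy(X[:, e], params)
        return out
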