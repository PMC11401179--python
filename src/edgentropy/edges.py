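"""Canonical edge indexing for undirected parcel graphs.

Every stage of the pipeline refers to edges by their position in the
canonical ordering: all unordered parcel pairs (i, j) with i < j, sorted
lexicographically. For P parcels there are P*(P-1)/2 edges; 116 parcels
give 6670.
"""

from __future__ import annotations

import numpy as np


def n_edges(n_parcels: int) -> int:
    """Number of undirected edges among ``n_parcels`` nodes."""
    return n_parcels * (n_parcels - 1) // 2


def edge_index(n_parcels: int) -> np.ndarray:
    """Canonical (lexicographic, i<j) edge list as an (E, 2) int array."""
    iu = np.triu_indices(n_parcels, k=1)
    return np.column_stack(iu)


def edge_ids(n_parcels: int) -> list[str]:
    """String labels "i_j" for the canonical edge list."""
    idx = edge_index(n_parcels)
    return [f"{i}_{j}" for i, j in idx]


def edge_position(i: int, j: int, n_parcels: int) -> int:
    """Position of edge (i, j), i < j, in the canonical ordering."""
    if not 0 <= i < j < n_parcels:
        raise ValueError(f"invalid edge ({i}, {j}) for {n_parcels} parcels")
    # offset of row i = sum_{k<i} (P-1-k)
    return i * (2 * n_parcels - i - 1) // 2 + (j - i - 1)


def edges_to_positions(edges: np.ndarray, n_parcels: int) -> np.ndarray:
    """Vectorized :func:`edge_position` for an (E, 2) array of pairs."""
    edges = np.asarray(edges, dtype=int)
    i, j = edges[:, 0], edges[:, 1]
    if np.any(i >= j) or np.any(i < 0) or np.any(j >= n_parcels):
        raise ValueError("edges must satisfy 0 <= i < j < n_parcels")
    return i * (2 * n_parcels - i - 1) // 2 + (j - i - 1)
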