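"""Functional connectomes: construction, validation and edge vectorization.

A connectome is a symmetric N x N matrix of Fisher z-transformed Pearson
correlations between regional fMRI time series, with an exactly zero diagonal.
Edge-indexed quantities throughout the package use a single fixed ordering:
the strict upper triangle in row-major order, i.e. for N = 4 the edges are
(0,1), (0,2), (0,3), (1,2), (1,3), (2,3) — the order of ``np.triu_indices``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import Atlas

#: Correlations are clipped to |r| <= 1 - R_CLIP_EPS before atanh so that
#: degenerate (perfectly collinear) node series produce a large finite z
#: (~8.4) instead of +/-inf.  Realistic |r| < 0.99 is perturbed by < 1e-7.
R_CLIP_EPS = 1e-7


@dataclass
class Connectome:
    """A validated symmetric zero-diagonal connectivity matrix."""

    matrix: np.ndarray
    subject_id: str | None = None
    scan: str | None = None

    def __post_init__(self) -> None:
        self.matrix = validate_matrix(self.matrix)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def validate_matrix(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Check symmetry / zero diagonal / finiteness; return a float64 copy.

    Off-by-rounding asymmetry within ``atol`` is symmetrized; anything larger
    raises.  Used on the precomputed-matrix input path, which bypasses
    :func:`build_connectome`.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"connectome must be square, got shape {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("connectome contains non-finite values")
    if not np.allclose(m, m.T, atol=atol, rtol=0.0):
        raise ValueError("connectome is not symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=atol):
        raise ValueError("connectome diagonal is not zero")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


def build_connectome(series: np.ndarray, atlas: Atlas | None = None, *,
                     subject_id: str | None = None,
                     scan: str | None = None) -> Connectome:
    """Pearson-correlate node time series and Fisher z-transform.

    Parameters
    ----------
    series
        Array of shape (n_nodes, n_frames); each row is one node's time
        course.  At least 3 frames; no node may have zero variance.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 2:
        raise ValueError("series must be 2-D (nodes x frames)")
    n_nodes, n_frames = s.shape
    if atlas is not None and n_nodes != atlas.n_nodes:
        raise ValueError(f"series has {n_nodes} nodes, atlas expects {atlas.n_nodes}")
    if n_frames < 3:
        raise ValueError("need at least 3 frames to estimate correlations")
    if not np.isfinite(s).all():
        raise ValueError("time series contain non-finite samples")
    sd = s.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ValueError(f"zero-variance node(s): {dead.tolist()}")
    r = np.corrcoef(s)
    r = np.clip(r, -1.0 + R_CLIP_EPS, 1.0 - R_CLIP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return Connectome(matrix=z, subject_id=subject_id, scan=scan)


# -- edge vectorization -----------------------------------------------------

def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) node indices of each edge in the canonical ordering (i < j)."""
    return np.triu_indices(n_nodes, k=1)


def vectorize(matrix: np.ndarray | Connectome) -> np.ndarray:
    """Strict upper triangle of a connectome as a length N(N-1)/2 vector."""
    m = matrix.matrix if isinstance(matrix, Connectome) else np.asarray(matrix)
    i, j = edge_pairs(m.shape[0])
    return m[i, j].astype(float)


def devectorize(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    v = np.asarray(values, dtype=float)
    if v.size != n_edges(n_nodes):
        raise ValueError(
            f"edge vector length {v.size} != {n_edges(n_nodes)} for {n_nodes} nodes"
        )
    m = np.zeros((n_nodes, n_nodes))
    i, j = edge_pairs(n_nodes)
    m[i, j] = v
    m[j, i] = v
    return m


def edge_index_of(i: int, j: int, n_nodes: int) -> int:
    """Position of edge (i, j), i != j, in the canonical edge vector."""
    if i == j:
        raise ValueError("self-loops have no edge index")
    i, j = (i, j) if i < j else (j, i)
    if not (0 <= i < j < n_nodes):
        raise ValueError(f"edge ({i},{j}) out of range for {n_nodes} nodes")
    # edges before row i: sum_{r<i} (n-1-r); offset within row i: j - i - 1
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)
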