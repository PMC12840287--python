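"""KNN patient-similarity graph and the normalized adjacency used by the GCN.

Subjects are nodes; an undirected unit-weight edge joins two subjects when
either is among the other's ``kn`` nearest neighbors by Euclidean distance
over the covariates (union symmetrization).  The GCN propagates over
A_hat = D~^{-1/2} (A + I) D~^{-1/2}, the self-looped symmetric-normalized
adjacency, whose eigenvalues lie in [-1, 1].

The graph is transductive: it is built over all subjects present in the
input (training and test alike), since prediction propagates over test
nodes; only training-node residuals enter the loss.  Distances are computed
on the features as given — any standardization is the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclass
class PatientGraph:
    distances: np.ndarray   # (n, n) Euclidean, symmetric, zero diagonal
    adjacency: np.ndarray   # (n, n) binary, symmetric, zero diagonal
    normalized: np.ndarray  # (n, n) D~^{-1/2} (A+I) D~^{-1/2}
    kn: int

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def edge_list(self) -> np.ndarray:
        """Upper-triangle (i, j) pairs, 0-based, one row per undirected edge."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack((iu, ju))


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix D_ij = sqrt(sum_m (X_im - X_jm)^2)."""
    X = np.asarray(X, dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("covariate matrix contains non-finite entries")
    return squareform(pdist(X, metric="euclidean"))


def knn_adjacency(D: np.ndarray, kn: int) -> np.ndarray:
    """Union-symmetrized KNN adjacency: edge iff either is a neighbor of the
    other.  Distance ties break by ascending index (stable sort) so the graph
    is deterministic across platforms."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= kn <= n - 1:
        raise ValueError(f"kn must be in [1, {n - 1}], got {kn}")
    work = D.copy()
    np.fill_diagonal(work, np.inf)  # never one's own neighbor
    order = np.argsort(work, axis=1, kind="stable")
    A = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), kn)
    A[rows, order[:, :kn].ravel()] = 1
    A = np.maximum(A, A.T)  # union symmetrization
    np.fill_diagonal(A, 0)
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-looped symmetric normalization A_hat = D~^{-1/2}(A+I)D~^{-1/2}."""
    A = np.asarray(A, dtype=float)
    At = A + np.eye(A.shape[0])
    dinv_sqrt = 1.0 / np.sqrt(At.sum(axis=1))
    return At * dinv_sqrt[:, None] * dinv_sqrt[None, :]


def build_patient_graph(X: np.ndarray, kn: int) -> PatientGraph:
    """Distance matrix → KNN adjacency → normalized adjacency, in one call."""
    D = pairwise_distances(X)
    A = knn_adjacency(D, kn)
    return PatientGraph(distances=D, adjacency=A,
                        normalized=normalize_adjacency(A), kn=kn)
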