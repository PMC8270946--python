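"""Graph construction and spectral embedding of the CCD feature space.

The CCD similarity matrix is turned into a distance matrix
d(t_i, t_j) = 1 - CCD(t_i, t_j), sparsified with a relaxed minimum
spanning tree (RMST), and embedded with Laplacian eigenmaps: the
eigenvectors of the graph Laplacian for the d smallest non-trivial
eigenvalues are the manifold coordinates. A PCA baseline on the raw
(pre-processed) signal and a plateau-based intrinsic-dimension estimate
round out the module.

The RMST starts from the MST (which guarantees a single connected
component) and adds the edge (i, j) whenever

    mw_ij + gamma * (d_i^k + d_j^k) > d_ij,

where mw_ij is the largest edge weight on the MST path between i and j
and d_i^k is node i's distance to its k-th nearest neighbour (k = 1 by
default). Candidate edges are examined in ascending distance and each
node accepts at most ``k_n`` relaxation-added edges on top of its MST
degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh

from .datatypes import CCDMatrix, DistanceMatrix, ManifoldEmbedding
from .stats import fdr_correct, rank_sum_test

#: Above this many nodes the eigen-solve switches to a sparse iterative solver.
DENSE_EIGEN_LIMIT = 2000


@dataclass
class RMSTParams:
    """Relaxation parameters for the RMST graph.

    gamma : relaxation strength (0 recovers the plain MST).
    k_n : maximum number of relaxation-added neighbours per node.
    k_local : which nearest-neighbour distance enters the relaxation term.
    """

    gamma: float = 3.0
    k_n: int = 5
    k_local: int = 1

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.k_n < 1 or self.k_local < 1:
            raise ValueError("k_n and k_local must be >= 1")


@dataclass
class StateGraph:
    """Undirected weighted graph over the T timepoints.

    ``mst_edges`` are the mandatory spanning-tree edges; ``extra_edges``
    are the relaxation additions. Both are (m, 2) int arrays with i < j.
    """

    n_nodes: int
    mst_edges: np.ndarray
    extra_edges: np.ndarray
    distances: np.ndarray  # full distance matrix (for edge weights)

    @property
    def edges(self) -> np.ndarray:
        if self.extra_edges.size == 0:
            return self.mst_edges
        return np.vstack([self.mst_edges, self.extra_edges])

    @property
    def n_edges(self) -> int:
        return len(self.mst_edges) + len(self.extra_edges)

    def edge_weights(self) -> np.ndarray:
        e = self.edges
        return self.distances[e[:, 0], e[:, 1]]

    def adjacency(self, weighting: str = "binary") -> np.ndarray:
        """Dense adjacency: binary (default) or similarity (1 - distance)."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        e = self.edges
        if weighting == "binary":
            w = np.ones(len(e))
        elif weighting == "similarity":
            w = 1.0 - self.distances[e[:, 0], e[:, 1]]
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        A[e[:, 0], e[:, 1]] = w
        A[e[:, 1], e[:, 0]] = w
        return A


def ccd_to_distance(ccd: CCDMatrix) -> DistanceMatrix:
    """Elementwise 1 - CCD with the diagonal forced to exactly zero."""
    d = 1.0 - ccd.matrix
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(matrix=d)


def minimum_spanning_tree(dist: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Kruskal MST with deterministic lexicographic (weight, i, j) tie-break.

    Returns a (T-1, 2) int array of edges (i < j) in the order they were
    accepted, i.e. ascending weight.
    """
    D = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    iu, ju = np.triu_indices(n, k=1)
    w = D[iu, ju]
    order = np.lexsort((ju, iu, w))
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = np.empty((n - 1, 2), dtype=np.int64)
    m = 0
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges[m] = (i, j)
            m += 1
            if m == n - 1:
                break
    return edges


def _mst_path_max_weights(n: int, mst_edges: np.ndarray, D: np.ndarray) -> np.ndarray:
    """mw[i, j] = max edge weight on the (unique) MST path from i to j.

    Computed by replaying Kruskal's component merges in ascending edge
    order: when the edge of weight w joins components A and B, that edge
    is the heaviest on every path between A and B.
    """
    w = D[mst_edges[:, 0], mst_edges[:, 1]]
    order = np.argsort(w, kind="stable")
    mw = np.zeros((n, n))
    comp_of = np.arange(n)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for idx in order:
        i, j = mst_edges[idx]
        ci, cj = comp_of[i], comp_of[j]
        a, b = members[ci], members[cj]
        mw[np.ix_(a, b)] = w[idx]
        mw[np.ix_(b, a)] = w[idx]
        if len(a) < len(b):  # merge smaller into larger
            a, b = b, a
            ci, cj = cj, ci
        for node in b:
            comp_of[node] = ci
        members[ci] = a + b
        del members[cj]
    return mw


def knn_distance(D: np.ndarray, k: int) -> np.ndarray:
    """Per-node distance to its k-th nearest neighbour (self excluded)."""
    n = D.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the {n - 1} available neighbours")
    masked = D.copy()
    np.fill_diagonal(masked, np.inf)
    return np.sort(masked, axis=1)[:, k - 1]


def rmst(dist: DistanceMatrix | np.ndarray, params: RMSTParams | None = None) -> StateGraph:
    """Relaxed minimum spanning tree of a distance matrix.

    Starts from the MST and adds non-tree edges satisfying the relaxation
    condition, in ascending distance, while both endpoints have fewer than
    ``k_n`` added edges. ``gamma = 0`` degrades gracefully to the MST
    (strict inequality plus the cycle property exclude every candidate).
    """
    params = params or RMSTParams()
    D = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = D.shape[0]
    mst_edges = minimum_spanning_tree(D)
    mw = _mst_path_max_weights(n, mst_edges, D)
    dk = knn_distance(D, params.k_local)

    in_mst = np.zeros((n, n), dtype=bool)
    in_mst[mst_edges[:, 0], mst_edges[:, 1]] = True
    iu, ju = np.triu_indices(n, k=1)
    candidate = ~in_mst[iu, ju]
    satisfied = mw[iu, ju] + params.gamma * (dk[iu] + dk[ju]) > D[iu, ju]
    keep = candidate & satisfied
    ci, cj, cw = iu[keep], ju[keep], D[iu, ju][keep]
    order = np.lexsort((cj, ci, cw))  # ascending distance, ties by (i, j)

    added = np.zeros(n, dtype=np.int64)
    extra: list[tuple[int, int]] = []
    for idx in order:
        i, j = int(ci[idx]), int(cj[idx])
        if added[i] < params.k_n and added[j] < params.k_n:
            extra.append((i, j))
            added[i] += 1
            added[j] += 1
    extra_edges = (
        np.asarray(extra, dtype=np.int64) if extra else np.empty((0, 2), dtype=np.int64)
    )
    return StateGraph(n_nodes=n, mst_edges=mst_edges, extra_edges=extra_edges, distances=D)


def graph_laplacian(graph: StateGraph, weighting: str = "binary") -> np.ndarray:
    """Combinatorial Laplacian L = Deg - A of the state graph."""
    A = graph.adjacency(weighting)
    _check_connected(graph)
    return np.diag(A.sum(axis=1)) - A


def _check_connected(graph: StateGraph) -> None:
    parent = np.arange(graph.n_nodes)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in graph.edges:
        parent[find(int(i))] = find(int(j))
    roots = {find(i) for i in range(graph.n_nodes)}
    if len(roots) > 1:
        raise ValueError(f"graph is disconnected ({len(roots)} components)")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    out = vectors.copy()
    for c in range(out.shape[1]):
        pivot = np.argmax(np.abs(out[:, c]))
        if out[pivot, c] < 0:
            out[:, c] = -out[:, c]
    return out


def laplacian_eigenmaps(L: np.ndarray | sparse.spmatrix, d: int) -> ManifoldEmbedding:
    """Embedding on the eigenvectors of the d smallest non-trivial eigenvalues.

    The trivial constant eigenvector (eigenvalue 0) is discarded. A second
    near-zero eigenvalue signals a disconnected graph and raises.
    """
    n = L.shape[0]
    if not 1 <= d <= n - 1:
        raise ValueError(f"d must be in [1, {n - 1}]")
    if sparse.issparse(L) or n > DENSE_EIGEN_LIMIT:
        Ls = sparse.csr_matrix(L)
        vals, vecs = eigsh(Ls, k=d + 1, sigma=-1e-6, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = eigh(np.asarray(L), subset_by_index=[0, d])
    if vals[0] > 1e-8:
        raise ValueError("Laplacian lacks a zero eigenvalue; not a valid Laplacian")
    if vals[1] < 1e-8:
        raise ValueError("multiple near-zero eigenvalues: graph is disconnected")
    coords = _fix_signs(vecs[:, 1 : d + 1])
    return ManifoldEmbedding(
        coords=coords,
        eigenvalues=np.maximum(vals[1 : d + 1], 0.0),
        method="laplacian_eigenmaps",
        ambient_dim=n,
    )


def pca_embedding(features: np.ndarray, d: int) -> ManifoldEmbedding:
    """Top-d principal-component scores of a (T, D) feature matrix.

    Observations are rows (timepoints); columns are centred before the
    decomposition. Eigenvalues are the per-component variances.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (T, D)")
    T, D = X.shape
    if not 1 <= d <= min(T, D):
        raise ValueError(f"d must be in [1, {min(T, D)}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = _fix_signs(U[:, :d] * s[:d])
    variances = (s[:d] ** 2) / max(T - 1, 1)
    return ManifoldEmbedding(
        coords=scores, eigenvalues=variances, method="pca", ambient_dim=D
    )


@dataclass
class IntrinsicDimensionResult:
    """Plateau estimate of the manifold's intrinsic dimensionality."""

    dimension: int
    plateau_found: bool
    pvalues: dict[int, np.ndarray] = field(default_factory=dict)


def estimate_intrinsic_dimension(
    accuracy_by_dim: dict[int, np.ndarray], alpha: float = 0.05
) -> IntrinsicDimensionResult:
    """Smallest dimension beyond which decoding accuracy stops improving.

    For each candidate d* (ascending), the accuracies at every d > d* are
    compared with those at d* by a two-sided rank-sum test; the family of
    p-values is FDR-corrected at ``alpha``. The first d* with no
    significant difference is the intrinsic dimension. If no plateau
    exists the largest dimension is returned with ``plateau_found=False``.
    """
    dims = sorted(accuracy_by_dim)
    if not dims:
        raise ValueError("accuracy_by_dim is empty")
    samples = {d: np.asarray(accuracy_by_dim[d], dtype=float) for d in dims}
    if len(dims) == 1:
        return IntrinsicDimensionResult(dimension=dims[0], plateau_found=True)
    for d in dims:
        if len(samples[d]) < 2:
            raise ValueError(f"need >= 2 accuracy samples per dimension (dim {d})")
    all_p: dict[int, np.ndarray] = {}
    for pos, d_star in enumerate(dims[:-1]):
        higher = dims[pos + 1 :]
        pvals = np.array(
            [rank_sum_test(samples[d], samples[d_star]) for d in higher]
        )
        all_p[d_star] = pvals
        _, reject = fdr_correct(pvals, alpha=alpha)
        if not reject.any():
            return IntrinsicDimensionResult(
                dimension=d_star, plateau_found=True, pvalues=all_p
            )
    warnings.warn(
        "no accuracy plateau found within the scanned dimensions; "
        "returning the largest dimension",
        stacklevel=2,
    )
    return IntrinsicDimensionResult(
        dimension=dims[-1], plateau_found=False, pvalues=all_p
    )
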