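"""Graph-Laplacian mode bases: connectome-style and EDR-wired graphs.

A mode basis can be built from a weighted vertex-level connectome (local
mesh edges merged with thresholded long-range connections) or from a
synthetic graph wired by the exponential distance rule (EDR), in which two
vertices are connected with probability exp(-alpha * d) for Euclidean
distance d.  Eigenvectors of the (optionally degree-normalized) graph
Laplacian play the same role as geometric eigenmodes but carry the graph's
topology instead of the surface's intrinsic geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares

from .mesh import TriangleMesh
from .eigenmodes import EigenmodeBasis, _fix_signs_and_order
from scipy.sparse.linalg import eigsh, ArpackNoConvergence


@dataclass
class SparseConnectome:
    """Symmetric non-negative weighted connectivity (streamline-count-like)."""

    weights: sp.csr_matrix

    def __post_init__(self):
        W = sp.csr_matrix(self.weights)
        if W.shape[0] != W.shape[1]:
            raise ValueError("connectome must be square")
        if (abs(W - W.T) > 1e-12 * max(abs(W).max(), 1e-30)).nnz:
            raise ValueError("connectome must be symmetric")
        if W.diagonal().any():
            raise ValueError("connectome must have zero diagonal")
        if W.nnz and W.data.min() < 0:
            raise ValueError("connectome weights must be non-negative")
        self.weights = W

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class EDRModel:
    """Fitted exponential-distance-rule decay exponent (mm^-1)."""

    alpha: float
    fitted_on: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _upper_pairs(A: sp.spmatrix) -> np.ndarray:
    """(E, 2) array of undirected edges i<j of a symmetric sparse matrix."""
    coo = sp.triu(A, k=1).tocoo()
    return np.column_stack([coo.row, coo.col])


def local_adjacency(mesh: TriangleMesh) -> sp.csr_matrix:
    """Binary adjacency connecting vertices that share a mesh edge."""
    e = mesh.edges()
    V = mesh.n_vertices
    A = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(V, V))
    A = A + A.T
    return A.tocsr()


def n_edges(A: sp.spmatrix) -> int:
    return sp.triu(A, k=1).nnz


def connection_density(A: sp.spmatrix) -> float:
    """Fraction of realized undirected edges: E / (V choose 2)."""
    V = A.shape[0]
    return n_edges(A) / (V * (V - 1) / 2)


def _threshold_top_edges(W: SparseConnectome, n_keep: int) -> sp.csr_matrix:
    """Keep the ``n_keep`` largest-weight undirected edges, binarized.

    Ties broken by descending weight then ascending (i, j) index pair, so
    the result is deterministic.
    """
    coo = sp.triu(W.weights, k=1).tocoo()
    if coo.nnz < n_keep:
        raise ValueError(
            f"requested {n_keep} edges but only {coo.nnz} nonzero weights available")
    order = np.lexsort((coo.col, coo.row, -coo.data))
    keep = order[:n_keep]
    V = W.n
    A = sp.coo_matrix((np.ones(n_keep), (coo.row[keep], coo.col[keep])), shape=(V, V))
    A = A + A.T
    return A.tocsr()


def threshold_fourfold(W: SparseConnectome, A_local: sp.spmatrix) -> sp.csr_matrix:
    """Binarize W keeping exactly 4x as many edges as the local adjacency."""
    return _threshold_top_edges(W, 4 * n_edges(A_local))


def threshold_to_density(W: SparseConnectome, density: float) -> sp.csr_matrix:
    """Binarize W at the requested undirected connection density."""
    V = W.n
    n_pairs = V * (V - 1) // 2
    n_keep = int(round(density * n_pairs))
    if not 0 < n_keep <= sp.triu(W.weights, k=1).nnz:
        raise ValueError(
            f"density {density} unachievable: needs {n_keep} of "
            f"{sp.triu(W.weights, k=1).nnz} available edges")
    return _threshold_top_edges(W, n_keep)


def merge_adjacency(A_local: sp.spmatrix, A_connectome: sp.spmatrix) -> sp.csr_matrix:
    """Elementwise logical OR of two binary adjacencies (A_C)."""
    A = ((A_local + A_connectome) > 0).astype(float)
    return sp.csr_matrix(A)


# ---------------------------------------------------------------------------
# EDR
# ---------------------------------------------------------------------------

def fit_edr_alpha(W: SparseConnectome, distances: np.ndarray,
                  min_pairs: int = 100) -> EDRModel:
    """Fit w ~ A exp(-alpha d) over nonzero weights by nonlinear least squares.

    Weights are max-normalized for conditioning and fitted with a free
    amplitude (the standard exponential-decay model a*exp(b*x)); only
    nonzero entries enter the residual.  A near-zero alpha
    (distance-independent weights) is flagged in the diagnostics.
    """
    pairs = _upper_pairs(W.weights)
    if len(pairs) < min_pairs:
        raise ValueError(f"need >= {min_pairs} nonzero weight-distance pairs, "
                         f"got {len(pairs)}")
    w = np.asarray(sp.triu(W.weights, k=1).tocoo().data, dtype=float)
    w = w / w.max()
    d = distances[pairs[:, 0], pairs[:, 1]]

    # log-linear initial guess on the positive weights
    slope, intercept = np.polyfit(d, np.log(np.maximum(w, 1e-12)), 1)
    x0 = [max(-slope, 1e-6), float(np.exp(np.clip(intercept, -20, 20)))]
    res = least_squares(lambda p: w - p[1] * np.exp(-p[0] * d), x0=x0,
                        bounds=([0.0, 0.0], [np.inf, np.inf]))
    if not res.success:
        raise RuntimeError(f"EDR fit did not converge: {res.message}; "
                           f"final cost {res.cost:g}")
    alpha = float(res.x[0])
    diag = {
        "cost": float(res.cost),
        "n_pairs": int(len(pairs)),
        "amplitude": float(res.x[1]),
        "rms_residual": float(np.sqrt(np.mean(res.fun ** 2))),
        "alpha_near_zero": bool(alpha * d.max() < 1e-3),
    }
    return EDRModel(alpha, fitted_on={"d_min": float(d.min()), "d_max": float(d.max())},
                    diagnostics=diag)


def generate_edr(distances: np.ndarray, alpha: float, seed: int) -> sp.csr_matrix:
    """Stochastic EDR wiring: connect pairs independently with p = exp(-alpha d)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    V = distances.shape[0]
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(V, k=1)
    p = np.exp(-alpha * distances[iu, ju])
    hit = rng.random(len(p)) < p
    A = sp.coo_matrix((np.ones(hit.sum()), (iu[hit], ju[hit])), shape=(V, V))
    A = A + A.T
    return A.tocsr()


# ---------------------------------------------------------------------------
# Laplacians and modes
# ---------------------------------------------------------------------------

def graph_laplacian(A: sp.spmatrix, normalized: bool = False) -> sp.csr_matrix:
    """Graph Laplacian L = (D - A) symmetrized; optionally D^-1/2 L D^-1/2.

    The normalized form requires every vertex to have at least one edge.
    """
    A = sp.csr_matrix(A)
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A
    L = 0.5 * (L + L.T)
    if normalized:
        if (deg == 0).any():
            isolated = np.nonzero(deg == 0)[0]
            raise ValueError(
                f"normalized Laplacian undefined for isolated vertices {isolated.tolist()[:20]}")
        dinv = sp.diags(1.0 / np.sqrt(deg))
        L = dinv @ L @ dinv
    return sp.csr_matrix(L)


def solve_graph_modes(L: sp.spmatrix, n_modes: int, tol: float = 0.0) -> EigenmodeBasis:
    """Smallest ``n_modes`` eigenpairs of a PSD graph Laplacian.

    The basis is Euclidean-orthonormal (identity inner product) and follows
    the same sign/ordering convention as geometric modes.
    """
    V = L.shape[0]
    if n_modes >= V:
        raise ValueError(f"n_modes={n_modes} must be < number of vertices {V}")
    try:
        evals, vecs = eigsh(sp.csc_matrix(L), k=n_modes, sigma=-1e-6, which="LM", tol=tol)
    except ArpackNoConvergence as exc:
        raise RuntimeError(
            f"eigensolver failed to converge: {len(exc.eigenvalues)} of "
            f"{n_modes} eigenpairs converged") from exc
    evals = np.where(np.abs(evals) < 1e-10, 0.0, evals)
    modes, evals = _fix_signs_and_order(vecs, evals)
    return EigenmodeBasis(modes, evals, mass=None)


# ---------------------------------------------------------------------------
# connectome text I/O (coordinate triplets)
# ---------------------------------------------------------------------------

def save_connectome(path: str, W: SparseConnectome) -> None:
    """Write upper-triangle entries as '# n <V>' header + 'i j weight' rows."""
    coo = sp.triu(W.weights, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write(f"# n {W.n}\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {w:.17g}\n")


def load_connectome(path: str) -> SparseConnectome:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["#", "n"]:
            raise ValueError(f"{path}: missing '# n <V>' header")
        V = int(header[2])
        rows, cols, vals = [], [], []
        for line in fh:
            if not line.strip():
                continue
            i, j, w = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(w))
    W = sp.coo_matrix((vals, (rows, cols)), shape=(V, V))
    return SparseConnectome((W + W.T).tocsr())
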