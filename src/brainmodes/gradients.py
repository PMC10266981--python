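"""Connectopic mapping: functional gradients of 3D structures.

Within a region of interest, each voxel's connectivity fingerprint is its
correlation with an SVD-reduced representation of the time series outside
the structure.  Pairwise fingerprint similarity (eta^2) feeds a Laplacian
Eigenmaps embedding whose leading non-constant eigenvectors are the
functional gradients; these are then matched, by absolute spatial
correlation, against the structure's volumetric geometric eigenmodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .eigenmodes import EigenmodeBasis
from .mesh import TetraMesh


@dataclass
class FingerprintInputs:
    """ROI time series A (T x N), outside series B (T x M), and derived
    reduced matrix B_tilde (T x T-1) and fingerprints C (N x T-1)."""

    A: np.ndarray
    B: np.ndarray
    B_tilde: np.ndarray | None = None
    C: np.ndarray | None = None


@dataclass
class GradientSet:
    """Ordered functional gradients (N x K) with variance-explained fractions."""

    gradients: np.ndarray
    variance_explained: np.ndarray
    eigenvalues: np.ndarray


def svd_reduce(B: np.ndarray) -> np.ndarray:
    """Reduce a T x M matrix (M >= T) to T x (T-1) by SVD.

    Columns are centred first; the output U_{1..T-1} S_{1..T-1} carries the
    full left-singular (temporal) structure, so correlations of ROI series
    with B_tilde reproduce those computable from the full B up to the rank
    reduction.
    """
    B = np.asarray(B, dtype=float)
    T, M = B.shape
    if M < T:
        raise ValueError(f"reduction expects M >= T, got T={T}, M={M}")
    Bc = B - B.mean(axis=0)
    U, s, _ = np.linalg.svd(Bc, full_matrices=False)
    return U[:, :T - 1] * s[:T - 1]


def fingerprints(A: np.ndarray, B_tilde: np.ndarray) -> np.ndarray:
    """Pearson correlations of each ROI voxel with each reduced column: (N, T-1)."""
    def zscore(x):
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        return x / np.where(sd == 0, 1.0, sd)

    T = A.shape[0]
    return zscore(A).T @ zscore(B_tilde) / T


def eta2_similarity(C: np.ndarray) -> np.ndarray:
    """Pairwise eta^2 similarity of connectivity fingerprints.

    For profiles a, b with elementwise means m_k = (a_k + b_k)/2 and grand
    mean Mbar of both profiles,

        eta^2 = 1 - sum_k [(a_k - m_k)^2 + (b_k - m_k)^2]
                    / sum_k [(a_k - Mbar)^2 + (b_k - Mbar)^2],

    the fraction of variance in one profile accounted for by the other;
    symmetric, unit diagonal, bounded in [0, 1].
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] < 2:
        raise ValueError("need >= 2 fingerprint columns")
    N, K = C.shape
    sq = np.einsum("ij,ij->i", C, C)          # ||a||^2
    s = C.sum(axis=1)                          # sum a_k
    # numerator: ||a - b||^2 / 2
    gram = C @ C.T
    num = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * gram)
    # denominator: ||a||^2 + ||b||^2 - (s_a + s_b)^2 / (2K)
    den = sq[:, None] + sq[None, :] - (s[:, None] + s[None, :]) ** 2 / (2.0 * K)
    if (den <= 1e-300).any() and not np.allclose(num[den <= 1e-300], 0):
        raise ValueError("zero total variance in a fingerprint pair")
    den = np.where(den <= 1e-300, 1.0, den)
    S = 1.0 - num / den
    S = np.clip(0.5 * (S + S.T), 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def laplacian_eigenmaps(S: np.ndarray, k: int = 20,
                        restrict_to_largest: bool = False) -> GradientSet:
    """Laplacian-Eigenmaps embedding of a similarity (affinity) matrix.

    Solves the generalized problem (D - S) v = lambda D v, drops the
    constant eigenvector, and returns the next ``k`` eigenvectors ordered
    by ascending eigenvalue.  Variance explained per gradient is its
    embedding weight (1 - lambda) over the sum across retained gradients.
    A disconnected affinity graph is an error unless
    ``restrict_to_largest`` (not implemented for dense S beyond detection).
    """
    S = np.asarray(S, dtype=float)
    N = S.shape[0]
    if S.shape != (N, N):
        raise ValueError("S must be square")
    W = S.copy()
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    if (deg <= 0).any():
        if restrict_to_largest:
            raise NotImplementedError("largest-component restriction not supported")
        raise ValueError("affinity graph has isolated nodes (disconnected)")
    L = np.diag(deg) - W
    evals, vecs = sla.eigh(L, np.diag(deg), subset_by_index=[0, k])
    # eigenvalue 0 <-> constant vector; drop it
    grads = vecs[:, 1:k + 1]
    lam = evals[1:k + 1]
    weight = np.clip(1.0 - lam, 0.0, None)
    tot = weight.sum()
    var = weight / tot if tot > 0 else np.zeros_like(weight)
    return GradientSet(grads, var, lam)


def connectopic_map(A: np.ndarray, B: np.ndarray, k: int = 20) -> tuple[GradientSet, FingerprintInputs]:
    """Full single-subject connectopic pipeline: SVD reduce, fingerprint,
    eta^2 similarity, Laplacian Eigenmaps."""
    Bt = svd_reduce(B)
    C = fingerprints(A, Bt)
    S = eta2_similarity(C)
    return laplacian_eigenmaps(S, k=k), FingerprintInputs(A, B, Bt, C)


def group_similarity(similarity_matrices: list[np.ndarray]) -> np.ndarray:
    """Average eta^2 similarity across subjects before embedding."""
    return np.mean(similarity_matrices, axis=0)


def modes_at_voxel_centers(basis: EigenmodeBasis, tet: TetraMesh) -> np.ndarray:
    """Interpolate tetra-mesh vertex modes to voxel centres.

    Requires a lattice mesh built by :func:`brainmodes.mesh.tetrahedralize_mask`
    (the voxel -> corner map is the trilinear interpolation stencil at the
    voxel centre: the mean of the 8 corner values).
    """
    if tet.voxel_corners is None:
        raise ValueError("tetra mesh lacks a voxel corner map; "
                         "build it with tetrahedralize_mask")
    return basis.modes[tet.voxel_corners].mean(axis=1)


def match_modes_gradients(mode_fields: np.ndarray, grads: GradientSet,
                          n_compare: int = 20) -> dict:
    """Match functional gradients to geometric modes by absolute correlation.

    ``mode_fields`` holds non-constant modes sampled on the same voxels as
    the gradients (N x >=n_compare).  Returns the |r| matrix (gradients x
    modes), the best-matching mode per gradient with its |r|, and the
    order difference |best mode index - gradient index| (0-based).
    """
    G = np.asarray(grads.gradients, dtype=float)
    M = np.asarray(mode_fields, dtype=float)
    if G.shape[0] != M.shape[0]:
        raise ValueError(f"support mismatch: gradients on {G.shape[0]} voxels, "
                         f"modes on {M.shape[0]}")
    kg = min(n_compare, G.shape[1])
    km = min(n_compare, M.shape[1])
    Gz = (G[:, :kg] - G[:, :kg].mean(axis=0)) / G[:, :kg].std(axis=0)
    Mz = (M[:, :km] - M[:, :km].mean(axis=0)) / M[:, :km].std(axis=0)
    r = np.abs(Gz.T @ Mz / G.shape[0])
    best = np.argmax(r, axis=1)
    return {
        "abs_corr": r,
        "best_mode": best,
        "best_r": r[np.arange(kg), best],
        "order_difference": np.abs(best - np.arange(kg)),
    }
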