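"""Laplace-Beltrami eigenmodes of triangle and tetrahedral meshes.

The surface/volume Laplacian is discretized with linear (P1) finite
elements, yielding a sparse stiffness matrix ``K`` (cotangent formula on
triangles, gradient formula on tets) and a consistent mass matrix ``M``.
Eigenmodes solve the generalized Helmholtz problem

    K psi = lambda M psi,       0 = lambda_1 <= lambda_2 <= ...

on a closed surface; the first mode is spatially constant.  On a sphere of
radius R the spectrum clusters into degenerate groups lambda = l(l+1)/R^2
of size 2l+1, the spherical-harmonic "eigengroups" used to assign a spatial
wavelength 2*pi*R / sqrt(l(l+1)) to each mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh, ArpackNoConvergence

from .mesh import TriangleMesh, TetraMesh, MeshValidationError, triangle_areas


@dataclass
class LBOperator:
    """Discretized Laplace-Beltrami operator: stiffness/mass sparse pair."""

    stiffness: sp.csr_matrix
    mass: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.stiffness.shape[0]


@dataclass
class EigenmodeBasis:
    """Mode matrix ``modes`` (V, N), eigenvalues (mm^-2) ascending.

    ``mass`` is the inner-product matrix under which the modes are
    orthonormal; ``None`` means the identity (graph-Laplacian bases).
    """

    modes: np.ndarray
    eigenvalues: np.ndarray
    mass: sp.spmatrix | None = None
    sign_convention: str = "max-abs-positive"

    @property
    def n_vertices(self) -> int:
        return self.modes.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def gram(self) -> np.ndarray:
        """Psi^T M Psi; identity to numerical precision for a valid basis."""
        if self.mass is None:
            return self.modes.T @ self.modes
        return self.modes.T @ (self.mass @ self.modes)

    def project_matrix(self) -> np.ndarray:
        """The (N, V) operator mapping a vertex field to mode amplitudes."""
        if self.mass is None:
            return self.modes.T
        return (self.mass @ self.modes).T


@dataclass
class EigenGroup:
    """Spherical-harmonic-like group l covering modes (l^2+1)..(l+1)^2."""

    l: int
    mode_indices: np.ndarray  # 1-based mode indices in this group
    wavelength: float         # mm; inf for the constant group l=0
    R_s: float


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _assemble_triangle(mesh: TriangleMesh) -> LBOperator:
    # open (boundary) meshes assemble fine with natural Neumann conditions;
    # closedness is checked where eigenmode work demands it
    mesh.validate(require_closed=False)
    v = mesh.vertices
    f = mesh.faces
    area = triangle_areas(mesh)
    if (area < 1e-12).any():
        bad = int(np.argmin(area))
        raise MeshValidationError(f"degenerate triangle {bad} (area {area[bad]:g})")

    ii, jj, vals = [], [], []
    # cotangent stiffness: for edge opposite corner k, weight = cot(angle_k)/2
    for k in range(3):
        a = v[f[:, k]]
        b = v[f[:, (k + 1) % 3]]
        c = v[f[:, (k + 2) % 3]]
        u, w = b - a, c - a
        cot = np.einsum("ij,ij->i", u, w) / (2.0 * area)
        i, j = f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        half = 0.5 * cot
        ii.extend([i, j, i, j])
        jj.extend([j, i, i, j])
        vals.extend([-half, -half, half, half])
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(ii), np.concatenate(jj))),
                      shape=(mesh.n_vertices,) * 2).tocsr()

    # consistent P1 mass: element matrix area/12 * (1 + delta_ij)
    mi, mj, mv = [], [], []
    for a_ in range(3):
        for b_ in range(3):
            mi.append(f[:, a_])
            mj.append(f[:, b_])
            mv.append(area * ((2.0 if a_ == b_ else 1.0) / 12.0))
    M = sp.coo_matrix((np.concatenate(mv), (np.concatenate(mi), np.concatenate(mj))),
                      shape=(mesh.n_vertices,) * 2).tocsr()
    return LBOperator(K, M)


def _assemble_tetra(mesh: TetraMesh) -> LBOperator:
    mesh.validate()
    v = mesh.vertices
    t = mesh.tets
    vol = mesh.tet_volumes()
    if (vol < 1e-14).any():
        bad = int(np.argmin(vol))
        raise MeshValidationError(f"degenerate tet {bad} (volume {vol[bad]:g})")

    # P1 gradients: for tet (p0..p3), grad of hat function at corner i is
    # n_i / (3 V) where n_i is the inward-scaled normal of the opposite face.
    p = [v[t[:, k]] for k in range(4)]
    grads = np.empty((len(t), 4, 3))
    for k in range(4):
        others = [p[m] for m in range(4) if m != k]
        n = np.cross(others[1] - others[0], others[2] - others[0])
        # orient toward corner k
        s = np.sign(np.einsum("ij,ij->i", p[k] - others[0], n))
        n *= s[:, None]
        # |n| = 2 A_opp and |grad phi_k| = A_opp / (3 V), so grad = n / (6 V)
        grads[:, k, :] = n / (6.0 * vol)[:, None]
    ii, jj, vals = [], [], []
    for a_ in range(4):
        for b_ in range(4):
            ii.append(t[:, a_])
            jj.append(t[:, b_])
            vals.append(vol * np.einsum("ij,ij->i", grads[:, a_], grads[:, b_]))
    K = sp.coo_matrix((np.concatenate(vals), (np.concatenate(ii), np.concatenate(jj))),
                      shape=(mesh.n_vertices,) * 2).tocsr()

    mi, mj, mv = [], [], []
    for a_ in range(4):
        for b_ in range(4):
            mi.append(t[:, a_])
            mj.append(t[:, b_])
            mv.append(vol * ((2.0 if a_ == b_ else 1.0) / 20.0))
    M = sp.coo_matrix((np.concatenate(mv), (np.concatenate(mi), np.concatenate(mj))),
                      shape=(mesh.n_vertices,) * 2).tocsr()
    return LBOperator(K, M)


def assemble_lbo(mesh: TriangleMesh | TetraMesh) -> LBOperator:
    """Assemble the P1 FEM stiffness/mass pair for a closed triangle mesh
    or a positively oriented tetrahedral mesh.

    The stiffness matrix annihilates constants (row sums ~ 0) and the mass
    matrix entries sum to the total surface area / volume.
    """
    if isinstance(mesh, TriangleMesh):
        return _assemble_triangle(mesh)
    if isinstance(mesh, TetraMesh):
        return _assemble_tetra(mesh)
    raise TypeError(f"unsupported mesh type {type(mesh)!r}")


# ---------------------------------------------------------------------------
# eigensolution
# ---------------------------------------------------------------------------

def _fix_signs_and_order(modes: np.ndarray, evals: np.ndarray,
                         cluster_rtol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic convention for the non-identifiable parts of the basis.

    Each mode is scaled so its largest-magnitude entry is positive; within
    numerically degenerate eigenvalue clusters, modes are ordered by the
    ascending index of that entry.  (Signs and within-group order are
    arbitrary for repeated eigenvalues.)
    """
    order = np.argsort(evals, kind="stable")
    evals = evals[order]
    modes = modes[:, order]
    peak = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[peak, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    modes = modes * signs
    # regroup within clusters of equal eigenvalue
    scale = max(abs(evals[-1]), 1.0)
    start = 0
    for end in range(1, len(evals) + 1):
        if end == len(evals) or abs(evals[end] - evals[start]) > cluster_rtol * scale:
            if end - start > 1:
                sub = np.argsort(peak[start:end], kind="stable")
                modes[:, start:end] = modes[:, start:end][:, sub]
            start = end
    return modes, evals


def solve_modes(op: LBOperator, n_modes: int, tol: float = 0.0,
                sigma: float = -1e-8) -> EigenmodeBasis:
    """Smallest ``n_modes`` generalized eigenpairs K psi = lambda M psi.

    Uses shift-invert ARPACK with a small negative shift so the singular
    stiffness (constant null space) poses no factorization problem.  Modes
    are mass-orthonormal and the constant mode is retained as mode 1.
    The default tolerance (machine precision) matters: looser tolerances
    can silently drop members of degenerate eigenvalue clusters.
    """
    if n_modes >= op.n:
        raise ValueError(f"n_modes={n_modes} must be < matrix size {op.n}")
    try:
        evals, vecs = eigsh(op.stiffness, k=n_modes, M=op.mass, sigma=sigma,
                            which="LM", tol=tol)
    except ArpackNoConvergence as exc:
        raise RuntimeError(
            f"eigensolver failed to converge: {len(exc.eigenvalues)} of "
            f"{n_modes} eigenpairs converged") from exc
    evals = np.maximum(evals, 0.0) if evals.min() > -1e-8 * max(evals.max(), 1) else evals
    modes, evals = _fix_signs_and_order(vecs, evals)
    return EigenmodeBasis(modes, evals, mass=op.mass)


# ---------------------------------------------------------------------------
# eigengroups
# ---------------------------------------------------------------------------

def mode_to_group(mode_index: int) -> int:
    """Group l of a 1-based mode index via cumulative degeneracy (l+1)^2.

    Mode 1 is the constant group l=0; modes 2-4 form group l=1; group l
    covers modes l^2+1 .. (l+1)^2.
    """
    if mode_index < 1:
        raise ValueError("mode_index is 1-based")
    return math.isqrt(mode_index - 1)


def eigengroup_wavelength(l: int, R_s: float) -> float:
    """Spatial wavelength 2*pi*R_s / sqrt(l(l+1)) of eigengroup l, in mm.

    Group 0 (the constant mode) has no finite wavelength and returns inf.
    """
    if R_s <= 0:
        raise ValueError("R_s must be positive")
    if l == 0:
        warnings.warn("group 0 is the constant mode; wavelength is infinite")
        return math.inf
    if l < 0:
        raise ValueError("l must be >= 0")
    return 2.0 * math.pi * R_s / math.sqrt(l * (l + 1))


def assign_eigengroups(basis: EigenmodeBasis | int, R_s: float) -> list[EigenGroup]:
    """Partition the first N modes into spherical eigengroups with wavelengths.

    Accepts a basis or a plain mode count.  Group l holds the 2l+1 modes
    with 1-based indices l^2+1 .. (l+1)^2 (the last group may be partial).
    """
    n = basis if isinstance(basis, int) else basis.n_modes
    groups: list[EigenGroup] = []
    l = 0
    while l * l < n:
        lo, hi = l * l + 1, min((l + 1) ** 2, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wl = eigengroup_wavelength(l, R_s)
        groups.append(EigenGroup(l, np.arange(lo, hi + 1), wl, R_s))
        l += 1
    return groups
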