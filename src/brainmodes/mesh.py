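"""Mesh and volume containers with I/O and basic geometry.

Triangle surface meshes represent the cortical sheet, tetrahedral meshes
represent solid (subcortical-like) structures, and voxel masks represent
volumetric segmentations.  All coordinates are in millimetres in a
right-handed frame; vertex/face indices are 0-based in memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import squareform, pdist


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed under the named dialect."""


class MeshValidationError(ValueError):
    """Raised when a parsed mesh violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Triangulated surface: ``vertices`` (V, 3) in mm, ``faces`` (F, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (F, 3)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with i < j."""
        e = np.vstack([self.faces[:, [0, 1]],
                       self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def validate(self, require_closed: bool = False) -> "TriangleMesh":
        """Check structural invariants, returning self on success.

        Verifies index ranges, non-degeneracy, edge-manifoldness and
        orientation consistency; with ``require_closed`` additionally checks
        that every edge is shared by exactly two faces and the Euler
        characteristic is 2 (sphere topology).
        """
        V = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= V):
            raise MeshValidationError("face indices out of range [0, V)")
        degen = (self.faces[:, 0] == self.faces[:, 1]) | \
                (self.faces[:, 1] == self.faces[:, 2]) | \
                (self.faces[:, 0] == self.faces[:, 2])
        if degen.any():
            raise MeshValidationError(
                f"degenerate faces (repeated vertex): {np.nonzero(degen)[0].tolist()}")
        # Directed half-edges: orientation consistency means every directed
        # edge occurs at most once, and each undirected edge at most twice.
        he = np.vstack([self.faces[:, [0, 1]],
                        self.faces[:, [1, 2]],
                        self.faces[:, [2, 0]]])
        keys = he[:, 0] * V + he[:, 1]
        uniq, counts = np.unique(keys, return_counts=True)
        if (counts > 1).any():
            bad = uniq[counts > 1]
            pairs = [(int(k // V), int(k % V)) for k in bad[:20]]
            raise MeshValidationError(
                f"inconsistent orientation / non-manifold directed edges: {pairs}")
        ue = np.sort(he, axis=1)
        ukeys = ue[:, 0] * V + ue[:, 1]
        uu, uc = np.unique(ukeys, return_counts=True)
        if (uc > 2).any():
            bad = uu[uc > 2]
            pairs = [(int(k // V), int(k % V)) for k in bad[:20]]
            raise MeshValidationError(f"non-manifold edges (shared by >2 faces): {pairs}")
        if require_closed:
            if (uc != 2).any():
                bad = uu[uc != 2]
                pairs = [(int(k // V), int(k % V)) for k in bad[:20]]
                raise MeshValidationError(f"boundary edges on closed surface: {pairs}")
            chi = self.euler_characteristic()
            if chi != 2:
                raise MeshValidationError(
                    f"Euler characteristic {chi} != 2 (not sphere topology)")
        return self


@dataclass
class TetraMesh:
    """Tetrahedral volume mesh: ``vertices`` (V, 3) in mm, ``tets`` (K, 4).

    ``voxel_corners`` optionally records, for meshes built from a voxel
    lattice, the 8 corner-vertex indices of each source voxel (used to
    interpolate vertex fields back to voxel centres).
    """

    vertices: np.ndarray
    tets: np.ndarray
    voxel_corners: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        a, b, c, d = (v[self.tets[:, k]] for k in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def orient(self) -> "TetraMesh":
        """Flip tets in place so all signed volumes are positive."""
        vol = self.tet_volumes()
        if (np.abs(vol) < 1e-12).any():
            raise MeshValidationError("zero-volume tetrahedron")
        neg = vol < 0
        self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]
        return self

    def validate(self) -> "TetraMesh":
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= self.n_vertices):
            raise MeshValidationError("tet indices out of range")
        if (self.tet_volumes() <= 0).any():
            raise MeshValidationError("non-positive tet volumes; call orient() first")
        return self


@dataclass
class VoxelMask:
    """Binary voxel grid plus a 4x4 voxel-index -> mm affine."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise MeshValidationError("mask grid must be 3D")
        if self.affine.shape != (4, 4):
            raise MeshValidationError("affine must be 4x4")
        if not self.grid.any():
            raise MeshValidationError("mask is empty")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise MeshValidationError("affine is singular")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of voxel centres, in C scan order."""
        idx = np.argwhere(self.grid).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class ParcellationLabels:
    """Per-vertex (or per-voxel) integer region labels; 0 = unassigned."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_regions(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def validate(self) -> "ParcellationLabels":
        if self.labels.size == 0 or self.labels.min() < 0:
            raise MeshValidationError("labels must be non-negative and nonempty")
        present = np.unique(self.labels[self.labels > 0])
        R = self.n_regions
        if R and not np.array_equal(present, np.arange(1, R + 1)):
            raise MeshValidationError("region IDs must be contiguous 1..R, each nonempty")
        return self

    def region_indices(self, r: int) -> np.ndarray:
        return np.nonzero(self.labels == r)[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _load_off(path: str) -> TriangleMesh:
    with open(path) as fh:
        tokens: list[str] = []
        lineno_of: list[int] = []
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0]
            for t in line.split():
                tokens.append(t)
                lineno_of.append(lineno)
    if not tokens or tokens[0] != "OFF":
        raise MeshFormatError(f"{path}: missing OFF header on line 1")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # skip edge count
        verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            if k != 3:
                raise MeshFormatError(
                    f"{path}: non-triangle face (degree {k}) near line {lineno_of[pos]}")
            faces.append([int(t) for t in tokens[pos + 1:pos + 4]])
            pos += 1 + k
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{path}: malformed OFF record ({exc})") from exc
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def _save_off(path: str, mesh: TriangleMesh) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _load_vtk(path: str) -> TriangleMesh:
    """Legacy-ASCII VTK POLYDATA reader (POINTS + POLYGONS sections only)."""
    with open(path) as fh:
        lines = fh.readlines()
    verts = faces = None
    i = 0
    try:
        while i < len(lines):
            parts = lines[i].split()
            if parts[:1] == ["POINTS"]:
                n = int(parts[1])
                vals: list[float] = []
                i += 1
                while len(vals) < 3 * n:
                    vals.extend(float(x) for x in lines[i].split())
                    i += 1
                verts = np.array(vals).reshape(n, 3)
                continue
            if parts[:1] == ["POLYGONS"]:
                n = int(parts[1])
                rows: list[list[int]] = []
                i += 1
                while i < len(lines) and len(rows) < n:
                    row = [int(x) for x in lines[i].split()]
                    if row:
                        if row[0] != 3 or len(row) < 4:
                            raise MeshFormatError(
                                f"{path}: non-triangle polygon at line {i + 1}")
                        rows.append(row[1:4])
                    i += 1
                if len(rows) < n:
                    raise MeshFormatError(f"{path}: truncated POLYGONS section")
                faces = rows
                continue
            i += 1
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{path}: malformed VTK near line {i + 1} ({exc})") from exc
    if verts is None or faces is None:
        raise MeshFormatError(f"{path}: VTK file lacks POINTS/POLYGONS sections")
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def _save_vtk(path: str, mesh: TriangleMesh) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbrainmodes surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _load_gifti(path: str) -> TriangleMesh:
    """GIFTI surface reader: accepts only pointset + triangle arrays."""
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises various types
        raise MeshFormatError(f"{path}: not readable as GIFTI ({exc})") from exc
    coords = tris = None
    for arr in img.darrays:
        code = arr.intent
        if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(arr.data, dtype=float)
        elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(arr.data, dtype=np.int64)
        else:
            raise MeshFormatError(
                f"{path}: unsupported GIFTI data array (intent {code}); "
                "only triangle-surface files are accepted")
    if coords is None or tris is None:
        raise MeshFormatError(f"{path}: GIFTI file lacks pointset/triangle arrays")
    return TriangleMesh(coords, tris)


_LOADERS = {"off": _load_off, "vtk": _load_vtk, "gifti": _load_gifti}
_SAVERS = {"off": _save_off, "vtk": _save_vtk}
_EXT_FORMAT = {".off": "off", ".vtk": "vtk", ".gii": "gifti"}


def load_mesh(path: str, format: str | None = None) -> TriangleMesh:
    """Load and validate a triangle mesh from OFF / legacy VTK / GIFTI.

    Vertex order is preserved as stored in the file.  Raises
    :class:`MeshFormatError` on parse failure and
    :class:`MeshValidationError` (listing offending edges) on non-manifold
    input.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _EXT_FORMAT.get(os.path.splitext(path)[1].lower())
    if fmt not in _LOADERS:
        raise MeshFormatError(f"unknown mesh format for {path!r} (fmt={fmt})")
    return _LOADERS[fmt](path).validate()


def save_mesh(path: str, mesh: TriangleMesh, format: str | None = None) -> None:
    """Write a mesh as OFF or legacy-ASCII VTK (coordinates at full precision)."""
    fmt = format or _EXT_FORMAT.get(os.path.splitext(path)[1].lower())
    if fmt not in _SAVERS:
        raise MeshFormatError(f"no writer for format {fmt!r}")
    _SAVERS[fmt](path, mesh)


def load_mask(path: str) -> VoxelMask:
    """Read a NIfTI-style binary mask (nonzero voxels are in the mask)."""
    import nibabel as nib

    img = nib.load(path)
    return VoxelMask(np.asarray(img.dataobj) > 0, img.affine)


def load_labels(path: str) -> ParcellationLabels:
    """Read a parcellation stored as one integer label per line."""
    return ParcellationLabels(np.loadtxt(path, dtype=np.int64, ndmin=1)).validate()


def save_labels(path: str, parc: ParcellationLabels) -> None:
    np.savetxt(path, parc.labels, fmt="%d")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def triangle_areas(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric (lumped) vertex areas: one third of incident triangle area.

    The per-vertex areas always sum to the total surface area.
    """
    fa = triangle_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fa / 3.0)
    return out


def pairwise_distance(mesh: TriangleMesh, metric: str = "euclidean",
                      max_vertices: int = 20000) -> np.ndarray:
    """Dense V x V Euclidean distance matrix in mm.

    Refuses meshes above ``max_vertices`` (the dense matrix grows as V^2).
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    V = mesh.n_vertices
    if V > max_vertices:
        raise MemoryError(
            f"pairwise_distance on V={V} exceeds cap {max_vertices}; "
            "raise max_vertices explicitly if this is intended")
    return squareform(pdist(mesh.vertices))


# ---------------------------------------------------------------------------
# voxel lattice tetrahedralization
# ---------------------------------------------------------------------------

# 5-tet split of the unit cube.  Even-parity voxels use the even corner set
# {000,110,101,011} as the central tetrahedron; odd-parity voxels the mirror
# set, so diagonals on shared faces conform between neighbours.
_CUBE = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                  [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
# corner index c_{xyz} = x + 2 y + 4 z
_TETS_EVEN = [(0, 3, 5, 6), (1, 0, 3, 5), (2, 0, 3, 6), (4, 0, 5, 6), (7, 3, 5, 6)]
_TETS_ODD = [(1, 2, 4, 7), (0, 1, 2, 4), (3, 1, 2, 7), (5, 1, 4, 7), (6, 2, 4, 7)]


def tetrahedralize_mask(mask: VoxelMask) -> TetraMesh:
    """Deterministic 5-tets-per-voxel lattice mesh of a binary mask.

    Diagonal choice alternates with voxel parity so that faces shared by
    neighbouring voxels match exactly; total tet volume equals
    ``voxel_volume * n_voxels``.  Requires a single 6-connected component.
    """
    lab, ncomp = ndimage.label(mask.grid, structure=ndimage.generate_binary_structure(3, 1))
    if ncomp != 1:
        sizes = np.bincount(lab.ravel())[1:]
        raise MeshValidationError(
            f"mask has {ncomp} 6-connected components (sizes {sizes.tolist()})")
    vox = np.argwhere(mask.grid)
    # corner lattice points of all voxels
    corners = (vox[:, None, :] + _CUBE[None, :, :]).reshape(-1, 3)
    uniq, inv = np.unique(corners, axis=0, return_inverse=True)
    corner_idx = inv.reshape(len(vox), 8)
    verts = uniq @ mask.affine[:3, :3].T + mask.affine[:3, 3] \
        - 0.5 * (mask.affine[:3, :3] @ np.ones(3))  # voxel centre at index coords
    parity = vox.sum(axis=1) % 2
    tets = np.empty((len(vox), 5, 4), dtype=np.int64)
    for scheme, sel in ((_TETS_EVEN, parity == 0), (_TETS_ODD, parity == 1)):
        for t, quad in enumerate(scheme):
            tets[sel, t, :] = corner_idx[sel][:, quad]
    mesh = TetraMesh(verts, tets.reshape(-1, 4), voxel_corners=corner_idx)
    return mesh.orient().validate()
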