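"""Decomposition of brain maps and time series in an eigenmode basis.

A vertex field y is expanded as y = sum_j a_j psi_j.  For mass-orthonormal
FEM bases the amplitudes are the discretized surface integrals
a = Psi^T M y; for graph bases (identity inner product) a = Psi^T y.
Downstream analyses score how well truncated expansions reconstruct
parcellated maps and functional-connectivity matrices, summarize maps by
their normalized modal power spectra, and assess map-to-map correspondence
against spin-test spatial nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr, spearmanr

from .eigenmodes import EigenmodeBasis
from .mesh import ParcellationLabels, TriangleMesh


@dataclass
class SpatialMap:
    """Per-vertex scalar field; optional boolean mask of valid vertices."""

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
        valid = self.values if self.mask is None else self.values[self.mask]
        if not np.isfinite(valid).all():
            raise ValueError("non-finite values on unmasked vertices")


@dataclass
class SurfaceTimeSeries:
    """Vertex x time data matrix with its sampling interval in seconds."""

    data: np.ndarray
    sampling_interval: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be (V, T) with T >= 2")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite samples")


@dataclass
class ModeCoefficients:
    """Amplitudes a: (N,) for a map or (N, T) for a time series."""

    a: np.ndarray
    basis_id: str = ""


@dataclass
class PowerSpectrum:
    """Normalized modal power P_j >= 0 with sum(P) = 1."""

    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if (self.P < -1e-12).any() or abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("power spectrum must be non-negative and sum to 1")


@dataclass
class FCMatrix:
    """Region x region Pearson functional-connectivity matrix."""

    fc: np.ndarray

    def __post_init__(self):
        self.fc = np.asarray(self.fc, dtype=float)
        if self.fc.ndim != 2 or self.fc.shape[0] != self.fc.shape[1]:
            raise ValueError("FC must be square")


def _basis_id(basis: EigenmodeBasis) -> str:
    return f"{basis.n_vertices}x{basis.n_modes}:{float(basis.eigenvalues.sum()):.12g}"


# ---------------------------------------------------------------------------
# projection / reconstruction
# ---------------------------------------------------------------------------

def decompose(y: SpatialMap | SurfaceTimeSeries | np.ndarray,
              basis: EigenmodeBasis) -> ModeCoefficients:
    """Mode amplitudes of a map or time series.

    Unmasked data use the quadrature projection a = Psi^T M y (exact on the
    basis span).  Masked maps are fitted by least squares on the unmasked
    vertices, which requires at least as many unmasked vertices as modes.
    """
    mask = None
    if isinstance(y, SpatialMap):
        mask, vals = y.mask, y.values
    elif isinstance(y, SurfaceTimeSeries):
        vals = y.data
    else:
        vals = np.asarray(y, dtype=float)
    if vals.shape[0] != basis.n_vertices:
        raise ValueError(f"vertex count mismatch: data {vals.shape[0]}, "
                         f"basis {basis.n_vertices}")
    if mask is not None and not mask.all():
        if mask.sum() < basis.n_modes:
            raise ValueError(
                f"underdetermined: {int(mask.sum())} unmasked vertices < "
                f"{basis.n_modes} modes")
        a, *_ = np.linalg.lstsq(basis.modes[mask], vals[mask], rcond=None)
    else:
        a = basis.project_matrix() @ vals
    return ModeCoefficients(a, basis_id=_basis_id(basis))


def reconstruct(a: ModeCoefficients | np.ndarray, basis: EigenmodeBasis,
                n_use: int | None = None,
                mode_subset: np.ndarray | None = None) -> np.ndarray:
    """Weighted sum of the first ``n_use`` modes (or an explicit 0-based subset)."""
    amp = a.a if isinstance(a, ModeCoefficients) else np.asarray(a, dtype=float)
    if mode_subset is not None:
        idx = np.asarray(mode_subset, dtype=int)
    else:
        n_use = amp.shape[0] if n_use is None else n_use
        if n_use > basis.n_modes:
            raise ValueError("n_use exceeds basis size")
        idx = np.arange(n_use)
    return basis.modes[:, idx] @ amp[idx]


def parcellate(y: SpatialMap | SurfaceTimeSeries | np.ndarray,
               parc: ParcellationLabels) -> np.ndarray:
    """Unweighted mean of the data within each region (label 0 excluded)."""
    vals = y.values if isinstance(y, SpatialMap) else \
        y.data if isinstance(y, SurfaceTimeSeries) else np.asarray(y, dtype=float)
    if len(parc.labels) != vals.shape[0]:
        raise ValueError("label length must equal vertex count")
    R = parc.n_regions
    out = np.empty((R,) + vals.shape[1:])
    for r in range(1, R + 1):
        idx = parc.region_indices(r)
        if idx.size == 0:
            raise ValueError(f"region {r} is empty")
        out[r - 1] = vals[idx].mean(axis=0)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero-variance vector")
    return float(pearsonr(x, y)[0])


def reconstruction_accuracy_map(y: SpatialMap, basis: EigenmodeBasis,
                                parc: ParcellationLabels, n_use: int) -> float:
    """Pearson r between parcellated empirical and reconstructed maps."""
    a = decompose(y, basis)
    rec = reconstruct(a, basis, n_use=n_use)
    return _pearson(parcellate(y, parc), parcellate(rec, parc))


def reconstruct_fc(ts: SurfaceTimeSeries, basis: EigenmodeBasis,
                   parc: ParcellationLabels, n_use: int
                   ) -> tuple[FCMatrix, FCMatrix, float]:
    """Empirical and mode-reconstructed parcel FC plus their upper-triangle r."""
    a = decompose(ts, basis)
    rec = reconstruct(a, basis, n_use=n_use)
    fc_emp = FCMatrix(np.corrcoef(parcellate(ts, parc)))
    fc_rec = FCMatrix(np.corrcoef(parcellate(rec, parc)))
    iu = np.triu_indices(fc_emp.fc.shape[0], k=1)
    r = _pearson(fc_emp.fc[iu], fc_rec.fc[iu])
    return fc_emp, fc_rec, r


def power_spectrum(a: ModeCoefficients | np.ndarray) -> PowerSpectrum:
    """Normalized modal power P_j = |a_j|^2 / sum_k |a_k|^2.

    Time-resolved amplitudes are pooled by total energy per mode.
    """
    amp = a.a if isinstance(a, ModeCoefficients) else np.asarray(a, dtype=float)
    p = np.abs(amp) ** 2
    if p.ndim == 2:
        p = p.sum(axis=1)
    tot = p.sum()
    if tot == 0:
        raise ValueError("all-zero amplitudes: power spectrum undefined")
    return PowerSpectrum(p / tot)


# ---------------------------------------------------------------------------
# mode-removal analysis
# ---------------------------------------------------------------------------

def mode_removal_curve(y: SpatialMap, basis: EigenmodeBasis,
                       parc: ParcellationLabels,
                       direction: str = "long-first") -> dict:
    """Reconstruction accuracy after incremental removal of modes.

    'long-first' removes mode 1, modes 1-2, ... while 'short-first' removes
    mode N, modes N-1..N, ...  Returns the accuracy curve, the all-modes
    baseline and the percentage drop at each removal count; the degenerate
    all-removed case is reported as NaN.
    """
    if direction not in ("long-first", "short-first"):
        raise ValueError("direction must be 'long-first' or 'short-first'")
    N = basis.n_modes
    a = decompose(y, basis)
    y_parc = parcellate(y, parc)
    baseline = _pearson(y_parc, parcellate(reconstruct(a, basis, n_use=N), parc))
    acc = np.empty(N + 1)
    acc[0] = baseline
    for m in range(1, N + 1):
        keep = np.arange(m, N) if direction == "long-first" else np.arange(0, N - m)
        if keep.size == 0:
            acc[m] = np.nan
            continue
        rec = reconstruct(a, basis, mode_subset=keep)
        rec_parc = parcellate(rec, parc)
        acc[m] = np.nan if np.std(rec_parc) == 0 else _pearson(y_parc, rec_parc)
    with np.errstate(invalid="ignore"):
        drop = 100.0 * (baseline - acc) / abs(baseline)
    return {"n_removed": np.arange(N + 1), "accuracy": acc,
            "baseline": baseline, "percent_drop": drop, "direction": direction}


# ---------------------------------------------------------------------------
# spin test
# ---------------------------------------------------------------------------

def spin_null_pvalue(map_a: np.ndarray, map_b: np.ndarray,
                     sphere_coords: np.ndarray, n_perm: int = 1000,
                     seed: int = 0) -> tuple[float, float]:
    """Spin-test significance of the Spearman correlation of two parcel maps.

    The null rotates the parcel centroids by random 3D rotations and
    reassigns each parcel to its nearest rotated centroid, preserving the
    spatial autocorrelation of map_b.  Returns (rho, P_spin) with P_spin
    the one-sided fraction of null correlations greater than the empirical
    one.
    """
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    coords = np.asarray(sphere_coords, dtype=float)
    if np.std(map_a) == 0 or np.std(map_b) == 0:
        raise ValueError("degenerate (constant) map")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rho = float(spearmanr(map_a, map_b)[0])
    rng = np.random.default_rng(seed)
    P = len(map_a)
    assigns = np.empty((n_perm, P), dtype=int)
    for k in range(n_perm):
        R = Rotation.random(rng=rng).as_matrix()
        rotated = coords @ R.T
        # parcel p takes the value of the parcel whose centroid lands nearest
        assigns[k] = np.argmin(cdist(coords, rotated), axis=1)
    from scipy.stats import rankdata

    ra = rankdata(map_a)
    has_ties = len(np.unique(map_b)) < P
    if has_ties:
        rb_perm = np.array([rankdata(map_b[a]) for a in assigns])
    else:
        rb_perm = rankdata(map_b)[assigns]  # ranks permute with the values
    ra_c = ra - ra.mean()
    rb_c = rb_perm - rb_perm.mean(axis=1, keepdims=True)
    null = (rb_c @ ra_c) / (np.linalg.norm(rb_c, axis=1) * np.linalg.norm(ra_c))
    p = float(np.mean(null > rho))
    return rho, p


# ---------------------------------------------------------------------------
# smoothing surrogates
# ---------------------------------------------------------------------------

def mesh_smooth(mesh: TriangleMesh, values: np.ndarray, fwhm: float) -> np.ndarray:
    """Approximate Gaussian smoothing on the mesh by iterated neighbour averaging.

    Each full neighbour-averaging step spreads a delta by roughly the mean
    squared edge length h^2, so sigma^2 / h^2 steps approximate a Gaussian
    kernel of width sigma = fwhm / 2.355; the fractional remainder is
    applied as a partial relaxation step so the kernel width varies
    continuously with FWHM.  Adequate for surrogate construction; not an
    exact heat-kernel smoother.
    """
    if fwhm <= 0:
        return np.asarray(values, dtype=float).copy()
    e = mesh.edges()
    h2 = float(np.mean(np.sum(
        (mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]]) ** 2, axis=1)))
    sigma2 = (fwhm / 2.3548) ** 2
    total = sigma2 / h2
    n_full = int(total)
    frac = total - n_full
    V = mesh.n_vertices
    A = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(V, V))
    A = (A + A.T).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    # include self so the operator is an averaging (mass-preserving) filter
    P = sp.diags(1.0 / (deg + 1.0)) @ (A + sp.eye(V, format="csr"))
    out = np.asarray(values, dtype=float).copy()
    for _ in range(n_full):
        out = P @ out
    if frac > 0:
        out = (1.0 - frac) * out + frac * (P @ out)
    return out


def msle(spec_a: PowerSpectrum, spec_b: PowerSpectrum) -> float:
    """Mean square logarithmic error between two modal power spectra.

    Uses log(1 + P) so zero powers are well defined; symmetric in its
    arguments.
    """
    pa, pb = spec_a.P, spec_b.P
    if pa.shape != pb.shape:
        raise ValueError("spectra must have equal length")
    return float(np.mean((np.log1p(pa) - np.log1p(pb)) ** 2))


def smoothing_surrogate_msle(empirical_spectra: list[PowerSpectrum],
                             mesh: TriangleMesh, basis: EigenmodeBasis,
                             fwhm_grid: np.ndarray, n_maps: int = 100,
                             seed: int = 0) -> np.ndarray:
    """MSLE between the mean empirical spectrum and smoothed-noise surrogates.

    For each FWHM, ``n_maps`` white-noise vertex maps are smoothed on the
    mesh, decomposed in ``basis``, and their mean power spectrum compared
    with the mean empirical spectrum.  Returns one MSLE per grid value.
    """
    fwhm_grid = np.asarray(fwhm_grid, dtype=float)
    if (fwhm_grid < 0).any():
        raise ValueError("FWHM values must be non-negative")
    emp = PowerSpectrum(np.mean([s.P for s in empirical_spectra], axis=0))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((mesh.n_vertices, n_maps))
    out = np.empty(len(fwhm_grid))
    for g, fwhm in enumerate(fwhm_grid):
        smoothed = mesh_smooth(mesh, noise, fwhm)
        a = decompose(smoothed, basis)
        spec = PowerSpectrum(np.mean(
            [power_spectrum(a.a[:, m]).P for m in range(n_maps)], axis=0))
        out[g] = msle(emp, spec)
    return out
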