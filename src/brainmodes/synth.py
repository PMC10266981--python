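"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of its arguments (bit-identical under a
fixed seed) and returns a :class:`PlantedTruth` record describing exactly
what was planted, so recovery tests never reconstruct the truth from the
data themselves.  The generators emulate the study conditions this package
analyses: sphere-like cortical meshes, BOLD-like time series (TR 0.72 s,
1,200 frames) whose spatial covariance is a planted mixture of geometric
eigenmodes, EDR-wired connectomes, and solid volumes carrying smooth
functional gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
import trimesh

from .eigenmodes import EigenmodeBasis
from .gradients import FingerprintInputs
from .mesh import (ParcellationLabels, TriangleMesh, VoxelMask,
                   pairwise_distance, triangle_areas)


@dataclass
class PlantedTruth:
    """Record of the ground truth planted by a generator."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps(asdict(self), default=default, indent=2)


@dataclass
class SynthConfig:
    """Convenience bundle of generator sizes and planted parameters."""

    seed: int
    subdivision: int = 4
    radius: float = 67.0
    n_regions: int = 50
    n_modes: int = 200
    n_frames: int = 1200
    tr: float = 0.72


# ---------------------------------------------------------------------------
# meshes and volumes
# ---------------------------------------------------------------------------

def make_icosphere(subdivision: int, radius: float = 1.0) -> TriangleMesh:
    """Icosahedral sphere mesh with 10 * 4^subdivision + 2 vertices."""
    if not 0 <= subdivision <= 7:
        raise ValueError("subdivision must be in 0..7")
    tm = trimesh.creation.icosphere(subdivisions=subdivision, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces)).validate(
        require_closed=True)


def _real_sph_harm(l: int, m: int, xyz: np.ndarray) -> np.ndarray:
    """Real spherical harmonic Y_lm evaluated at unit vectors."""
    from scipy.special import sph_harm_y

    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    Y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return np.real(Y)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(Y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(Y)


def make_bumpy_sphere(subdivision: int, radius: float, bump_amplitude: float,
                      seed: int = 0, l_max: int = 6,
                      max_retries: int = 3) -> tuple[TriangleMesh, PlantedTruth]:
    """Sphere with a seeded band-limited radial perturbation (folded stand-in)."""
    if bump_amplitude >= 0.3 * radius:
        raise ValueError("bump_amplitude must be < 0.3 * radius")
    base = make_icosphere(subdivision, 1.0)
    rng = np.random.default_rng(seed)
    coeffs = {}
    amp = bump_amplitude
    for attempt in range(max_retries):
        fld = np.zeros(base.n_vertices)
        rng_a = np.random.default_rng(seed)
        for l in range(2, l_max + 1):
            for m in range(-l, l + 1):
                c = rng_a.standard_normal()
                coeffs[(l, m)] = c
                fld += c * _real_sph_harm(l, m, base.vertices)
        if amp > 0 and np.abs(fld).max() > 0:
            fld = fld / np.abs(fld).max()
        r = radius + amp * fld
        mesh = TriangleMesh(base.vertices * r[:, None], base.faces)
        if triangle_areas(mesh).min() > 1e-10:
            truth = PlantedTruth("make_bumpy_sphere", seed,
                                 {"radius": radius, "amplitude": amp, "l_max": l_max})
            return mesh.validate(require_closed=True), truth
        amp *= 0.5
    raise RuntimeError("could not embed bumpy sphere without inverted triangles")


def make_ellipsoid_volume(semi_axes: tuple[float, float, float],
                          voxel_size: float = 1.0) -> VoxelMask:
    """Voxelized solid ellipsoid mask (single 6-connected component)."""
    a = np.asarray(semi_axes, dtype=float)
    if (a <= 2 * voxel_size).any():
        raise ValueError("semi-axes must exceed 2 * voxel size")
    n = np.ceil(a / voxel_size).astype(int) + 2
    shape = 2 * n + 1
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    centre = n.astype(float)
    pos = (idx - centre) * voxel_size
    grid = ((pos / a) ** 2).sum(axis=-1) <= 1.0
    if not grid.any():
        raise ValueError("empty ellipsoid mask")
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = -centre * voxel_size
    return VoxelMask(grid, affine)


def make_parcellation(mesh: TriangleMesh, n_regions: int,
                      seed: int = 0) -> ParcellationLabels:
    """Farthest-point-sampled region centres with nearest-centre assignment."""
    V = mesh.n_vertices
    if n_regions > V // 10:
        raise ValueError("n_regions must be <= V / 10")
    rng = np.random.default_rng(seed)
    centres = [int(rng.integers(V))]
    d = np.linalg.norm(mesh.vertices - mesh.vertices[centres[0]], axis=1)
    for _ in range(n_regions - 1):
        nxt = int(np.argmax(d))
        centres.append(nxt)
        d = np.minimum(d, np.linalg.norm(mesh.vertices - mesh.vertices[nxt], axis=1))
    cpos = mesh.vertices[centres]
    assign = np.argmin(
        ((mesh.vertices[:, None, :] - cpos[None, :, :]) ** 2).sum(axis=2), axis=1)
    return ParcellationLabels(assign + 1).validate()


def parcel_centroids(mesh: TriangleMesh, parc: ParcellationLabels,
                     project_to_sphere: bool = True) -> np.ndarray:
    """Mean vertex position per region, optionally renormalized to the sphere."""
    R = parc.n_regions
    out = np.empty((R, 3))
    for r in range(1, R + 1):
        out[r - 1] = mesh.vertices[parc.region_indices(r)].mean(axis=0)
    if project_to_sphere:
        radius = np.linalg.norm(mesh.vertices, axis=1).mean()
        out = out / np.linalg.norm(out, axis=1, keepdims=True) * radius
    return out


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def planted_mode_variances(eigenvalues: np.ndarray, exponent: float) -> np.ndarray:
    """Planted per-mode variance profile (1 + lambda/lambda_2)^(-exponent).

    Eigenvalues are normalized by the first nonzero eigenvalue so the
    profile is independent of the mesh's physical scale; exponent 0 gives a
    flat spectrum, larger exponents concentrate variance in
    long-wavelength modes.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    nonzero = lam[lam > 1e-12 * max(lam.max(), 1e-30)]
    ref = nonzero[0] if nonzero.size else 1.0
    return (1.0 + lam / ref) ** (-exponent)


def synth_bold_from_modes(basis: EigenmodeBasis, powerlaw_exponent: float = 1.5,
                          noise_sd: float = 0.1, n_frames: int = 1200,
                          tr: float = 0.72, seed: int = 0,
                          ar_coef: float = 0.8) -> tuple[np.ndarray, PlantedTruth]:
    """BOLD-like surface time series from AR(1) modal amplitudes plus noise.

    Amplitude a_j(t) is a stationary AR(1) process with variance following
    :func:`planted_mode_variances`; y = Psi a + Gaussian vertex noise.
    Returns the (V, T) data and the planted truth (per-mode variances).
    """
    if powerlaw_exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed)
    var = planted_mode_variances(basis.eigenvalues, powerlaw_exponent)
    sd = np.sqrt(var)
    N = basis.n_modes
    innov_sd = sd * np.sqrt(1.0 - ar_coef ** 2)
    a = np.empty((N, n_frames))
    a[:, 0] = sd * rng.standard_normal(N)
    eps = rng.standard_normal((N, n_frames - 1))
    for t in range(1, n_frames):
        a[:, t] = ar_coef * a[:, t - 1] + innov_sd * eps[:, t - 1]
    y = basis.modes @ a
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(y.shape)
    truth = PlantedTruth("synth_bold_from_modes", seed, {
        "mode_variances": var, "ar_coef": ar_coef, "noise_sd": noise_sd,
        "tr": tr, "n_frames": n_frames, "exponent": powerlaw_exponent})
    return y, truth


def synth_task_map(basis: EigenmodeBasis, coefficients: np.ndarray | dict,
                   noise_sd: float = 0.0, seed: int = 0
                   ) -> tuple[np.ndarray, PlantedTruth]:
    """Activation-like map y = Psi c + noise with a planted coefficient vector.

    ``coefficients`` may be a dense length-N vector or a {0-based mode
    index: value} mapping.
    """
    c = np.zeros(basis.n_modes)
    if isinstance(coefficients, dict):
        for j, v in coefficients.items():
            if not 0 <= j < basis.n_modes:
                raise ValueError(f"mode index {j} out of range")
            c[j] = v
    else:
        arr = np.asarray(coefficients, dtype=float)
        c[:len(arr)] = arr
    rng = np.random.default_rng(seed)
    y = basis.modes @ c
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(y.shape)
    truth = PlantedTruth("synth_task_map", seed,
                         {"coefficients": c, "noise_sd": noise_sd})
    return y, truth


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def synth_connectome(mesh: TriangleMesh, alpha: float = 0.12,
                     long_range_fraction: float = 0.0, seed: int = 0,
                     weight_jitter: float = 0.0):
    """EDR-wired weighted connectome with optional planted long-range edges.

    Pairs are connected with probability exp(-alpha d); connected pairs get
    weight exp(-alpha d) * (1 + jitter), jitter uniform in
    [-weight_jitter, weight_jitter].  A fraction of additional uniform
    long-range edges is sprinkled among unconnected pairs whose distance
    exceeds the 90th percentile of the EDR edge distances.
    """
    from .graph import SparseConnectome

    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0 <= long_range_fraction <= 0.1:
        raise ValueError("long_range_fraction must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    D = pairwise_distance(mesh)
    V = mesh.n_vertices
    iu, ju = np.triu_indices(V, k=1)
    d = D[iu, ju]
    p = np.exp(-alpha * d)
    hit = rng.random(len(d)) < p
    w = np.zeros(len(d))
    w[hit] = np.exp(-alpha * d[hit])
    if weight_jitter > 0:
        w[hit] *= 1.0 + weight_jitter * rng.uniform(-1, 1, hit.sum())
    lr_idx = np.array([], dtype=int)
    if long_range_fraction > 0 and hit.any():
        q90 = np.quantile(d[hit], 0.9)
        candidates = np.nonzero(~hit & (d > q90))[0]
        n_lr = min(int(round(long_range_fraction * hit.sum())), len(candidates))
        lr_idx = rng.choice(candidates, size=n_lr, replace=False)
        w[lr_idx] = np.exp(-alpha * q90) * rng.uniform(0.5, 1.5, n_lr)
    nz = w > 0
    W = sp.coo_matrix((w[nz], (iu[nz], ju[nz])), shape=(V, V))
    W = (W + W.T).tocsr()
    truth = PlantedTruth("synth_connectome", seed, {
        "alpha": alpha, "long_range_fraction": long_range_fraction,
        "n_edr_edges": int(hit.sum()), "n_long_range": int(len(lr_idx)),
        "long_range_pairs": np.column_stack([iu[lr_idx], ju[lr_idx]])
        if len(lr_idx) else np.empty((0, 2), dtype=int)})
    return SparseConnectome(W), truth


# ---------------------------------------------------------------------------
# gradient volumes
# ---------------------------------------------------------------------------

def synth_gradient_fc(axes: np.ndarray, n_subjects: int = 5, noise: float = 0.2,
                      seed: int = 0, n_frames: int = 120, n_outside: int = 300,
                      n_latent: int = 40, bump_width: float = 1.5,
                      axis_scales: np.ndarray | None = None
                      ) -> tuple[list[FingerprintInputs], PlantedTruth]:
    """Voxel time series whose fingerprint similarity decays along planted axes.

    ``axes`` is (N_voxels, K) of smooth spatial fields.  Each axis is
    standardized and scaled by a decaying factor so the first axis carries
    the widest similarity range; voxels are driven by latent signals with
    Gaussian-bump loadings in axis space, so fingerprint similarity decays
    with distance along the planted axes.  One FingerprintInputs per
    subject; the same spatial loadings, independent signals and noise.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if axes.ndim != 2:
        raise ValueError("axes must be (N, K)")
    if axes.shape[0] < axes.shape[1]:
        axes = axes.T
    N, K = axes.shape
    if K < 1:
        raise ValueError("need >= 1 planted axis")
    scales = np.asarray(axis_scales, dtype=float) if axis_scales is not None \
        else 0.6 ** np.arange(K)
    ax = (axes - axes.mean(axis=0)) / axes.std(axis=0) * scales
    rng = np.random.default_rng(seed)
    centres = ax[rng.integers(0, N, size=n_latent)]
    dist2 = ((ax[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    W = np.exp(-dist2 / (2.0 * bump_width ** 2))      # (N, n_latent)
    V_mix = rng.standard_normal((n_outside, n_latent))
    subjects = []
    for s in range(n_subjects):
        Z = rng.standard_normal((n_frames, n_latent))
        A = Z @ W.T + noise * rng.standard_normal((n_frames, N))
        B = Z @ V_mix.T + noise * rng.standard_normal((n_frames, n_outside))
        subjects.append(FingerprintInputs(A, B))
    truth = PlantedTruth("synth_gradient_fc", seed, {
        "axes": ax, "axis_scales": scales, "noise": noise,
        "bump_width": bump_width, "n_latent": n_latent})
    return subjects, truth
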