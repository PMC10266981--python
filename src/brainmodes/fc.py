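"""Functional-connectivity benchmarks: edge FC, node FC, FCD and its KS fit.

Static FC is compared edgewise (Fisher-z upper triangles) and nodewise
(mean regional strength).  Functional connectivity dynamics (FCD) tracks
the similarity of instantaneous interregional synchrony over time: signals
are band-passed (0.04-0.07 Hz), Hilbert transformed, and the cosine of
argument differences Delta(i,j,t) = cos(theta_i - theta_j) is correlated
(cosine-normalized) between time frames.  Model and data FCD value
distributions are compared with the two-sample KS statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert
from scipy.stats import pearsonr

from .decomposition import FCMatrix


@dataclass
class FCDMatrix:
    """Frame x frame synchrony-similarity matrix phi_uv with unit diagonal."""

    phi: np.ndarray
    normalizers: np.ndarray = field(default=None)  # d_x per retained frame

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.phi.shape[0], k=1)
        return self.phi[iu]


def _fisher_z(r: np.ndarray, clip: float = 1 - 1e-6) -> np.ndarray:
    return np.arctanh(np.clip(r, -clip, clip))


def edge_fc(model_fc: FCMatrix, data_fc: FCMatrix) -> float:
    """Pearson r of Fisher-z-transformed upper-triangle FC values."""
    a, b = model_fc.fc, data_fc.fc
    if a.shape != b.shape:
        raise ValueError(f"FC size mismatch: {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=1)
    return float(pearsonr(_fisher_z(a[iu]), _fisher_z(b[iu]))[0])


def node_fc(model_fc: FCMatrix, data_fc: FCMatrix) -> float:
    """Pearson r of mean regional FC strengths (row means incl. diagonal)."""
    a, b = model_fc.fc, data_fc.fc
    if a.shape != b.shape:
        raise ValueError(f"FC size mismatch: {a.shape} vs {b.shape}")
    sa, sb = a.mean(axis=1), b.mean(axis=1)
    if np.std(sa) == 0 or np.std(sb) == 0:
        raise ValueError("undefined correlation: constant strength vector")
    return float(pearsonr(sa, sb)[0])


def fcd(ts: np.ndarray, sampling_interval: float,
        band: tuple[float, float] | None = (0.04, 0.07),
        edge_drop: int = 10, four_quadrant: bool = False) -> FCDMatrix:
    """FCD matrix of a region x time series.

    Applies a zero-phase second-order Butterworth band-pass (skipped when
    ``band`` is None), Hilbert transforms each region, computes the
    two-quadrant argument theta = arctan(H/x) (four-quadrant optional), the
    pairwise synchrony Delta(i,j,t) = cos(theta_i - theta_j) over i > j,
    and the cosine similarity phi_uv of the Delta vectors between frames.
    The first/last ``edge_drop`` frames are discarded to suppress filter
    edge effects.
    """
    x = np.asarray(ts, dtype=float)
    if x.ndim != 2:
        raise ValueError("time series must be (regions, time)")
    R, T = x.shape
    if band is not None:
        nyq = 0.5 / sampling_interval
        lo, hi = band
        if not 0 < lo < hi < nyq:
            raise ValueError(f"band {band} Hz infeasible at sampling interval "
                             f"{sampling_interval}s (Nyquist {nyq:g} Hz)")
        if T * sampling_interval < 10 / lo:
            warnings.warn("fewer than ~10 cycles of the low band edge; "
                          "FCD estimates may be unstable")
        b, a = butter(2, [lo / nyq, hi / nyq], btype="bandpass")
        x = filtfilt(b, a, x, axis=1)
    H = np.imag(hilbert(x, axis=1))
    theta = np.arctan2(H, x) if four_quadrant else np.arctan(H / np.where(x == 0, 1e-300, x))
    if edge_drop:
        if T <= 2 * edge_drop:
            raise ValueError("edge_drop leaves no frames")
        theta = theta[:, edge_drop:T - edge_drop]
    W = theta.shape[1]
    iu, ju = np.triu_indices(R, k=1)
    delta = np.cos(theta[iu] - theta[ju])  # (n_pairs, W)
    d = np.sqrt(np.sum(delta ** 2, axis=0))
    phi = (delta / d).T @ (delta / d)
    return FCDMatrix(phi, normalizers=d)


def ks_statistic(fcd_a: FCDMatrix | list[FCDMatrix],
                 fcd_b: FCDMatrix | list[FCDMatrix]) -> float:
    """Two-sample KS statistic between upper-triangle FCD distributions.

    Lists of FCD matrices are concatenated (pooling across realizations).
    """
    def pool(x):
        mats = x if isinstance(x, (list, tuple)) else [x]
        vals = np.concatenate([m.upper_values() for m in mats])
        if vals.size == 0:
            raise ValueError("empty FCD distribution")
        return vals

    from scipy.stats import ks_2samp
    return float(ks_2samp(pool(fcd_a), pool(fcd_b), method="asymp").statistic)
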