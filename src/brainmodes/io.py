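"""Plain-text dense matrix format and the eigenmode-basis container.

Matrices are stored as '# key value' header lines followed by whitespace-
separated rows; bases are stored as NumPy .npz archives holding the mode
matrix, eigenvalues and a checksum of the mass matrix they are orthonormal
under.
"""

from __future__ import annotations

import hashlib

import numpy as np
import scipy.sparse as sp

from .eigenmodes import EigenmodeBasis


def write_matrix(path: str, data: np.ndarray, **meta) -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    header = "\n".join(f"{k} {v}" for k, v in meta.items())
    np.savetxt(path, data, header=header, fmt="%.17g")


def read_matrix(path: str) -> tuple[np.ndarray, dict]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) >= 2:
                try:
                    meta[parts[0]] = float(parts[1])
                except ValueError:
                    meta[parts[0]] = parts[1]
    return np.atleast_2d(np.loadtxt(path)), meta


def mass_checksum(mass: sp.spmatrix | None) -> str:
    if mass is None:
        return "identity"
    m = sp.csr_matrix(mass)
    h = hashlib.sha256()
    h.update(m.indptr.tobytes())
    h.update(m.indices.tobytes())
    h.update(np.round(m.data, 12).tobytes())
    return h.hexdigest()[:16]


def save_basis(path: str, basis: EigenmodeBasis) -> None:
    np.savez_compressed(path, modes=basis.modes, eigenvalues=basis.eigenvalues,
                        mass_checksum=np.array(mass_checksum(basis.mass)),
                        sign_convention=np.array(basis.sign_convention))


def load_basis(path: str, mass: sp.spmatrix | None = None) -> EigenmodeBasis:
    """Load a basis; pass the mass matrix to restore the inner product.

    Raises if the supplied mass matrix does not match the stored checksum.
    """
    with np.load(path) as z:
        modes = z["modes"]
        evals = z["eigenvalues"]
        stored = str(z["mass_checksum"])
        sign = str(z["sign_convention"])
    if mass is not None and mass_checksum(mass) != stored:
        raise ValueError("mass matrix does not match the stored checksum")
    if mass is None and stored != "identity":
        raise ValueError("basis was built with a mass inner product; pass mass=")
    return EigenmodeBasis(modes, evals, mass=mass, sign_convention=sign)
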