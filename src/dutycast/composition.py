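"""Aitchison-simplex utilities: closure and the isometric log-ratio (ILR)
transform.

A D-part composition lives on the unit simplex (positive shares summing to
one). The ILR transform maps it to D-1 unconstrained real coordinates via an
orthonormal contrast matrix whose rows are orthogonal to the all-ones vector;
it is an isometry between Aitchison geometry on the simplex and Euclidean
geometry on R^(D-1), which is what lets ordinary least squares be applied to
share series. The default contrast is the Helmert-derived basis, but every
operation accepts any orthonormal basis: predictions recombined on the
revenue scale are invariant to that choice (a rotation of coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DomainError

__all__ = [
    "IlrBasis",
    "helmert_basis",
    "random_basis",
    "closure",
    "ilr_transform",
    "ilr_inverse",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal ILR contrast matrix of shape (D-1, D).

    Rows are mutually orthonormal and each is orthogonal to the all-ones
    vector; both properties are asserted at construction.
    """

    matrix: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] - 1:
            raise DomainError(
                f"ILR basis must have shape (D-1, D); got {m.shape}"
            )
        gram = m @ m.T
        if not np.allclose(gram, np.eye(m.shape[0]), atol=_ORTHO_TOL):
            raise DomainError("ILR basis rows are not orthonormal")
        if not np.allclose(m @ np.ones(m.shape[1]), 0.0, atol=_ORTHO_TOL):
            raise DomainError("ILR basis rows are not orthogonal to ones")
        object.__setattr__(self, "matrix", m)

    @property
    def n_parts(self) -> int:
        return self.matrix.shape[1]


def helmert_basis(n_parts: int = 4) -> IlrBasis:
    """Helmert-derived orthonormal contrast for ``n_parts`` components."""
    if n_parts < 2:
        raise DomainError("need at least 2 parts for an ILR basis")
    return IlrBasis(scipy.linalg.helmert(n_parts, full=False), label="helmert")


def random_basis(n_parts: int, seed: int) -> IlrBasis:
    """A random orthonormal ILR basis (rotation of the Helmert contrast).

    Used to exercise basis invariance; any orthonormal basis of the
    hyperplane orthogonal to the ones vector is valid.
    """
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n_parts - 1, n_parts - 1)))
    q *= np.sign(np.diag(r))  # fix QR sign ambiguity for reproducibility
    return IlrBasis(q @ helmert_basis(n_parts).matrix, label=f"random-{seed}")


def closure(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalise positive values to unit-sum shares along ``axis``."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise DomainError("closure requires strictly positive finite values")
    return v / v.sum(axis=axis, keepdims=True)


def ilr_transform(shares: np.ndarray, basis: IlrBasis) -> np.ndarray:
    """Map compositions (last axis = D parts) to ILR coordinates.

    ``z = Psi @ log(x)``; because the rows of Psi are orthogonal to the ones
    vector this equals the usual contrast of centred log-ratios.
    """
    x = np.asarray(shares, dtype=float)
    if x.shape[-1] != basis.n_parts:
        raise DomainError(
            f"composition has {x.shape[-1]} parts, basis expects {basis.n_parts}"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DomainError("ILR requires strictly positive shares")
    return np.log(x) @ basis.matrix.T


def ilr_inverse(coords: np.ndarray, basis: IlrBasis) -> np.ndarray:
    """Map ILR coordinates (last axis = D-1) back to unit-sum compositions."""
    z = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(z)):
        raise DomainError("ILR inverse requires finite coordinates")
    if z.shape[-1] != basis.n_parts - 1:
        raise DomainError(
            f"{z.shape[-1]} coordinates do not match a {basis.n_parts}-part basis"
        )
    logx = z @ basis.matrix
    logx -= logx.max(axis=-1, keepdims=True)  # overflow guard
    ex = np.exp(logx)
    return ex / ex.sum(axis=-1, keepdims=True)
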