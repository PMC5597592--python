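"""Mapping-matrix algebra for resolution transformations.

A mapping scheme is an m-beads x n-atoms weight matrix with convex rows
(non-negative, summing to one).  Applied to coordinates it produces bead
positions; applied to displacement vectors it produces bead displacements.
Displacement patterns in the matrix's null space are invisible at the
coarse resolution; the conservation ratio quantifies, mode by mode, how
much positional RMSD survives the transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .errors import MappingDefinitionError, ShapeError, ValidationError

__all__ = [
    "MappingScheme",
    "ConservationProfile",
    "identity_mapping",
    "uniform_mapping",
    "map_coordinates",
    "map_vector",
    "conservation_ratio",
    "in_kernel",
    "kernel_basis",
    "map_covariance",
    "conservation_profile",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MappingScheme:
    """m x n weight matrix with bead/atom name bookkeeping.

    Rows must be non-negative and sum to 1 (use :meth:`normalized` to
    rescale raw weights); ``m <= n``.
    """

    weights: np.ndarray
    bead_names: tuple[str, ...]
    atom_names: tuple[str, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2:
            raise ShapeError("weights must be a 2-D matrix")
        m, n = w.shape
        if m > n:
            raise ValidationError(f"more beads ({m}) than atoms ({n})")
        if len(self.bead_names) != m or len(self.atom_names) != n:
            raise ShapeError("name lists do not match weight matrix shape")
        if np.any(w < 0):
            raise ValidationError("mapping weights must be non-negative")
        rowsums = w.sum(axis=1)
        if np.any(rowsums == 0):
            bad = int(np.argmin(rowsums))
            raise MappingDefinitionError(f"bead '{self.bead_names[bad]}' has zero total weight")
        if np.any(np.abs(rowsums - 1.0) > _ROW_SUM_TOL):
            raise ValidationError(
                "rows must sum to 1; call MappingScheme.normalized() on raw weights"
            )

    @property
    def n_beads(self) -> int:
        return self.weights.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def normalized(cls, weights, bead_names, atom_names) -> "MappingScheme":
        """Build a scheme from raw non-negative weights, rescaling each row to sum 1."""
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2:
            raise ShapeError("weights must be a 2-D matrix")
        rowsums = w.sum(axis=1, keepdims=True)
        if np.any(rowsums == 0):
            bad = int(np.argmin(rowsums[:, 0]))
            raise MappingDefinitionError(f"bead '{bead_names[bad]}' has zero total weight")
        return cls(w / rowsums, tuple(bead_names), tuple(atom_names))


@dataclass(frozen=True)
class ConservationProfile:
    """Per-mode conservation ratios for one mapping scheme."""

    alpha: np.ndarray
    mapping_label: str
    mode_count: int = field(default=0)

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", a)
        if self.mode_count == 0:
            object.__setattr__(self, "mode_count", a.size)
        if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
            raise ValidationError("conservation ratios must lie in [0, 1]")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"mode": np.arange(self.mode_count), "alpha": self.alpha}
        ).to_csv(path, index=False)


def identity_mapping(n_atoms: int, atom_names=None) -> MappingScheme:
    names = tuple(atom_names) if atom_names is not None else tuple(f"a{i}" for i in range(n_atoms))
    return MappingScheme(np.eye(n_atoms), names, names)


def uniform_mapping(n_atoms: int, ratio: int, atom_names=None) -> MappingScheme:
    """Consecutive blocks of `ratio` atoms per bead, equal weights.

    When ``n_atoms`` is not divisible by ``ratio`` the final bead absorbs
    the remainder.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    if ratio > n_atoms:
        raise ValueError(f"ratio {ratio} exceeds atom count {n_atoms}")
    n_beads = n_atoms // ratio
    bounds = [i * ratio for i in range(n_beads)] + [n_atoms]
    w = np.zeros((n_beads, n_atoms))
    for i in range(n_beads):
        w[i, bounds[i] : bounds[i + 1]] = 1.0
    names = tuple(atom_names) if atom_names is not None else tuple(f"a{i}" for i in range(n_atoms))
    beads = tuple(f"B{i}" for i in range(n_beads))
    return MappingScheme.normalized(w, beads, names)


def _check_atom_dim(n_given: int, scheme: MappingScheme) -> None:
    if n_given != scheme.n_atoms:
        raise ShapeError(
            f"atom dimension {n_given} does not match scheme with {scheme.n_atoms} atoms"
        )


def map_coordinates(coords: np.ndarray, scheme: MappingScheme) -> np.ndarray:
    """Apply the weight matrix per frame: (..., n, 3) -> (..., m, 3)."""
    c = np.asarray(coords, dtype=float)
    if c.ndim < 2 or c.shape[-1] != 3:
        raise ShapeError("coordinates must have shape (..., n, 3)")
    _check_atom_dim(c.shape[-2], scheme)
    return np.einsum("ij,...jk->...ik", scheme.weights, c)


def map_vector(vec: np.ndarray, scheme: MappingScheme) -> np.ndarray:
    """Map a flat 3n displacement vector to its 3m bead counterpart."""
    v = np.asarray(vec, dtype=float).ravel()
    if v.size != 3 * scheme.n_atoms:
        raise ShapeError(f"expected length {3 * scheme.n_atoms}, got {v.size}")
    return map_coordinates(v.reshape(scheme.n_atoms, 3), scheme).ravel()


def conservation_ratio(vec: np.ndarray, scheme: MappingScheme) -> float:
    """Fraction of a displacement pattern's RMSD retained after mapping.

    The numerator is the RMS bead displacement of the mapped vector; the
    denominator is the RMS of a weighted mean of squared atomic
    displacements with the scheme's convex weights, which bounds the
    ratio by 1.
    """
    v = np.asarray(vec, dtype=float).ravel()
    if v.size != 3 * scheme.n_atoms:
        raise ShapeError(f"expected length {3 * scheme.n_atoms}, got {v.size}")
    sq_atom = (v.reshape(-1, 3) ** 2).sum(axis=1)
    if not np.any(sq_atom > 0):
        raise ValidationError("conservation ratio is undefined for the zero vector")
    m = scheme.n_beads
    bead = map_coordinates(v.reshape(-1, 3), scheme)
    num = np.sqrt((bead**2).sum() / m)
    den = np.sqrt((scheme.weights @ sq_atom).sum() / m)
    return float(num / den)


def in_kernel(vec: np.ndarray, scheme: MappingScheme, tol: float = 1e-10) -> bool:
    """True iff the mapped vector vanishes relative to the input norm."""
    v = np.asarray(vec, dtype=float).ravel()
    mapped = map_vector(v, scheme)
    return bool(np.linalg.norm(mapped) <= tol * np.linalg.norm(v))


def kernel_basis(scheme: MappingScheme) -> np.ndarray:
    """Orthonormal basis (columns) of displacement patterns eliminated by the mapping.

    Works in the full 3n space: the kernel of (W (x) I3).
    """
    big = np.kron(scheme.weights, np.eye(3))
    return null_space(big)


def map_covariance(cov: np.ndarray, scheme: MappingScheme, *, atol: float = 1e-8) -> np.ndarray:
    """Transform a 3n x 3n covariance to the 3m x 3m bead representation."""
    c = np.asarray(cov, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ShapeError("covariance must be square")
    if c.shape[0] != 3 * scheme.n_atoms:
        raise ShapeError(f"expected {3 * scheme.n_atoms} rows, got {c.shape[0]}")
    if not np.allclose(c, c.T, atol=atol):
        raise ValidationError("covariance matrix is not symmetric")
    big = np.kron(scheme.weights, np.eye(3))
    out = big @ c @ big.T
    return 0.5 * (out + out.T)


def conservation_profile(
    eigenvectors: np.ndarray, scheme: MappingScheme, label: str = ""
) -> ConservationProfile:
    """Conservation ratio of each column eigenvector under one scheme."""
    vecs = np.asarray(eigenvectors, dtype=float)
    if vecs.ndim != 2:
        raise ShapeError("eigenvectors must be a (3n, k) matrix of columns")
    alphas = np.array([conservation_ratio(vecs[:, k], scheme) for k in range(vecs.shape[1])])
    return ConservationProfile(np.clip(alphas, 0.0, 1.0), label or f"{scheme.n_beads}x{scheme.n_atoms}")
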