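"""Positional covariance PCA and basis/covariance comparison statistics.

Conventions
-----------
* Coordinates are flattened (particle, axis)-major, so row/column ``3*p + a``
  of the covariance refers to axis ``a`` of particle ``p``.
* Covariance uses divisor K (population); with the pooled conformation
  counts this pipeline targets, the K vs K-1 distinction is negligible and
  the trace identity Σλ = total variance then holds exactly.
* Eigenvector signs follow a deterministic convention: the component with
  the largest magnitude is made positive.  Order inside numerically
  degenerate eigenvalue blocks is fixed only by this tiebreak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ShapeError, ValidationError
from .cgmap import MappingScheme, map_vector
from .superpose import AlignedEnsemble

__all__ = [
    "PCAModel",
    "ProjectionSeries",
    "compute_covariance",
    "eigendecompose",
    "pca_from_ensemble",
    "normalized_eigenvalues",
    "project",
    "cumulative_variance",
    "covariance_pcc",
    "dot_product_matrix",
]


@dataclass
class PCAModel:
    """Eigendecomposition of a positional covariance matrix.

    ``eigenvectors`` holds orthonormal columns; ``eigenvalues`` (Ang^2)
    are sorted descending and clamped at zero.
    """

    mean_structure: np.ndarray  # (N_p, 3)
    eigenvectors: np.ndarray  # (3 N_p, k)
    eigenvalues: np.ndarray  # (k,)
    covariance: np.ndarray  # (3 N_p, 3 N_p)
    particle_count: int

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValidationError("eigenvalues must be sorted descending")
        self.eigenvalues = ev

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


@dataclass
class ProjectionSeries:
    """Per-mode, per-copy projection time series, shape (k, N_L, T), Ang."""

    values: np.ndarray
    mode_ids: list[int]
    frame_interval: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 3:
            raise ShapeError("projection values must be (modes, copies, frames)")
        if not np.all(np.isfinite(v)):
            raise ValidationError("projection values contain non-finite entries")
        self.values = v

    def pooled(self, mode: int) -> np.ndarray:
        i = self.mode_ids.index(mode)
        return self.values[i].ravel()

    def to_frame(self):
        import pandas as pd

        k, n_l, t = self.values.shape
        mode = np.repeat(self.mode_ids, n_l * t)
        copy = np.tile(np.repeat(np.arange(n_l), t), k)
        frame = np.tile(np.arange(t), k * n_l)
        return pd.DataFrame(
            {"mode": mode, "copy": copy, "frame": frame, "value": self.values.ravel()}
        )


def compute_covariance(aligned) -> tuple[np.ndarray, np.ndarray]:
    """Mean structure and 3N x 3N positional covariance (divisor K)."""
    conf = aligned.conformations if isinstance(aligned, AlignedEnsemble) else np.asarray(aligned, float)
    if conf.ndim != 3 or conf.shape[2] != 3:
        raise ShapeError("conformations must be (K, N_p, 3)")
    k = conf.shape[0]
    if k < 2:
        raise InsufficientDataError("covariance needs at least 2 conformations")
    flat = conf.reshape(k, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / k
    cov = 0.5 * (cov + cov.T)
    return mean.reshape(-1, 3), cov


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def eigendecompose(covariance: np.ndarray, mean_structure: np.ndarray, *, atol: float = 1e-8) -> PCAModel:
    """Descending-eigenvalue decomposition with the package sign convention."""
    cov = np.asarray(covariance, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ShapeError("covariance must be square")
    scale = max(np.abs(cov).max(), 1.0)
    if not np.allclose(cov, cov.T, atol=atol * scale):
        raise ValidationError("covariance matrix is not symmetric")
    mean = np.asarray(mean_structure, float).reshape(-1, 3)
    if 3 * mean.shape[0] != cov.shape[0]:
        raise ShapeError("mean structure does not match covariance dimension")
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam1 = max(vals[0], 0.0)
    if vals[-1] < -1e-8 * max(lam1, 1.0):
        raise ValidationError(f"covariance has a significantly negative eigenvalue: {vals[-1]}")
    vals = np.clip(vals, 0.0, None)
    return PCAModel(mean, _fix_signs(vecs), vals, cov, mean.shape[0])


def pca_from_ensemble(aligned) -> PCAModel:
    mean, cov = compute_covariance(aligned)
    return eigendecompose(cov, mean)


def normalized_eigenvalues(model: PCAModel) -> np.ndarray:
    """Eigenvalues divided by the particle count, for cross-resolution plots."""
    if model.particle_count <= 0:
        raise ValidationError("particle count must be positive")
    return model.eigenvalues / model.particle_count


def project(conformations, model: PCAModel, modes: int | list[int] = 1,
            n_copies: int = 1, frame_interval: float | None = None) -> ProjectionSeries:
    """Project conformations (already in the model's frame) onto eigenvectors.

    Accepts an AlignedEnsemble (copy structure inferred) or a raw
    (K, N_p, 3) stack with ``n_copies`` given; pooling must be copy-major.
    """
    if isinstance(conformations, AlignedEnsemble):
        n_copies = conformations.n_copies
        frame_interval = frame_interval or conformations.frame_interval
        conf = conformations.conformations
    else:
        conf = np.asarray(conformations, float)
    if conf.ndim != 3 or conf.shape[2] != 3:
        raise ShapeError("conformations must be (K, N_p, 3)")
    if conf.shape[1] != model.particle_count:
        raise ShapeError(
            f"conformations have {conf.shape[1]} particles, model expects {model.particle_count}"
        )
    mode_ids = list(range(modes)) if isinstance(modes, int) else list(modes)
    k = conf.shape[0]
    centered = conf.reshape(k, -1) - model.mean_structure.ravel()
    p = centered @ model.eigenvectors[:, mode_ids]  # (K, k_modes)
    t = k // n_copies
    values = p.T.reshape(len(mode_ids), n_copies, t)
    return ProjectionSeries(values, mode_ids, frame_interval)


def cumulative_variance(model: PCAModel) -> np.ndarray:
    """Fraction of total variance captured by the leading k modes."""
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValidationError("cumulative variance undefined for an all-zero spectrum")
    return np.cumsum(model.eigenvalues) / total


def covariance_pcc(m_i: np.ndarray, m_j: np.ndarray) -> float:
    """Pearson correlation of the elements of two covariance matrices."""
    a = np.asarray(m_i, float).ravel()
    b = np.asarray(m_j, float).ravel()
    if a.size != b.size:
        raise ShapeError("matrices must have equal shapes")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValidationError("Pearson correlation undefined for constant matrices")
    return float(np.dot(a, b) / denom)


def dot_product_matrix(model_i: PCAModel, model_j: PCAModel, k: int,
                       mapping: MappingScheme | None = None) -> np.ndarray:
    """k x k matrix of absolute dot products between leading eigenvectors.

    When ``mapping`` is given, model_i's eigenvectors are mapped to the
    bead space and renormalized to unit length first.  Mapped vectors are
    generally no longer orthogonal, so off-diagonal structure is expected.
    """
    vi = model_i.eigenvectors[:, :k]
    if mapping is not None:
        vi = np.column_stack([map_vector(vi[:, c], mapping) for c in range(vi.shape[1])])
        norms = np.linalg.norm(vi, axis=0)
        if np.any(norms == 0):
            raise ValidationError("a mapped eigenvector vanished; cannot renormalize")
        vi = vi / norms
    vj = model_j.eigenvectors[:, :k]
    if vi.shape[0] != vj.shape[0]:
        raise ShapeError("bases live in different dimensions after mapping")
    return np.abs(vi.T @ vj)
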