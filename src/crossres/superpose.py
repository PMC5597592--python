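"""Least-squares structure superposition and two-pass reference construction.

Superposition is non-mass-weighted by default (a ``weights`` argument
exists at the library level but the pipeline never sets it).  The optimal
rotation is the classic SVD solution with a reflection guard: when the
best orthogonal transform is improper, the smallest singular direction is
flipped so chirality is never mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InsufficientDataError, ShapeError, ValidationError
from .trajio import MoleculeEnsemble

__all__ = ["AlignedEnsemble", "superpose_pair", "align_ensemble", "build_reference", "batch_rmsd"]


@dataclass
class AlignedEnsemble:
    """Conformations superposed onto a common reference frame."""

    conformations: np.ndarray  # (K, N_p, 3)
    reference: np.ndarray  # (N_p, 3)
    fit_selection: np.ndarray
    rmsd: np.ndarray | None = None  # per-conformation fit rmsd
    n_copies: int = 1
    frame_interval: float | None = None

    @property
    def n_conformations(self) -> int:
        return self.conformations.shape[0]

    @property
    def n_particles(self) -> int:
        return self.conformations.shape[1]

    def per_copy(self) -> np.ndarray:
        t = self.n_conformations // self.n_copies
        return self.conformations.reshape(self.n_copies, t, self.n_particles, 3)


def _as_selection(selection, n: int) -> np.ndarray:
    if selection is None:
        return np.arange(n)
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise GeometryError("fit selection must contain at least 3 particles")
    return sel


def _check_degenerate(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise GeometryError("fit selection is collinear or coincident")


def _optimal_rotation(mobile_sel: np.ndarray, ref_sel: np.ndarray, weights=None):
    """Rotation matrix and centroids minimizing weighted squared deviation."""
    if weights is None:
        w = np.full(len(mobile_sel), 1.0 / len(mobile_sel))
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    mc = (w[:, None] * mobile_sel).sum(axis=0)
    rc = (w[:, None] * ref_sel).sum(axis=0)
    h = (w[:, None] * (mobile_sel - mc)).T @ (ref_sel - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    return rot, mc, rc


def superpose_pair(mobile, reference, selection=None, weights=None):
    """Superpose `mobile` onto `reference`; returns (transformed, rmsd).

    The transform is fitted on `selection` and applied to all particles;
    the rmsd is over the selection after transformation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeError("mobile and reference must both be (N, 3)")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(reference))):
        raise ValidationError("superposition input contains non-finite values")
    sel = _as_selection(selection, mobile.shape[0])
    _check_degenerate(reference[sel])
    _check_degenerate(mobile[sel])
    rot, mc, rc = _optimal_rotation(mobile[sel], reference[sel], weights)
    transformed = (mobile - mc) @ rot.T + rc
    diff = transformed[sel] - reference[sel]
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return transformed, rmsd


def _superpose_many(conformations: np.ndarray, reference: np.ndarray, sel: np.ndarray):
    """Vectorized superposition of (K, N, 3) onto one reference."""
    mob_sel = conformations[:, sel, :]
    mc = mob_sel.mean(axis=1, keepdims=True)
    rc = reference[sel].mean(axis=0)
    h = np.einsum("kni,nj->kij", mob_sel - mc, reference[sel] - rc) / sel.size
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("kij,kjl->kil", np.transpose(vt, (0, 2, 1)), np.transpose(u, (0, 2, 1)))))
    flip = np.zeros_like(h)
    flip[:, 0, 0] = 1.0
    flip[:, 1, 1] = 1.0
    flip[:, 2, 2] = d
    rot = np.einsum("kij,kjl,klm->kim", np.transpose(vt, (0, 2, 1)), flip, np.transpose(u, (0, 2, 1)))
    out = np.einsum("knj,kij->kni", conformations - mc, rot) + rc
    diff = out[:, sel, :] - reference[sel]
    rmsd = np.sqrt((diff**2).sum(axis=2).mean(axis=1))
    return out, rmsd


def batch_rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> np.ndarray:
    """RMSD between paired structure stacks (B, N, 3) vs (B, N, 3).

    With ``superpose`` each pair is optimally superposed first.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ShapeError("paired stacks must have identical shapes")
    if superpose:
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        h = np.einsum("kni,knj->kij", ac, bc)
        u, s, vt = np.linalg.svd(h)
        d = np.linalg.det(np.einsum("kij,kjl->kil", np.transpose(vt, (0, 2, 1)), np.transpose(u, (0, 2, 1))))
        s_corr = s.copy()
        s_corr[:, 2] *= np.sign(d)
        # rmsd^2 = (|A|^2 + |B|^2 - 2 tr(S')) / N, the standard closed form
        n = a.shape[1]
        sq = (ac**2).sum(axis=(1, 2)) + (bc**2).sum(axis=(1, 2)) - 2.0 * s_corr.sum(axis=1)
        return np.sqrt(np.maximum(sq, 0.0) / n)
    diff = a - b
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def align_ensemble(ensemble, reference, selection=None) -> AlignedEnsemble:
    """Superpose every conformation independently onto a fixed reference."""
    conf, n_copies, dt = _ensemble_arrays(ensemble)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != conf.shape[1:]:
        raise ShapeError("reference particle count does not match ensemble")
    sel = _as_selection(selection, conf.shape[1])
    _check_degenerate(reference[sel])
    aligned, rmsd = _superpose_many(conf, reference, sel)
    return AlignedEnsemble(aligned, reference.copy(), sel, rmsd, n_copies, dt)


def build_reference(ensemble, selection=None, seed_index: int = 0, iterate: bool = False,
                    tol: float = 1e-8, max_iter: int = 50) -> AlignedEnsemble:
    """Two-pass average reference: align to an arbitrary seed conformation,
    average, realign everything to that average, and average again.  The
    second average is the reference; it is insensitive to the seed choice.

    ``iterate`` continues the align/average cycle to convergence instead
    of stopping after two passes (off by default).
    """
    conf, n_copies, dt = _ensemble_arrays(ensemble)
    if conf.shape[0] < 2:
        raise InsufficientDataError("reference construction needs at least 2 conformations")
    sel = _as_selection(selection, conf.shape[1])
    seed = conf[seed_index]
    _check_degenerate(seed[sel])
    aligned, _ = _superpose_many(conf, seed, sel)
    avg1 = aligned.mean(axis=0)
    aligned, _ = _superpose_many(conf, avg1, sel)
    avg2 = aligned.mean(axis=0)
    if iterate:
        prev = avg1
        for _ in range(max_iter):
            if np.max(np.abs(avg2 - prev)) < tol:
                break
            prev = avg2
            aligned, _ = _superpose_many(conf, avg2, sel)
            avg2 = aligned.mean(axis=0)
    aligned, rmsd = _superpose_many(conf, avg2, sel)
    return AlignedEnsemble(aligned, avg2, sel, rmsd, n_copies, dt)


def _ensemble_arrays(ensemble):
    if isinstance(ensemble, MoleculeEnsemble):
        return ensemble.conformations, ensemble.n_copies, ensemble.frame_interval
    if isinstance(ensemble, AlignedEnsemble):
        return ensemble.conformations, ensemble.n_copies, ensemble.frame_interval
    arr = np.asarray(ensemble, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError("ensemble must be (K, N_p, 3)")
    return arr, 1, None
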