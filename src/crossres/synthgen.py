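"""Synthetic multi-copy pseudo-lipid trajectories with known ground truth.

Each molecule copy fluctuates around a fixed two-chain base structure
along a small set of planted orthonormal collective modes.  Mode
amplitudes follow independent stationary Ornstein-Uhlenbeck processes
(exact discretization, so the analytic autocorrelation exp(-tau/tau_OU)
holds at every lag), plus an isotropic noise floor in all directions.
Copies are statistically independent; an optional per-frame rigid motion
exercises the superposition stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .trajio import ParticleTable, Trajectory

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_pseudo_lipid",
    "random_orthonormal_modes",
    "sample_ou_modes",
    "generate_system",
    "write_ground_truth",
    "read_ground_truth",
]


def make_pseudo_lipid(n_head: int = 3, n_tail: int = 4, tails: int = 2):
    """Deterministic two-chain zig-zag geometry with addressable names.

    Head particles N1..Nn stack on the z axis; each tail hangs below,
    zig-zagging in x (chain A mirrored into chain B).  Names avoid the
    leading-H hydrogen convention so every particle reads as heavy.
    Returns (base_structure (N_p, 3) Ang, ParticleTable).
    """
    if n_head < 1 or n_tail < 2:
        raise ValueError("need n_head >= 1 and n_tail >= 2")
    coords, names = [], []
    for i in range(n_head):
        coords.append((0.0, 0.0, 2.0 + 1.5 * (n_head - 1 - i)))
        names.append(f"N{i + 1}")
    chain_ids = "ABCDEFGH"[:tails]
    for c, cid in enumerate(chain_ids):
        sign = 1.0 if c % 2 == 0 else -1.0
        x0 = sign * 2.0
        for i in range(n_tail):
            zig = sign * (0.5 if i % 2 else -0.5)
            coords.append((x0 + zig, 1.5 * c, -1.3 * (i + 1)))
            names.append(f"C{i + 1}{cid}")
    base = np.asarray(coords, float)
    table = ParticleTable.from_names(
        names, ["PSL"] * len(names), [0] * len(names), elements=["C"] * len(names)
    )
    return base, table


def _rigid_body_subspace(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (columns) of rigid translations + infinitesimal
    rotations about the base structure's centroid."""
    n = base.shape[0]
    centered = base - base.mean(axis=0)
    cols = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        cols.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        cols.append(np.cross(np.broadcast_to(e, (n, 3)), centered).ravel())
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def random_orthonormal_modes(base: np.ndarray, k: int, seed,
                             exclude_rigid: bool = True) -> np.ndarray:
    """k mutually orthonormal 3N mode vectors (columns), optionally
    orthogonal to the rigid-body subspace so alignment leaves them intact."""
    rng = np.random.default_rng(seed)
    dim = base.size
    raw = rng.standard_normal((dim, k))
    if exclude_rigid:
        rigid = _rigid_body_subspace(base)
        raw -= rigid @ (rigid.T @ raw)
    q, _ = np.linalg.qr(raw)
    return q[:, :k]


@dataclass
class SyntheticSpec:
    """Full description of a synthetic multi-copy system."""

    base_structure: np.ndarray
    particles: ParticleTable
    planted_modes: np.ndarray  # (3 N_p, k) orthonormal columns
    planted_eigenvalues: np.ndarray  # Ang^2, descending
    mode_relaxation_times: np.ndarray  # frames
    noise_floor: float = 0.0  # Ang^2 isotropic, non-planted directions
    n_copies: int = 1
    n_frames: int = 100
    rigid_motion: bool = False
    seed: int = 0
    mixture_mode1: tuple[float, float] | None = None  # (offset Ang, weight) bimodal PC1

    def __post_init__(self):
        self.base_structure = np.asarray(self.base_structure, float)
        self.planted_modes = np.asarray(self.planted_modes, float)
        lam = np.asarray(self.planted_eigenvalues, float)
        tau = np.asarray(self.mode_relaxation_times, float)
        k = self.planted_modes.shape[1]
        if lam.size != k or tau.size != k:
            raise ValidationError("eigenvalues/relaxation times must match mode count")
        gram = self.planted_modes.T @ self.planted_modes
        if not np.allclose(gram, np.eye(k), atol=1e-10):
            raise ValidationError("planted modes must be orthonormal within 1e-10")
        if np.any(np.diff(lam) > 0):
            raise ValidationError("planted eigenvalues must be descending")
        if lam.size and lam[-1] <= self.noise_floor:
            raise ValidationError("planted eigenvalues must exceed the noise floor")
        if np.any(tau <= 0):
            raise ValidationError("relaxation times must be positive")
        self.planted_eigenvalues = lam
        self.mode_relaxation_times = tau


@dataclass
class GroundTruth:
    modes: np.ndarray
    eigenvalues: np.ndarray
    relaxation_times: np.ndarray
    noise_floor: float
    seed: int
    mode_amplitudes: np.ndarray | None = field(default=None, repr=False)  # (N_L, k, T)


def _ou_series(rng, lam: float, tau: float, t: int) -> np.ndarray:
    """Stationary OU series: variance lam, autocorrelation exp(-lag/tau)."""
    rho = np.exp(-1.0 / tau)
    x = np.empty(t)
    x[0] = rng.standard_normal() * np.sqrt(lam)
    innov = rng.standard_normal(t - 1) * np.sqrt(lam * (1.0 - rho**2))
    for i in range(1, t):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def sample_ou_modes(spec: SyntheticSpec, copy_index: int = 0) -> np.ndarray:
    """Amplitude series (k, T) for one molecule copy, deterministic in the
    spec seed: the global seed fans out to per-copy, per-mode substreams."""
    k = spec.planted_modes.shape[1]
    out = np.empty((k, spec.n_frames))
    for m in range(k):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 7919 + copy_index, m])
        )
        out[m] = _ou_series(rng, spec.planted_eigenvalues[m], spec.mode_relaxation_times[m], spec.n_frames)
        if spec.mixture_mode1 is not None and m == 0:
            offset, weight = spec.mixture_mode1
            pick = rng.random(spec.n_frames) < weight
            out[m] = out[m] + np.where(pick, offset, 0.0)
    return out


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_system(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Build the multi-copy trajectory and its ground-truth record.

    Each copy at each frame is base + sum_k a_k(t) mode_k + noise; copies
    are laid out as consecutive particle blocks with residue ids 0..N_L-1.
    """
    n_p = spec.base_structure.shape[0]
    k = spec.planted_modes.shape[1]
    t, n_l = spec.n_frames, spec.n_copies
    coords = np.empty((t, n_l * n_p, 3))
    amps = np.empty((n_l, k, t))
    modes3 = spec.planted_modes.T.reshape(k, n_p, 3)
    for c in range(n_l):
        a = sample_ou_modes(spec, c)
        amps[c] = a
        conf = spec.base_structure[None] + np.einsum("kt,kpi->tpi", a, modes3)
        noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 104729 + c]))
        if spec.noise_floor > 0:
            # noise lives only in the orthogonal complement of the planted
            # modes, so recovered leading eigenvalues are unbiased
            noise = noise_rng.standard_normal((t, n_p * 3)) * np.sqrt(spec.noise_floor)
            noise -= (noise @ spec.planted_modes) @ spec.planted_modes.T
            conf = conf + noise.reshape(t, n_p, 3)
        if spec.rigid_motion:
            rig = np.random.default_rng(np.random.SeedSequence([spec.seed, 1299709 + c]))
            for fi in range(t):
                rot = _random_rotation(rig)
                shift = rig.uniform(-20.0, 20.0, 3)
                conf[fi] = conf[fi] @ rot.T + shift
        coords[:, c * n_p : (c + 1) * n_p, :] = conf
    names = list(spec.particles.names) * n_l
    resnames = list(spec.particles.residue_names) * n_l
    resids = np.repeat(np.arange(n_l), n_p)
    table = ParticleTable.from_names(names, resnames, resids,
                                     elements=list(spec.particles.elements) * n_l)
    traj = Trajectory(coords, table, frame_interval=1.0)
    truth = GroundTruth(
        spec.planted_modes.copy(),
        spec.planted_eigenvalues.copy(),
        spec.mode_relaxation_times.copy(),
        spec.noise_floor,
        spec.seed,
        amps,
    )
    return traj, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Plain-text sidecar: eigenvalues, relaxation times, modes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# seed {truth.seed} noise_floor {truth.noise_floor}\n")
        fh.write("eigenvalues " + " ".join(f"{v:.12g}" for v in truth.eigenvalues) + "\n")
        fh.write("relaxation_times " + " ".join(f"{v:.12g}" for v in truth.relaxation_times) + "\n")
        fh.write(f"modes {truth.modes.shape[0]} {truth.modes.shape[1]}\n")
        np.savetxt(fh, truth.modes, fmt="%.12g")


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        header = fh.readline().split()
        seed, noise = int(header[2]), float(header[4])
        eig = np.array([float(v) for v in fh.readline().split()[1:]])
        tau = np.array([float(v) for v in fh.readline().split()[1:]])
        rows, cols = (int(v) for v in fh.readline().split()[1:])
        modes = np.loadtxt(fh).reshape(rows, cols)
    return GroundTruth(modes, eig, tau, noise, seed)
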