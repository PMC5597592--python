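"""Ensemble and dynamics comparison statistics.

Covers projection densities and the effective potentials derived from
them, radial distribution functions (intra- and inter-molecular),
RMSD-versus-lag curves with power-law fits of the normalized curve,
projection autocorrelation with e^-2 characteristic times, and the
eigenvalue-weighted geometric-mean speedup ratio between two simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    FitError,
    InsufficientDataError,
    ShapeError,
    UnresolvedTimescaleError,
    ValidationError,
)
from .pca import ProjectionSeries
from .superpose import batch_rmsd
from .trajio import Trajectory

__all__ = [
    "BOLTZMANN_KJ_MOL_K",
    "DensityProfile",
    "LagCurve",
    "AutocorrResult",
    "SpeedupReport",
    "RDFResult",
    "projection_density",
    "effective_potential",
    "rmsd_lag",
    "fit_nrmsd",
    "autocorrelation",
    "characteristic_time",
    "speedup_ratio",
    "radial_distribution",
]

BOLTZMANN_KJ_MOL_K = 0.008314462618  # kJ / (mol K)

DEFAULT_DENSITY_BIN = 0.1  # Ang, projection histograms
DEFAULT_RDF_BIN = 0.2  # Ang


@dataclass
class DensityProfile:
    """Unit-integral 1-D probability density with optional effective energy."""

    bin_centers: np.ndarray
    probability_density: np.ndarray
    bin_width: float
    effective_energy: np.ndarray | None = None  # k_B T units, NaN where empty
    temperature: float | None = None

    def __post_init__(self):
        p = np.asarray(self.probability_density, float)
        if np.any(p < 0):
            raise ValidationError("probability density must be non-negative")
        integral = p.sum() * self.bin_width
        if abs(integral - 1.0) > 1e-6:
            raise ValidationError(f"density integrates to {integral}, expected 1")
        self.probability_density = p

    def energy_kj_mol(self) -> np.ndarray:
        if self.effective_energy is None or self.temperature is None:
            raise ValidationError("effective energy not computed")
        return self.effective_energy * BOLTZMANN_KJ_MOL_K * self.temperature


@dataclass
class LagCurve:
    """RMSD as a function of frame lag, with its normalized form and fit."""

    lags: np.ndarray
    rmsd: np.ndarray
    rmsd_eq: float | None = None
    nrmsd: np.ndarray | None = None
    fit_c1: float | None = None
    fit_c2: float | None = None


@dataclass
class AutocorrResult:
    """Normalized autocorrelation of one projection mode."""

    lags: np.ndarray
    R: np.ndarray
    characteristic_time: float | None = None
    crossing_method: str | None = None  # interpolated | extrapolated


@dataclass
class SpeedupReport:
    """Eigenvalue-weighted geometric mean of per-mode timescale ratios."""

    per_mode_ratios: np.ndarray
    weights: np.ndarray
    ratio: float
    excluded_modes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must be non-negative and sum to 1")
        if self.ratio <= 0:
            raise ValidationError("speedup ratio must be positive")
        self.weights = w


@dataclass
class RDFResult:
    """Radial distribution (intermolecular g(r) -> 1, or unit-integral
    same-molecule distance density)."""

    bin_centers: np.ndarray
    g: np.ndarray
    mode: str
    pair_description: tuple[str, str] = ("", "")


def _pooled_samples(series, mode):
    if isinstance(series, ProjectionSeries):
        return series.pooled(mode if mode is not None else series.mode_ids[0])
    return np.asarray(series, float).ravel()


def projection_density(series, mode: int | None = None,
                       bin_width: float = DEFAULT_DENSITY_BIN) -> DensityProfile:
    """Histogram of pooled projection values, normalized to unit integral."""
    x = _pooled_samples(series, mode)
    if x.size < 100:
        raise InsufficientDataError(f"need at least 100 samples, got {x.size}")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, bin_width)


def effective_potential(density: DensityProfile, temperature: float) -> DensityProfile:
    """Fill the Boltzmann-inverted energy, in k_B T units, masking empty bins."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    p = density.probability_density
    energy = np.full_like(p, np.nan)
    occupied = p > 0
    energy[occupied] = -np.log(p[occupied])
    return DensityProfile(
        density.bin_centers, p, density.bin_width, effective_energy=energy, temperature=temperature
    )


def rmsd_lag(aligned_copies, lags, selection=None, superpose: bool = True,
             frame_interval: float = 1.0, t_stride: int = 1) -> LagCurve:
    """Mean over molecule copies of the time-averaged RMSD between frames
    separated by each lag.  ``aligned_copies`` is (N_L, T, N_p, 3); with
    ``superpose`` each frame pair is optimally superposed first.  ``t_stride``
    subsamples the time origins to bound cost on long trajectories."""
    arr = np.asarray(aligned_copies, float)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ShapeError("aligned copies must be (N_L, T, N_p, 3)")
    if selection is not None:
        arr = arr[:, :, np.asarray(selection, int), :]
    n_l, t = arr.shape[0], arr.shape[1]
    lags = np.asarray(sorted(int(l) for l in lags), int)
    if np.any(lags >= t):
        raise ValueError(f"lag {lags.max()} >= trajectory length {t}")
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    out = np.empty(lags.size)
    for li, lag in enumerate(lags):
        if lag == 0:
            out[li] = 0.0
            continue
        per_copy = np.empty(n_l)
        for c in range(n_l):
            a = arr[c, : t - lag : t_stride]
            b = arr[c, lag::1][:: t_stride][: a.shape[0]]
            per_copy[c] = batch_rmsd(a, b, superpose=superpose).mean()
        out[li] = per_copy.mean()
    return LagCurve(lags * float(frame_interval), out)


def fit_nrmsd(curve: LagCurve, rmsd_eq: float, threshold: float = 0.7) -> tuple[float, float]:
    """Power-law fit c1 * tau^c2 of the normalized curve, restricted to the
    region nrmsd < threshold, by ordinary least squares in log-log space.
    Returns (c1, c2) and stores them (plus nrmsd) on the curve."""
    if rmsd_eq <= 0:
        raise ValueError("rmsd_eq must be positive")
    nrmsd = curve.rmsd / rmsd_eq
    eligible = (nrmsd < threshold) & (nrmsd > 0) & (curve.lags > 0)
    if eligible.sum() < 3:
        raise FitError(f"only {int(eligible.sum())} points with nrmsd < {threshold}; need 3")
    slope, intercept = np.polyfit(np.log(curve.lags[eligible]), np.log(nrmsd[eligible]), 1)
    curve.rmsd_eq = float(rmsd_eq)
    curve.nrmsd = nrmsd
    curve.fit_c1 = float(np.exp(intercept))
    curve.fit_c2 = float(slope)
    return curve.fit_c1, curve.fit_c2


def _autocov_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocovariance of a mean-removed series via FFT."""
    t = x.size
    nfft = 1 << (2 * t - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov / t


def autocorrelation(series, mode: int | None = None, max_lag: int | None = None,
                    frame_interval: float | None = None) -> AutocorrResult:
    """Mean-removed normalized autocovariance per molecule copy, averaged
    over copies; R(0) = 1 by construction."""
    if isinstance(series, ProjectionSeries):
        i = series.mode_ids.index(mode if mode is not None else series.mode_ids[0])
        data = series.values[i]  # (N_L, T)
        frame_interval = frame_interval or series.frame_interval
    else:
        data = np.atleast_2d(np.asarray(series, float))
    n_l, t = data.shape
    if t < 10:
        raise InsufficientDataError(f"need at least 10 frames, got {t}")
    if max_lag is None:
        max_lag = t // 2
    max_lag = min(max_lag, t - 1)
    acc = np.zeros(max_lag + 1)
    for c in range(n_l):
        x = data[c] - data[c].mean()
        var = np.dot(x, x) / t
        if var == 0:
            raise ValidationError(f"copy {c} has zero-variance projection series")
        acc += _autocov_fft(x, max_lag) / var
    r = acc / n_l
    r[0] = 1.0
    lags = np.arange(max_lag + 1) * float(frame_interval or 1.0)
    return AutocorrResult(lags, r)


E_MINUS_2 = float(np.exp(-2.0))


def characteristic_time(ac: AutocorrResult) -> AutocorrResult:
    """Locate the first e^-2 crossing of R (starting value taken as 1.0).

    The crossing is linearly interpolated between the bracketing lags;
    when R never crosses within the computed lags, the line through the
    last two points is extrapolated.  A non-decaying R raises."""
    lags, r = np.asarray(ac.lags, float), np.asarray(ac.R, float)
    if lags.size < 2:
        raise InsufficientDataError("need R on at least 2 lags")
    below = np.nonzero(r < E_MINUS_2)[0]
    if below.size:
        j = int(below[0])
        i = j - 1
        # R(0) is treated as exactly 1.0 for the crossing search
        r0 = 1.0 if i == 0 else r[i]
        tau = lags[i] + (lags[j] - lags[i]) * (r0 - E_MINUS_2) / (r0 - r[j])
        method = "interpolated"
    else:
        slope = (r[-1] - r[-2]) / (lags[-1] - lags[-2])
        if slope >= 0:
            raise UnresolvedTimescaleError(
                "autocorrelation does not decay; characteristic time unresolved"
            )
        tau = lags[-1] + (E_MINUS_2 - r[-1]) / slope
        method = "extrapolated"
    if tau <= 0:
        raise UnresolvedTimescaleError(f"non-positive crossing time {tau}")
    ac.characteristic_time = float(tau)
    ac.crossing_method = method
    return ac


def speedup_ratio(times_i, times_j, eigenvalues, policy: str = "strict") -> SpeedupReport:
    """Eigenvalue-weighted geometric mean of per-mode characteristic-time
    ratios between simulations i and j.

    Unresolved times (NaN) either raise (policy='strict') or drop the mode
    with renormalized weights (policy='exclude')."""
    ti = np.asarray(times_i, float)
    tj = np.asarray(times_j, float)
    ev = np.asarray(eigenvalues, float)
    if not (ti.size == tj.size == ev.size):
        raise ShapeError("times and eigenvalues must have equal mode counts")
    if np.any(ev < 0):
        raise ValidationError("eigenvalues must be non-negative")
    bad = ~(np.isfinite(ti) & np.isfinite(tj))
    excluded: tuple[int, ...] = ()
    if bad.any():
        if policy == "strict":
            raise ValidationError(f"unresolved characteristic times at modes {np.nonzero(bad)[0].tolist()}")
        excluded = tuple(int(i) for i in np.nonzero(bad)[0])
        warnings.warn(f"excluding modes {excluded} with unresolved times; weights renormalized")
        keep = ~bad
        ti, tj, ev = ti[keep], tj[keep], ev[keep]
    if np.any(ti <= 0) or np.any(tj <= 0):
        raise ValidationError("characteristic times must be positive")
    if ev.sum() <= 0:
        raise ValidationError("eigenvalue weights sum to zero")
    weights = ev / ev.sum()
    ratios = ti / tj
    ratio = float(np.exp(np.dot(weights, np.log(ratios))))
    return SpeedupReport(ratios, weights, ratio, excluded)


def _same_molecule_pairs(rids, sel_a, sel_b):
    pairs = []
    identical = np.array_equal(sel_a, sel_b)
    for i in sel_a:
        for j in sel_b:
            if i == j or rids[i] != rids[j]:
                continue
            if identical and i > j:
                continue
            pairs.append((i, j))
    return np.array(pairs, int).reshape(-1, 2)


def radial_distribution(traj: Trajectory, sel_a, sel_b, mode: str,
                        bin_width: float = DEFAULT_RDF_BIN,
                        r_max: float | None = None) -> RDFResult:
    """Radial distribution between two particle selections.

    intermolecular: minimum-image pair histogram normalized by ideal-gas
    shell counts at the mean pair density, so g(r) -> 1 for homogeneous
    systems; requires box information.
    intramolecular: distance distribution over same-molecule pairs,
    normalized to unit integral.
    """
    if mode not in ("intermolecular", "intramolecular"):
        raise ValueError(f"unknown RDF mode '{mode}'")
    sel_a = np.asarray(sel_a, int)
    sel_b = np.asarray(sel_b, int)
    identical = np.array_equal(sel_a, sel_b)
    if not identical and np.intersect1d(sel_a, sel_b).size:
        raise ValidationError("selections must be disjoint or identical")
    rids = traj.particles.residue_ids
    coords = traj.coordinates

    if mode == "intramolecular":
        pairs = _same_molecule_pairs(rids, sel_a, sel_b)
        if pairs.size == 0:
            raise ValidationError("no same-molecule pairs between the selections")
        d = np.linalg.norm(coords[:, pairs[:, 0]] - coords[:, pairs[:, 1]], axis=2).ravel()
        # auto range extends one bin past the largest distance so a value
        # sitting exactly on a bin edge is never dropped
        rmax = r_max if r_max is not None else float((np.floor(d.max() / bin_width) + 1) * bin_width)
        edges = np.arange(0.0, rmax + 0.5 * bin_width, bin_width)
        counts, edges = np.histogram(d[d < edges[-1]], bins=edges)
        if counts.sum() == 0:
            raise ValidationError("no pair distances inside the histogram range")
        dens = counts / (counts.sum() * bin_width)
        return RDFResult(0.5 * (edges[:-1] + edges[1:]), dens, mode)

    if traj.box is None:
        raise ValidationError("intermolecular RDF requires box information")
    if r_max is None:
        raise ValueError("intermolecular RDF requires r_max")
    half_min_box = float(traj.box.min()) / 2.0
    if r_max > half_min_box:
        raise ValueError(f"r_max {r_max} exceeds half the smallest box length {half_min_box}")
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    # exact count of distinct cross-molecule pairs, independent of distance
    if identical:
        _, per_res = np.unique(rids[sel_a], return_counts=True)
        n_pairs_used = sel_a.size * (sel_a.size - 1) // 2 - int((per_res * (per_res - 1) // 2).sum())
    else:
        ra, ca = np.unique(rids[sel_a], return_counts=True)
        rb, cb = np.unique(rids[sel_b], return_counts=True)
        shared = {int(r): int(c) for r, c in zip(ra, ca)}
        same_tot = sum(shared.get(int(r), 0) * int(c) for r, c in zip(rb, cb))
        n_pairs_used = sel_a.size * sel_b.size - same_tot
    if n_pairs_used <= 0:
        raise ValidationError("no cross-molecule pairs between the selections")
    for fi in range(traj.n_frames):
        box = traj.box[fi]
        x = coords[fi] % box
        if identical:
            tree = cKDTree(x[sel_a], boxsize=box)
            raw = tree.query_pairs(r_max, output_type="ndarray")
            gi, gj = sel_a[raw[:, 0]], sel_a[raw[:, 1]]
        else:
            ta = cKDTree(x[sel_a], boxsize=box)
            tb = cKDTree(x[sel_b], boxsize=box)
            mat = ta.sparse_distance_matrix(tb, r_max, output_type="coo_matrix")
            gi, gj = sel_a[mat.row], sel_b[mat.col]
        cross = rids[gi] != rids[gj]
        gi, gj = gi[cross], gj[cross]
        delta = coords[fi, gi] - coords[fi, gj]
        delta -= box * np.round(delta / box)
        d = np.linalg.norm(delta, axis=1)
        counts += np.histogram(d, bins=edges)[0]
    volume = float(np.prod(traj.box.mean(axis=0)))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs_used * shell / volume
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, counts / traj.n_frames / ideal, 0.0)
    return RDFResult(0.5 * (edges[:-1] + edges[1:]), g, mode)
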