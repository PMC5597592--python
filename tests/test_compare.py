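import numpy as np
import pytest
from scipy.stats import norm

from crossres import compare, synthgen, trajio
from crossres.errors import (
    FitError,
    InsufficientDataError,
    UnresolvedTimescaleError,
    ValidationError,
)


class TestProjectionDensity:
    def test_constant_samples(self):
        x = np.full(200, 3.14)
        dens = compare.projection_density(x, bin_width=0.1)
        occupied = dens.probability_density > 0
        assert occupied.sum() == 1
        center = dens.bin_centers[occupied][0]
        assert abs(center - 3.14) <= 0.05 + 1e-12

    def test_gaussian_matches_pdf(self):
        # at 1e6 samples the histogram noise floor (~0.002) sits well below
        # the 0.01 tolerance; at 1e5 the expected max deviation exceeds it
        rng = np.random.default_rng(42)
        x = rng.standard_normal(1_000_000)
        dens = compare.projection_density(x, bin_width=0.1)
        expected = norm.pdf(dens.bin_centers)
        assert np.abs(dens.probability_density - expected).max() < 0.01

    def test_symmetric_input(self, rng):
        x = rng.normal(size=500)
        both = np.concatenate([x, -x])
        dens = compare.projection_density(both, bin_width=0.5)
        # fold the density about zero and compare
        p = dens.probability_density
        np.testing.assert_allclose(p, p[::-1], atol=1e-12)

    def test_unit_integral(self, rng):
        dens = compare.projection_density(rng.normal(size=1000), bin_width=0.2)
        assert dens.probability_density.sum() * dens.bin_width == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            compare.projection_density(np.zeros(50))


class TestEffectivePotential:
    def test_uniform_density_flat(self):
        rng = np.random.default_rng(0)
        dens = compare.projection_density(rng.uniform(0, 10, 200_000), bin_width=1.0)
        pot = compare.effective_potential(dens, 300.0)
        inner = pot.effective_energy[1:-1]  # edge bins are partially filled
        assert np.nanmax(inner) - np.nanmin(inner) < 0.05

    def test_ratio_e_gives_one_kbt(self):
        # two bins with densities in ratio e:1 differ by exactly 1 kBT
        width = 1.0
        p = np.array([np.e, 1.0])
        p = p / (p.sum() * width)
        dens = compare.DensityProfile(np.array([0.5, 1.5]), p, width)
        pot = compare.effective_potential(dens, 310.0)
        diff = pot.effective_energy[1] - pot.effective_energy[0]
        assert diff == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_curvature(self):
        rng = np.random.default_rng(7)
        sigma = 2.0
        x = rng.normal(scale=sigma, size=400_000)
        dens = compare.projection_density(x, bin_width=0.2)
        pot = compare.effective_potential(dens, 300.0)
        sel = np.abs(pot.bin_centers) < 2.5
        coef = np.polyfit(pot.bin_centers[sel], pot.effective_energy[sel], 2)
        curvature = 2 * coef[0]  # E = x^2/(2 sigma^2) => E'' = 1/sigma^2
        assert curvature == pytest.approx(1 / sigma**2, rel=0.02)

    def test_empty_bins_masked_not_infinite(self):
        width = 1.0
        p = np.array([0.5, 0.0, 0.5])
        dens = compare.DensityProfile(np.arange(3.0), p, width)
        pot = compare.effective_potential(dens, 300.0)
        assert np.isnan(pot.effective_energy[1])
        assert np.isfinite(pot.effective_energy[[0, 2]]).all()

    def test_bad_temperature(self):
        dens = compare.DensityProfile(np.array([0.0]), np.array([1.0]), 1.0)
        with pytest.raises(ValueError):
            compare.effective_potential(dens, -1.0)

    def test_kj_mol_conversion(self):
        width = 1.0
        p = np.array([np.e, 1.0]) / (np.e + 1.0)
        dens = compare.DensityProfile(np.array([0.5, 1.5]), p, width)
        pot = compare.effective_potential(dens, 300.0)
        kj = pot.energy_kj_mol()
        assert kj[1] - kj[0] == pytest.approx(compare.BOLTZMANN_KJ_MOL_K * 300.0, rel=1e-12)


class TestRmsdLag:
    def test_frozen_trajectory(self, rng):
        frame = rng.normal(size=(5, 3))
        arr = np.broadcast_to(frame, (2, 50, 5, 3)).copy()
        curve = compare.rmsd_lag(arr, [1, 5, 10])
        # closed-form rmsd suffers sqrt cancellation; 1e-6 Ang is zero here
        np.testing.assert_allclose(curve.rmsd, 0.0, atol=1e-6)

    def test_iid_gaussian_flat(self):
        rng = np.random.default_rng(3)
        sigma = 0.7
        arr = rng.normal(scale=sigma, size=(1, 10_000, 40, 3))
        curve = compare.rmsd_lag(arr, [1, 10, 100], superpose=False)
        expected = sigma * np.sqrt(6.0)
        np.testing.assert_allclose(curve.rmsd, expected, rtol=0.02)

    def test_hand_computed_lag1(self):
        # single copy, T=3, 2 particles, superposition disabled
        f0 = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        f1 = np.array([[0.0, 1, 0], [1.0, 1, 0]])
        f2 = np.array([[0.0, 3, 0], [1.0, 3, 0]])
        arr = np.stack([f0, f1, f2])[None]
        curve = compare.rmsd_lag(arr, [1], superpose=False)
        # rmsd(f0,f1) = 1, rmsd(f1,f2) = 2, time average = 1.5
        assert curve.rmsd[0] == pytest.approx(1.5, abs=1e-12)

    def test_lag_too_large(self, rng):
        arr = rng.normal(size=(1, 10, 3, 3))
        with pytest.raises(ValueError):
            compare.rmsd_lag(arr, [10])

    def test_monotone_for_ou_dynamics(self, pseudo_lipid):
        base, table = pseudo_lipid
        modes = synthgen.random_orthonormal_modes(base, 2, seed=3)
        spec = synthgen.SyntheticSpec(
            base, table, modes, np.array([4.0, 1.0]), np.array([40.0, 20.0]),
            noise_floor=0.0, n_copies=4, n_frames=4000, seed=3,
        )
        traj, _ = synthgen.generate_system(spec)
        ens = trajio.extract_molecule_ensemble(traj, "PSL")
        arr = ens.per_copy()
        curve = compare.rmsd_lag(arr, [1, 5, 20, 80, 300], superpose=False)
        assert np.all(np.diff(curve.rmsd) > -0.02 * curve.rmsd.max())


class TestFitNrmsd:
    def test_planted_power_law(self):
        lags = np.arange(1.0, 21.0)
        rmsd_eq = 2.0
        curve = compare.LagCurve(lags, rmsd_eq * 0.5 * lags**0.2)
        c1, c2 = compare.fit_nrmsd(curve, rmsd_eq)
        assert c1 == pytest.approx(0.5, abs=1e-6)
        assert c2 == pytest.approx(0.2, abs=1e-6)

    def test_constant_curve(self):
        lags = np.arange(1.0, 11.0)
        curve = compare.LagCurve(lags, np.full(10, 1.0))
        _, c2 = compare.fit_nrmsd(curve, 2.0)
        assert c2 == pytest.approx(0.0, abs=1e-9)

    def test_out_of_region_points_ignored(self):
        lags = np.arange(1.0, 21.0)
        nr = 0.5 * lags**0.2
        curve = compare.LagCurve(lags, nr)
        base_fit = compare.fit_nrmsd(curve, 1.0)
        extended = compare.LagCurve(
            np.concatenate([lags, [100.0, 200.0]]), np.concatenate([nr, [0.9, 0.95]])
        )
        assert compare.fit_nrmsd(extended, 1.0) == pytest.approx(base_fit, abs=1e-12)

    def test_too_few_points(self):
        curve = compare.LagCurve(np.array([1.0, 2.0]), np.array([0.5, 0.6]))
        with pytest.raises(FitError):
            compare.fit_nrmsd(curve, 1.0)


class TestAutocorrelation:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 500)
        ac = compare.autocorrelation(x[None])
        assert ac.R[0] == 1.0
        # biased (1/T) estimator: exactly -(T-1)/T at lag 1
        assert ac.R[1] == pytest.approx(-1.0, abs=2e-3)

    def test_r0_is_one(self, rng):
        ac = compare.autocorrelation(rng.normal(size=(2, 500)))
        assert ac.R[0] == 1.0

    def test_ou_matches_analytic(self):
        tau = 20.0
        spec_rng = np.random.default_rng(11)
        # direct OU simulation, 4 copies x T = 1e5 (copy averaging keeps
        # the estimator noise safely below the 0.02 band)
        rho = np.exp(-1 / tau)
        t = 100_000
        x = np.empty((4, t))
        x[:, 0] = spec_rng.standard_normal(4)
        innov = spec_rng.standard_normal((4, t - 1)) * np.sqrt(1 - rho**2)
        for i in range(1, t):
            x[:, i] = rho * x[:, i - 1] + innov[:, i - 1]
        ac = compare.autocorrelation(x, max_lag=80)
        lags = np.arange(61)
        np.testing.assert_allclose(ac.R[:61], np.exp(-lags / tau), atol=0.02)

    def test_zero_variance(self):
        with pytest.raises(ValidationError):
            compare.autocorrelation(np.ones((1, 100)))

    def test_short_series(self):
        with pytest.raises(InsufficientDataError):
            compare.autocorrelation(np.arange(5.0)[None])


class TestCharacteristicTime:
    def test_exponential_crossing(self):
        lags = np.linspace(0, 50, 2001)
        ac = compare.AutocorrResult(lags, np.exp(-lags / 5.0))
        out = compare.characteristic_time(ac)
        assert out.characteristic_time == pytest.approx(10.0, abs=0.05)
        assert out.crossing_method == "interpolated"

    def test_extrapolated_crossing(self):
        # line through (0, 1) and (4, 0.5) hits e^-2 at 6.917
        ac = compare.AutocorrResult(np.array([0.0, 4.0]), np.array([1.0, 0.5]))
        out = compare.characteristic_time(ac)
        expected = 4.0 + (np.exp(-2) - 0.5) / ((0.5 - 1.0) / 4.0)
        assert out.characteristic_time == pytest.approx(expected, abs=1e-12)
        assert out.characteristic_time == pytest.approx(6.92, abs=0.01)
        assert out.crossing_method == "extrapolated"

    def test_non_decaying_flagged(self):
        ac = compare.AutocorrResult(np.arange(5.0), np.ones(5))
        with pytest.raises(UnresolvedTimescaleError):
            compare.characteristic_time(ac)

    def test_planted_ou_two_tau(self, pseudo_lipid):
        base, table = pseudo_lipid
        modes = synthgen.random_orthonormal_modes(base, 1, seed=5)
        spec = synthgen.SyntheticSpec(
            base, table, modes, np.array([1.0]), np.array([25.0]),
            noise_floor=0.0, n_copies=1, n_frames=100_000, seed=5,
        )
        amps = synthgen.sample_ou_modes(spec)
        ac = compare.characteristic_time(compare.autocorrelation(amps[0][None], max_lag=400))
        assert ac.characteristic_time == pytest.approx(2 * 25.0, rel=0.1)


class TestSpeedupRatio:
    def test_uniform_ratio(self):
        rep = compare.speedup_ratio([5.0, 10.0, 50.0], [1.0, 2.0, 10.0], [3.0, 2.0, 1.0])
        assert rep.ratio == pytest.approx(5.0, rel=1e-12)

    def test_single_mode(self):
        rep = compare.speedup_ratio([7.0], [2.0], [1.0])
        assert rep.ratio == pytest.approx(3.5)

    def test_closed_form(self):
        rep = compare.speedup_ratio([2.0, 8.0], [1.0, 1.0], [3.0, 1.0])
        expected = np.exp(0.75 * np.log(2) + 0.25 * np.log(8))
        assert rep.ratio == pytest.approx(expected, abs=1e-12)
        assert rep.ratio == pytest.approx(2.8284, abs=1e-4)

    def test_antisymmetry(self, rng):
        ti = rng.uniform(1, 10, 4)
        tj = rng.uniform(1, 10, 4)
        ev = rng.uniform(0.5, 5, 4)
        fwd = compare.speedup_ratio(ti, tj, ev).ratio
        back = compare.speedup_ratio(tj, ti, ev).ratio
        assert fwd * back == pytest.approx(1.0, rel=1e-12)

    def test_weights_sum_to_one(self):
        rep = compare.speedup_ratio([1.0, 2.0], [2.0, 1.0], [3.0, 1.0])
        assert rep.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_strict_policy_raises_on_nan(self):
        with pytest.raises(ValidationError):
            compare.speedup_ratio([1.0, np.nan], [1.0, 1.0], [1.0, 1.0], policy="strict")

    def test_exclude_policy_renormalizes(self):
        with pytest.warns(UserWarning):
            rep = compare.speedup_ratio([4.0, np.nan], [2.0, 1.0], [1.0, 1.0], policy="exclude")
        assert rep.ratio == pytest.approx(2.0)
        assert rep.excluded_modes == (1,)


def _point_gas_trajectory(rng, n_points, box):
    coords = rng.uniform(0, box, size=(1, n_points, 3))
    table = trajio.ParticleTable.from_names(
        ["C"] * n_points, ["GAS"] * n_points, np.arange(n_points),
        elements=["C"] * n_points,
    )
    return trajio.Trajectory(coords, table, box=np.array([[box] * 3]))


class TestRadialDistribution:
    def test_fixed_pair_delta_peak(self):
        coords = np.array([[[0.0, 0, 0], [7.0, 0, 0]]])
        table = trajio.ParticleTable.from_names(["C1", "C2"], ["M", "M"], [0, 0])
        traj = trajio.Trajectory(coords, table)
        out = compare.radial_distribution(traj, [0], [1], "intramolecular", bin_width=0.2)
        peak = out.bin_centers[np.argmax(out.g)]
        assert abs(peak - 7.0) <= 0.1 + 1e-9  # within half a bin of the true distance
        assert out.g.sum() * 0.2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_below_min_distance(self, rng):
        coords = rng.uniform(20, 30, size=(2, 4, 3))
        table = trajio.ParticleTable.from_names(["C"] * 4, ["M"] * 4, [0] * 4)
        traj = trajio.Trajectory(coords, table)
        out = compare.radial_distribution(traj, [0, 1], [2, 3], "intramolecular", bin_width=0.1)
        dmin = min(
            np.linalg.norm(coords[f, i] - coords[f, j])
            for f in range(2) for i in (0, 1) for j in (2, 3)
        )
        assert np.all(out.g[out.bin_centers < dmin - 0.1] == 0)

    def test_ideal_gas_flat(self):
        rng = np.random.default_rng(99)
        traj = _point_gas_trajectory(rng, 30_000, box=150.0)
        out = compare.radial_distribution(
            traj, np.arange(30_000), np.arange(30_000), "intermolecular",
            bin_width=0.5, r_max=10.0,
        )
        window = (out.bin_centers >= 5.0) & (out.bin_centers <= 10.0)
        np.testing.assert_allclose(out.g[window], 1.0, atol=0.05)

    def test_rmax_exceeds_half_box(self, rng):
        traj = _point_gas_trajectory(rng, 100, box=20.0)
        with pytest.raises(ValueError):
            compare.radial_distribution(
                traj, np.arange(100), np.arange(100), "intermolecular", r_max=15.0
            )

    def test_intermolecular_requires_box(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 5.0
        table = trajio.ParticleTable.from_names(["C1", "C2"], ["M", "M"], [0, 1])
        traj = trajio.Trajectory(coords, table)
        with pytest.raises(ValidationError):
            compare.radial_distribution(traj, [0], [1], "intermolecular", r_max=5.0)

    def test_same_molecule_pairs_excluded_intermolecular(self, rng):
        # two diatomic molecules; intra-pair distance 1.0 must not appear
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0], [10.0, 10, 10], [11.0, 10, 10]]])
        table = trajio.ParticleTable.from_names(["A", "B"] * 2, ["M"] * 4, [0, 0, 1, 1])
        traj = trajio.Trajectory(coords, table, box=np.array([[40.0, 40.0, 40.0]]))
        out = compare.radial_distribution(
            traj, np.arange(4), np.arange(4), "intermolecular", bin_width=0.5, r_max=19.0
        )
        assert out.g[out.bin_centers < 2.0].sum() == 0


class TestDistributionOrderingProperty:
    def test_lower_variance_higher_peak(self):
        rng = np.random.default_rng(21)
        narrow = rng.normal(scale=1.0, size=50_000)
        wide = rng.normal(scale=2.0, size=50_000)
        d_narrow = compare.projection_density(narrow, bin_width=0.1)
        d_wide = compare.projection_density(wide, bin_width=0.1)
        assert d_narrow.probability_density.max() > d_wide.probability_density.max()
        iqr = lambda x: np.subtract(*np.percentile(x, [75, 25]))
        assert iqr(narrow) < iqr(wide)
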