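"""Angular conversion, MSD estimation and fitting, distributions and maps.

The MSD oracle is a literal double loop over (trajectory, start index,
lag) — independent of the vectorised production path — and must agree
exactly.  Fit oracles solve the weighted normal equations directly.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.special import erfc

from dxtrack.geometry import BeamlineGeometry, bragg_angle, AU111
from dxtrack.kinetics import (
    AngularTrajectory,
    MSDCurve,
    density_map_2d,
    difference_map,
    displacement_distribution,
    ensemble_msd,
    fit_msd_cluster,
    fit_msd_linear,
    tail_fraction,
    to_angular,
)
from dxtrack.synthetic import (
    ConditionModel,
    PopulationParams,
    bgt_model,
    cch_model,
    simulate_angular_trajectories,
)

from conftest import drift_trajectory, random_trajectories, spot_trajectory_from_polar


# -------------------------------------------------------------- to_angular

class TestToAngular:
    def test_stationary_spot_gives_zero_angles(self, geometry):
        polar = [(0.334, 0.8)] * 5
        tr = spot_trajectory_from_polar(polar, geometry)
        ang = to_angular(tr, geometry)
        assert np.allclose(ang.theta, 0, atol=1e-9)
        assert np.allclose(ang.chi, 0, atol=1e-9)
        assert np.allclose(ang.t, 0.1 * np.arange(5))

    def test_pure_azimuthal_motion(self, geometry):
        # 1 degree per frame: chi_k = 17.4533*k mrad, theta = 0
        polar = [(0.334, 0.5 + math.radians(k)) for k in range(5)]
        ang = to_angular(spot_trajectory_from_polar(polar, geometry), geometry)
        assert np.allclose(ang.theta, 0, atol=1e-6)
        assert np.allclose(ang.chi, 17.4533 * np.arange(5), atol=1e-2)

    def test_pure_radial_motion(self, geometry):
        p1 = (math.atan(17.40 / 50.0), 0.2)
        p2 = (math.atan(17.58 / 50.0), 0.2)
        ang = to_angular(spot_trajectory_from_polar([p1, p2], geometry), geometry)
        assert ang.chi[1] == pytest.approx(0.0, abs=1e-6)
        assert ang.theta[1] == pytest.approx(1.6038, abs=0.002)

    def test_unlabelled_trajectory_rejected(self, geometry):
        tr = spot_trajectory_from_polar([(0.334, 0.0)] * 3, geometry, ring=None)
        with pytest.raises(ValueError, match="ring label"):
            to_angular(tr, geometry)


# ------------------------------------------------------------ ensemble MSD

def oracle_msd(trajectories, axis, max_lag):
    """Literal pooled-pair double loop."""
    sums = {k: 0.0 for k in range(1, max_lag + 1)}
    counts = {k: 0 for k in range(1, max_lag + 1)}
    tau = trajectories[0].t[1] - trajectories[0].t[0]
    for tr in trajectories:
        x = tr.axis(axis)
        for k in range(1, max_lag + 1):
            for i in range(len(x) - k):
                sums[k] += (x[i + k] - x[i]) ** 2
                counts[k] += 1
    lags, msd, n = [], [], []
    for k in range(1, max_lag + 1):
        if counts[k]:
            lags.append(k * tau)
            msd.append(sums[k] / counts[k])
            n.append(counts[k])
    return np.array(lags), np.array(msd), np.array(n)


class TestEnsembleMSD:
    def test_constant_drift_is_exact(self):
        tr = drift_trajectory(3.0, 0.0, 8)
        curve = ensemble_msd([tr], "theta", max_lag_frames=7)
        ks = np.arange(1, 8)
        assert np.allclose(curve.msd, (3.0 * ks) ** 2, atol=1e-12)
        assert np.array_equal(curve.n_pairs, 8 - ks)

    def test_constant_trajectory_gives_zero(self):
        tr = drift_trajectory(0.0, 0.0, 10)
        curve = ensemble_msd([tr], "chi")
        assert np.allclose(curve.msd, 0.0)

    def test_equals_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(17)
        trajs = random_trajectories(rng, 20)
        for axis in ("theta", "chi"):
            curve = ensemble_msd(trajs, axis, max_lag_frames=7)
            lags, msd, n = oracle_msd(trajs, axis, 7)
            assert np.allclose(curve.lags, lags, atol=1e-12)
            assert np.allclose(curve.msd, msd, rtol=0, atol=1e-10)
            assert np.array_equal(curve.n_pairs, n)

    def test_no_trajectories_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd([], "theta")

    def test_wrap_seam_invariance(self, geometry):
        # same angular path rendered near chi = pi and rotated 90 deg away
        rng = np.random.default_rng(3)
        steps = rng.normal(0, 0.02, 9)  # rad, crosses the seam repeatedly
        tt = bragg_angle(AU111, geometry.peak_energy) * 2
        curves = []
        for base in (math.pi - 0.03, math.pi / 2):
            chi = base + np.concatenate([[0.0], np.cumsum(steps)])
            polar = [(tt, ((c + math.pi) % (2 * math.pi)) - math.pi) for c in chi]
            ang = to_angular(spot_trajectory_from_polar(polar, geometry), geometry)
            curves.append(ensemble_msd([ang], "chi"))
        assert np.allclose(curves[0].msd, curves[1].msd, rtol=1e-9)


# ------------------------------------------------------------------ fitting

class TestFitMSD:
    def test_exact_line_recovered_with_zero_se(self):
        lags = 0.1 * np.arange(1, 8)
        curve = MSDCurve("theta", lags, 2.0 + 3.0 * lags,
                         np.full(7, 100, dtype=int))
        fit = fit_msd_linear(curve)
        assert fit.slope == pytest.approx(3.0, abs=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept_se == pytest.approx(0.0, abs=1e-9)

    def test_dominant_weight_pins_the_line(self):
        lags = 0.1 * np.arange(1, 8)
        rng = np.random.default_rng(2)
        y = 5.0 + 10.0 * lags + rng.normal(0, 1.0, 7)
        w = np.ones(7)
        w[3] = 1e6
        curve = MSDCurve("chi", lags, y, w.astype(int))
        fit = fit_msd_linear(curve)
        # weighted normal equations solved directly as the oracle
        X = np.column_stack([np.ones(7), lags])
        beta = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ (w * y))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-6)
        assert fit.slope == pytest.approx(beta[1], abs=1e-6)
        assert abs(fit.intercept + fit.slope * lags[3] - y[3]) < 1e-3

    def test_too_few_lags_rejected(self):
        curve = MSDCurve("theta", [0.1], [1.0], [10])
        with pytest.raises(ValueError, match="2 lags"):
            fit_msd_linear(curve, lag_range=(0.1, 0.1))

    def test_bgt_chi_slope_recovery_within_3_cluster_se(self):
        """The antagonist-condition twist slope is recovered from a
        176-trajectory synthetic ensemble within 3 clustered SE of the
        generative 2*D_chi = 2.311 mrad^2/ms."""
        trajs = simulate_angular_trajectories(bgt_model(), 0)
        fit = fit_msd_cluster(trajs, "chi")
        assert abs(fit.slope - 2.311) <= 3 * fit.slope_se

    def test_cluster_fit_matches_weighted_point_estimates(self):
        trajs = simulate_angular_trajectories(bgt_model(), 1)
        for axis in ("theta", "chi"):
            wls = fit_msd_linear(ensemble_msd(trajs, axis))
            clu = fit_msd_cluster(trajs, axis)
            assert clu.slope == pytest.approx(wls.slope, rel=1e-9)
            assert clu.intercept == pytest.approx(wls.intercept, rel=1e-9)
            # clustered SEs account for within-trajectory dependence
            assert clu.slope_se > wls.slope_se


class TestEstimatorCorrectness:
    """Parameter recovery for pure Brownian rotation with static noise:
    slope estimates 2D and intercept 2*sigma^2 within 3 clustered SE."""

    @pytest.mark.parametrize("D", [1.0, 10.0])
    @pytest.mark.parametrize("sigma2", [2.5, 7.5])
    @pytest.mark.parametrize("seed", range(5))
    def test_recovery(self, D, sigma2, seed):
        model = ConditionModel(
            label="test",
            populations=(PopulationParams(1.0, D, D, math.sqrt(sigma2),
                                          math.sqrt(sigma2)),),
            n_trajectories=150,
        )
        trajs = simulate_angular_trajectories(model, seed)
        fit = fit_msd_cluster(trajs, "theta")
        assert abs(fit.slope - 2 * D) <= 3 * fit.slope_se
        assert abs(fit.intercept - 2 * sigma2) <= 3 * fit.intercept_se


# ------------------------------------------------------- distributions/maps

class TestDisplacementDistribution:
    def test_drift_concentrates_in_single_bin(self):
        trajs = [drift_trajectory(2.0, 2.0, 9, tid=i) for i in range(5)]
        dist = displacement_distribution(trajs, "theta", dt=0.3)
        assert np.count_nonzero(dist.mass) == 1
        assert dist.mass.max() == pytest.approx(1.0)

    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(8)
        trajs = random_trajectories(rng, 30)
        dist = displacement_distribution(trajs, "chi", dt=0.2)
        assert dist.total_mass() == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_tail_matches_erfc(self):
        # iid N(0, sigma^2) displacements built as length-2 trajectories
        rng = np.random.default_rng(21)
        sigma, n = 4.0, 5000
        d = rng.normal(0, sigma, n)
        trajs = [
            AngularTrajectory(i, [0.0, 0.1], [0.0, d[i]], [0.0, d[i]])
            for i in range(n)
        ]
        x = sigma  # threshold
        frac = tail_fraction(trajs, "theta", dt=0.1, threshold=x)
        p = erfc(x / (sigma * math.sqrt(2)))
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_no_pairs_at_lag_rejected(self):
        trajs = [drift_trajectory(1.0, 1.0, 3)]
        with pytest.raises(ValueError):
            displacement_distribution(trajs, "theta", dt=0.9)

    def test_non_multiple_dt_rejected(self):
        trajs = [drift_trajectory(1.0, 1.0, 8)]
        with pytest.raises(ValueError, match="multiple"):
            displacement_distribution(trajs, "theta", dt=0.25)


class TestTailFraction:
    def test_zero_threshold_is_one(self):
        trajs = [drift_trajectory(1.0, 1.0, 8)]
        assert tail_fraction(trajs, "theta", dt=0.1, threshold=0.0) == 1.0

    def test_threshold_beyond_max_is_zero(self):
        trajs = [drift_trajectory(1.0, 1.0, 8)]
        assert tail_fraction(trajs, "theta", dt=0.1, threshold=1e6) == 0.0

    def test_agonist_vs_antagonist_twist_tails(self):
        """Twist displacements above 10 mrad at 0.7 ms are present with
        agonist but essentially absent with antagonist."""
        cch = simulate_angular_trajectories(cch_model(), 0)
        bgt = simulate_angular_trajectories(bgt_model(), 0)
        f_cch = tail_fraction(cch, "chi", dt=0.7, threshold=10.0)
        f_bgt = tail_fraction(bgt, "chi", dt=0.7, threshold=10.0)
        assert f_cch > f_bgt
        assert f_bgt < 0.005


class TestDensityMaps:
    def test_total_mass_is_one(self):
        rng = np.random.default_rng(9)
        trajs = random_trajectories(rng, 40)
        dmap = density_map_2d(trajs, dt=0.2)
        assert dmap.total_mass() == pytest.approx(1.0, abs=1e-12)

    def test_single_drift_occupies_one_cell(self):
        dmap = density_map_2d([drift_trajectory(2.0, 3.0, 9)], dt=0.3)
        assert np.count_nonzero(dmap.mass) == 1

    def test_difference_with_self_is_zero(self):
        rng = np.random.default_rng(10)
        trajs = random_trajectories(rng, 30)
        dmap = density_map_2d(trajs, dt=0.2)
        diff = difference_map(dmap, dmap)
        assert np.allclose(diff.mass, 0.0)
        assert diff.total_mass() == pytest.approx(0.0, abs=1e-12)

    def test_difference_map_sums_to_zero(self):
        rng = np.random.default_rng(11)
        a = density_map_2d(random_trajectories(rng, 30), dt=0.2)
        b = density_map_2d(random_trajectories(rng, 25), dt=0.2)
        assert difference_map(a, b).total_mass() == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_binning_rejected(self):
        rng = np.random.default_rng(12)
        trajs = random_trajectories(rng, 20)
        a = density_map_2d(trajs, dt=0.2)
        b = density_map_2d(trajs, dt=0.2, theta_edges=np.logspace(-1, 2, 20))
        with pytest.raises(ValueError, match="edges"):
            difference_map(a, b)

    def test_mismatched_lag_rejected(self):
        rng = np.random.default_rng(13)
        trajs = random_trajectories(rng, 20)
        a = density_map_2d(trajs, dt=0.1)
        b = density_map_2d(trajs, dt=0.2)
        with pytest.raises(ValueError, match="lag"):
            difference_map(a, b)

    def test_independent_axes_factorise(self):
        """With independent per-axis generative motion the joint map is the
        outer product of its marginals (chi-square on one independent pair
        per trajectory, alpha = 0.001)."""
        from scipy.stats import chi2_contingency

        model = ConditionModel(
            label="x",
            populations=(PopulationParams(1.0, 5.0, 5.0, 2.0, 2.0),),
            n_trajectories=12000,
        )
        trajs = simulate_angular_trajectories(model, 99)
        # one lag-1 pair per trajectory -> independent samples
        dth = np.array([abs(tr.theta[1] - tr.theta[0]) for tr in trajs])
        dch = np.array([abs(tr.chi[1] - tr.chi[0]) for tr in trajs])
        edges = np.quantile(np.concatenate([dth, dch]), np.linspace(0, 1, 5))
        edges[0], edges[-1] = 0.0, np.inf
        counts = np.histogram2d(dth, dch, bins=(edges, edges))[0]
        _, p, _, _ = chi2_contingency(counts)
        assert p > 0.001

    def test_agonist_minus_antagonist_enriches_gating_band(self):
        """CCh - BGT difference maps put net positive mass at twist
        displacements of 10-50 mrad (seeds 0-4)."""
        for seed in range(5):
            cch = simulate_angular_trajectories(cch_model(), seed)
            bgt = simulate_angular_trajectories(bgt_model(), seed)
            a = density_map_2d(cch, dt=0.7, condition_label="CCh")
            b = density_map_2d(bgt, dt=0.7, condition_label="BGT")
            diff = difference_map(a, b)
            chi_lo = np.searchsorted(diff.chi_edges, 10.0)
            chi_hi = np.searchsorted(diff.chi_edges, 50.0, side="right") - 1
            assert diff.mass[:, chi_lo:chi_hi].sum() > 0
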