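"""Unit tests of the PET kinetics module: schedule handling, IDIF extraction,
plasma conversion, basis construction, and the basis-function fit."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, solve_ivp

from batquant import kinetics as kin
from batquant import synthio


class TestFrameSchedule:
    def test_default_schedule_spans_45_minutes(self, schedule):
        assert schedule.n_frames == 35
        assert schedule.total_s == 2700.0
        assert schedule.starts_s[0] == 0.0
        # frames are contiguous
        np.testing.assert_allclose(schedule.ends_s[:-1], schedule.starts_s[1:])

    @pytest.mark.parametrize(
        "starts,durs",
        [
            ([0, 0], [5, 5]),  # not strictly increasing
            ([0, 4], [5, 5]),  # overlapping
            ([0, 5], [5, 0]),  # zero duration
        ],
    )
    def test_invalid_schedules_rejected(self, starts, durs):
        with pytest.raises(ValueError):
            kin.FrameSchedule(np.array(starts, float), np.array(durs, float))

    def test_csv_roundtrip(self, schedule, tmp_path):
        p = tmp_path / "sched.csv"
        schedule.to_csv(p)
        back = kin.FrameSchedule.from_csv(p)
        np.testing.assert_allclose(back.starts_s, schedule.starts_s)
        np.testing.assert_allclose(back.durations_s, schedule.durations_s)


class TestExtractIdif:
    def test_uniform_field_gives_constant_tac(self, schedule):
        pet = np.full((4, 4, 6, schedule.n_frames), 7.5)
        mask = np.zeros((4, 4, 6), bool)
        mask[1, 1, 3] = True
        tac = kin.extract_idif(pet, mask, schedule)
        np.testing.assert_allclose(tac.activity, 7.5)

    def test_two_voxel_hand_mean(self, schedule):
        pet = np.zeros((2, 1, 1, schedule.n_frames))
        pet[0, 0, 0, 0] = 3.0
        pet[1, 0, 0, 0] = 5.0
        tac = kin.extract_idif(pet, np.ones((2, 1, 1)), schedule)
        assert tac.activity[0] == 4.0

    def test_slice_exclusion_empties_mask(self, schedule):
        pet = np.zeros((2, 2, 5, schedule.n_frames))
        mask = np.zeros((2, 2, 5), bool)
        mask[:, :, 0] = True  # only inferior slices
        with pytest.raises(ValueError, match="5 inferior"):
            kin.extract_idif(pet, mask, schedule, excluded_inferior_slices=5)


class TestBloodToPlasma:
    def test_ratio_scales_values(self, schedule):
        wb = kin.TimeActivityCurve(schedule, np.full(schedule.n_frames, 100.0))
        cp = kin.blood_to_plasma(wb, ratio=1.1)
        mids = schedule.midpoints_min
        np.testing.assert_allclose(
            np.interp(mids, cp.times_min, cp.plasma), 110.0, rtol=1e-9
        )

    def test_unit_ratio_is_identity_at_midpoints(self, schedule, rng):
        vals = rng.uniform(10, 50, schedule.n_frames)
        wb = kin.TimeActivityCurve(schedule, vals)
        cp = kin.blood_to_plasma(wb, ratio=1.0)
        np.testing.assert_allclose(
            np.interp(schedule.midpoints_min, cp.times_min, cp.plasma), vals, rtol=1e-9
        )

    def test_zero_curve_stays_zero(self, schedule):
        wb = kin.TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        cp = kin.blood_to_plasma(wb)
        assert np.all(cp.plasma == 0)

    def test_nonpositive_ratio_rejected(self, schedule):
        wb = kin.TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(ValueError):
            kin.blood_to_plasma(wb, ratio=0.0)


class TestBuildBasis:
    def test_theta_grid_is_log_spaced(self, basis):
        assert basis.thetas.size == 50
        assert basis.thetas[0] == pytest.approx(0.02)
        assert basis.thetas[-1] == pytest.approx(1.0)
        ratios = basis.thetas[1:] / basis.thetas[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_constant_input_matches_closed_form(self, schedule):
        # for Cp = c from t=0: (Cp * exp(-theta t))(t) = (c/theta)(1 - e^{-theta t})
        c = 12.0
        t = schedule.fine_times_min()
        cp = kin.InputFunction(t, np.full_like(t, c))
        basis = kin.build_basis(cp, schedule, n=5, theta_min=0.05, theta_max=0.8)
        starts, ends = schedule.starts_s / 60, schedule.ends_s / 60
        for j, theta in enumerate(basis.thetas):
            # frame average of the closed form
            anti = lambda x: (c / theta) * (x + np.exp(-theta * x) / theta)
            expected = (anti(ends) - anti(starts)) / (ends - starts)
            np.testing.assert_allclose(basis.basis[:, j], expected, rtol=1e-3)

    def test_large_theta_basis_vanishes(self, cp, schedule):
        # delta-kernel limit: conv(Cp, exp(-theta t)) ~ Cp/theta for large theta
        b = kin.build_basis(cp, schedule, n=2, theta_min=2.0, theta_max=20.0)
        assert b.basis[:, 1].max() < b.basis[:, 0].max()
        assert b.basis[:, 1].max() < cp.plasma.max() / 15

    def test_short_input_function_rejected(self, schedule):
        t = np.arange(0, 10) * (0.5 / 60)
        cp = kin.InputFunction(t, np.ones_like(t))
        with pytest.raises(ValueError, match="cover"):
            kin.build_basis(cp, schedule)


def _fixed_theta_ls(tac, basis, j):
    """Oracle: unconstrained least squares at one fixed clearance rate."""
    A = np.column_stack([basis.irr_basis, basis.basis[:, j]])
    w = np.sqrt(basis.schedule.durations_s)
    coef, *_ = np.linalg.lstsq(A * w[:, None], tac * w, rcond=None)
    return coef


class TestFitVoxel:
    def test_zero_tac_gives_zero_fit(self, schedule, basis):
        tac = kin.TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        fit = kin.fit_voxel(tac, basis)
        assert fit.ki == 0.0
        assert fit.rss == 0.0

    def test_pure_trapping_basis_member_recovered_exactly(self, schedule, basis):
        ki_true = 0.037
        tac = kin.TimeActivityCurve(schedule, ki_true * basis.irr_basis)
        fit = kin.fit_voxel(tac, basis)
        assert fit.ki == pytest.approx(ki_true, abs=1e-10)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_recovery_of_reference_truth(self, cp, schedule, basis):
        truth = synthio.KineticTruth(K1=0.1, k2=0.4, k3=0.1)  # Ki=0.02, theta=0.5
        tac = synthio.simulate_tac(truth, cp, schedule)
        fit = kin.fit_voxel(tac, basis)
        assert abs(fit.ki - truth.ki) < 1e-3
        grid_ratio = basis.thetas[1] / basis.thetas[0]
        assert truth.theta / grid_ratio <= fit.theta <= truth.theta * grid_ratio

    def test_noiseless_grid_recovery_within_grid_step_bound(self, cp, schedule, basis):
        """Across the truth grid, Ki error stays within the error induced by
        quantising theta to the nearest basis grid values."""
        for K1 in (0.05, 0.1, 0.2):
            for k2 in (0.2, 0.5, 1.0):
                for k3 in (0.02, 0.05, 0.1):
                    k2c = min(k2, 1.0 - k3)  # cap so theta stays on the grid
                    truth = synthio.KineticTruth(K1, k2c, k3)
                    tac = synthio.simulate_tac(truth, cp, schedule)
                    fit = kin.fit_voxel(tac, basis)
                    lo = np.searchsorted(basis.thetas, truth.theta) - 1
                    bound = max(
                        abs(_fixed_theta_ls(tac.activity, basis, j)[0] - truth.ki)
                        for j in (max(lo, 0), min(lo + 1, 49))
                    )
                    assert abs(fit.ki - truth.ki) <= bound + 1e-6, (K1, k2c, k3)

    def test_rss_not_larger_than_any_grid_theta(self, cp, schedule, basis, rng):
        """Exhaustive optimality: the winning RSS beats every fixed-theta fit."""
        truth = synthio.KineticTruth(0.12, 0.35, 0.08)
        tac = synthio.simulate_tac(truth, cp, schedule).activity
        tac = tac + rng.standard_normal(tac.size) * 0.02 * tac.max()
        fit = kin.fit_voxel(kin.TimeActivityCurve(basis.schedule, tac), basis)
        w = basis.schedule.durations_s
        for j in range(basis.thetas.size):
            coef = np.clip(_fixed_theta_ls(tac, basis, j), 0, None)
            resid = tac - coef[0] * basis.irr_basis - coef[1] * basis.basis[:, j]
            assert fit.rss <= np.sum(w * resid**2) + 1e-9

    def test_rss_not_larger_than_ki_only_fit(self, cp, schedule, basis, rng):
        truth = synthio.KineticTruth(0.1, 0.4, 0.1)
        tac = synthio.simulate_tac(truth, cp, schedule).activity
        tac = tac + rng.standard_normal(tac.size) * 0.05 * tac.max()
        fit = kin.fit_voxel(kin.TimeActivityCurve(basis.schedule, tac), basis)
        assert fit.rss <= fit.rss_ki_only + 1e-12

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_scaling_equivariance(self, cp, schedule, basis, scale):
        truth = synthio.KineticTruth(0.1, 0.4, 0.1)
        tac = synthio.simulate_tac(truth, cp, schedule).activity
        f1 = kin.fit_voxel(kin.TimeActivityCurve(schedule, tac), basis)
        f2 = kin.fit_voxel(kin.TimeActivityCurve(schedule, scale * tac), basis)
        assert f2.ki == pytest.approx(scale * f1.ki, rel=1e-9)
        assert f2.amplitude == pytest.approx(scale * f1.amplitude, rel=1e-9)
        assert f2.theta == f1.theta

    def test_nonfinite_tac_rejected(self, schedule, basis):
        tac = np.zeros(schedule.n_frames)
        tac[3] = np.nan
        with pytest.raises(ValueError):
            kin.fit_voxels(tac[None, :], basis)

    def test_patlak_consistency_on_fast_equilibrating_truths(self, cp, schedule, basis):
        """For noiseless irreversible TACs whose exponential transient clears
        well before 20 min, the basis-function Ki matches the late-time
        Patlak slope to within 5%."""
        t = cp.times_min
        icp = cumulative_trapezoid(cp.plasma, t, initial=0.0)
        mids = schedule.midpoints_min
        cp_mid = np.interp(mids, t, cp.plasma)
        icp_mid = np.interp(mids, t, icp)
        late = mids > 20
        for K1, k2, k3 in [(0.1, 0.4, 0.1), (0.2, 0.9, 0.1), (0.05, 0.45, 0.05)]:
            truth = synthio.KineticTruth(K1, k2, k3)
            tac = synthio.simulate_tac(truth, cp, schedule)
            fit = kin.fit_voxel(tac, basis)
            slope = np.polyfit(
                icp_mid[late] / cp_mid[late], tac.activity[late] / cp_mid[late], 1
            )[0]
            assert abs(fit.ki - slope) / slope < 0.05


class TestSimulateTacOracle:
    def test_matches_stiff_ode_integration(self, cp, schedule):
        """Forward model vs direct integration of the compartment ODEs
        (dC1/dt = K1*Cp - (k2+k3)*C1, dC2/dt = k3*C1) with exact frame
        averaging via an auxiliary integral state."""
        truth = synthio.KineticTruth(K1=0.1, k2=0.4, k3=0.1)
        t = cp.times_min

        def rhs(tt, y):
            cpv = np.interp(tt, t, cp.plasma)
            c1, c2, _ = y
            return [
                truth.K1 * cpv - (truth.k2 + truth.k3) * c1,
                truth.k3 * c1,
                c1 + c2,
            ]

        sol = solve_ivp(
            rhs,
            (0, schedule.total_s / 60),
            [0.0, 0.0, 0.0],
            method="LSODA",
            dense_output=True,
            rtol=1e-9,
            atol=1e-12,
            max_step=0.25,
        )
        starts, ends = schedule.starts_s / 60, schedule.ends_s / 60
        oracle = (sol.sol(ends)[2] - sol.sol(starts)[2]) / (ends - starts)
        tac = synthio.simulate_tac(truth, cp, schedule)
        peak = oracle.max()
        assert np.max(np.abs(tac.activity - oracle)) / peak < 0.005


class TestKiAndGurMaps:
    def test_phantom_label_recovery_and_determinism(self, cp, schedule, basis):
        labels = np.zeros((4, 4, 3), int)
        labels[:2, :2, :] = 1
        labels[2:, 2:, :] = 2
        spec = synthio.PhantomSpec(
            labels=labels,
            kinetics={
                1: synthio.KineticTruth(0.1, 0.4, 0.1),
                2: synthio.KineticTruth(0.05, 0.45, 0.05),
            },
        )
        ph = synthio.make_pet_phantom(spec, cp, schedule)
        m1 = kin.ki_map(ph.pet4d, basis)
        m2 = kin.ki_map(ph.pet4d, basis)
        np.testing.assert_array_equal(m1, m2)
        for lab, truth in spec.kinetics.items():
            np.testing.assert_allclose(m1[labels == lab], truth.ki, atol=1.2e-3)
        assert np.all(m1[labels == 0] == 0) or np.allclose(m1[labels == 0], 0)

    def test_empty_mask_gives_zero_map(self, basis, schedule):
        pet = np.ones((2, 2, 2, schedule.n_frames))
        out = kin.ki_map(pet, basis, body_mask=np.zeros((2, 2, 2)))
        assert np.all(out == 0)

    def test_gur_unit_arithmetic(self):
        ki = np.full((2, 2, 2), 0.02)
        g = kin.gur_map(ki, 5.0, 5.0, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(g.data, 10.0)

    def test_gur_uses_mean_glucose(self):
        ki = np.full((1, 1, 1), 0.02)
        a = kin.gur_map(ki, 4.8, 5.2, (1, 1, 1))
        b = kin.gur_map(ki, 5.0, 5.0, (1, 1, 1))
        np.testing.assert_allclose(a.data, b.data)

    def test_zero_ki_gives_zero_gur(self):
        g = kin.gur_map(np.zeros((2, 2, 2)), 5.0, 5.0, (1, 1, 1))
        assert np.all(g.data == 0)

    def test_nonpositive_glucose_rejected(self):
        with pytest.raises(ValueError):
            kin.gur_map(np.zeros((1, 1, 1)), 0.0, 5.0, (1, 1, 1))
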