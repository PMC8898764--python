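"""van Vleck chi_M T, |B/J| fitting, Zeeman/powder magnetization, mixtures."""

import numpy as np
import pytest

from despin import (
    ChiTFitConfig,
    ExchangeSystem,
    MagnetometryCurve,
    ZFSSystem,
    chi_t,
    fit_chi_t,
    mixture_response,
    powder_moment,
    zeeman_magnetization,
)
from despin.constants import CURIE_C, KB_CM, MUB_CM_PER_T
from despin.magnetometry import fibonacci_sphere, powder_magnetization_curve
from despin.zfs import spin_matrices, zfs_hamiltonian


class TestChiT:
    def test_high_temperature_limit_equal_weight_average(self):
        """As T -> inf every level weighs equally: <S(S+1)> = 885/60 = 14.75,
        so chi_M T -> 0.125049 g^2 * 14.75 = 7.378 for g = 2."""
        val = chi_t(ExchangeSystem(J=-40.0, B=120.0), 2.0, [1e6])[0]
        assert val == pytest.approx(CURIE_C * 4.0 * 14.75, rel=1e-3)

    def test_low_temperature_curie_limit_of_isolated_ground_doublet(self):
        val = chi_t(ExchangeSystem(J=-100.0, B=0.0), 2.0, [2.0])[0]
        assert val == pytest.approx(CURIE_C * 4.0 * 0.75, rel=1e-4)  # 0.3751

    def test_antiferromagnetic_chit_increases_with_temperature(self):
        T = np.arange(52.0, 291.0, 2.0)
        for r in (2.0, 2.9, 3.7):
            y = chi_t(ExchangeSystem(J=-40.0, B=r * 40.0), 2.0, T)
            assert np.all(np.diff(y) > 0)

    def test_shift_invariance_under_uniform_energy_offset(self):
        """chi_t built from Boltzmann ratios is invariant to the ladder's
        zero of energy: doubling (J, B) at doubled temperature matches."""
        a = chi_t(ExchangeSystem(J=-10.0, B=25.0), 2.0, [40.0, 120.0])
        b = chi_t(ExchangeSystem(J=-20.0, B=50.0), 2.0, [80.0, 240.0])
        assert np.allclose(a, b)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            chi_t(ExchangeSystem(J=-1.0, B=1.0), 2.0, [0.0])


class TestFitChiT:
    def test_noiseless_self_consistency_recovers_ratio_to_3_decimals(self):
        T = np.arange(52.0, 291.0, 2.0)
        y = chi_t(ExchangeSystem(J=-40.0, B=3.7 * 40.0), 2.0, T)
        curve = MagnetometryCurve("susceptibility", T, y)
        res = fit_chi_t(curve, ChiTFitConfig(g=2.0, compute_profile=False))
        assert res.success
        assert res.r == pytest.approx(3.700, abs=1e-3)

    def test_profile_minimum_sits_at_the_fitted_ratio(self):
        T = np.arange(52.0, 291.0, 2.0)
        y = chi_t(ExchangeSystem(J=-40.0, B=2.0 * 40.0), 2.0, T)
        res = fit_chi_t(
            MagnetometryCurve("susceptibility", T, y),
            ChiTFitConfig(g=2.0, r_profile=(0.5, 4.0, 0.25)),
        )
        assert res.profile_r[np.argmin(res.profile_cost)] == pytest.approx(
            2.0, abs=0.25
        )

    def test_low_temperature_points_excluded_without_override(self):
        T = np.arange(2.0, 291.0, 2.0)
        y = chi_t(ExchangeSystem(J=-40.0, B=148.0), 2.0, T)
        curve = MagnetometryCurve("susceptibility", T, y)
        res = fit_chi_t(curve, ChiTFitConfig(g=2.0, compute_profile=False))
        assert res.n_points == int((T > 50.0).sum())
        res_all = fit_chi_t(
            curve, ChiTFitConfig(g=2.0, allow_low_t=True, compute_profile=False)
        )
        assert res_all.n_points == T.size

    def test_too_few_points_above_window_rejected(self):
        T = np.arange(52.0, 70.0, 2.0)
        y = chi_t(ExchangeSystem(J=-40.0, B=80.0), 2.0, T)
        with pytest.raises(ValueError, match="t_min"):
            fit_chi_t(MagnetometryCurve("susceptibility", T, y))

    def test_degenerate_constant_data_flagged(self):
        T = np.arange(52.0, 291.0, 2.0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_chi_t(
                MagnetometryCurve("susceptibility", T, np.full_like(T, 1.5))
            )

    def test_replicate_recovery_within_printed_uncertainty(self, rng):
        """1% noise, a handful of replicates: median |r_hat - r| <= 0.1,
        the uncertainty quoted for the Te complex fit."""
        T = np.arange(52.0, 291.0, 2.0)
        truth = chi_t(ExchangeSystem(J=-40.0, B=148.0), 2.0, T)
        cfg = ChiTFitConfig(g=2.0, compute_profile=False)
        rs = []
        for _ in range(5):
            y = truth * (1.0 + 0.01 * rng.standard_normal(T.size))
            rs.append(fit_chi_t(MagnetometryCurve("susceptibility", T, y), cfg).r)
        assert abs(np.median(rs) - 3.7) <= 0.1


class TestZeemanMagnetization:
    def test_saturation_at_g_times_s_without_zfs(self):
        m = zeeman_magnetization(ZFSSystem(S=1.5, D=0.0, g=2.0), 7.0, T=0.01)
        assert m == pytest.approx(3.0, abs=1e-6)

    def test_s_half_isotropic_in_direction(self, rng):
        zfs = ZFSSystem(S=0.5, g=2.0)
        dirs = rng.standard_normal((5, 3))
        vals = [zeeman_magnetization(zfs, 3.0, d, 2.0) for d in dirs]
        assert np.ptp(vals) < 1e-12

    def test_expectation_matches_finite_difference_derivative(self):
        """Hellmann-Feynman moment vs numerical -dF/dB to 1e-6 relative
        (free-energy derivative equals the thermal moment)."""
        zfs = ZFSSystem(S=1.5, D=11.0, E_over_D=0.33, g=2.0)
        for direction in [(0, 0, 1), (1, 0, 0), (1, 1, 1)]:
            n = np.asarray(direction, float)
            n /= np.linalg.norm(n)
            T, B, h = 2.0, 4.0, 1e-5

            def free_energy(b):
                w = np.linalg.eigvalsh(zfs_hamiltonian(zfs, b * n))
                w0 = w.min()
                return w0 - KB_CM * T * np.log(
                    np.exp(-(w - w0) / (KB_CM * T)).sum()
                )

            m_fd = -(free_energy(B + h) - free_energy(B - h)) / (2 * h) / MUB_CM_PER_T
            m = zeeman_magnetization(zfs, B, n, T)
            assert m == pytest.approx(m_fd, rel=1e-6)

    def test_zfs_makes_magnetization_anisotropic(self):
        zfs = ZFSSystem(S=1.5, D=11.0, E_over_D=0.33, g=2.0)
        mz = zeeman_magnetization(zfs, 7.0, (0, 0, 1), 2.0)
        mx = zeeman_magnetization(zfs, 7.0, (1, 0, 0), 2.0)
        assert abs(mz - mx) > 0.1

    def test_zero_field_zero_moment_and_monotone_in_field(self):
        zfs = ZFSSystem(S=1.5, D=11.0, E_over_D=0.115, g=2.0)
        assert zeeman_magnetization(zfs, 0.0, (0, 0, 1), 2.0) == pytest.approx(0.0, abs=1e-10)
        fields = np.linspace(0.0, 7.0, 15)
        m = [zeeman_magnetization(zfs, b, (1, 1, 0), 2.0) for b in fields]
        assert np.all(np.diff(m) > -1e-12)


class TestPowderMoment:
    def test_isotropic_system_powder_equals_any_orientation(self):
        zfs = ZFSSystem(S=1.5, D=0.0, g=2.0)
        avg, mx = powder_moment(zfs, 5.0, 2.0, n_orient=100)
        single = zeeman_magnetization(zfs, 5.0, (0, 0, 1), 2.0)
        assert avg == pytest.approx(single, rel=1e-10)
        assert mx == pytest.approx(single, rel=1e-10)

    def test_average_never_exceeds_max_orientation(self):
        zfs = ZFSSystem(S=1.5, D=11.0, E_over_D=0.33, g=2.0)
        for b in (0.5, 3.0, 7.0):
            avg, mx = powder_moment(zfs, b, 2.0, n_orient=200)
            assert avg <= mx + 1e-12

    def test_orientation_grid_refinement_converges(self):
        zfs = ZFSSystem(S=1.5, D=11.0, E_over_D=0.33, g=2.0)
        coarse, _ = powder_moment(zfs, 7.0, 2.0, n_orient=300)
        fine, _ = powder_moment(zfs, 7.0, 2.0, n_orient=1200)
        assert abs(coarse - fine) / fine < 0.005

    def test_coarse_grid_warned(self):
        with pytest.warns(UserWarning, match="coarse"):
            powder_moment(ZFSSystem(S=0.5, g=2.0), 1.0, 2.0, n_orient=10)

    def test_powder_curve_saturates_and_stays_below_gs(self):
        zfs = ZFSSystem(S=1.5, D=11.0, E_over_D=0.33, g=2.0)
        curve = powder_magnetization_curve(
            zfs, np.arange(0.5, 7.1, 0.5), 2.0, n_orient=150
        )
        assert np.all(np.diff(curve.ordinate) > -1e-9)
        assert curve.ordinate[-1] < 3.0  # ZFS anisotropy keeps M below g*S

    def test_fibonacci_grid_is_unit_and_balanced(self):
        pts = fibonacci_sphere(400)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestMixture:
    def _curie_curve(self, S, g, T):
        y = np.full_like(T, CURIE_C * g * g * S * (S + 1.0))
        return MagnetometryCurve("susceptibility", T, y)

    def test_identical_components_leave_curve_unchanged(self):
        T = np.linspace(2, 290, 20)
        c = self._curie_curve(0.5, 2.0, T)
        out = mixture_response([c, c], [0.5, 0.5])
        assert np.allclose(out.ordinate, c.ordinate)

    def test_pure_weight_returns_first_component(self):
        T = np.linspace(2, 290, 20)
        a, b = self._curie_curve(0.5, 2.0, T), self._curie_curve(1.5, 2.0, T)
        out = mixture_response([a, b], [1.0, 0.0])
        assert np.allclose(out.ordinate, a.ordinate)

    def test_fifty_fifty_spin_isomer_curie_value(self):
        """(0.3751 + 1.8757)/2 = 1.125 cm^3 K mol^-1 for g = 2."""
        T = np.linspace(2, 290, 20)
        out = mixture_response(
            [self._curie_curve(0.5, 2.0, T), self._curie_curve(1.5, 2.0, T)],
            [0.5, 0.5],
        )
        assert out.ordinate[0] == pytest.approx(1.1254, abs=1e-3)

    def test_mismatched_abscissae_rejected(self):
        a = self._curie_curve(0.5, 2.0, np.linspace(2, 290, 20))
        b = self._curie_curve(0.5, 2.0, np.linspace(2, 290, 21))
        with pytest.raises(ValueError, match="abscissa"):
            mixture_response([a, b], [0.5, 0.5])

    def test_invalid_weights_rejected(self):
        T = np.linspace(2, 290, 10)
        c = self._curie_curve(0.5, 2.0, T)
        with pytest.raises(ValueError, match="sum to 1"):
            mixture_response([c, c], [0.7, 0.6])
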