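"""GLE model: kernel transform, observables, asymptotes, derived parameters."""

import mpmath as mp
import numpy as np
import pytest

from glediff import (
    GLEParameters,
    ParameterDomainError,
    d_infinity,
    derive_parameters,
    long_time,
    observable,
    relaxation_hats,
    short_time,
    zeta_hat,
)
from glediff.constants import KB


def mp_zeta_hat(s, p):
    """Direct arbitrary-precision evaluation of the kernel transform."""
    with mp.workdps(50):
        sm = mp.mpf(s)
        ts = mp.mpf(p.tau) * sm
        return float(
            mp.mpf(p.M) * mp.mpf(p.omega_s)
            + mp.mpf(p.M) * mp.mpf(p.omega_p)
            * ts ** (mp.mpf(p.delta) * mp.mpf(p.lam) - mp.mpf(p.nu))
            / (1 + ts ** mp.mpf(p.lam)) ** mp.mpf(p.delta)
        )


class TestZetaHat:
    def test_pure_viscous_kernel_is_constant(self):
        p = GLEParameters(M=100.0, T=300.0, omega_s=2.0, omega_p=0.0,
                          tau=1.0, lam=1.0, nu=1.0)
        s = np.logspace(-3, 3, 20)
        assert np.allclose(zeta_hat(s, p), p.M * 2.0)

    def test_limits_under_brownian_constraint(self, ref_params):
        """With delta*lam = nu the zero-frequency limit is the total
        friction xi_s + xi_p; at high frequency the retarded term dies and
        only the instantaneous friction xi_s remains."""
        total = ref_params.xi_s + ref_params.xi_p
        assert zeta_hat(1e-14, ref_params) == pytest.approx(total, rel=1e-4)
        assert zeta_hat(1e14, ref_params) == pytest.approx(ref_params.xi_s, rel=1e-4)

    def test_against_multiprecision_oracle(self, ref_params):
        for s in (1.0 / ref_params.tau, ref_params.omega_s, 3.7e-3):
            assert zeta_hat(s, ref_params) == pytest.approx(
                mp_zeta_hat(s, ref_params), rel=1e-12
            )


class TestRelaxationHats:
    def test_langevin_resolvent_when_no_elastic_term(self):
        p = GLEParameters(M=50.0, T=300.0, omega_s=1.5, omega_p=0.0,
                          tau=1.0, lam=1.0, nu=1.0)
        s = np.logspace(-2, 2, 10)
        g, _, _ = relaxation_hats(s, p)
        assert np.allclose(g, 1.0 / (p.M * s + p.M * 1.5), rtol=1e-14)

    def test_ladder_identities(self, ref_params):
        rng = np.random.default_rng(3)
        s = np.exp(rng.uniform(-6, 6, 20))
        g, H, I = relaxation_hats(s, ref_params)
        assert np.allclose(s * H, g, rtol=1e-14)
        assert np.allclose(s * I, H, rtol=1e-14)

    def test_g_hat_at_omega_s_matches_direct_evaluation(self, ref_params):
        s = ref_params.omega_s
        g = relaxation_hats(s, ref_params)[0]
        assert g == pytest.approx(
            1.0 / (ref_params.M * s + mp_zeta_hat(s, ref_params)), rel=1e-12
        )


class TestObservables:
    def test_langevin_closed_form_vacf(self):
        """xi_p = 0 reduces to Langevin dynamics with exponential VACF."""
        p = GLEParameters(M=41697.0, T=310.0, omega_s=0.98, omega_p=0.0,
                          tau=1.0, lam=1.0, nu=1.0)
        t = np.logspace(-2, 1, 25)
        cv = observable("vacf", t, p).values
        exact = 2.0 * p.kBT / p.M * np.exp(-p.omega_s * t)
        assert np.max(np.abs(cv - exact) / exact) <= 1e-6

    def test_frozen_elastic_term_gives_harmonic_plateau(self, ref_params):
        """Elastic component frozen at 1 confines the particle: MSD
        plateaus at 2 d kB T/(M omega_0^2)."""
        t = np.array([3e5, 1e6, 1e7])
        msd = observable("msd", t, ref_params, kernel_variant="frozen").values
        plateau = 2 * ref_params.dim * ref_params.kBT / (
            ref_params.M * ref_params.omega_0**2
        )
        assert np.allclose(msd, plateau, rtol=1e-6)

    def test_msd_nonnegative_nondecreasing(self, ref_params):
        t = np.logspace(-2, 6, 60)
        msd = observable("msd", t, ref_params).values
        assert np.all(msd >= 0)
        assert np.all(np.diff(msd) > 0)

    def test_thermalization_of_vacf_origin(self):
        """Cv(t->0+) = 2 kB T/M (d=2) within 0.1% for CM parameter sets."""
        for kwargs in (
            dict(omega_s=0.98, omega_p=447.0, tau=13.4e3, lam=0.715, nu=0.715),
            dict(omega_s=2.0, omega_p=30.0, tau=100.0, lam=0.5, nu=0.45, delta=0.9),
            dict(omega_s=0.3, omega_p=5.0, tau=50.0, lam=0.9, nu=0.9),
        ):
            p = GLEParameters(M=1000.0, T=310.0, delta=kwargs.pop("delta", 1.0),
                              **kwargs)
            t0 = 1e-7 / p.omega_s
            cv0 = observable("vacf", np.array([t0]), p).values[0]
            assert cv0 == pytest.approx(2 * p.kBT / p.M, rel=1e-3)

    def test_kinematic_consistency_msd_derivative_is_d(self, ref_params):
        """Numerical d(MSD)/dt / (2d) reproduces D(t) to <= 0.5%."""
        t = np.logspace(0, 6, 120)
        msd = observable("msd", t, ref_params).values
        d_model = observable("dcoef", t, ref_params).values
        dmsd = np.gradient(msd, np.log(t)) / t  # d/dt via log grid
        inner = slice(3, -3)
        rel = np.abs(dmsd[inner] / (2 * ref_params.dim) - d_model[inner]) / d_model[inner]
        assert np.max(rel) <= 5e-3

    def test_green_kubo_consistency(self, ref_params):
        """int_0^t Cv/2 dtau = D(t) (d = 2) to <= 1%."""
        from scipy.integrate import cumulative_trapezoid

        t = np.geomspace(1e-4, 1e5, 400)
        cv = observable("vacf", t, ref_params, accuracy_goal=1e-7).values
        d_model = observable("dcoef", t, ref_params).values
        integral = cumulative_trapezoid(cv, t, initial=0.0) / 2.0
        # add the t=0 ballistic sliver missing from the grid
        integral += ref_params.kBT / ref_params.M * t[0]
        check = slice(40, None)
        assert np.max(np.abs(integral[check] - d_model[check]) / d_model[check]) <= 0.01

    def test_unknown_kind_rejected(self, ref_params):
        with pytest.raises(ParameterDomainError):
            observable("speed", [1.0], ref_params)


class TestAsymptotes:
    def test_short_time_ballistic_limit(self, ref_params):
        t = np.array([1e-6])
        assert short_time("msd", t, ref_params)[0] / t[0] ** 2 == pytest.approx(
            2 * ref_params.kBT / ref_params.M, rel=1e-5
        )

    def test_short_time_matches_inversion(self, ref_params):
        """<= 1% agreement with the full model at t = 0.01/omega_s."""
        t = np.array([0.01 / ref_params.omega_s])
        for kind in ("msd", "vacf", "dcoef"):
            full = observable(kind, t, ref_params).values[0]
            assert short_time(kind, t, ref_params)[0] == pytest.approx(full, rel=0.01)

    def test_short_time_vacf_arithmetic(self, ref_params):
        got = short_time("vacf", np.array([0.1]), ref_params)[0]
        expected = 2 * ref_params.kBT / ref_params.M * (1 - 0.098)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vacf_tail_negative_and_matches_inversion(self, ref_params):
        """ILT/asymptote ratio -> 1 (within 5% at t = 100 tau); the tail is
        negative since Gamma(-lam) < 0."""
        t = np.array([100 * ref_params.tau])
        asym = long_time("vacf", t, ref_params)[0]
        full = observable("vacf", t, ref_params, accuracy_goal=1e-5).values[0]
        assert asym < 0
        assert full / asym == pytest.approx(1.0, abs=0.05)

    def test_d_plateau_and_msd_slope(self, ref_params):
        t = np.array([1e8, 1e9])
        d_inf_internal = ref_params.kBT / (ref_params.xi_s + ref_params.xi_p)
        assert np.allclose(long_time("dcoef", t, ref_params), d_inf_internal)
        slope = long_time("msd", t, ref_params) / t
        assert np.allclose(slope, 4 * d_inf_internal)
        # full model approaches the plateau from above
        full = observable("dcoef", t[:1], ref_params).values[0]
        assert full == pytest.approx(d_inf_internal, rel=5e-3)

    def test_requires_brownian_constraint_and_noninteger_lam(self):
        p = GLEParameters(M=100.0, T=300.0, omega_s=1.0, omega_p=10.0,
                          tau=10.0, lam=0.5, nu=0.8)
        with pytest.raises(ParameterDomainError):
            long_time("msd", np.array([1.0]), p)
        p2 = GLEParameters(M=100.0, T=300.0, omega_s=1.0, omega_p=10.0,
                           tau=10.0, lam=1.0, nu=1.0)
        with pytest.raises(ParameterDomainError):
            long_time("vacf", np.array([1.0]), p2)


class TestDerivedParameters:
    def test_reference_values(self, ref_params):
        d = derive_parameters(ref_params)
        assert d.omega0 == pytest.approx(0.183, rel=0.01)
        assert d.xi_p == pytest.approx(0.0309, rel=0.01)
        assert d.xi_s == pytest.approx(0.067e-3, rel=0.015)
        assert d.D_inf == pytest.approx(0.137, rel=0.01)

    def test_langevin_einstein_relation(self):
        p = GLEParameters(M=1000.0, T=300.0, omega_s=1.0, omega_p=0.0,
                          tau=1.0, lam=1.0, nu=1.0)
        assert d_infinity(p) == pytest.approx(
            KB * 300.0 / (1000.0 * 1.0) * 1e6, rel=1e-12
        )

    def test_mass_scaling(self, ref_params):
        heavier = GLEParameters(**{**ref_params.__dict__, "M": 2 * ref_params.M})
        assert d_infinity(heavier) == pytest.approx(
            d_infinity(ref_params) / 2.0, rel=1e-12
        )

    def test_exponential_kernel_diffusion_coefficient(self):
        """The transient-confinement (exponential) kernel has long-time
        diffusion coefficient kB T/[M(omega_s + omega_0^2 tau)], identical
        to D_inf of the full model with omega_p = omega_0^2 tau."""
        p = GLEParameters(M=500.0, T=300.0, omega_s=1.0, omega_p=20.0,
                          tau=40.0, lam=1.0, nu=1.0)
        t = np.array([1e6])
        d_exp = observable("dcoef", t, p, kernel_variant="exponential").values[0]
        expected = p.kBT / (p.M * (p.omega_s + p.omega_0**2 * p.tau))
        assert d_exp == pytest.approx(expected, rel=1e-6)
        assert d_infinity(p) == pytest.approx(expected * 1e6, rel=1e-12)

    def test_brownian_recovery_timescale(self, ref_params):
        """|D(t)/D_inf - 1| stays above 5% out to ~100 ns and first comes
        within 3% only at lags of order hundreds of ns."""
        d_inf = ref_params.kBT / (ref_params.xi_s + ref_params.xi_p)
        early = observable("dcoef", np.array([1e3, 1e4, 8e4]), ref_params).values
        assert np.all(np.abs(early / d_inf - 1.0) > 0.05)
        late = observable("dcoef", np.array([6e5, 1e6]), ref_params).values
        assert np.all(np.abs(late / d_inf - 1.0) < 0.03)

    def test_parameter_validation(self):
        with pytest.raises(ParameterDomainError):
            GLEParameters(M=-1.0, T=300.0, omega_s=1.0, omega_p=1.0,
                          tau=1.0, lam=0.7, nu=0.7)
        with pytest.raises(ParameterDomainError):
            GLEParameters(M=1.0, T=300.0, omega_s=1.0, omega_p=1.0,
                          tau=1.0, lam=0.7, nu=0.7, dim=4)
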