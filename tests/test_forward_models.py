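"""Forward-model physics: Green's-function properties, Siegert relation, IRF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from hemoptics.forward_models import (
    DTOF,
    G2Curve,
    Geometry,
    OpticalProperties,
    ValidationError,
    convolve_irf,
    effective_reflection_coefficient,
    g1_from_g2,
    g1_semiinf,
    g2_from_g1,
    td_reflectance,
    wavenumber_in_medium,
)


def cw_reflectance_oracle(op, geom):
    """Independently coded steady-state semi-infinite reflectance (closed form).

    Image-dipole flux solution with mueff = sqrt(3 mua musp); must equal the
    time integral of the time-domain solution.
    """
    z0, zb = geom.boundary(op)
    mueff = np.sqrt(3.0 * op.mua * op.musp)
    r1 = np.sqrt(z0**2 + geom.rho**2)
    r2 = np.sqrt((z0 + 2 * zb) ** 2 + geom.rho**2)
    return (1.0 / (4 * np.pi)) * (
        z0 * (mueff + 1 / r1) * np.exp(-mueff * r1) / r1**2
        + (z0 + 2 * zb) * (mueff + 1 / r2) * np.exp(-mueff * r2) / r2**2
    )


class TestTdReflectance:
    def test_positive_and_finite(self, op, geom):
        t = np.logspace(0, 4, 200)
        r = td_reflectance(op, geom, t)
        assert np.all(r >= 0) and np.all(np.isfinite(r))

    def test_vanishes_at_both_limits(self, op, geom):
        r = td_reflectance(op, geom, np.array([1e-3, 1e7]))
        assert r[0] < 1e-30 and r[1] < 1e-30

    def test_nonpositive_time_rejected(self, op, geom):
        with pytest.raises(ValidationError):
            td_reflectance(op, geom, np.array([0.0, 10.0]))

    def test_mua_scaling_is_beer_lambert(self, op, geom):
        """Raising mua by d multiplies R(t) by exp(-d v t) exactly (boundary frozen)."""
        t = np.linspace(10, 5000, 97)
        z0, zb = geom.boundary(op)
        frozen = Geometry(rho=geom.rho, z0=z0, zb=zb)
        r1 = td_reflectance(op, frozen, t)
        d = 0.013
        op2 = OpticalProperties(mua=op.mua + d, musp=op.musp, n=op.n)
        r2 = td_reflectance(op2, frozen, t)
        np.testing.assert_allclose(r2, r1 * np.exp(-d * op.v * t), rtol=1e-12)

    @pytest.mark.parametrize("mua,musp", [(0.005, 0.6), (0.01, 1.0), (0.03, 1.6)])
    def test_time_integral_equals_cw_closed_form(self, geom, mua, musp):
        op = OpticalProperties(mua=mua, musp=musp)
        # integrate in log-time: the peak is narrow on the linear axis
        val, _ = quad(
            lambda u: td_reflectance(op, geom, np.array([np.exp(u)]))[0] * np.exp(u),
            np.log(1e-3),
            np.log(1e5),
            limit=300,
        )
        assert val == pytest.approx(cw_reflectance_oracle(op, geom), rel=1e-3)


class TestG1:
    def test_zero_flow_means_no_decay(self, op, geom):
        tau = np.logspace(-7, -2, 40)
        np.testing.assert_allclose(
            g1_semiinf(op, geom, 0.0, wavenumber_in_medium(785), tau), 1.0
        )

    def test_short_lag_limit_and_monotone_decay(self, op, geom):
        k0 = wavenumber_in_medium(785)
        assert g1_semiinf(op, geom, 1e-6, k0, np.array([1e-12]))[0] == pytest.approx(1.0, abs=1e-6)
        g1 = g1_semiinf(op, geom, 1e-6, k0, np.logspace(-7, -2, 100))
        assert np.all(np.diff(g1) <= 0) and np.all((g1 >= 0) & (g1 <= 1))
        assert np.all(np.diff(g1[g1 > 1e-12]) < 0)  # strictly decreasing until floor

    def test_half_decay_lag_decreases_with_flow(self, op, geom):
        """Bisection oracle: tau at g1=0.5 is inversely related to BFi."""
        k0 = wavenumber_in_medium(785)

        def half_lag(bfi):
            lo, hi = 1e-9, 1e-1
            for _ in range(80):
                mid = np.sqrt(lo * hi)
                if g1_semiinf(op, geom, bfi, k0, np.array([mid]))[0] > 0.5:
                    lo = mid
                else:
                    hi = mid
            return np.sqrt(lo * hi)

        bfis = np.logspace(-7, -5, 10)
        lags = [half_lag(b) for b in bfis]
        assert np.all(np.diff(lags) < 0)

    def test_negative_bfi_rejected(self, op, geom):
        with pytest.raises(ValidationError):
            g1_semiinf(op, geom, -1e-7, 1e4, np.array([1e-5]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mua=st.floats(0.003, 0.05),
        musp=st.floats(0.5, 2.5),
        bfi=st.floats(0, 1e-5),
        rho=st.floats(10, 30),
    )
    def test_g1_bounded_and_nonincreasing(self, mua, musp, bfi, rho):
        op = OpticalProperties(mua=mua, musp=musp)
        geom = Geometry(rho=rho)
        g1 = g1_semiinf(op, geom, bfi, wavenumber_in_medium(785), np.logspace(-7, -2, 50))
        assert np.all((g1 >= 0) & (g1 <= 1)) and np.all(np.diff(g1) <= 1e-12)


class TestSiegert:
    def test_limits_and_substitution(self):
        assert g2_from_g1(np.array([0.0]), 0.5)[0] == 1.0
        assert g2_from_g1(np.array([1.0]), 0.5)[0] == 1.5

    def test_round_trip_identity(self):
        g1 = np.linspace(0, 1, 11)
        np.testing.assert_allclose(g1_from_g2(g2_from_g1(g1, 0.37), 0.37), g1, atol=1e-14)

    @pytest.mark.parametrize("beta", [0.0, -0.1, 1.5])
    def test_invalid_beta_rejected(self, beta):
        with pytest.raises(ValidationError):
            g2_from_g1(np.array([0.5]), beta)

    def test_simulated_g2_within_siegert_bounds(self, op, geom):
        beta = 0.43
        g1 = g1_semiinf(op, geom, 3e-6, wavenumber_in_medium(785), np.logspace(-7, -2, 80))
        g2 = g2_from_g1(g1, beta)
        assert np.all(g2 >= 1.0 - 1e-12) and np.all(g2 <= 1.0 + beta + 1e-12)


class TestConvolveIrf:
    def test_unit_impulse_is_identity(self):
        model = np.exp(-np.arange(50) / 7.0)
        irf = np.zeros(50)
        irf[0] = 1.0
        np.testing.assert_allclose(convolve_irf(model, irf, 1.0), model)

    def test_shifted_impulse_shifts_curve(self):
        model = np.exp(-np.arange(50) / 7.0)
        irf = np.zeros(50)
        irf[5] = 1.0
        out = convolve_irf(model, irf, 1.0)
        np.testing.assert_allclose(out[5:], model[:-5])
        np.testing.assert_allclose(out[:5], 0.0)

    def test_matches_double_loop_oracle_and_sum_rule(self):
        rng = np.random.default_rng(3)
        model = rng.random(40)
        irf = rng.random(40)
        bw = 2.0
        n = len(model)
        oracle = np.zeros(n)
        for i in range(n):
            for j in range(i + 1):
                oracle[i] += model[j] * irf[i - j]
        oracle *= bw
        out = convolve_irf(model, irf, bw)
        np.testing.assert_allclose(out, oracle, rtol=1e-12)
        # untruncated sum rule
        full = np.convolve(model, irf) * bw
        assert full.sum() == pytest.approx(model.sum() * irf.sum() * bw, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            convolve_irf(np.ones(5), np.ones(6), 1.0)


class TestDomainTypes:
    def test_optical_properties_validation(self):
        with pytest.raises(ValidationError):
            OpticalProperties(mua=-0.01, musp=1.0)
        with pytest.raises(ValidationError):
            OpticalProperties(mua=0.01, musp=0.0)
        with pytest.raises(ValidationError):
            OpticalProperties(mua=0.01, musp=1.0, n=0.9)
        with pytest.warns(UserWarning, match="musp/mua"):
            OpticalProperties(mua=0.5, musp=1.0)

    def test_reff_increases_with_index_mismatch(self):
        assert effective_reflection_coefficient(1.4) > effective_reflection_coefficient(1.1)

    def test_g2curve_requires_increasing_tau(self):
        with pytest.raises(ValidationError):
            G2Curve(tau=np.array([1e-6, 1e-6]), g2=np.array([1.4, 1.4]))

    def test_dtof_requires_uniform_bins(self):
        with pytest.raises(ValidationError):
            DTOF(
                t_bins=np.array([0.0, 1.0, 3.0]),
                counts=np.ones(3),
                irf=np.ones(3),
            )
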