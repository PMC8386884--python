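"""Closed-form relaxation physics: prefactors, spectral densities, rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.constants import hbar, mu_0

from cartrelax import models
from cartrelax.models import (
    CouplingConstant,
    FastExchangeModel,
    ParameterError,
    RmtdModel,
    SpectralDensity,
    deadtime_loss,
    fast_exchange_rate,
    hdo_frequency_shift_factor,
    hdo_intramolecular_factor,
    pg_weight_fraction,
    r1_dipolar,
    r1rho,
    r2_dipolar,
    rmtd_spectral_density,
)


class TestCouplingConstant:
    def test_dipolar_construction_matches_formula(self):
        gamma, r, spin = models.GAMMA_H, 1.6e-10, 0.5
        const = CouplingConstant.dipolar(gamma, r, spin)
        expected = (mu_0 / (4 * math.pi)) ** 2 * gamma**4 * hbar**2 / 5 * r**-6 * spin * 1.5
        assert const.const_value == pytest.approx(expected, rel=1e-10)

    def test_quadrupolar_construction_matches_formula(self):
        eq = 2 * math.pi * 220e3  # deuteron-like coupling, rad/s
        const = CouplingConstant.quadrupolar(eq, asymmetry=0.1)
        expected = 3 / 80 * eq**2 * (1 + 0.1**2 / 3)
        assert const.const_value == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_rejects_nonpositive_const(self, bad):
        with pytest.raises(ParameterError):
            CouplingConstant("dipolar_homonuclear", bad)


def _dense_oracle(model: RmtdModel, omega: float, n: int = 200_001) -> float:
    """Brute-force trapezoidal mode integral on a dense log-k grid."""
    k = np.geomspace(model.k_low, model.k_high, n)
    tau = model.mode_correlation_time(k)
    integrand = model.amplitude * k ** (-model.chi) * tau / (1 + (omega * tau) ** 2)
    return float(np.trapezoid(integrand, k))


class TestRmtdSpectralDensity:
    @pytest.mark.parametrize("chi", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("statistics", ["gaussian", "cauchy"])
    def test_quadrature_matches_dense_oracle(self, chi, statistics):
        model = RmtdModel(chi=chi, statistics=statistics)
        w = model.mid_band_omega
        assert rmtd_spectral_density(model, w) == pytest.approx(
            _dense_oracle(model, w), rel=1e-5
        )

    @pytest.mark.parametrize("chi", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_gaussian_midband_slope(self, chi):
        model = RmtdModel(chi=chi, statistics="gaussian")
        w0 = model.mid_band_omega
        w = np.array([w0 / 1.2, w0 * 1.2])
        I = rmtd_spectral_density(model, w)
        slope = (np.diff(np.log(I)) / np.diff(np.log(w))).item()
        assert slope == pytest.approx(-(1 + chi) / 2, abs=0.02)

    @pytest.mark.parametrize("chi", [0.1, 0.27, 0.5, 0.7, 0.9])
    def test_cauchy_midband_slope_wide_cutoffs(self, chi):
        # heavy-tailed mode integrand: the asymptotic slope needs a wide band
        model = RmtdModel(
            chi=chi, statistics="cauchy", k_low=1e2, k_high=1e16,
            transport_coefficient=1.0,
        )
        w = np.array([6e3, 6e4])
        I = rmtd_spectral_density(model, w)
        slope = (np.diff(np.log(I)) / np.diff(np.log(w))).item()
        assert slope == pytest.approx(-chi, abs=0.02)

    def test_zero_frequency_plateau_finite(self):
        model = RmtdModel(chi=0.5, statistics="gaussian")
        value = rmtd_spectral_density(model, 0.0)
        assert np.isfinite(value) and value > 0

    def test_monotone_nonincreasing(self):
        model = RmtdModel(chi=0.4, statistics="gaussian")
        w = np.geomspace(1e0, 1e8, 12)
        I = rmtd_spectral_density(model, w)
        assert np.all(np.diff(I) <= 0)

    def test_rejects_negative_omega(self):
        model = RmtdModel(chi=0.5, statistics="gaussian")
        with pytest.raises(ParameterError):
            rmtd_spectral_density(model, -1.0)

    @pytest.mark.parametrize("kwargs", [
        {"chi": 0.0}, {"chi": 1.0}, {"chi": 0.5, "k_low": 1e8, "k_high": 1e4},
        {"chi": 0.5, "transport_coefficient": -1.0},
    ])
    def test_rejects_invalid_model(self, kwargs):
        kwargs.setdefault("statistics", "gaussian")
        with pytest.raises(ParameterError):
            RmtdModel(**kwargs)


class TestDipolarRates:
    CONST = CouplingConstant("dipolar_homonuclear", 7.0)

    def test_white_spectrum_extreme_narrowing(self):
        dens = SpectralDensity.white(0.3)
        r1 = r1_dipolar(dens, self.CONST, 1e5)
        r2 = r2_dipolar(dens, self.CONST, 1e5)
        rho = r1rho(dens, self.CONST, 1e3, 1e5)
        assert r1 == pytest.approx(5 * 7.0 * 0.3, rel=1e-12)
        assert r2 == pytest.approx(r1, rel=1e-12)
        assert rho == pytest.approx(r1, rel=1e-12)

    def test_zero_spectrum_gives_zero(self):
        dens = SpectralDensity.white(0.0)
        assert r1_dipolar(dens, self.CONST, 1e6) == 0
        assert r2_dipolar(dens, self.CONST, 1e6) == 0

    def test_lorentzian_extreme_narrowing_r1_equals_r2(self):
        tau = 1e-12  # omega*tau << 1
        dens = SpectralDensity.lorentzian(tau)
        omega = 1e6
        assert r1_dipolar(dens, self.CONST, omega) == pytest.approx(
            r2_dipolar(dens, self.CONST, omega), rel=1e-6
        )

    def test_slow_motion_t2_to_t1_ratio_is_ten_thirds(self):
        # I(omega), I(2 omega) negligible against I(0)
        dens = SpectralDensity(lambda w: np.where(np.asarray(w) == 0, 1.0, 1e-9))
        omega = 1e7
        T1_zero_field = 1.0 / r1_dipolar(dens, self.CONST, 0.0)
        T2 = 1.0 / r2_dipolar(dens, self.CONST, omega)
        assert T2 / T1_zero_field == pytest.approx(10 / 3, abs=1e-3)

    def test_r1rho_zero_lock_equals_r2(self):
        model = RmtdModel(chi=0.5, statistics="gaussian")
        dens = SpectralDensity.rmtd(model)
        omega = model.mid_band_omega
        assert r1rho(dens, self.CONST, 0.0, omega) == pytest.approx(
            r2_dipolar(dens, self.CONST, omega), rel=1e-10
        )

    def test_r1rho_lock_dominated_limit(self):
        dens = SpectralDensity(lambda w: np.where(np.asarray(w) < 1e3, 1.0, 1e-12))
        rho = r1rho(dens, self.CONST, 10.0, 1e8)
        assert rho == pytest.approx(1.5 * 7.0, rel=1e-6)

    def test_negative_density_rejected(self):
        dens = SpectralDensity(lambda w: -np.ones_like(np.asarray(w, float)))
        with pytest.raises(ParameterError):
            r1_dipolar(dens, self.CONST, 1e5)


class TestFastExchange:
    def test_arithmetic_example(self):
        model = FastExchangeModel(p_a=0.5, T_surf=0.1, T_bulk=2.0)
        assert fast_exchange_rate(model) == pytest.approx(5.25, rel=1e-12)

    def test_limits(self):
        assert fast_exchange_rate(
            FastExchangeModel(0.0, 0.1, 2.0)
        ) == pytest.approx(0.5)
        assert fast_exchange_rate(
            FastExchangeModel(1.0, 0.1, 2.0)
        ) == pytest.approx(10.0)

    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1), lam=st.floats(0, 1),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_adsorbed_fraction(self, p1, p2, lam):
        T_surf, T_bulk = 0.05, 2.5
        mix = lam * p1 + (1 - lam) * p2
        r_mix = fast_exchange_rate(FastExchangeModel(mix, T_surf, T_bulk))
        r_lin = lam * fast_exchange_rate(
            FastExchangeModel(p1, T_surf, T_bulk)
        ) + (1 - lam) * fast_exchange_rate(FastExchangeModel(p2, T_surf, T_bulk))
        assert r_mix == pytest.approx(r_lin, rel=1e-9, abs=1e-12)

    def test_surface_term_from_sv_rho(self):
        model = FastExchangeModel(
            0.01, 0.1, 2.0, surface_to_volume=5.0, surface_relaxivity=0.02
        )
        assert model.surface_term == pytest.approx(0.1)

    def test_rejects_out_of_range_fraction(self):
        with pytest.raises(ParameterError):
            FastExchangeModel(1.2, 0.1, 2.0)


class TestDeadtimeLoss:
    @pytest.mark.parametrize("T2, expected", [(20.0, 0.43), (30.0, 0.22)])
    def test_printed_losses_at_15us(self, T2, expected):
        assert deadtime_loss(15.0, T2) == pytest.approx(expected, abs=5e-3)

    def test_zero_dead_time(self):
        assert deadtime_loss(0.0, 25.0) == 0.0

    @given(
        t=st.floats(1.0, 100.0), dt=st.floats(0.1, 10.0), T2=st.floats(40.0, 200.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_monotone(self, t, dt, T2):
        # t <= 2.75 T2 keeps exp(-(t/T2)^2) above float saturation
        assert deadtime_loss(t + dt, T2) > deadtime_loss(t, T2)
        assert deadtime_loss(t, T2 + dt) < deadtime_loss(t, T2)

    def test_rejects_nonpositive_T2(self):
        with pytest.raises(ParameterError):
            deadtime_loss(15.0, 0.0)


class TestIsotopeFactors:
    def test_rate_reduction_factor_about_42(self):
        assert hdo_intramolecular_factor() == pytest.approx(42.4, abs=0.1)

    def test_frequency_shift_factor_about_6_5(self):
        assert hdo_frequency_shift_factor() == pytest.approx(6.51, abs=0.01)

    def test_equal_ratios_give_unity(self):
        assert hdo_intramolecular_factor(1.0, 1.0) == 1.0
        assert hdo_frequency_shift_factor(2.0, 2.0) == 1.0


class TestPgWeightFraction:
    def test_14_percent_signal_is_about_22_wtpercent(self):
        w = pg_weight_fraction(0.14)
        assert w == pytest.approx(0.2244, abs=5e-4)

    @pytest.mark.parametrize("f, expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_boundary_values(self, f, expected):
        assert pg_weight_fraction(f) == expected

    @given(f=st.floats(0.001, 0.999))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_with_signal_fraction(self, f):
        d_pg, d_w = 40 / 640, 2 / 18
        w = pg_weight_fraction(f, d_pg, d_w)
        back = w * d_pg / (w * d_pg + (1 - w) * d_w)
        assert back == pytest.approx(f, rel=1e-9)

    def test_strictly_increasing(self):
        f = np.linspace(0, 1, 30)
        w = np.array([pg_weight_fraction(x) for x in f])
        assert np.all(np.diff(w) > 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ParameterError):
            pg_weight_fraction(1.5)
        with pytest.raises(ParameterError):
            pg_weight_fraction(0.5, proton_density_pg=0.0)
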