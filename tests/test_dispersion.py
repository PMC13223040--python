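"""Analytic field: coefficient formulas, drift, decay and puff properties."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bvocmc import (
    Environment,
    SourceEvent,
    DispersionScheme,
    FieldOptions,
    pasquill_f_textbook,
    dispersion_coeffs,
    air_density,
    vertical_drift,
    drift_acceleration,
    decay_rate,
    puff_concentration,
    continuous_concentration,
)
from bvocmc.dispersion import puff_column_integral


class TestScalars:
    def test_coeffs_hand_values(self):
        r_y, r_z = dispersion_coeffs(100.0)
        assert r_y == pytest.approx(0.08 * 1e4 / 1.01, rel=1e-12)      # 792.08
        assert r_z == pytest.approx(0.000128 * 1e4 / 1.03**2, rel=1e-12)

    def test_coeffs_vanish_at_origin_and_grow(self):
        r_y, r_z = dispersion_coeffs(0.0)
        assert r_y == 0.0 and r_z == 0.0
        xs = np.linspace(0.0, 500.0, 200)
        ry, rz = dispersion_coeffs(xs)
        assert np.all(np.diff(ry) > 0) and np.all(np.diff(rz) > 0)

    def test_coeffs_negative_x_rejected(self):
        with pytest.raises(ValueError):
            dispersion_coeffs(-1.0)

    def test_textbook_preset_lateral_coefficient(self):
        sch = pasquill_f_textbook()
        r_y, _ = dispersion_coeffs(100.0, sch)
        assert r_y == pytest.approx(0.0008 * 1e4 / 1.01, rel=1e-12)

    def test_air_density_hand_value_and_scaling(self, env):
        rho = air_density(env)
        assert rho == pytest.approx(101325 * 0.029 / (8.314 * 293.15), rel=1e-12)
        assert air_density(env.replace(T=2 * env.T)) == pytest.approx(rho / 2)
        assert rho == pytest.approx(1.2056, abs=2e-4)

    def test_vertical_drift(self, env):
        assert vertical_drift(0.0, env) == 0.0
        # heavy tracer sinks; hand value at t = 1 s
        expected = ((air_density(env) - 1.26) * 9.81 / 1.26) / 2.0
        assert vertical_drift(1.0, env) == pytest.approx(expected, rel=1e-12)
        assert vertical_drift(1.0, env) == pytest.approx(-0.2117, abs=2e-4)
        neutral = env.replace(rho_b=air_density(env))
        assert vertical_drift(3.0, neutral) == 0.0

    def test_decay_rate(self, env):
        assert decay_rate(env) == pytest.approx(
            1e10 * math.exp(-50000 / (8.314 * 293.15)), rel=1e-12)
        assert decay_rate(env) == pytest.approx(12.3, abs=0.1)
        assert decay_rate(env.replace(E_a=0.0)) == env.A
        assert decay_rate(env.replace(T=285.0)) < decay_rate(env.replace(T=315.0))

    def test_environment_validation(self):
        with pytest.raises(ValueError):
            Environment(T=-5)
        with pytest.raises(ValueError):
            Environment(u=-1)
        with pytest.raises(ValueError):
            SourceEvent(m=-1)


class TestPuffField:
    def test_gaussian_tail_vanishes(self, env, src):
        c = puff_concentration(1.0, 1e6, 0.8, 0.3, src, env)
        assert c == 0.0

    @given(y=st.floats(-3.0, 3.0), t=st.floats(0.05, 1.5),
           x=st.floats(0.1, 4.0))
    def test_lateral_symmetry(self, y, t, x):
        env, src = Environment(), SourceEvent()
        assert puff_concentration(x, y, 0.7, t, src, env) == \
            puff_concentration(x, -y, 0.7, t, src, env)

    def test_image_degeneracy_at_ground_source(self, env):
        src0 = SourceEvent(m=0.0016, H=0.0)
        opts = FieldOptions(include_drift=False, include_decay=False)
        both = puff_concentration(1.0, 0.1, 0.02, 0.33, src0, env, opts=opts)
        single = puff_concentration(
            1.0, 0.1, 0.02, 0.33, src0, env,
            opts=opts.replace(ground_reflection=False))
        assert both == pytest.approx(2 * single, rel=1e-12)

    def test_nonnegative_and_causal(self, env, src):
        xs = np.linspace(0.0, 3.0, 40)
        c = puff_concentration(xs, 0.0, 0.7, 0.4, src, env)
        assert np.all(c >= 0)
        assert puff_concentration(1.0, 0.0, 0.7, -0.1, src, env) == 0.0

    def test_singular_origin_contract(self, env):
        src = SourceEvent(m=0.0016, H=0.8)
        # on the source point at release: infinity sentinel; off it: zero
        assert np.isinf(puff_concentration(0.0, 0.0, 0.8, 1e-12, src, env,
                                           opts=FieldOptions(include_drift=False)))
        assert puff_concentration(0.0, 0.5, 0.8, 1e-12, src, env) == 0.0

    def test_domain_errors(self, env, src):
        with pytest.raises(ValueError):
            puff_concentration(-0.5, 0.0, 0.5, 0.1, src, env)
        with pytest.raises(ValueError):
            puff_concentration(0.5, 0.0, -0.5, 0.1, src, env)

    def _integral_consistent(self, t, env, opts, m=0.0016, H=0.8):
        """Cartesian grid integral of the consistent-mode field over the
        whole space (the below-ground tail is double-exponentially small)."""
        sch = DispersionScheme(normalization_mode="consistent")
        src = SourceEvent(m=m, H=H)
        xc = env.u * t
        ry, rz = dispersion_coeffs(xc)
        rx = math.sqrt(ry * rz)
        sx, sy, sz_ = (math.sqrt(2 * r) for r in (rx, ry, rz))
        xs = np.linspace(max(xc - 8 * sx, 0.0), xc + 8 * sx, 141)
        ys = np.linspace(-8 * sy, 8 * sy, 141)
        zs = np.linspace(max(H - 8 * sz_, 0.0), H + 8 * sz_, 141)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        C = puff_concentration(X, Y, Z, t, src, env, sch, opts)
        return np.trapezoid(np.trapezoid(np.trapezoid(C, zs, axis=2),
                                         ys, axis=1), xs, axis=0)

    def test_mass_conservation_consistent_mode(self, env):
        opts = FieldOptions(include_drift=False, include_decay=False,
                            ground_reflection=False)
        total = self._integral_consistent(0.5, env, opts)
        assert total == pytest.approx(0.0016, rel=5e-3)

    def test_decayed_mass_consistent_mode(self, env):
        opts = FieldOptions(include_drift=False, include_decay=True,
                            ground_reflection=False)
        t = 0.25
        total = self._integral_consistent(t, env, opts)
        assert total == pytest.approx(0.0016 * math.exp(-decay_rate(env) * t),
                                      rel=5e-3)

    def test_peak_concentration_non_increasing(self, env, src):
        opts = FieldOptions(include_decay=False)
        # keep the drifting puff centre above ground
        ts = np.linspace(0.05, 1.5, 50)
        peaks = [puff_concentration(env.u * t, 0.0, src.H + vertical_drift(t, env),
                                    t, src, env, opts=opts) for t in ts]
        assert np.all(np.diff(peaks) <= 1e-18)

    def test_degenerate_limit_matches_isotropic_solution(self, env):
        """With equal lateral/vertical spreads the consistent-mode field
        reduces to the isotropic closed form with exponent
        -((x-ut)^2 + y^2)/(4r)."""
        c = 0.01
        sch = DispersionScheme(cy_num=c, cy_den=1e-12, cz_num=c, cz_den=1e-12,
                               normalization_mode="consistent")
        opts = FieldOptions(include_drift=False, include_decay=False)
        src = SourceEvent(m=0.0016, H=0.8)
        t, x, y, z = 0.4, 1.1, 0.2, 0.9
        r = c * (env.u * t) ** 2
        expected = (src.m / (4 * math.pi * r) ** 1.5
                    * math.exp(-((x - env.u * t) ** 2 + y**2) / (4 * r))
                    * (math.exp(-((z - src.H) ** 2) / (4 * r))
                       + math.exp(-((z + src.H) ** 2) / (4 * r))))
        got = puff_concentration(x, y, z, t, src, env, sch, opts)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_column_integral_matches_quadrature(self, env, src):
        """The closed-form vertical column integral agrees with dense
        pointwise quadrature of the field."""
        zs = np.linspace(0.55, 0.95, 4001)
        x, y, t = 1.0, 0.05, 0.34
        c = puff_concentration(x, y, zs, t, src, env)
        direct = np.trapezoid(c, zs)
        col = puff_column_integral(x, y, 0.55, 0.95, t, src, env)
        assert col == pytest.approx(direct, rel=1e-6)


class TestContinuous:
    def test_zero_rate(self, env):
        assert continuous_concentration(1.0, 0.0, 0.8, 1.0, 0.0, env) == 0.0

    def test_linearity_in_rate(self, env):
        c1 = continuous_concentration(1.0, 0.0, 0.78, 1.0, 1.0, env)
        c2 = continuous_concentration(1.0, 0.0, 0.78, 1.0, 2.0, env)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)
        assert c1 > 0

    def test_step_halving_converges(self, env):
        # reference point d = 1 m on the plume path
        z = 0.8 + vertical_drift(1.0 / env.u, env)
        a = continuous_concentration(1.0, 0.0, z, 1.5, 1.0, env, quad=0.001)
        b = continuous_concentration(1.0, 0.0, z, 1.5, 1.0, env, quad=0.0005)
        assert a == pytest.approx(b, rel=1e-2)

    def test_config_error(self, env):
        with pytest.raises(ValueError):
            continuous_concentration(1.0, 0.0, 0.8, 1.0, 1.0, env, quad=-0.1)
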