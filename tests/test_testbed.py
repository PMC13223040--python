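"""Corrected model, synthetic traces and B-parameter recovery."""

import numpy as np
import pytest

from bvocmc import (
    Environment,
    SourceEvent,
    FieldOptions,
    InterferenceGeometry,
    AttenuationParams,
    CorrectionParams,
    FixtureSpec,
    corrected_concentration,
    simulate_sensor_trace,
    CorrectionModel,
    fit_correction_params,
    attenuation_factor,
    puff_concentration,
    decay_rate,
)

GEOM = InterferenceGeometry(0.5, 0.5)
ATT = AttenuationParams()
TRUE = FixtureSpec().true_params


class TestCorrectedField:
    def test_reduces_to_attenuated_base_model(self, env):
        corr = CorrectionParams(b1=1, b2=1, b3=1, b4=decay_rate(env), b5=1)
        pts = [(1.2, 0.05, 0.7, 0.4), (0.6, -0.1, 0.35, 0.2),
               (2.0, 0.0, 0.5, 0.66)]
        for x, y, z, t in pts:
            lhs = corrected_concentration(x, y, z, t, SourceEvent(), env,
                                          GEOM, ATT, corr)
            rhs = attenuation_factor(GEOM, ATT) * puff_concentration(
                x, y, z, t, SourceEvent(), env)
            assert lhs == pytest.approx(rhs, rel=1e-14)

    def test_zero_amplitude(self, env):
        corr = CorrectionParams(b5=0.0)
        assert corrected_concentration(1.0, 0.0, 0.5, 0.4, SourceEvent(),
                                       env, GEOM, ATT, corr) == 0.0

    def test_linear_in_amplitude(self, env):
        c1 = corrected_concentration(1.0, 0.0, 0.75, 0.34, SourceEvent(),
                                     env, GEOM, ATT, CorrectionParams(b5=1.0))
        c2 = corrected_concentration(1.0, 0.0, 0.75, 0.34, SourceEvent(),
                                     env, GEOM, ATT, CorrectionParams(b5=2.5))
        assert c2 == pytest.approx(2.5 * c1, rel=1e-12)

    def test_literal_mode_bench_curve_unimodal(self, env):
        """Constant-spread variant with near-unity corrections: a finite,
        positive, unimodal distance profile at fixed time (bench scale)."""
        corr = CorrectionParams(b1=0.9731, b2=0.9413, b3=0.9853, b4=7.0579,
                                b5=0.8778)
        xs = np.linspace(0.0, 3.0, 120)
        c = corrected_concentration(xs, 0.0, 0.3, 1.0, SourceEvent(H=0.4),
                                    env.replace(u=0.0), GEOM, ATT, corr,
                                    param_mode="literal")
        assert np.all(np.isfinite(c)) and np.all(c >= 0) and c.max() > 0
        k = int(np.argmax(c))
        assert np.all(np.diff(c[: k + 1]) >= 0)
        assert np.all(np.diff(c[k:]) <= 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CorrectionParams(b1=0.0)
        with pytest.raises(ValueError):
            CorrectionParams(b4=-1.0)
        with pytest.raises(ValueError):
            corrected_concentration(1.0, 0.0, 0.5, 0.4, param_mode="bogus")


class TestTraceGenerator:
    def test_noiseless_trace_is_normalized_model(self, env):
        fix = FixtureSpec(noise_sd=0.0)
        tr = simulate_sensor_trace(fix, env, GEOM, ATT)
        model = CorrectionModel(tr, env, GEOM, ATT)
        pred = model.predict(fix.true_params.replace(b5=1.0))
        assert np.allclose(pred, tr.values, atol=1e-12)
        assert tr.values.max() == pytest.approx(1.0)

    def test_deterministic_given_seed(self, env):
        a = simulate_sensor_trace(FixtureSpec(seed=4), env, GEOM, ATT)
        b = simulate_sensor_trace(FixtureSpec(seed=4), env, GEOM, ATT)
        assert np.array_equal(a.values, b.values)

    def test_noise_calibration(self, env):
        fix = FixtureSpec(noise_sd=0.05, seed=9, n_points=400)
        noisy = simulate_sensor_trace(fix, env, GEOM, ATT)
        clean = simulate_sensor_trace(fix.replace(noise_sd=0.0), env, GEOM,
                                      ATT)
        ratio = noisy.values / clean.values
        sd = np.std(ratio / np.mean(ratio))
        assert sd == pytest.approx(0.05, rel=0.25)

    def test_degenerate_geometry_raises(self, env):
        # sensors far above the sinking plume see nothing
        fix = FixtureSpec(heights=(5.0, 6.0), noise_sd=0.0)
        with pytest.raises(ValueError, match="zero"):
            simulate_sensor_trace(fix, env, GEOM, ATT)

    def test_fixture_validation(self):
        with pytest.raises(ValueError):
            FixtureSpec(n_points=4)
        with pytest.raises(ValueError):
            FixtureSpec(u=0.0)


class TestFit:
    def test_noiseless_recovery_exact(self, env):
        tr = simulate_sensor_trace(FixtureSpec(noise_sd=0.0), env, GEOM, ATT)
        res = CorrectionModel(tr, env, GEOM, ATT).fit()
        est = res.params.as_array()[:4]
        assert np.max(np.abs(est / TRUE.as_array()[:4] - 1)) < 1e-2
        assert res.rsquared > 0.9999

    def test_recovery_within_5pct_at_2pct_noise(self, env):
        errs = []
        for seed in (0, 1, 2):
            tr = simulate_sensor_trace(FixtureSpec(seed=seed), env, GEOM, ATT)
            res = CorrectionModel(tr, env, GEOM, ATT).fit()
            errs.append(np.abs(res.params.as_array()[:4]
                               / TRUE.as_array()[:4] - 1))
            assert res.rsquared >= 0.99
        assert np.max(errs) < 0.05

    def test_far_init_multistart_reaches_same_optimum(self, env):
        tr = simulate_sensor_trace(FixtureSpec(seed=3), env, GEOM, ATT)
        far = CorrectionParams(b1=10.214, b2=10.047, b3=10.758, b4=75.994)
        res_far = CorrectionModel(tr, env, GEOM, ATT).fit(init=far,
                                                          multistart=10)
        res_near = CorrectionModel(tr, env, GEOM, ATT).fit()
        assert np.allclose(res_far.params.as_array(),
                           res_near.params.as_array(), rtol=1e-4)

    def test_b5_reported_non_identifiable(self, env):
        tr = simulate_sensor_trace(FixtureSpec(seed=1), env, GEOM, ATT)
        res = CorrectionModel(tr, env, GEOM, ATT).fit()
        assert res.b5_identifiable is False
        assert res.params.b5 == 1.0
        assert "not identifiable" in res.summary()

    def test_wrapper_returns_params_and_gof(self, env):
        tr = simulate_sensor_trace(FixtureSpec(seed=2), env, GEOM, ATT)
        params, gof = fit_correction_params(tr, env=env, geom=GEOM, att=ATT)
        assert gof.r2 > 0.99
        assert params.b4 > 0

    def test_too_short_trace_rejected(self, env):
        tr = simulate_sensor_trace(FixtureSpec(seed=1), env, GEOM, ATT)
        import dataclasses
        short = dataclasses.replace(
            tr, positions=tr.positions[:5], values=tr.values[:5],
            meta={**tr.meta, "z": tr.meta["z"][:5], "t": tr.meta["t"][:5]})
        with pytest.raises(ValueError, match="at least 6"):
            CorrectionModel(short, env, GEOM, ATT)
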