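"""Leakage-model fitting: integral operators, OLS, variable projection."""

import numpy as np
import pytest

from dscleak import (
    ValidationError,
    correct_curve,
    cumulative_integral,
    exp_weighted_integral,
    fit_bidirectional,
    fit_stack,
    fit_unidirectional,
)


class TestCumulativeIntegral:
    def test_hand_trapezoid(self):
        assert np.allclose(cumulative_integral(np.array([0.0, 2.0, 0.0]), 1.0),
                           [0.0, 1.0, 2.0])

    def test_constant_curve(self):
        c, dt = 3.0, 0.5
        out = cumulative_integral(np.full(10, c), dt)
        assert np.allclose(out, c * np.arange(10) * dt)

    def test_linearity(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        assert np.allclose(
            cumulative_integral(a + b, 1.1),
            cumulative_integral(a, 1.1) + cumulative_integral(b, 1.1),
        )


class TestExpWeightedIntegral:
    def test_kep_zero_equals_cumulative_exactly(self, reference):
        a = exp_weighted_integral(reference.values, reference.time_step, 0.0)
        b = cumulative_integral(reference.values, reference.time_step)
        assert np.array_equal(a, b)

    def test_constant_curve_relaxes_to_c_over_kep(self):
        c, kep = 2.0, 0.05
        out = exp_weighted_integral(np.full(3000, c), 1.0, kep)
        assert out[-1] == pytest.approx(c / kep, rel=1e-2)

    def test_impulse_decays_exponentially(self):
        y = np.zeros(30)
        y[5] = 4.0
        kep, dt = 0.3, 1.0
        out = exp_weighted_integral(y, dt, kep)
        post = out[7:]
        ratios = post[1:] / post[:-1]
        assert np.allclose(ratios, np.exp(-kep * dt))

    def test_vector_kep_rows_match_scalar_calls(self, reference):
        keps = np.array([-0.1, 0.0, 0.02, 0.5])
        block = exp_weighted_integral(reference.values, reference.time_step, keps)
        for i, k in enumerate(keps):
            single = exp_weighted_integral(reference.values, reference.time_step, float(k))
            assert np.array_equal(block[i], single)


class TestUnidirectionalFit:
    def test_self_fit(self, reference):
        fit = fit_unidirectional(reference.values, reference.values, reference.time_step)
        assert fit.k1 == pytest.approx(1.0, abs=1e-10)
        assert fit.k2 == pytest.approx(0.0, abs=1e-10)
        assert fit.converged

    def test_exact_recovery(self, reference):
        dt = reference.time_step
        voxel = 1.2 * reference.values - 0.03 * cumulative_integral(reference.values, dt)
        fit = fit_unidirectional(voxel, reference.values, dt)
        assert fit.k1 == pytest.approx(1.2, abs=1e-8)
        assert fit.k2 == pytest.approx(0.03, abs=1e-8)

    def test_zero_voxel(self, reference):
        fit = fit_unidirectional(np.zeros_like(reference.values),
                                 reference.values, reference.time_step)
        assert fit.k1 == 0.0 and fit.k2 == 0.0

    def test_zero_reference_not_converged(self, reference):
        fit = fit_unidirectional(reference.values,
                                 np.zeros_like(reference.values), reference.time_step)
        assert not fit.converged

    def test_ols_matches_lstsq_oracle_on_random_problems(self, reference, rng):
        """Closed-form normal equations vs an independent SVD least-squares
        solve, on 100 random problems."""
        dt = reference.time_step
        ref = reference.values
        X = np.column_stack([ref, -cumulative_integral(ref, dt)])
        for _ in range(100):
            voxel = rng.normal(0, 1, ref.shape) + rng.normal(1.5, 0.5) * ref
            fit = fit_unidirectional(voxel, ref, dt)
            beta, *_ = np.linalg.lstsq(X, voxel, rcond=None)
            assert fit.k1 == pytest.approx(beta[0], rel=1e-6, abs=1e-9)
            assert fit.k2 == pytest.approx(beta[1], rel=1e-6, abs=1e-9)


class TestBidirectionalFit:
    def test_exact_recovery_of_all_three_parameters(self, reference):
        dt = reference.time_step
        truth = (1.0, -0.05, 0.02)
        voxel = truth[0] * reference.values - truth[1] * exp_weighted_integral(
            reference.values, dt, truth[2]
        )
        fit = fit_bidirectional(voxel, reference.values, dt)
        assert fit.k1 == pytest.approx(truth[0], rel=1e-4)
        assert fit.k2 == pytest.approx(truth[1], rel=1e-4)
        assert fit.kep == pytest.approx(truth[2], rel=1e-4)

    def test_kep_zero_data_reproduces_unidirectional_exactly(self, reference):
        dt = reference.time_step
        voxel = 1.4 * reference.values - (-0.02) * cumulative_integral(reference.values, dt)
        uni = fit_unidirectional(voxel, reference.values, dt)
        bi = fit_bidirectional(voxel, reference.values, dt)
        assert bi.kep == 0.0
        assert bi.k1 == pytest.approx(uni.k1, abs=1e-8)
        assert bi.k2 == pytest.approx(uni.k2, abs=1e-8)

    def test_reference_self_fit(self, reference):
        fit = fit_bidirectional(reference.values, reference.values, reference.time_step)
        assert fit.k1 == pytest.approx(1.0, abs=1e-8)
        assert fit.k2 == pytest.approx(0.0, abs=1e-8)
        assert fit.kep == 0.0

    def test_nesting_never_worse_than_unidirectional(self, reference, rng):
        dt = reference.time_step
        n = 50
        k1 = rng.uniform(0.5, 3, n)
        k2 = rng.uniform(-0.08, 0.02, n)
        kep = rng.uniform(0, 0.08, n)
        leak = exp_weighted_integral(reference.values, dt, kep)
        V = k1[:, None] * reference.values - k2[:, None] * leak
        V = V + rng.normal(0, 0.5, V.shape)
        out = fit_stack(V, reference.values, dt, model="all")
        assert np.all(out["ss_res_bidir"] <= out["ss_res_unidir"] + 1e-10)

    def test_scale_equivariance(self, reference):
        dt = reference.time_step
        voxel = 0.9 * reference.values - (-0.04) * exp_weighted_integral(
            reference.values, dt, 0.03
        )
        f1 = fit_bidirectional(voxel, reference.values, dt)
        f2 = fit_bidirectional(5.0 * voxel, reference.values, dt)
        assert f2.k1 == pytest.approx(5 * f1.k1, rel=1e-6)
        assert f2.k2 == pytest.approx(5 * f1.k2, rel=1e-6)
        assert f2.kep == pytest.approx(f1.kep, rel=1e-4, abs=1e-8)


class TestCorrectCurve:
    def test_zero_k2_identity(self, reference):
        fit = fit_unidirectional(reference.values, reference.values, reference.time_step)
        out = correct_curve(reference.values, fit, reference.values, reference.time_step)
        assert np.allclose(out, reference.values, atol=1e-10)

    def test_forward_model_cancellation(self, reference):
        """Correcting a noiseless forward-model voxel must leave exactly
        K1 times the reference."""
        dt = reference.time_step
        voxel = 1.3 * reference.values - (-0.06) * cumulative_integral(reference.values, dt)
        fit = fit_unidirectional(voxel, reference.values, dt)
        out = correct_curve(voxel, fit, reference.values, dt)
        assert np.allclose(out, 1.3 * reference.values, atol=1e-6)

    def test_t2star_dominant_sign_convention(self, reference):
        """Elevated-tail voxel: fitted K2 < 0 and the corrected tail and
        bolus integral decrease."""
        dt = reference.time_step
        voxel = 1.0 * reference.values - (-0.05) * exp_weighted_integral(
            reference.values, dt, 0.02
        )
        fit = fit_bidirectional(voxel, reference.values, dt)
        assert fit.k2 < 0
        out = correct_curve(voxel, fit, reference.values, dt)
        assert out[-1] < voxel[-1]
        assert out.sum() < voxel.sum()

    def test_non_converged_fit_rejected(self, reference):
        fit = fit_unidirectional(reference.values,
                                 np.zeros_like(reference.values), reference.time_step)
        with pytest.raises(ValidationError):
            correct_curve(reference.values, fit, reference.values, reference.time_step)


def test_fit_range_too_short_rejected(reference):
    with pytest.raises(ValidationError):
        fit_unidirectional(reference.values, reference.values,
                           reference.time_step, fit_range=slice(0, 5))
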