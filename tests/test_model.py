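"""Super-resolution estimator: initialization, Jacobian, recovery, volume."""

import numpy as np
import pytest
from scipy.optimize._numdiff import approx_derivative

from sero import (
    FitConfig,
    ParameterColumn,
    SchemeConfig,
    ShotSignals,
    SuperResolutionModel,
    fit_column,
    fit_volume,
    generate_direct_scheme,
    generate_sero_scheme,
    local_fit_init,
    normalize_signals,
    predict_signal,
    regularization_residuals,
)


def homogeneous_column(n, s0=2.0, d=1.0, v=0.4, t1=1.2):
    return ParameterColumn(
        np.full(n, s0), np.full(n, d), np.full(n, v), np.full(n, t1)
    )


class TestNormalization:
    def test_scales_by_global_maximum(self):
        sig = ShotSignals(np.array([1.0, 4.0, 2.0]))
        out, c = normalize_signals(sig)
        assert c == 4.0
        np.testing.assert_allclose(out.values, [0.25, 1.0, 0.5])

    def test_identity_when_already_normalized(self):
        sig = ShotSignals(np.array([0.5, 1.0]))
        out, c = normalize_signals(sig)
        assert c == 1.0
        np.testing.assert_array_equal(out.values, sig.values)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_signals(ShotSignals(np.zeros(3)))

    def test_denormalized_s0_matches_unnormalized_fit(
        self, small_sero_scheme, small_phantom, small_noiseless
    ):
        """On noiseless data the fit is scale-equivariant: the S0 reported
        after normalization equals the S0 of a raw-scale fit."""
        cfg = FitConfig(lam=0.0)
        a = fit_column(small_noiseless, small_sero_scheme, cfg.with_(normalize=True))
        b = fit_column(
            small_noiseless,
            small_sero_scheme,
            cfg.with_(normalize=False, bounds={**cfg.bounds, "s0": (0.0, 40.0)}),
        )
        np.testing.assert_allclose(a.params.s0, b.params.s0, rtol=1e-4)


class TestRegularization:
    def test_constant_profiles_have_zero_penalty(self):
        params = homogeneous_column(10)
        assert np.all(regularization_residuals(params, 0.5) == 0)

    def test_single_step_contributes_lambda(self):
        params = homogeneous_column(6)
        params.d = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        r = regularization_residuals(params, lam=0.01)
        assert np.sum(r**2) == pytest.approx(0.01)

    def test_objective_gradient_matches_numeric(self, small_sero_scheme, small_phantom):
        sig = predict_signal(small_phantom, small_sero_scheme)
        model = SuperResolutionModel(
            sig, small_sero_scheme, FitConfig(lam=0.01, normalize=False)
        )
        y = sig.values[model._rows]
        rng = np.random.default_rng(0)
        x = model._pack(small_phantom) * rng.uniform(0.9, 1.1, 4 * model.n)

        def objective(z):
            r = model._residuals(z, y)
            return r @ r

        analytic = 2 * model._jacobian(x).T @ model._residuals(x, y)
        numeric = approx_derivative(objective, x, rel_step=1e-6)
        np.testing.assert_allclose(analytic, numeric, rtol=2e-4, atol=1e-8)


class TestJacobian:
    def test_matches_finite_differences(self, small_sero_scheme, small_phantom):
        sig = predict_signal(small_phantom, small_sero_scheme)
        model = SuperResolutionModel(
            sig, small_sero_scheme, FitConfig(lam=0.01, normalize=False)
        )
        y = sig.values[model._rows]
        rng = np.random.default_rng(1)
        x = model._pack(small_phantom) * rng.uniform(0.85, 1.15, 4 * model.n)
        J = model._jacobian(x)
        J_fd = approx_derivative(
            lambda z: model._residuals(z, y), x, rel_step=1e-7
        )
        assert np.max(np.abs(J - J_fd)) / np.max(np.abs(J)) < 1e-5


class TestLocalInit:
    def test_recovers_homogeneous_truth(self, sero_scheme):
        """The slice-averaged-TR approximation keeps the local init close
        to truth on a homogeneous noiseless column (it is a starting point,
        not an estimator, so only the average interior error is held)."""
        truth = homogeneous_column(50)
        sig = predict_signal(truth, sero_scheme)
        init, fallback = local_fit_init(sig, sero_scheme)
        assert not fallback.any()
        interior = slice(4, 46)
        assert np.mean(np.abs(init.s0[interior] / truth.s0[interior] - 1)) < 0.10
        assert np.mean(np.abs(init.d[interior] / truth.d[interior] - 1)) < 0.10

    def test_row_sum_scaling_makes_init_k_invariant(self):
        """Doubling the slice thickness leaves the initialized S0 at the
        sub-voxel scale (signals are divided by the W row sum).  Long shot
        spacing puts every sub-voxel near full relaxation, isolating the
        volume scaling from TR effects."""
        outs = []
        for k in (2, 4):
            cfg = SchemeConfig(
                n=16, k=k, m=200, shot_spacing=5.0, min_mean_tr=0.0, seed=6
            )
            sch = generate_sero_scheme(cfg)
            truth = homogeneous_column(16)
            init, _ = local_fit_init(predict_signal(truth, sch), sch)
            outs.append(init.s0.mean())
        assert outs[0] == pytest.approx(outs[1], rel=0.02)
        assert outs[0] == pytest.approx(2.0, rel=0.02)

    def test_underdetermined_position_falls_back(self):
        cfg = SchemeConfig(n=12, k=1, m=12, b_levels=(0.5,))
        sch = generate_direct_scheme(cfg)  # single b, single pass
        sig = ShotSignals(np.full(12, 1.0))
        init, fallback = local_fit_init(sig, sch)
        assert fallback.all()


class TestFitColumn:
    def test_noiseless_sero_recovery(self, small_sero_scheme, small_phantom, small_noiseless):
        res = fit_column(small_noiseless, small_sero_scheme, FitConfig(lam=0.0))
        assert res.converged
        k = small_sero_scheme.config.k
        interior = slice(k, small_sero_scheme.n - k)
        for (name, tru), (_, est) in zip(
            small_phantom.items(), res.params.items()
        ):
            np.testing.assert_allclose(
                est[interior], tru[interior], rtol=1e-2, err_msg=name
            )

    def test_noiseless_direct_with_frozen_true_t1(self, small_phantom):
        """With T1 fixed at truth, direct sampling recovers S0, D, V to
        1e-3 relative error; the frozen-T1 flag is raised automatically."""
        cfg = SchemeConfig(n=12, k=1, m=240)
        sch = generate_direct_scheme(cfg)
        sig = predict_signal(small_phantom, sch)
        res = fit_column(
            sig, sch, FitConfig(lam=0.0, t1_frozen_value=small_phantom.t1)
        )
        assert res.t1_frozen
        np.testing.assert_allclose(res.params.s0, small_phantom.s0, rtol=1e-3)
        np.testing.assert_allclose(res.params.d, small_phantom.d, rtol=1e-3)
        np.testing.assert_allclose(res.params.v, small_phantom.v, atol=5e-3)

    def test_direct_recovers_saturation_product(self, small_phantom):
        """With T1 frozen at a nominal value, the product
        S0 (1 - exp(-TR/T1)) is recovered exactly on noiseless data."""
        cfg = SchemeConfig(n=12, k=1, m=240)
        sch = generate_direct_scheme(cfg)
        sig = predict_signal(small_phantom, sch)
        res = fit_column(
            sig, sch, FitConfig(lam=0.0, exclude_first_coverage_shots=True)
        )
        tr = cfg.n * cfg.shot_spacing
        truth_product = small_phantom.s0 * -np.expm1(-tr / small_phantom.t1)
        est_product = res.params.s0 * -np.expm1(-tr / res.params.t1)
        np.testing.assert_allclose(est_product, truth_product, rtol=1e-3)

    def test_huge_lambda_flattens_profiles(self, small_sero_scheme, small_noiseless):
        res = fit_column(small_noiseless, small_sero_scheme, FitConfig(lam=1e6))
        for name, arr in res.params.items():
            assert np.max(np.abs(np.diff(arr))) < 1e-2, name

    def test_objective_never_increases_from_init(
        self, small_sero_scheme, small_noiseless
    ):
        model = SuperResolutionModel(
            small_noiseless, small_sero_scheme, FitConfig(lam=0.01)
        )
        res = model.fit()
        assert res.objective_value <= model.objective(res.init) + 1e-12

    def test_estimates_within_bounds(self, small_sero_scheme, small_noiseless):
        cfg = FitConfig(lam=0.01)
        noisy = ShotSignals(
            small_noiseless.values
            * np.random.default_rng(2).uniform(0.7, 1.3, small_noiseless.m)
        )
        res = fit_column(noisy, small_sero_scheme, cfg)
        for name, arr in res.params_normalized.items():
            lo, hi = cfg.bounds[name]
            assert arr.min() >= lo - 1e-12 and arr.max() <= hi + 1e-12

    def test_summary_mentions_key_diagnostics(
        self, small_sero_scheme, small_noiseless
    ):
        res = fit_column(small_noiseless, small_sero_scheme, FitConfig(lam=0.01))
        text = res.summary()
        assert "lambda: 0.01" in text
        assert "converged" in text
        for name in ("s0", "d", "v", "t1"):
            assert name in text

    def test_signal_length_mismatch_rejected(self, small_sero_scheme):
        with pytest.raises(ValueError):
            SuperResolutionModel(ShotSignals(np.ones(3)), small_sero_scheme)


class TestFitVolume:
    def test_identical_columns_identical_results(self, small_sero_scheme, small_phantom):
        sig = predict_signal(small_phantom, small_sero_scheme).values
        stack = np.broadcast_to(sig, (2, 2, sig.size)).copy()
        maps, qc = fit_volume(stack, small_sero_scheme, FitConfig(lam=0.01))
        for name, arr in maps.items():
            for ix in range(2):
                for iy in range(2):
                    np.testing.assert_array_equal(arr[ix, iy], arr[0, 0])
        assert qc.shape[0] == 4 and qc["converged"].all()

    def test_empty_columns_skipped(self, small_sero_scheme):
        stack = np.zeros((1, 2, small_sero_scheme.m))
        maps, qc = fit_volume(stack, small_sero_scheme)
        assert qc["empty"].all()
        assert np.all(maps["s0"] == 0)
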