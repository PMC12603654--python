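import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from durerp import (BasisSpec, KernelSpec, Signal, fit_model, make_kernel,
                    marginal_effects, render_continuous)
from durerp.design import time_expand_fir
from durerp.fit import _as_type_specs, _solve_gram, solve_least_squares
from conftest import make_events


class TestSparseSolver:
    def test_matches_dense_pseudoinverse(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        beta, _ = _solve_gram(sparse.csr_matrix(X), y[None, :])
        expected = np.linalg.pinv(X) @ y
        np.testing.assert_allclose(beta[:, 0], expected, atol=1e-8)

    def test_rank_deficient_returns_minimum_norm(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        X = np.hstack([X, X[:, :2]])  # duplicate columns -> rank 4
        y = rng.normal(size=30)
        beta, rank = _solve_gram(sparse.csr_matrix(X), y[None, :])
        expected = np.linalg.pinv(X) @ y
        np.testing.assert_allclose(beta[:, 0], expected, atol=1e-8)
        assert rank == 4

    def test_all_zero_column_warns_and_zeroes_coefficient(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 3))
        X[:, 1] = 0.0
        y = rng.normal(size=15)
        with pytest.warns(UserWarning, match="all-zero"):
            beta, _ = _solve_gram(sparse.csr_matrix(X), y[None, :])
        assert beta[1, 0] == 0.0

    def test_zero_response_gives_zero_coefficients(self, sfreq):
        ev = make_events([0.5, 0.6, 0.7])
        window = BasisSpec(0.0, 1.0, sfreq)
        specs = _as_type_specs(ev, "y ~ 1 + duration", window)
        D = time_expand_fir(ev, specs, sfreq, 1000)
        fit = solve_least_squares(D, Signal(np.zeros((1, 1000)), sfreq))
        for tf in fit.types.values():
            np.testing.assert_allclose(tf.coef, 0.0, atol=1e-12)


class TestModelFitting:
    def test_epoch_intercept_equals_epoch_mean(self, scaled_spec):
        ev = make_events(np.linspace(0.3, 1.5, 12))
        window = BasisSpec(-0.1, 2.0, 100.0)
        sig = render_continuous(ev, scaled_spec, total_padding=3.0)
        fit = fit_model(sig, ev, "y ~ 1", overlap_correction=False, window=window)
        coef = fit.single().coef[0, 0]
        # oracle: direct epoch average
        epochs = np.stack([
            sig.data[0, round(o * 100) - 10: round(o * 100) + 200]
            for o in ev["onset"]])
        np.testing.assert_allclose(coef, epochs.mean(axis=0), atol=1e-10)

    def test_deconvolution_recovers_two_overlapping_event_types(self, sfreq):
        """Two interleaved event types with known kernels, heavy overlap."""
        spec_a = KernelSpec("hanning", 0.5, sfreq)
        spec_b = KernelSpec("scaled_hanning", 0.5, sfreq, base_amplitude=0.7)
        rng = np.random.default_rng(11)
        onsets_a = 2.0 + np.cumsum(rng.uniform(0.8, 1.6, 40))
        onsets_b = onsets_a + rng.uniform(0.2, 0.5, 40)  # b overlaps a
        ev = pd.concat([
            pd.DataFrame({"onset": onsets_a, "duration": 0.5, "trial_type": "A"}),
            pd.DataFrame({"onset": onsets_b, "duration": 0.9, "trial_type": "B"}),
        ]).sort_values("onset").reset_index(drop=True)
        sig = render_continuous(ev, {"A": spec_a, "B": spec_b}, total_padding=2.0)
        win = BasisSpec(-0.1, 1.1, sfreq)
        fit = fit_model(sig, ev, {"A": "y ~ 1", "B": "y ~ 1"}, True, win)
        k_a = make_kernel(spec_a, 0.5)
        k_b = make_kernel(spec_b, 0.9)
        est_a = fit.types["A"].coef[0, 0, 10:10 + len(k_a)]
        est_b = fit.types["B"].coef[0, 0, 10:10 + len(k_b)]
        np.testing.assert_allclose(est_a, k_a, atol=1e-6)
        np.testing.assert_allclose(est_b, k_b, atol=1e-6)

    def test_epoch_averaging_keeps_overlap_contamination(self, sfreq):
        spec = KernelSpec("hanning", 0.5, sfreq)
        ev = make_events([0.5] * 30, spacing=0.4)  # 0.5 s kernels overlap
        sig = render_continuous(ev, spec, total_padding=2.0)
        win = BasisSpec(-0.1, 1.1, sfreq)
        fit = fit_model(sig, ev, "y ~ 1", overlap_correction=False, window=win)
        k = make_kernel(spec, 0.5)
        est = fit.single().coef[0, 0, 10:10 + len(k)]
        assert np.abs(est - k).max() > 0.05  # averaging cannot remove overlap
        fit_dc = fit_model(sig, ev, "y ~ 1", overlap_correction=True, window=win)
        est_dc = fit_dc.single().coef[0, 0, 10:10 + len(k)]
        assert np.abs(est_dc - k).max() < 1e-6

    def test_epoch_and_fir_agree_for_isolated_events(self, distinct_duration_sim):
        signal, events, durs, window = distinct_duration_sim
        f_mu = fit_model(signal, events, "y ~ 1 + bin(duration, 15)", False, window)
        f_dc = fit_model(signal, events, "y ~ 1 + bin(duration, 15)", True, window)
        np.testing.assert_allclose(f_mu.single().coef, f_dc.single().coef,
                                   atol=1e-8)

    def test_event_order_permutation_invariance(self, distinct_duration_sim):
        signal, events, durs, window = distinct_duration_sim
        shuffled = events.sample(frac=1.0, random_state=9)
        f1 = fit_model(signal, events, "y ~ 1 + duration", True, window)
        f2 = fit_model(signal, shuffled, "y ~ 1 + duration", True, window)
        np.testing.assert_allclose(f1.single().coef, f2.single().coef, atol=1e-9)

    def test_nested_models_never_increase_fit_residual(self, distinct_duration_sim):
        signal, events, durs, window = distinct_duration_sim
        rss = {}
        for f in ("y ~ 1", "y ~ 1 + duration", "y ~ 1 + spl(duration, 5)"):
            fit = fit_model(signal, events, f, True, window)
            rss[f] = fit.diagnostics["residual_ss"][0]
        assert rss["y ~ 1 + duration"] <= rss["y ~ 1"] + 1e-9
        assert rss["y ~ 1 + spl(duration, 5)"] <= rss["y ~ 1 + duration"] + 1e-9

    def test_output_shape_identical_across_modes(self, distinct_duration_sim):
        signal, events, durs, window = distinct_duration_sim
        for formula in ("y ~ 1", "y ~ 1 + spl(duration, 5)"):
            a = fit_model(signal, events, formula, False, window).single()
            b = fit_model(signal, events, formula, True, window).single()
            assert a.coef.shape == b.coef.shape
            assert a.column_labels == b.column_labels


class TestSerialization:
    def test_fit_roundtrip_preserves_predictions(self, distinct_duration_sim, tmp_path):
        signal, events, durs, window = distinct_duration_sim
        fit = fit_model(signal, events, "y ~ 1 + spl(duration, 5)", True, window)
        path = tmp_path / "coef.tsv"
        fit.save(path)
        from durerp.fit import FitResult
        loaded = FitResult.load(path)
        np.testing.assert_allclose(loaded.single().coef, fit.single().coef,
                                   rtol=1e-9, atol=1e-12)
        e1 = marginal_effects(fit, durs)
        e2 = marginal_effects(loaded, durs)
        np.testing.assert_allclose(e2.curves, e1.curves, rtol=1e-8, atol=1e-9)
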