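import numpy as np
import pandas as pd
import pytest

from durerp import BasisSpec, TermSpec, parse_formula, winsorize
from durerp.design import (BSplineEncoder, CategoricalEncoder, build_epoch_design,
                           time_expand_fir)
from durerp.fit import _as_type_specs
from conftest import make_events


class TestFormulaParsing:
    @pytest.mark.parametrize("formula,expected", [
        ("y ~ 1", [("1", "intercept", None)]),
        ("y ~ 1 + duration", [("1", "intercept", None), ("duration", "linear", None)]),
        ("y ~ 1 + bin(duration, 10)", [("1", "intercept", None),
                                       ("duration", "categorical", 10)]),
        ("y ~ 1 + spl(duration, 5) + sac_amplitude",
         [("1", "intercept", None), ("duration", "bspline", 5),
          ("sac_amplitude", "linear", None)]),
    ])
    def test_wilkinson_terms(self, formula, expected):
        terms = parse_formula(formula)
        assert [(t.covariate, t.encoding, t.param) for t in terms] == expected

    def test_malformed_formula_rejected(self):
        with pytest.raises(ValueError):
            parse_formula("y ~ 1 + spl(duration)")
        with pytest.raises(ValueError):
            TermSpec("x", "categorical", 1)
        with pytest.raises(ValueError):
            TermSpec("x", "bspline", 2)


class TestEncoders:
    def test_linear_encoding_is_identity(self):
        from durerp import encode_duration
        cols, labels, enc = encode_duration(TermSpec("x", "linear"),
                                            np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(cols[:, 0], [1, 2, 3])
        assert labels == ["x"]

    def test_categorical_equal_count_bins(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(np.arange(100, dtype=float))
        enc = CategoricalEncoder("x", 10).fit(values)
        cols = enc.transform(values)
        assert cols.shape == (100, 9)
        counts = np.bincount(enc.assign(values), minlength=10)
        np.testing.assert_array_equal(counts, np.full(10, 10))
        assert set(np.unique(cols)) <= {0.0, 1.0}

    def test_categorical_right_closed_edges(self):
        enc = CategoricalEncoder("x", 4).fit(np.arange(1.0, 13.0))
        # values at edges fall into the lower bin; out-of-range values clamp
        assert enc.assign([enc.edges_[0]])[0] == 0
        assert enc.assign([enc.edges_[0] + 0.01])[0] == 1
        assert enc.assign([-100.0])[0] == 0
        assert enc.assign([100.0])[0] == 3

    def test_categorical_tied_values_keep_equal_counts(self):
        # 40% of values tied at the floor: rank-based bins stay equal-count
        values = np.concatenate([np.full(20, 0.2), np.linspace(0.3, 1.0, 30)])
        enc = CategoricalEncoder("x", 5).fit(values)
        counts = np.bincount(enc.train_bins_, minlength=5)
        np.testing.assert_array_equal(counts, np.full(5, 10))

    def test_categorical_tie_heavy_values_error_names_covariate(self):
        with pytest.raises(ValueError, match="reaction_time"):
            CategoricalEncoder("reaction_time", 5).fit(np.ones(50))

    def test_bspline_partition_of_unity(self):
        rng = np.random.default_rng(1)
        values = rng.gamma(2.0, 0.4, 300)
        for df in (4, 5, 10):
            enc = BSplineEncoder("x", df).fit(values)
            basis = enc.basis(np.linspace(values.min(), values.max(), 211))
            assert basis.shape[1] == df
            np.testing.assert_allclose(basis.sum(axis=1), 1.0, atol=1e-10)
            assert basis.min() >= 0 and basis.max() <= 1 + 1e-12

    def test_bspline_drops_one_column(self):
        values = np.linspace(0.1, 2.0, 60)
        enc = BSplineEncoder("x", 5).fit(values)
        assert enc.transform(values).shape == (60, 4)

    def test_bspline_clamps_outside_knot_span(self):
        enc = BSplineEncoder("x", 5).fit(np.linspace(0.5, 1.5, 50))
        lo = enc.transform([0.0])
        np.testing.assert_allclose(lo, enc.transform([0.5]), atol=1e-12)


class TestWinsorize:
    def test_inside_range_unchanged_and_degenerate_identity(self):
        v = np.array([10.0, 20.0, 30.0])
        np.testing.assert_array_equal(winsorize(v, 0, 100), v)

    def test_clips_to_percentiles(self):
        v = np.arange(1.0, 101.0)
        out = winsorize(v, 5, 95)
        assert out.min() == pytest.approx(np.percentile(v, 5))
        assert out.max() == pytest.approx(np.percentile(v, 95))
        inner = (v > np.percentile(v, 5)) & (v < np.percentile(v, 95))
        np.testing.assert_array_equal(out[inner], v[inner])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            winsorize(np.arange(10.0), 60, 40)


class TestEpochDesign:
    def test_shapes_and_intercept(self, sfreq):
        ev = make_events(np.linspace(0.3, 1.0, 20))
        window = BasisSpec(-0.1, 1.5, sfreq)
        terms = parse_formula("y ~ 1 + duration")
        ed = build_epoch_design(ev, terms, window)
        assert ed.matrix.shape == (20, 2)
        np.testing.assert_array_equal(ed.matrix[:, 0], 1.0)

    def test_out_of_bounds_events_dropped(self, sfreq):
        ev = make_events([0.5] * 10, spacing=2.0)
        window = BasisSpec(-0.1, 1.5, sfreq)
        # signal ends at 16 s: onsets 18 and 20 s have epochs beyond the end
        n_samples = int(16 * sfreq)
        ed = build_epoch_design(ev, parse_formula("y ~ 1"), window, n_samples)
        expected_dropped = int(np.sum(ev["onset"] + 1.5 > 16.0))
        assert ed.n_dropped == expected_dropped == 3
        assert ed.matrix.shape[0] == 7


class TestFIRTimeExpansion:
    def test_single_event_intercept_diagonal(self, sfreq):
        ev = make_events([0.5], start=1.0)
        window = BasisSpec(0.0, 0.3, sfreq)
        specs = _as_type_specs(ev, "y ~ 1", window)
        D = time_expand_fir(ev, specs, sfreq, 200)
        assert D.matrix.nnz == 30
        rows, cols = D.matrix.nonzero()
        np.testing.assert_array_equal(rows, 100 + np.arange(30))
        np.testing.assert_array_equal(cols, np.arange(30))
        assert np.all(D.matrix.data == 1.0)

    def test_nnz_counting(self, sfreq):
        # E events x n_lags x term columns, no truncation/coincidence
        ev = make_events([0.4, 0.6, 0.8], spacing=5.0)
        window = BasisSpec(-0.1, 1.0, sfreq)
        specs = _as_type_specs(ev, "y ~ 1 + duration", window)
        D = time_expand_fir(ev, specs, sfreq, 3000)
        assert D.matrix.nnz == 3 * window.n_lags * 2

    def test_two_event_types_concatenate_columns(self, sfreq):
        ev = pd.concat([make_events([0.5, 0.5], trial_type="fixation"),
                        make_events([0.5, 0.5], start=2.3, trial_type="stimulus")]
                       ).sort_values("onset").reset_index(drop=True)
        specs = {"fixation": (parse_formula("y ~ 1"), BasisSpec(0, 0.8, sfreq)),
                 "stimulus": (parse_formula("y ~ 1"), BasisSpec(0, 0.4, sfreq))}
        D = time_expand_fir(ev, specs, sfreq, 2000)
        assert D.matrix.shape[1] == 80 + 40
        assert set(D.column_meta["event_type"]) == {"fixation", "stimulus"}

    def test_boundary_rows_truncated_not_wrapped(self, sfreq):
        ev = make_events([0.5], start=0.05)
        window = BasisSpec(-0.1, 0.5, sfreq)
        specs = _as_type_specs(ev, "y ~ 1", window)
        D = time_expand_fir(ev, specs, sfreq, 500)
        rows, _ = D.matrix.nonzero()
        assert rows.min() >= 0
        assert D.n_truncated == 5  # five pre-onset lags fall before sample 0

    def test_column_meta_covers_all_columns_once(self, sfreq):
        ev = make_events(np.linspace(0.3, 1.2, 10))
        window = BasisSpec(-0.1, 1.0, sfreq)
        specs = _as_type_specs(ev, "y ~ 1 + spl(duration, 5)", window)
        D = time_expand_fir(ev, specs, sfreq, 5000)
        assert len(D.column_meta) == D.matrix.shape[1]
        assert D.column_meta[["basis_index", "lag"]].duplicated().sum() == 0
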