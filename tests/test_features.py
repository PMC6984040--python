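"""Feature extractors: signed areas, spectra, correlations, lags, DTW."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import sinusoid_panel
from rsfi.features import (
    FeatureExtractor,
    correlation_matrix,
    cyclic_order_equal,
    cyclicity_spectrum,
    dtw_distance,
    dtw_matrix,
    lagged_correlation,
    lead_matrix,
    matricize,
    recover_ordering,
    vectorize_upper,
)
from rsfi.preprocess import end_match


class TestLeadMatrix:
    def test_identical_rows_give_zero_area(self, rng):
        x = end_match(rng.standard_normal((1, 100)))[0]
        lm = lead_matrix(np.vstack([x, x]))
        np.testing.assert_allclose(lm.values, 0.0, atol=1e-12)

    def test_quarter_phase_circle_area(self):
        # f = cos, g = sin (= cos delayed by pi/2): unit circle, area pi
        X = sinusoid_panel([0.0, np.pi / 2], n_time=300)
        lm = lead_matrix(X, end_matched=True)
        assert abs(abs(lm.values[0, 1]) - np.pi) < 0.01 * np.pi

    def test_sign_convention_follower_is_positive(self):
        # row 1 delayed by pi/4 behind row 0 -> A[0, 1] = +pi*sin(pi/4)
        X = sinusoid_panel([0.0, np.pi / 4], n_time=300)
        lm = lead_matrix(X, end_matched=True)
        expected = np.pi * np.sin(np.pi / 4)
        assert abs(lm.values[0, 1] - expected) < 0.01 * expected
        assert lm.values[1, 0] == -lm.values[0, 1]

    def test_requires_end_matched_input(self, rng):
        X = rng.standard_normal((3, 50))
        with pytest.raises(ValueError, match="end-match"):
            lead_matrix(X)
        lead_matrix(X, end_matched=True)  # flag enforces it internally

    def test_translation_invariance(self, rng):
        X = end_match(rng.standard_normal((4, 120)))
        shifted = X + rng.standard_normal(4)[:, None]
        np.testing.assert_allclose(
            lead_matrix(shifted).values, lead_matrix(X).values, atol=1e-10
        )

    def test_time_reversal_flips_sign(self, rng):
        X = end_match(rng.standard_normal((5, 200)))
        fwd = lead_matrix(X).values
        rev = lead_matrix(X[:, ::-1]).values
        np.testing.assert_allclose(rev, -fwd, atol=1e-9)


class TestCyclicitySpectrum:
    def test_zero_matrix_degenerate(self):
        lm = lead_matrix(np.zeros((4, 10)))
        spec = cyclicity_spectrum(lm)
        assert spec.degenerate
        with pytest.raises(ValueError, match="degenerate"):
            recover_ordering(spec)

    def test_phase_shifted_sinusoids_are_rank_two(self):
        X = sinusoid_panel([0.0, 0.9, 1.7, 2.8, 4.1, 5.3], n_time=400)
        spec = cyclicity_spectrum(lead_matrix(X, end_matched=True))
        mags = np.abs(spec.eigenvalues)
        assert mags[2] < 1e-6 * mags[0]

    def test_eigenvalues_purely_imaginary(self, rng):
        X = end_match(rng.standard_normal((6, 150)))
        spec = cyclicity_spectrum(lead_matrix(X))
        mags = np.abs(spec.eigenvalues)
        assert np.abs(spec.eigenvalues.real).max() < 1e-8 * mags.max()

    def test_recover_ordering_matches_planted(self):
        offsets = np.array([0, np.pi / 3, 2 * np.pi / 3, np.pi,
                            4 * np.pi / 3, 5 * np.pi / 3])
        X = sinusoid_panel(offsets, n_time=600)
        order = recover_ordering(cyclicity_spectrum(lead_matrix(X, end_matched=True)))
        assert cyclic_order_equal(order, np.argsort(offsets))

    def test_time_reversal_reverses_order(self):
        offsets = np.array([0.0, 0.9, 1.7, 2.8, 4.1, 5.3])
        X = sinusoid_panel(offsets, n_time=600)
        fwd = recover_ordering(cyclicity_spectrum(lead_matrix(X, end_matched=True)))
        rev = recover_ordering(
            cyclicity_spectrum(lead_matrix(X[:, ::-1], end_matched=True))
        )
        assert cyclic_order_equal(rev, fwd[::-1])

    def test_tied_phases_stay_adjacent(self):
        offsets = np.array([0.0, 1.2, 1.2, 2.9])
        X = sinusoid_panel(offsets, n_time=600)
        order = recover_ordering(
            cyclicity_spectrum(lead_matrix(X, end_matched=True))
        ).tolist()
        pos = {roi: i for i, roi in enumerate(order)}
        assert abs(pos[1] - pos[2]) == 1


class TestCorrelation:
    def test_known_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        pairs = np.vstack([x, 2 * x + 1, -x, np.array([1.0, 3.0, 2.0, 4.0])])
        R = correlation_matrix(pairs).values
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)
        assert R[0, 3] == pytest.approx(0.8)

    def test_constant_row_names_roi(self):
        X = np.vstack([np.arange(5.0), np.full(5, 1.0)])
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(X, roi_names=["good", "flat"])


class TestLaggedCorrelation:
    def test_self_pair_zero_lag_unit_correlation(self, rng):
        x = np.cumsum(rng.standard_normal(200))
        res = lagged_correlation(np.vstack([x, x]), max_lag=5, tr=2.0)
        assert res.tdm[0, 1] == 0.0
        assert res.lcm[0, 1] == pytest.approx(1.0)

    def test_delayed_copy_recovers_delay(self, rng):
        from scipy.ndimage import gaussian_filter1d

        x = gaussian_filter1d(rng.standard_normal(400), 6)
        y = np.roll(x, 3)  # y follows x by 3 samples
        X = np.vstack([x, y])[:, 50:350]
        res = lagged_correlation(X, max_lag=5, tr=2.0)
        assert res.tdm[0, 1] == pytest.approx(6.0)  # positive: y follows x
        assert res.lcm[0, 1] >= 0.99
        assert res.tdm[1, 0] == pytest.approx(-6.0)

    def test_quarter_period_sinusoids(self):
        t = np.arange(200)
        x = np.sin(2 * np.pi * t / 20)
        y = np.sin(2 * np.pi * t / 20 - np.pi / 2)
        res = lagged_correlation(np.vstack([x, y]), max_lag=8, tr=1.0)
        assert abs(res.tdm[0, 1]) == pytest.approx(5.0)

    def test_parabolic_refinement_stays_close_to_peak(self, rng):
        from scipy.ndimage import gaussian_filter1d

        x = gaussian_filter1d(rng.standard_normal(400), 6)
        X = np.vstack([x, np.roll(x, 2)])[:, 50:350]
        coarse = lagged_correlation(X, max_lag=5, tr=1.0)
        fine = lagged_correlation(X, max_lag=5, tr=1.0, interpolate="parabolic")
        assert abs(fine.tdm[0, 1] - coarse.tdm[0, 1]) < 1.0
        assert np.abs(fine.tdm + fine.tdm.T).max() == 0.0

    def test_max_lag_bounds_enforced(self, rng):
        X = rng.standard_normal((2, 40))
        with pytest.raises(ValueError, match="max_lag"):
            lagged_correlation(X, max_lag=10)


def _dtw_oracle(x, y):
    """Exponential-time recursion on the accumulated-cost definition."""

    def rec(k, j):
        d = abs(x[k] - y[j])
        if k == 0 and j == 0:
            return d
        if k == 0:
            return d + rec(0, j - 1)
        if j == 0:
            return d + rec(k - 1, 0)
        return d + min(rec(k - 1, j), rec(k - 1, j - 1), rec(k, j - 1))

    return rec(len(x) - 1, len(y) - 1)


class TestDtw:
    def test_identical_series_zero_distance_diagonal_path(self, rng):
        x = rng.standard_normal(20)
        d, path = dtw_distance(x, x)
        assert d == 0.0
        assert path == [(i, i) for i in range(20)]

    def test_textbook_example(self):
        d, _ = dtw_distance(np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0]))
        assert d == 1.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
    )
    def test_dp_equals_recursive_oracle(self, xs, ys):
        x, y = np.array(xs, dtype=float), np.array(ys, dtype=float)
        d, _ = dtw_distance(x, y)
        assert d == pytest.approx(_dtw_oracle(x, y), abs=1e-12)

    def test_bounded_by_aligned_cost(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        d, _ = dtw_distance(x, y)
        assert d <= np.sum(np.abs(x - y)) + 1e-12

    def test_matrix_symmetry_zero_diagonal_and_homogeneity(self, rng):
        X = rng.standard_normal((4, 40))
        D = dtw_matrix(X).values
        np.testing.assert_array_equal(np.diag(D), 0.0)
        np.testing.assert_allclose(D, D.T)
        D3 = dtw_matrix(3.0 * X).values
        np.testing.assert_allclose(D3, 3.0 * D, rtol=1e-12)

    def test_band_window_validation_and_effect(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        d_free, _ = dtw_distance(x, y)
        d_band, _ = dtw_distance(x, y, window=2)
        assert d_band >= d_free
        with pytest.raises(ValueError, match="empty"):
            dtw_distance(np.array([]), y)


class TestVectorize:
    def test_length_528_for_33_rois(self, rng):
        M = rng.standard_normal((33, 33))
        assert vectorize_upper(M).size == 528

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(3, 12))
    def test_symmetric_and_skew_round_trips(self, n):
        rng = np.random.default_rng(n)
        v = rng.standard_normal(n * (n - 1) // 2)
        S = matricize(v, "dtw")
        np.testing.assert_allclose(vectorize_upper(S), v)
        np.testing.assert_allclose(S, S.T)
        A = matricize(v, "skew")
        np.testing.assert_allclose(vectorize_upper(A), v)
        np.testing.assert_allclose(A, -A.T)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            vectorize_upper(np.zeros((3, 4)))


def test_feature_extractor_transforms_stack(small_panel):
    _, panel = small_panel
    X = [r.matrix for r in panel.records[:3]]
    out = FeatureExtractor(kind="lead").transform(X)
    assert out.shape == (3, 8 * 7 // 2)
    out2 = FeatureExtractor(kind="lead").fit_transform(X)
    np.testing.assert_array_equal(out, out2)
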