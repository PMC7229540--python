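"""Fine locator: matrix-product window vs zero-padding oracle, searches."""

import numpy as np
import pytest

from subshift import (
    ShiftVector,
    UpsampleConfig,
    apply_shift,
    bidirectional_search,
    correlation_surface,
    cross_power_spectrum,
    dft_row_factor,
    evaluate_window_rows,
    forward_spectrum,
    full_window_argmax,
    make_phantom,
    make_shifted_pair,
    make_window,
    upsampled_value,
)
from subshift.fine import _exp_factor, _is_unimodal

from conftest import zeropad_upsampled_values


def _cross(reference, moving, normalized=True):
    return cross_power_spectrum(
        forward_spectrum(reference), forward_spectrum(moving), normalized=normalized
    )


class TestUpsampleConfig:
    def test_window_and_step(self):
        cfg = UpsampleConfig(epsilon=100)
        assert cfg.window_size == 150
        assert cfg.step == 30

    def test_small_epsilon_window_floor(self):
        assert UpsampleConfig(epsilon=2).window_size == 3
        assert UpsampleConfig(epsilon=2).step == 1

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError, match="window"):
            UpsampleConfig(epsilon=1)
        with pytest.raises(ValueError):
            UpsampleConfig(epsilon=0)
        with pytest.raises(ValueError, match="step"):
            UpsampleConfig(epsilon=10, step_fraction=1.0)


class TestDftRowFactor:
    def test_zero_lag_row_is_ones(self):
        cfg = UpsampleConfig(epsilon=4)
        w = cfg.window_size
        row = dft_row_factor(cfg, 0.0, 16, [w // 2])  # lag exactly 0
        assert np.allclose(row, 1.0)

    def test_conjugate_symmetry_of_opposite_lags(self):
        a_plus = _exp_factor(np.array([0.3]), 16)
        a_minus = _exp_factor(np.array([-0.3]), 16)
        assert np.abs(a_plus - np.conj(a_minus)).max() < 1e-12

    def test_integer_lags_reproduce_plain_correlation(self, rng):
        """At integer lags the exponential rows give the fft2 surface values."""
        arr1 = rng.standard_normal((12, 12))
        arr2 = rng.standard_normal((12, 12))
        p = _cross(arr1, arr2, normalized=False)
        surf = correlation_surface(p).values
        a = _exp_factor(np.arange(12, dtype=float), 12)  # integer row lags
        c = _exp_factor(np.arange(12, dtype=float), 12)
        product = (a @ p.values @ c.T) / (12 * 12)
        assert np.abs(product.real - surf).max() < 1e-8 * np.abs(surf).max()

    def test_out_of_range_rows(self):
        cfg = UpsampleConfig(epsilon=4)
        with pytest.raises(ValueError):
            dft_row_factor(cfg, 0.0, 16, [cfg.window_size])


class TestUpsampledValue:
    def test_identity_pair_at_origin(self, ramp_image):
        p = _cross(ramp_image, ramp_image)
        val = upsampled_value(p, 0.0, 0.0)
        assert val.real == pytest.approx(16 * 16)
        assert abs(val.imag) < 1e-9

    def test_integer_lag_matches_surface(self, rng):
        arr1 = rng.standard_normal((10, 14))
        arr2 = rng.standard_normal((10, 14))
        p = _cross(arr1, arr2, normalized=False)
        surf = correlation_surface(p).values
        for dy, dx in [(0, 0), (3, 5), (9, 13), (7, 0)]:
            val = upsampled_value(p, float(dy), float(dx)).real / (10 * 14)
            assert val == pytest.approx(surf[dy, dx], abs=1e-8 * abs(surf).max())

    def test_grid_point_matches_zeropad_oracle(self, rng):
        arr1 = rng.standard_normal((8, 8))
        arr2 = rng.standard_normal((8, 8))
        p = _cross(arr1, arr2)
        eps = 4
        oracle = zeropad_upsampled_values(p.values, eps)
        for j1, j2 in [(0, 0), (5, 30), (17, 2), (31, 31)]:
            val = upsampled_value(p, j1 / eps, j2 / eps)
            assert abs(val - oracle[j1, j2]) < 1e-8 * np.abs(oracle).max()


class TestWindowEvaluation:
    def test_full_fill_matches_one_shot_product(self, phantom64):
        truth = ShiftVector(0.3, -0.2)
        case = make_shifted_pair(phantom64, truth)
        p = _cross(case.reference, case.moving)
        cfg = UpsampleConfig(epsilon=10)
        w = make_window(p, ShiftVector(0.0, 0.0), cfg)
        evaluate_window_rows(p, w, np.arange(w.size))
        # one-shot three-matrix product
        a = dft_row_factor(cfg, 0.0, 64, np.arange(w.size))
        c = dft_row_factor(cfg, 0.0, 64, np.arange(w.size))  # square image: same rule
        oneshot = a @ p.values @ c.T
        assert np.abs(w.values - oneshot).max() < 1e-10 * max(1.0, np.abs(oneshot).max())

    def test_repeated_request_is_noop(self, phantom64):
        p = _cross(phantom64, phantom64)
        cfg = UpsampleConfig(epsilon=10)
        w = make_window(p, ShiftVector(0.0, 0.0), cfg)
        evaluate_window_rows(p, w, [3, 4])
        before = (w.values.copy(), w.evaluations)
        evaluate_window_rows(p, w, [3, 4])
        assert w.evaluations == before[1]
        assert np.array_equal(w.values, before[0])

    def test_rows_match_zeropad_oracle(self, rng):
        """Every filled row equals the corresponding oracle row (on-grid center)."""
        arr1 = rng.standard_normal((16, 16))
        arr2 = np.roll(arr1, (2, 1), axis=(0, 1))
        p = _cross(arr1, arr2)
        cfg = UpsampleConfig(epsilon=8)
        center = ShiftVector(2.0, 1.0)
        w = make_window(p, center, cfg)
        evaluate_window_rows(p, w, [0, 5, 11])
        oracle = zeropad_upsampled_values(p.values, 8)
        half = w.size // 2
        for r in (0, 5, 11):
            for c in range(w.size):
                j1 = int(round((center.dy * 8 + r - half))) % (16 * 8)
                j2 = int(round((center.dx * 8 + c - half))) % (16 * 8)
                assert abs(w.values[r, c] - oracle[j1, j2]) < 1e-8 * np.abs(oracle).max()


class TestFullWindowArgmax:
    def test_evaluations_is_w_squared(self, phantom64):
        p = _cross(phantom64, phantom64)
        cfg = UpsampleConfig(epsilon=10)
        peak = full_window_argmax(p, ShiftVector(0.0, 0.0), cfg)
        assert peak.evaluations == cfg.window_size**2

    def test_window_block_matches_global_zeropad(self, rng):
        """Acceptance-grade oracle equivalence on one instance (more in
        test_acceptance): window == block of the globally upsampled surface."""
        arr1 = rng.standard_normal((16, 16))
        arr2 = np.roll(arr1, (3, -2), axis=(0, 1))
        p = _cross(arr1, arr2)
        eps = 6
        cfg = UpsampleConfig(epsilon=eps)
        center = ShiftVector(3.0, -2.0)
        w = make_window(p, center, cfg)
        evaluate_window_rows(p, w, np.arange(w.size))
        oracle = zeropad_upsampled_values(p.values, eps)
        half = w.size // 2
        n1 = n2 = 16 * eps
        rowsel = (np.arange(w.size) - half + int(center.dy * eps)) % n1
        colsel = (np.arange(w.size) - half + int(center.dx * eps)) % n2
        block = oracle[np.ix_(rowsel, colsel)]
        assert np.abs(w.values - block).max() < 1e-8 * np.abs(oracle).max()

    def test_residual_fraction_recovered_at_eps2(self, phantom64):
        truth = ShiftVector(2.5, -1.5)
        case = make_shifted_pair(phantom64, truth)
        p = _cross(case.reference, case.moving)
        peak = full_window_argmax(p, ShiftVector(2.0, -1.0), UpsampleConfig(epsilon=2))
        est = (2.0 + peak.offset_pixels[0], -1.0 + peak.offset_pixels[1])
        assert abs(est[0] - truth.dy) <= 0.5
        assert abs(est[1] - truth.dx) <= 0.5


class TestBidirectionalSearch:
    def test_peak_at_center_found_quickly(self, phantom64):
        p = _cross(phantom64, phantom64)
        cfg = UpsampleConfig(epsilon=100)
        peak = bidirectional_search(p, ShiftVector(0.0, 0.0), cfg)
        assert peak.offset_pixels == (0.0, 0.0)
        assert not peak.used_fallback
        assert peak.evaluations < cfg.window_size**2

    def test_fractional_shift_to_hundredth_pixel(self):
        phantom = make_phantom((128, 128), seed=21)
        truth = ShiftVector(0.34, -0.27)
        case = make_shifted_pair(phantom, truth)
        p = _cross(case.reference, case.moving)
        peak = bidirectional_search(p, ShiftVector(0.0, 0.0), UpsampleConfig(epsilon=100))
        assert abs(peak.offset_pixels[0] - truth.dy) <= 0.01
        assert abs(peak.offset_pixels[1] - truth.dx) <= 0.01

    def test_matches_full_argmax_on_unimodal_window(self, phantom64, rng):
        cfg = UpsampleConfig(epsilon=50)
        for _ in range(5):
            truth = ShiftVector(*(rng.uniform(-0.4, 0.4, 2)))
            case = make_shifted_pair(phantom64, truth)
            p = _cross(case.reference, case.moving)
            fast = bidirectional_search(p, ShiftVector(0.0, 0.0), cfg)
            full = full_window_argmax(p, ShiftVector(0.0, 0.0), cfg)
            assert fast.offset_upsampled == full.offset_upsampled
            assert fast.evaluations < full.evaluations

    def test_degenerate_window_falls_back(self):
        """An all-equal window cannot be bracketed; full evaluation kicks in."""
        from subshift.core import CrossSpectrum

        vals = np.zeros((16, 16), dtype=complex)
        vals[0, 0] = 1.0  # constant surface: correlation flat
        p = CrossSpectrum(vals, normalized=True)
        peak = bidirectional_search(p, ShiftVector(0.0, 0.0), UpsampleConfig(epsilon=10))
        assert peak.used_fallback
        assert peak.evaluations == peak.window_size**2

    @pytest.mark.parametrize("eps", [10, 100, 1000])
    def test_quantization_bound(self, eps, phantom64, rng):
        """|estimate - truth| <= 1/eps per axis on noiseless band-limited pairs."""
        cfg = UpsampleConfig(epsilon=eps)
        for _ in range(3):
            truth = ShiftVector(*(rng.uniform(-0.45, 0.45, 2)))
            case = make_shifted_pair(phantom64, truth)
            p = _cross(case.reference, case.moving)
            peak = bidirectional_search(p, ShiftVector(0.0, 0.0), cfg)
            assert abs(peak.offset_pixels[0] - truth.dy) <= 1.0 / eps + 1e-6
            assert abs(peak.offset_pixels[1] - truth.dx) <= 1.0 / eps + 1e-6


def test_is_unimodal_helper():
    assert _is_unimodal([1.0, 3.0, 2.0])
    assert _is_unimodal([3.0, 2.0, 1.0])
    assert _is_unimodal([1.0, 2.0, 3.0])
    assert not _is_unimodal([1.0, 2.0, 1.0, 2.0])
    assert not _is_unimodal([2.0, 2.0, 1.0])
    assert not _is_unimodal([])
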