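import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specocc.preprocess import (
    PreprocessConfig,
    PreprocessError,
    apply_preprocess,
    msc,
    normalize,
    savgol,
    snv,
)

from conftest import make_set


def brute_savgol(y, x, window, polyorder, deriv):
    """Independent local-polynomial least-squares oracle (per position)."""
    from math import factorial

    n = y.size
    half = window // 2
    out = np.empty(n)
    for j in range(n):
        lo, hi = max(0, j - half), min(n, j + half + 1)
        if hi - lo < polyorder + 1:
            if lo == 0:
                hi = polyorder + 1
            else:
                lo = n - (polyorder + 1)
        coeffs = np.polyfit(x[lo:hi] - x[j], y[lo:hi], polyorder)
        out[j] = coeffs[::-1][deriv] * factorial(deriv) if deriv <= polyorder else 0.0
    return out


class TestSNV:
    def test_three_point_example(self):
        out = snv(make_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.intensities[0], [-1.0, 0.0, 1.0])

    def test_constant_row_errors_with_sample_name(self):
        with pytest.raises(PreprocessError, match="s0"):
            snv(make_set([[5.0, 5.0, 5.0]]))

    def test_rows_standardized(self, rng):
        out = snv(make_set(rng.standard_normal((20, 100))))
        assert np.abs(out.intensities.mean(axis=1)).max() < 1e-12
        assert np.abs(out.intensities.std(axis=1, ddof=1) - 1).max() < 1e-12

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((3, 40))
        base = snv(make_set(x)).intensities
        mapped = snv(make_set(a * x + b)).intensities
        np.testing.assert_allclose(mapped, base, atol=1e-9)


class TestMSC:
    def test_exact_affine_recovers_reference(self, rng):
        ref = rng.standard_normal(30)
        out = msc(make_set([2 * ref + 3]), reference=ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-12)

    def test_identity_on_reference_itself(self, rng):
        ref = rng.standard_normal(30)
        out = msc(make_set([ref]), reference=ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-12)

    def test_ols_oracle_on_noisy_family(self, rng):
        ref = np.sin(np.linspace(0, 6, 200)) + 2
        rows, slopes, intercepts = [], [], []
        for _ in range(15):
            b, a = rng.uniform(0.5, 2), rng.uniform(-1, 1)
            rows.append(b * ref + a + rng.normal(0, 1e-6, ref.size))
        out = msc(make_set(rows), reference=ref).intensities
        for row in out:
            slope, intercept = np.polyfit(ref, row, 1)
            assert abs(slope - 1) < 1e-4
            assert abs(intercept) < 1e-4

    def test_offset_invariance(self, rng):
        ref = rng.standard_normal(30) + 5
        x = rng.standard_normal((4, 30)) + ref
        base = msc(make_set(x), reference=ref).intensities
        shifted = msc(make_set(x + 7.0), reference=ref).intensities
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_constant_reference_rejected(self):
        with pytest.raises(PreprocessError, match="constant"):
            msc(make_set([[1.0, 2.0, 3.0]]), reference=np.ones(3))


class TestNormalize:
    def test_max_mode(self):
        out = normalize(make_set([[2.0, 4.0]]), mode="max")
        np.testing.assert_allclose(out.intensities[0], [0.5, 1.0])

    def test_area_mode(self):
        out = normalize(make_set([[1.0, 3.0]]), mode="area")
        np.testing.assert_allclose(out.intensities[0], [0.25, 0.75])

    def test_area_rows_sum_to_one(self, rng):
        out = normalize(make_set(rng.standard_normal((10, 60))), mode="area")
        np.testing.assert_allclose(np.abs(out.intensities).sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(PreprocessError):
            normalize(make_set([[0.0, 0.0]]), mode="max")


class TestSavgol:
    def test_quadratic_first_derivative_exact(self):
        w = np.linspace(0, 10, 101)
        y = w**2
        out = savgol(make_set([y], wavenumbers=w), window=7, polyorder=2,
                     deriv_order=1)
        np.testing.assert_allclose(out.intensities[0], 2 * w, atol=1e-8)

    def test_constant_signal_derivative_is_zero(self):
        out = savgol(make_set([np.full(50, 3.0)]), window=9, polyorder=2,
                     deriv_order=1)
        np.testing.assert_allclose(out.intensities[0], 0.0, atol=1e-10)

    def test_identity_when_polyorder_saturates_window(self, rng):
        y = rng.standard_normal(40)
        out = savgol(make_set([y]), window=5, polyorder=4, deriv_order=0)
        np.testing.assert_allclose(out.intensities[0], y, atol=1e-8)

    @pytest.mark.parametrize("window,polyorder,deriv", [(7, 2, 0), (7, 2, 1),
                                                        (9, 3, 2), (5, 2, 1)])
    def test_matches_brute_force_oracle(self, rng, window, polyorder, deriv):
        w = np.arange(0.0, 60.0, 1.5)
        y = rng.standard_normal(w.size)
        out = savgol(make_set([y], wavenumbers=w), window, polyorder, deriv)
        oracle = brute_savgol(y, w, window, polyorder, deriv)
        np.testing.assert_allclose(out.intensities[0], oracle, atol=1e-8)

    def test_descending_axis_derivative_sign(self, rng):
        w = np.linspace(0, 10, 101)
        y = 3.0 * w
        asc = savgol(make_set([y], wavenumbers=w), 7, 2, 1).intensities[0]
        desc = savgol(make_set([y[::-1]], wavenumbers=w[::-1]), 7, 2, 1).intensities[0]
        np.testing.assert_allclose(asc, 3.0, atol=1e-8)
        np.testing.assert_allclose(desc, 3.0, atol=1e-8)

    def test_non_uniform_axis_rejected(self, rng):
        w = np.array([0.0, 1.0, 2.5, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(PreprocessError, match="uniform"):
            savgol(make_set([np.zeros(7)], wavenumbers=w), 5, 2, 0)

    def test_window_exceeding_axis_rejected(self):
        with pytest.raises(PreprocessError, match="window"):
            savgol(make_set([[1.0, 2.0, 3.0]]), 5, 2, 0)


class TestConfig:
    @pytest.mark.parametrize("kw", [dict(window=4), dict(window=1),
                                    dict(window=5, polyorder=5),
                                    dict(polyorder=1, deriv_order=2)])
    def test_invalid_savgol_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            PreprocessConfig(method="savgol", **{"polyorder": 2, **kw})

    def test_apply_dispatch_preserves_shape_and_pairing(self, small_set):
        for method in ["none", "snv", "msc", "normalize", "smooth"]:
            out = apply_preprocess(PreprocessConfig(method=method, window=5),
                                   small_set)
            assert out.intensities.shape == small_set.intensities.shape
            assert out.sample_ids == small_set.sample_ids
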