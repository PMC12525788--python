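import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirseed.io import GridError, SpectraSet
from nirseed.preprocess import (
    DegenerateSpectrumError,
    MathTreatment,
    apply_math_treatment,
    detrend,
    gap_segment_derivative,
    snv,
)


def brute_gap_derivative(x, grid, d, gap, s1, s2):
    """Independent loop-based oracle: average each point over the centered
    segment, then difference symmetric stencil points, trimming edges."""
    x = list(map(float, x))
    grid = list(map(float, grid))

    def smooth(v, g, s):
        if s == 1:
            return v, g
        half = (s - 1) // 2
        out = [sum(v[i - half:i + half + 1]) / s
               for i in range(half, len(v) - half)]
        return out, g[half:len(g) - half]

    def diff(v, g, gap):
        h = int(np.floor(gap / 2 + 0.5))
        dl = (g[1] - g[0]) * 2 * h
        out = [(v[i + h] - v[i - h]) / dl for i in range(h, len(v) - h)]
        return out, g[h:len(g) - h]

    x, grid = smooth(x, grid, s1)
    x, grid = smooth(x, grid, s2)
    for _ in range(d):
        x, grid = diff(x, grid, gap)
    return np.array(x), np.array(grid)


class TestSNV:
    def test_three_point_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0], atol=1e-12)

    def test_alternating_example(self):
        # mean 0.25, sample SD sqrt(0.03)
        out = snv(np.array([0.4, 0.1, 0.4, 0.1]))
        expect = np.array([0.15, -0.15, 0.15, -0.15]) / np.sqrt(0.03)
        np.testing.assert_allclose(out, expect, atol=1e-4)
        assert abs(out[0] - 0.8660) < 1e-4

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            snv(np.array([5.0, 5.0, 5.0]))

    @settings(deadline=None, max_examples=50)
    @given(arrays(np.float64, st.integers(5, 80),
                  elements=st.floats(-10, 10, allow_nan=False),
                  unique=True))
    def test_output_standardized(self, x):
        out = snv(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1.0) < 1e-10


class TestDetrend:
    def test_annihilates_exact_quadratic(self, small_grid):
        x = 2.0 + 0.003 * small_grid + 1e-6 * small_grid**2
        out = detrend(x, small_grid, order=2)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_residual_mean_zero(self, small_grid, rng):
        x = rng.normal(size=small_grid.size)
        for order in (0, 1, 2, 3):
            assert abs(detrend(x, small_grid, order).mean()) < 1e-10

    def test_quadratic_plus_orthogonal_wave_recovers_wave(self, small_grid):
        # Gram-Schmidt the sine against {1, λ, λ²} by explicit inner
        # products (independent of the least-squares path under test)
        sine = np.sin(2 * np.pi * (small_grid - 1100) / 100)
        t = (small_grid - small_grid.mean()) / small_grid.std()
        basis = []
        for b in (np.ones_like(t), t, t**2):
            for q in basis:
                b = b - (q @ b) * q
            basis.append(b / np.sqrt(b @ b))
        wave = sine.copy()
        for q in basis:
            wave = wave - (q @ wave) * q
        x = (1.0 + 0.002 * small_grid + 2e-7 * small_grid**2) + wave
        out = detrend(x, small_grid, order=2)
        np.testing.assert_allclose(out, wave, atol=1e-6)

    def test_rank_error(self):
        with pytest.raises(np.linalg.LinAlgError):
            detrend(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
                    order=2)


class TestGapSegmentDerivative:
    def test_affine_second_derivative_zero(self, small_grid):
        x = 1.3 + 0.004 * small_grid
        d, g = gap_segment_derivative(x, small_grid, 2, 5, 5, 1)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        assert g[0] > small_grid[0] and g[-1] < small_grid[-1]

    @pytest.mark.parametrize("gap,s1,s2", [(5, 5, 1), (4, 3, 3), (2, 1, 1)])
    def test_quadratic_gives_analytic_constant(self, small_grid, gap, s1, s2):
        a = 3e-6
        d, _ = gap_segment_derivative(a * small_grid**2, small_grid,
                                      2, gap, s1, s2)
        np.testing.assert_allclose(d, 2 * a, rtol=1e-9)

    def test_identity_treatment(self, small_grid, rng):
        x = rng.normal(size=small_grid.size)
        d, g = gap_segment_derivative(x, small_grid, 0, 1, 1, 1)
        np.testing.assert_array_equal(d, x)
        np.testing.assert_array_equal(g, small_grid)

    @pytest.mark.parametrize("d,gap,s1,s2", [
        (1, 5, 5, 1), (1, 4, 3, 1), (2, 5, 5, 1), (2, 3, 5, 3),
    ])
    def test_matches_brute_force_oracle(self, small_grid, rng, d, gap, s1, s2):
        x = rng.normal(size=small_grid.size)
        ours, og = gap_segment_derivative(x, small_grid, d, gap, s1, s2)
        ref, rg = brute_gap_derivative(x, small_grid, d, gap, s1, s2)
        np.testing.assert_array_equal(og, rg)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_linearity(self, small_grid, rng):
        x, y = rng.normal(size=(2, small_grid.size))
        dx, _ = gap_segment_derivative(x, small_grid, 2, 5, 5, 1)
        dy, _ = gap_segment_derivative(y, small_grid, 2, 5, 5, 1)
        dz, _ = gap_segment_derivative(2.5 * x - 3 * y, small_grid, 2, 5, 5, 1)
        np.testing.assert_allclose(dz, 2.5 * dx - 3 * dy, atol=1e-10)

    def test_stencil_too_large(self):
        with pytest.raises(ValueError):
            gap_segment_derivative(np.arange(4.0), np.arange(4.0) * 2 + 1100,
                                   2, 5, 1, 1)


class TestMathTreatment:
    def test_tuple_validation(self):
        with pytest.raises(ValueError):
            MathTreatment(derivative_order=3)
        with pytest.raises(ValueError):
            MathTreatment(smooth1=4)
        MathTreatment(smooth2=1)  # 1 = no second pass

    def test_serialization_round_trip(self):
        mt = MathTreatment(snv=True, detrend=True, derivative_order=2,
                           gap=5, smooth1=5, smooth2=1, window=(1100, 2498))
        assert MathTreatment.from_dict(mt.to_dict()) == mt

    def test_snv_only_equals_snv(self, tiny_set):
        mt = MathTreatment(snv=True, detrend=False, derivative_order=0,
                           gap=1, smooth1=1, smooth2=1, window=None)
        out = apply_math_treatment(tiny_set, mt)
        np.testing.assert_allclose(out.absorbance, snv(tiny_set.absorbance),
                                   atol=1e-12)

    def test_window_point_count(self):
        grid = np.arange(400.0, 2500.0, 2.0)
        rng = np.random.default_rng(0)
        s = SpectraSet(grid, rng.normal(0.5, 0.1, (2, grid.size)),
                       np.array(["a", "b"], dtype=object), [2021, 2021])
        mt = MathTreatment(snv=False, detrend=False, derivative_order=0,
                           gap=1, smooth1=1, smooth2=1, window=(1100, 2498))
        out = apply_math_treatment(s, mt)
        assert out.n_points == 700

    def test_identity_treatment_is_noop(self, tiny_set):
        out = apply_math_treatment(tiny_set, MathTreatment.identity())
        np.testing.assert_array_equal(out.absorbance, tiny_set.absorbance)

    def test_permutation_equivariance(self, tiny_set, rng):
        mt = MathTreatment()
        perm = rng.permutation(len(tiny_set))
        a = apply_math_treatment(tiny_set, mt).absorbance[perm]
        b = apply_math_treatment(tiny_set.subset(perm), mt).absorbance
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_window_outside_grid(self, tiny_set):
        with pytest.raises(GridError):
            apply_math_treatment(tiny_set, MathTreatment(window=(400, 2498)))

    def test_constant_spectrum_names_culprit(self, small_grid):
        a = np.vstack([np.full(small_grid.size, 0.7),
                       np.linspace(0, 1, small_grid.size)])
        s = SpectraSet(small_grid, a, np.array(["flat", "ok"], dtype=object),
                       [2021, 2021])
        with pytest.raises(DegenerateSpectrumError, match="flat"):
            apply_math_treatment(s, MathTreatment(window=None))
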