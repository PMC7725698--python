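"""Time-domain precision measures: frozen hand computations, geometric
invariances, and the exact finite-length signal-type bound."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gazenoise import (
    DegenerateSegmentError,
    GazeSegment,
    InvalidSegmentError,
    UndefinedSignalTypeError,
    bcea,
    bcea_ellipse,
    points_inside_bcea_ellipse,
    rms_s2s,
    signal_magnitude,
    signal_type,
    signal_type_bound,
    sqrt_bcea,
    std_2d,
    summarize,
)


def seg(x, y=None, fs=100.0):
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros_like(x)
    return GazeSegment(x=x, y=y, fs=fs)


class TestRmsS2S:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0, 1, 2, 3], [0, 0, 0, 0], 1.0),  # three unit steps
            ([2, 2, 2, 2], [5, 5, 5, 5], 0.0),  # constant
            ([0, 1, 0, 1], [0, 0, 0, 0], 1.0),  # alternating unit steps
            ([0, 0, 0], [0, 3, 7], math.sqrt((9 + 16) / 2)),  # vertical only
        ],
    )
    def test_hand_computed(self, x, y, expected):
        assert rms_s2s(seg(x, y)) == pytest.approx(expected, abs=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(InvalidSegmentError):
            seg([1.0])

    def test_non_finite_raises(self):
        with pytest.raises(InvalidSegmentError):
            seg([0.0, np.nan, 1.0])

    def test_equals_std_of_mean_zero_steps(self, rng):
        # RMS of steps equals the STD of the step sequence when the
        # steps have zero mean: construct such a sequence explicitly.
        steps = rng.standard_normal(400)
        steps -= steps.mean()
        x = np.concatenate(([0.0], np.cumsum(steps)))
        # RMS-S2S averages the 400 squared steps; with zero-mean steps
        # that is exactly the population STD of the step sequence.
        assert rms_s2s(seg(x)) == pytest.approx(np.std(steps), rel=1e-12)


class TestStd2D:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0, 1, 2], [0, 0, 0], math.sqrt(2.0 / 3.0)),  # 1/n denominator
            ([3, 3, 3], [1, 1, 1], 0.0),
            ([0, 1, 0, 1], [0, 0, 0, 0], 0.5),
        ],
    )
    def test_hand_computed(self, x, y, expected):
        assert std_2d(seg(x, y)) == pytest.approx(expected, abs=1e-12)

    def test_population_denominator(self, rng):
        x = rng.standard_normal(17)
        y = rng.standard_normal(17)
        expected = math.sqrt(np.var(x) + np.var(y))  # ddof=0
        assert std_2d(seg(x, y)) == pytest.approx(expected, rel=1e-12)


class TestBcea:
    def test_orthogonal_unit_variance(self):
        # sigma_x = sigma_y = 1, rho = 0, k = 1 -> 2*pi exactly
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert bcea(seg(x, y), k=1.0) == pytest.approx(2 * math.pi, rel=1e-12)

    def test_perfectly_correlated_is_zero(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert bcea(seg(x, x.copy())) == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_axis_raises(self):
        with pytest.raises(DegenerateSegmentError):
            bcea(seg([0, 1, 2], [5, 5, 5]))

    def test_k_scales_area_linearly(self, rng):
        s = seg(rng.standard_normal(50), rng.standard_normal(50))
        assert bcea(s, k=2.0) == pytest.approx(2 * bcea(s, k=1.0), rel=1e-12)

    def test_isotropic_matches_2kpi_sigma2(self, rng):
        sigma = 0.3
        s = seg(rng.normal(0, sigma, 20000), rng.normal(0, sigma, 20000))
        assert bcea(s) == pytest.approx(2 * math.pi * sigma**2, rel=0.05)

    def test_containment_fraction(self, rng):
        pts = rng.standard_normal((200000, 2))
        s = GazeSegment(x=pts[:, 0], y=pts[:, 1], fs=100.0)
        frac = points_inside_bcea_ellipse(s).mean()
        assert frac == pytest.approx(1 - math.exp(-1), abs=0.01)


class TestBceaEllipse:
    @staticmethod
    def _diag_cov_data():
        # sample covariance exactly diag(4, 1)
        x = 2.0 * np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        return x, y

    def test_axis_aligned(self):
        x, y = self._diag_cov_data()
        ell = bcea_ellipse(seg(x, y))
        assert ell.lambda1 == pytest.approx(4.0, rel=1e-12)
        assert ell.lambda2 == pytest.approx(1.0, rel=1e-12)
        assert ell.aspect_ratio == pytest.approx(2.0, rel=1e-12)
        assert ell.orientation == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("angle", [math.pi / 6, -math.pi / 5, math.pi / 2])
    def test_rotated_recovers_angle(self, angle):
        x, y = self._diag_cov_data()
        c, s = math.cos(angle), math.sin(angle)
        ell = bcea_ellipse(seg(c * x - s * y, s * x + c * y))
        expected = angle if angle <= math.pi / 2 else angle - math.pi
        assert ell.aspect_ratio == pytest.approx(2.0, rel=1e-9)
        assert ell.orientation == pytest.approx(expected, abs=1e-9)
        assert -math.pi / 2 < ell.orientation <= math.pi / 2

    def test_isotropic_aspect_ratio_near_one(self, rng):
        s = seg(rng.standard_normal(50000), rng.standard_normal(50000))
        assert bcea_ellipse(s).aspect_ratio == pytest.approx(1.0, abs=0.05)

    def test_collinear_raises(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(DegenerateSegmentError):
            bcea_ellipse(seg(x, 2 * x))


class TestCompositeMeasures:
    def test_pythagorean(self):
        assert signal_magnitude(3.0, 4.0) == pytest.approx(5.0)
        assert signal_magnitude(0.0, 0.7) == pytest.approx(0.7)

    def test_negative_input_raises(self):
        with pytest.raises(InvalidSegmentError):
            signal_magnitude(-1.0, 1.0)
        with pytest.raises(InvalidSegmentError):
            signal_type(-1.0, 1.0)

    def test_alternating_segment(self):
        s = seg([0, 1, 0, 1])
        r, d = rms_s2s(s), std_2d(s)
        assert signal_type(r, d) == pytest.approx(2.0, abs=1e-12)
        assert signal_magnitude(r, d) == pytest.approx(math.sqrt(1.25), rel=1e-12)

    def test_zero_std_raises(self):
        with pytest.raises(UndefinedSignalTypeError):
            signal_type(1.0, 0.0)

    def test_slow_ramp_is_strongly_colored(self):
        s = seg(np.linspace(0, 1, 500))
        assert signal_type(rms_s2s(s), std_2d(s)) < 0.1  # far below sqrt(2)

    def test_white_noise_near_sqrt2(self, rng):
        s = seg(rng.standard_normal(5000), rng.standard_normal(5000))
        assert signal_type(rms_s2s(s), std_2d(s)) == pytest.approx(
            math.sqrt(2), abs=0.05
        )

    def test_summarize_consistency(self, rng):
        s = seg(rng.standard_normal(256), rng.standard_normal(256), fs=250.0)
        out = summarize(s, with_alpha=True)
        assert out.signal_magnitude**2 == pytest.approx(
            out.rms_s2s**2 + out.std**2, rel=1e-12
        )
        assert out.sqrt_bcea == pytest.approx(sqrt_bcea(s), rel=1e-12)
        assert out.alpha is not None and math.isfinite(out.alpha)


finite_xy = hnp.arrays(
    np.float64,
    st.integers(min_value=4, max_value=64).map(lambda n: (2, n)),
    elements=st.floats(-100, 100, allow_nan=False, width=64),
)


class TestInvariants:
    @given(data=finite_xy)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_signal_type_within_exact_bound(self, data):
        """The step/spread ratio never exceeds the path-Laplacian bound
        2*cos(pi/2n)*sqrt(n/(n-1)), which tends to the nominal limit 2."""
        x, y = data
        s = GazeSegment(x=x, y=y, fs=100.0)
        d = std_2d(s)
        if d == 0.0:
            return
        t = signal_type(rms_s2s(s), d)
        assert 0.0 <= t <= signal_type_bound(len(s)) + 1e-9

    @given(data=finite_xy, dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_translation_invariance(self, data, dx, dy):
        x, y = data
        a = GazeSegment(x=x, y=y, fs=100.0)
        b = GazeSegment(x=x + dx, y=y + dy, fs=100.0)
        assert rms_s2s(a) == pytest.approx(rms_s2s(b), rel=1e-6, abs=1e-9)
        assert std_2d(a) == pytest.approx(std_2d(b), rel=1e-6, abs=1e-9)

    @given(angle=st.floats(-math.pi, math.pi))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rotation_invariance(self, angle):
        rng = np.random.default_rng(99)
        x, y = rng.standard_normal(64), rng.standard_normal(64)
        a = GazeSegment(x=x, y=y, fs=100.0)
        c, s = math.cos(angle), math.sin(angle)
        b = GazeSegment(x=c * x - s * y, y=s * x + c * y, fs=100.0)
        assert rms_s2s(a) == pytest.approx(rms_s2s(b), rel=1e-9)
        assert std_2d(a) == pytest.approx(std_2d(b), rel=1e-9)

    def test_magnitude_identity(self, rng):
        for _ in range(20):
            s = seg(rng.standard_normal(30), rng.standard_normal(30))
            r, d = rms_s2s(s), std_2d(s)
            assert signal_magnitude(r, d) ** 2 == pytest.approx(
                r**2 + d**2, rel=1e-12
            )
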