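import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import latgraph as lg
from latgraph._viridis import VIRIDIS_TABLE
from latgraph.metric import ColorDifferenceParams

# Published CIEDE2000 verification pairs (L*, a*, b*) x 2 with reference
# difference values, covering the hue-discontinuity and compensation-term
# branches of the formula.
CIEDE2000_PAIRS = [
    (50.0000, 2.6772, -79.7751, 50.0000, 0.0000, -82.7485, 2.0425),
    (50.0000, 3.1571, -77.2803, 50.0000, 0.0000, -82.7485, 2.8615),
    (50.0000, 2.8361, -74.0200, 50.0000, 0.0000, -82.7485, 3.4412),
    (50.0000, -1.3802, -84.2814, 50.0000, 0.0000, -82.7485, 1.0000),
    (50.0000, -1.1848, -84.8006, 50.0000, 0.0000, -82.7485, 1.0000),
    (50.0000, -0.9009, -85.5211, 50.0000, 0.0000, -82.7485, 1.0000),
    (50.0000, 0.0000, 0.0000, 50.0000, -1.0000, 2.0000, 2.3669),
    (50.0000, -1.0000, 2.0000, 50.0000, 0.0000, 0.0000, 2.3669),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0009, 7.1792),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0010, 7.1792),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0011, 7.2195),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0012, 7.2195),
    (50.0000, -0.0010, 2.4900, 50.0000, 0.0009, -2.4900, 4.8045),
    (50.0000, -0.0010, 2.4900, 50.0000, 0.0010, -2.4900, 4.8045),
    (50.0000, -0.0010, 2.4900, 50.0000, 0.0011, -2.4900, 4.7461),
    (50.0000, 2.5000, 0.0000, 50.0000, 0.0000, -2.5000, 4.3065),
    (50.0000, 2.5000, 0.0000, 73.0000, 25.0000, -18.0000, 27.1492),
    (50.0000, 2.5000, 0.0000, 61.0000, -5.0000, 29.0000, 22.8977),
    (50.0000, 2.5000, 0.0000, 56.0000, -27.0000, -3.0000, 31.9030),
    (50.0000, 2.5000, 0.0000, 58.0000, 24.0000, 15.0000, 19.4535),
    (50.0000, 2.5000, 0.0000, 50.0000, 3.1736, 0.5854, 1.0000),
    (50.0000, 2.5000, 0.0000, 50.0000, 3.2972, 0.0000, 1.0000),
    (50.0000, 2.5000, 0.0000, 50.0000, 1.8634, 0.5757, 1.0000),
    (50.0000, 2.5000, 0.0000, 50.0000, 3.2592, 0.3350, 1.0000),
    (60.2574, -34.0099, 36.2677, 60.4626, -34.1751, 39.4387, 1.2644),
    (63.0109, -31.0961, -5.8663, 62.8187, -29.7946, -4.0864, 1.2630),
    (61.2901, 3.7196, -5.3901, 61.4292, 2.2480, -4.9620, 1.8731),
    (35.0831, -44.1164, 3.7933, 35.0232, -40.0716, 1.5901, 1.8645),
    (22.7233, 20.0904, -46.6940, 23.0331, 14.9730, -42.5619, 2.0373),
    (36.4612, 47.8580, 18.3852, 36.2715, 50.5065, 21.2231, 1.4146),
    (90.8027, -2.0831, 1.4410, 91.1528, -1.6435, 0.0447, 1.4441),
    (90.9257, -0.5406, -0.9208, 88.6381, -0.8985, -0.7239, 1.5381),
    (6.7747, -0.2908, -2.4247, 5.8714, -0.0985, -2.2286, 0.6377),
    (2.0776, 0.0795, -1.1350, 0.9033, -0.0636, -0.5514, 0.9082),
]


class TestLatToColor:
    def test_endpoints(self):
        crange = lg.ColormapRange(-100.0, 0.0)
        assert np.allclose(lg.lat_to_color(np.array([-100.0]), crange)[0], VIRIDIS_TABLE[0])
        assert np.allclose(lg.lat_to_color(np.array([0.0]), crange)[0], VIRIDIS_TABLE[-1])

    def test_clamping(self):
        crange = lg.ColormapRange(-100.0, 0.0)
        low = lg.lat_to_color(np.array([-1100.0]), crange)
        assert np.allclose(low[0], VIRIDIS_TABLE[0])
        high = lg.lat_to_color(np.array([500.0]), crange)
        assert np.allclose(high[0], VIRIDIS_TABLE[-1])

    def test_midpoint_interpolates_table(self):
        crange = lg.ColormapRange(0.0, 1.0)
        got = lg.lat_to_color(np.array([0.5]), crange)[0]
        x = 0.5 * 255
        frac = x - 127
        expected = (1 - frac) * VIRIDIS_TABLE[127] + frac * VIRIDIS_TABLE[128]
        assert np.allclose(got, expected, atol=1e-12)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            lg.ColormapRange(0.0, 0.0)


class TestSrgbToLab:
    def test_white_black_gray(self):
        lab = lg.srgb_to_lab(np.array([[1.0, 1, 1], [0.0, 0, 0], [0.5, 0.5, 0.5]]))
        assert lab[0, 0] == pytest.approx(100.0, abs=0.01)
        assert abs(lab[0, 1]) <= 0.01 and abs(lab[0, 2]) <= 0.01
        assert np.abs(lab[1]).max() <= 1e-9
        assert lab[2, 0] == pytest.approx(53.39, abs=0.01)

    def test_matches_reference_colorimetry(self):
        from skimage.color import rgb2lab

        rng = np.random.default_rng(0)
        rgb = rng.random((200, 3))
        ours = lg.srgb_to_lab(rgb)
        ref = rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3)
        # reference derives its sRGB matrix from primaries at full precision;
        # ours uses the standard published 7-digit coefficients
        assert np.abs(ours - ref).max() <= 0.01

    def test_lightness_bounds_on_colormap(self):
        lab = lg.srgb_to_lab(VIRIDIS_TABLE)
        assert lab[:, 0].min() >= -1e-9 and lab[:, 0].max() <= 100 + 1e-9


class TestCiede2000:
    @pytest.mark.parametrize("pair", CIEDE2000_PAIRS)
    def test_published_verification_pairs(self, pair):
        l1, a1, b1, l2, a2, b2, expected = pair
        got = float(lg.ciede2000(np.array([l1, a1, b1]), np.array([l2, a2, b2])))
        assert got == pytest.approx(expected, abs=1e-4)

    def test_symmetry_and_identity(self):
        rng = np.random.default_rng(1)
        lab = np.column_stack(
            [rng.uniform(0, 100, 1000), rng.uniform(-80, 80, 1000), rng.uniform(-80, 80, 1000)]
        )
        lab2 = np.column_stack(
            [rng.uniform(0, 100, 1000), rng.uniform(-80, 80, 1000), rng.uniform(-80, 80, 1000)]
        )
        fwd = lg.ciede2000(lab, lab2)
        bwd = lg.ciede2000(lab2, lab)
        assert np.abs(fwd - bwd).max() <= 1e-10
        assert np.abs(lg.ciede2000(lab, lab)).max() == 0.0
        assert fwd.min() >= 0.0

    def test_matches_reference_implementation(self):
        from skimage.color import deltaE_ciede2000

        rng = np.random.default_rng(2)
        lab1 = np.column_stack(
            [rng.uniform(0, 100, 500), rng.uniform(-100, 100, 500), rng.uniform(-100, 100, 500)]
        )
        lab2 = lab1 + rng.normal(0, 10, lab1.shape)
        ours = lg.ciede2000(lab1, lab2)
        ref = deltaE_ciede2000(lab1, lab2)
        assert np.abs(ours - ref).max() <= 1e-6

    def test_weighting_factors_scale_terms(self):
        a = np.array([50.0, 10.0, -10.0])
        b = np.array([70.0, 10.0, -10.0])  # pure lightness difference
        base = float(lg.ciede2000(a, b))
        half = float(lg.ciede2000(a, b, ColorDifferenceParams(k_l=2.0)))
        assert half == pytest.approx(base / 2.0, rel=1e-9)


class TestMDE:
    def test_zero_on_identical(self):
        vals = np.array([-120.0, -80.0, -10.0])
        assert lg.mde(vals, vals, lg.ColormapRange(-150, 0)) == 0.0

    def test_restricted_range_zero_contribution(self):
        # both estimate and truth above s_max: colours clamp identically
        crange = lg.ColormapRange(-150.0, -50.0)
        est = np.array([-10.0, -100.0])
        tru = np.array([-1.0, -100.0])
        both = lg.mde(est, tru, crange)
        only_second = lg.mde(est[1:], tru[1:], crange)
        assert both == pytest.approx(only_second / 2.0)
        assert lg.mde(np.array([-10.0]), np.array([-1.0]), crange) == 0.0

    def test_two_point_chained_oracle(self):
        crange = lg.ColormapRange(-150.0, 0.0)
        est = np.array([-120.0, -30.0])
        tru = np.array([-110.0, -45.0])
        expected = np.mean(
            [
                float(
                    lg.ciede2000(
                        lg.srgb_to_lab(lg.lat_to_color(np.array([e]), crange))[0],
                        lg.srgb_to_lab(lg.lat_to_color(np.array([t]), crange))[0],
                    )
                )
                for e, t in zip(est, tru)
            ]
        )
        assert lg.mde(est, tru, crange) == pytest.approx(expected, abs=1e-9)

    def test_length_mismatch_and_empty(self):
        crange = lg.ColormapRange(0, 1)
        with pytest.raises(ValueError):
            lg.mde(np.zeros(2), np.zeros(3), crange)
        with pytest.raises(ValueError):
            lg.mde(np.zeros(0), np.zeros(0), crange)

    @given(st.floats(-500, 500))
    @settings(max_examples=25, deadline=None)
    def test_joint_shift_invariance(self, shift):
        est = np.array([-120.0, -80.0, -33.0])
        tru = np.array([-110.0, -95.0, -31.0])
        base = lg.mde(est, tru, lg.ColormapRange(-150.0, 0.0))
        moved = lg.mde(
            est + shift, tru + shift, lg.ColormapRange(-150.0 + shift, 0.0 + shift)
        )
        assert moved == pytest.approx(base, abs=1e-9)


class TestNMSE:
    def test_zero_on_identical(self):
        vals = np.array([1.0, 2.0, 3.0])
        assert lg.nmse(vals, vals) == 0.0

    def test_mean_predictor_gives_one(self):
        truth = np.array([-10.0, 0.0, 25.0, 40.0])
        est = np.full_like(truth, truth.mean())
        assert lg.nmse(est, truth) == pytest.approx(1.0)

    def test_direct_formula(self):
        rng = np.random.default_rng(3)
        est, tru = rng.normal(0, 10, 5), rng.normal(0, 10, 5)
        direct = ((est - tru) ** 2).sum() / ((tru - tru.mean()) ** 2).sum()
        assert lg.nmse(est, tru) == pytest.approx(direct, abs=1e-12)

    def test_constant_truth_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            lg.nmse(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
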