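"""Image-chain stages: grey conversion, crop, filters, masking, contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placidollt.exceptions import BoundaryError, EmptyROIError, FormatError, ParameterError
from placidollt.io import Annotation, PupilCircle, PupilPolygon
from placidollt.preprocess import (
    PreprocessConfig,
    apply_pupil_mask,
    bandpass_filter,
    crop_centre_square,
    enhance_contrast,
    gaussian_smooth,
    process_frame,
    to_grey,
)


class TestToGrey:
    @pytest.mark.parametrize(
        "rgb, expected", [((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 100, 100), 100)]
    )
    def test_luminance_of_uniform_pixels(self, rgb, expected):
        img = np.full((4, 4, 3), rgb, dtype=np.uint8)
        assert np.all(to_grey(img) == expected)

    def test_grey_passthrough(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert np.array_equal(to_grey(img), img)

    def test_bad_channel_count(self):
        with pytest.raises(FormatError):
            to_grey(np.zeros((4, 4, 2)))

    def test_bt601_weights(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[..., 1] = 200  # pure green
        assert to_grey(img)[0, 0] == round(0.587 * 200)


class TestCrop:
    def test_window_arithmetic(self):
        img = np.zeros((512, 680))
        crop, origin = crop_centre_square(img, centre=(340, 256))
        assert crop.shape == (241, 241)
        assert origin == (220, 136)

    def test_out_of_bounds_centre(self):
        with pytest.raises(BoundaryError, match="feasible centre range"):
            crop_centre_square(np.zeros((512, 680)), centre=(100, 100))

    def test_constant_content_preserved(self):
        crop, _ = crop_centre_square(np.full((300, 300), 7.0), centre=(150, 150))
        assert np.all(crop == 7.0)


class TestBandpass:
    def test_flat_field_removed(self):
        out = bandpass_filter(np.full((64, 64), 180.0))
        assert np.all(out == 0.0)

    def test_flat_field_with_midgrey_offset(self):
        out = bandpass_filter(np.full((64, 64), 180.0), offset=128.0)
        assert np.all(out == 128.0)

    def test_ring_frequencies_pass_slow_gradients_blocked(self):
        # signed response (offset 128, float) to measure the linear transfer
        x = np.arange(1200, dtype=float)
        for period, lo, hi in [(12, 0.5, 1.01), (400, 0.0, 0.10)]:
            wave = 128 + 60 * np.sin(2 * np.pi * x / period)
            img = np.tile(wave, (8, 1))
            out = bandpass_filter(img, offset=128.0, bit_exact=False)
            inner = out[:, 300:-300]  # avoid boundary transients
            gain = (inner.max() - inner.min()) / 120.0
            assert lo < gain <= hi, period

    def test_invalid_sigmas(self):
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros((8, 8)), sigma_low=5, sigma_high=2)

    def test_output_range(self, rng):
        img = rng.integers(0, 256, size=(50, 50)).astype(float)
        out = bandpass_filter(img)
        assert out.min() >= 0 and out.max() <= 255


class TestGaussianSmooth:
    def test_constant_preserved(self):
        assert np.all(gaussian_smooth(np.full((32, 32), 77.0)) == 77.0)

    def test_impulse_response_matches_kernel(self):
        img = np.zeros((65, 65))
        img[32, 32] = 255.0
        out = gaussian_smooth(img, sigma=4.0, bit_exact=False)
        centre = 255.0 / (2 * np.pi * 16)
        assert out[32, 32] == pytest.approx(centre, rel=1e-3)
        # one-sigma neighbour down by exp(-1/2)
        assert out[32, 36] == pytest.approx(centre * np.exp(-0.5), rel=1e-3)

    def test_noise_variance_decreases(self, rng):
        img = rng.normal(128, 20, size=(128, 128))
        out = gaussian_smooth(img, sigma=4.0, bit_exact=False)
        assert out.var() < img.var()

    def test_invalid_sigma(self):
        with pytest.raises(ParameterError):
            gaussian_smooth(np.zeros((8, 8)), sigma=0)


class TestPupilMask:
    def test_circle_lattice_count(self):
        img = np.ones((241, 241))
        pupil = PupilCircle(centre=(120, 120), radius=50)
        values, mask = apply_pupil_mask(img, pupil)
        # exact lattice count oracle
        yy, xx = np.mgrid[0:241, 0:241]
        want = int(((xx - 120) ** 2 + (yy - 120) ** 2 < 50**2).sum())
        assert values.size == want
        assert abs(want - np.pi * 50**2) < 2 * np.pi * 50  # boundary slack

    def test_polygon_covering_full_crop(self):
        img = np.ones((241, 241))
        poly = PupilPolygon(np.array([[-0.5, -0.5], [241, -0.5], [241, 241], [-0.5, 241]]))
        values, _ = apply_pupil_mask(img, poly)
        assert values.size == 241 * 241

    def test_circle_outside_crop(self):
        with pytest.raises(EmptyROIError):
            apply_pupil_mask(np.ones((50, 50)), PupilCircle(centre=(500, 500), radius=10))


class TestEnhanceContrast:
    @pytest.mark.parametrize("v, expected", [(85, 255), (10, 30), (120, 255), (0, 0)])
    def test_gain_three_with_saturation(self, v, expected):
        assert enhance_contrast(np.array([v], dtype=float))[0] == expected

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(min_value=0, max_value=255), min_size=2, max_size=50),
    )
    def test_monotone_nondecreasing(self, values):
        arr = np.sort(np.asarray(values, dtype=float))
        out = enhance_contrast(arr)
        assert np.all(np.diff(out) >= 0)


class TestProcessFrame:
    @pytest.fixture
    def annotation(self):
        return Annotation(centre=(150, 150), pupil=PupilCircle((150, 150), 80))

    def test_constant_frame_survives_as_constant(self, annotation):
        img = np.full((300, 300, 3), 130, dtype=np.uint8)
        roi = process_frame(img, annotation)
        # flat field is removed by the band-pass, so the ROI is uniformly 0
        assert np.all(roi.values == 0.0)

    def test_constant_frame_with_midgrey_offset(self, annotation):
        img = np.full((300, 300, 3), 130, dtype=np.uint8)
        cfg = PreprocessConfig(bandpass_offset=128.0)
        roi = process_frame(img, annotation, cfg)
        # 128 * 3 saturates at 255 after the contrast gain
        assert np.all(roi.values == 255.0)

    def test_deterministic(self, annotation, rng):
        img = rng.integers(0, 256, size=(300, 300, 3)).astype(np.uint8)
        a = process_frame(img, annotation)
        b = process_frame(img, annotation)
        assert np.array_equal(a.values, b.values)
        assert a.provenance == b.provenance

    def test_ring_frame_histogram_is_bimodal(self, annotation):
        # rings vs gaps should populate two separated intensity clusters
        yy, xx = np.mgrid[0:300, 0:300]
        r = np.hypot(xx - 150, yy - 150)
        img = (60 + 120 * (np.sin(2 * np.pi * r / 16) >= 0)).astype(np.uint8)
        roi = process_frame(img, annotation)
        counts = np.bincount(roi.values.astype(int), minlength=256).astype(float)
        smooth = np.convolve(counts, np.ones(5) / 5, mode="same")
        first = int(smooth.argmax())
        masked = smooth.copy()
        masked[max(first - 10, 0) : first + 11] = 0
        second = int(masked.argmax())
        assert abs(first - second) >= 20  # gap level vs ring level
        assert masked[second] > 0.3 * smooth[first]

    def test_stage_error_is_annotated(self):
        ann = Annotation(centre=(10, 10), pupil=PupilCircle((10, 10), 5))
        with pytest.raises(BoundaryError, match="crop_centre_square"):
            process_frame(np.zeros((300, 300), dtype=np.uint8), ann)

    def test_provenance_records_parameters(self, annotation):
        img = np.full((300, 300), 90, dtype=np.uint8)
        roi = process_frame(img, annotation)
        assert roi.provenance["config"]["smooth_sigma"] == 4.0
        assert roi.provenance["stages"][0] == "to_grey"

    def test_only_masking_changes_pixel_count(self, annotation):
        img = np.full((300, 300), 90, dtype=np.uint8)
        roi = process_frame(img, annotation)
        assert roi.n == int(roi.mask.sum())
        assert roi.mask.shape == (241, 241)
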