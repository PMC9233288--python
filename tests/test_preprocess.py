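import numpy as np
import pytest
from PIL import Image, ImageDraw

import iopchart as ic
from iopchart import preprocess as pp
from iopchart.errors import FrameNotFound, FrameNotRectangular, InputError

from conftest import make_truth, preprocess_scan


def brute_force_binarize(img: np.ndarray, window: int, offset: float) -> np.ndarray:
    """Independent per-pixel oracle: explicit 2-D Gaussian-weighted window
    with replicated borders."""
    sigma = 0.3 * ((window - 1) * 0.5 - 1) + 0.8
    x = np.arange(window) - (window - 1) / 2
    k1 = np.exp(-(x**2) / (2 * sigma**2))
    k2 = np.outer(k1, k1)
    k2 = k2 / k2.sum()
    r = window // 2
    pad = np.pad(img.astype(np.float64), r, mode="edge")
    out = np.zeros(img.shape, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            mean = (pad[i : i + window, j : j + window] * k2).sum()
            out[i, j] = img[i, j] < mean - offset
    return out


class TestBinarizeAdaptive:
    def test_constant_image_is_all_background(self):
        img = np.full((50, 50), 128, dtype=np.uint8)
        assert not pp.binarize_adaptive(img, window=27, offset=10).any()

    def test_single_black_pixel_matches_oracle(self):
        img = np.full((9, 9), 255, dtype=np.uint8)
        img[4, 4] = 0
        got = pp.binarize_adaptive(img, window=5, offset=10)
        assert got[4, 4]
        np.testing.assert_array_equal(got, brute_force_binarize(img, 5, 10))

    def test_default_parameterization(self):
        """Defaults are the 27x27 Gaussian neighborhood with offset 10."""
        import inspect

        sig = inspect.signature(pp.binarize_adaptive)
        assert sig.parameters["window"].default == 27
        assert sig.parameters["offset"].default == 10.0

    @pytest.mark.parametrize("window", [3, 7])
    def test_random_images_match_oracle(self, window):
        rng = np.random.default_rng(7)
        for _ in range(10):
            img = rng.integers(0, 256, size=(16, 20), dtype=np.uint8)
            np.testing.assert_array_equal(
                pp.binarize_adaptive(img, window=window, offset=10),
                brute_force_binarize(img, window, 10),
            )

    def test_parameter_errors(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(InputError):
            pp.binarize_adaptive(img, window=4)
        with pytest.raises(InputError):
            pp.binarize_adaptive(np.zeros((0, 0), dtype=np.uint8))


def _border_image(size=(760, 1000), rect=((100, 80), (900, 680)), width=3):
    img = Image.new("L", (size[1], size[0]), 255)
    d = ImageDraw.Draw(img)
    d.rectangle([rect[0], rect[1]], outline=0, width=width)
    return np.asarray(img) < 128


class TestFindMainFrame:
    def test_perfect_rectangle_corners(self):
        binary = _border_image()
        quad = pp.find_main_frame(binary)
        expected = [(100, 80), (900, 80), (900, 680), (100, 680)]
        for got, exp in zip(quad.corners, expected):
            assert np.hypot(got[0] - exp[0], got[1] - exp[1]) <= 2.0

    def test_interior_content_is_ignored(self):
        binary = _border_image()
        rng = np.random.default_rng(0)
        # scribbles well inside the frame
        rr = rng.integers(150, 600, 500)
        cc = rng.integers(150, 850, 500)
        binary[rr, cc] = True
        quad = pp.find_main_frame(binary)
        expected = [(100, 80), (900, 80), (900, 680), (100, 680)]
        for got, exp in zip(quad.corners, expected):
            assert np.hypot(got[0] - exp[0], got[1] - exp[1]) <= 2.0

    def test_cut_off_corner_completed(self):
        """A missing corner is recovered by intersecting the frame edges."""
        binary = _border_image()
        binary[:180, 780:] = False  # erase the top-right corner region
        quad = pp.find_main_frame(binary)
        expected = [(100, 80), (900, 80), (900, 680), (100, 680)]
        for got, exp in zip(quad.corners, expected):
            assert np.hypot(got[0] - exp[0], got[1] - exp[1]) <= 5.0

    @pytest.mark.parametrize("angle_deg", [-5, -3, 3, 5])
    def test_rotated_rectangle_recovered(self, angle_deg):
        """Corners of a rotated frame land within 5 px of ground truth."""
        cx, cy = 500, 380
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        base = np.array([(100, 80), (900, 80), (900, 680), (100, 680)], dtype=float)
        true = (base - (cx, cy)) @ rot.T + (cx, cy)
        img = Image.new("L", (1000, 760), 255)
        d = ImageDraw.Draw(img)
        d.line([tuple(p) for p in np.vstack([true, true[:1]])], fill=0, width=3)
        quad = pp.find_main_frame(np.asarray(img) < 128)
        for got, exp in zip(quad.corners, true):
            assert np.hypot(got[0] - exp[0], got[1] - exp[1]) <= 5.0

    def test_blank_image_raises(self):
        with pytest.raises(FrameNotFound):
            pp.find_main_frame(np.zeros((300, 300), dtype=bool))

    def test_small_contour_raises(self):
        binary = _border_image(rect=((450, 350), (550, 420)))
        with pytest.raises(FrameNotFound):
            pp.find_main_frame(binary)

    def test_non_rectangular_shape_rejected(self):
        img = Image.new("L", (1000, 760), 255)
        d = ImageDraw.Draw(img)
        d.polygon([(500, 60), (950, 700), (50, 700)], outline=0, width=3)
        with pytest.raises(FrameNotRectangular):
            pp.find_main_frame(np.asarray(img) < 128)


class TestCropToCanonical:
    def test_identity_warp_is_pixel_exact(self, template):
        truth = make_truth((15, 18, 17, 14, 16))
        from iopchart.synth import render_canonical

        arr = render_canonical(truth, ic.RenderConfig.noiseless(seed=0), template)
        scan = ic.RawScan(pixels=arr, source_id="canon")
        W, H = template.canonical_width, template.canonical_height
        quad = ic.Quadrilateral(
            corners=((0.0, 0.0), (W - 1.0, 0.0), (W - 1.0, H - 1.0), (0.0, H - 1.0))
        )
        out = pp.crop_to_canonical(scan, quad, template)
        np.testing.assert_array_equal(out.pixels, arr)

    def test_rotated_scan_gridlines_on_template(self, template):
        """After cropping a rotated scan, gridlines sit on template x positions."""
        truth = make_truth((15, 18, 17, 14, 16))
        cfg = ic.RenderConfig(seed=5, noise_sigma=0.0, jitter_px=0.0, rotation_deg=3.0)
        chart = preprocess_scan(ic.render_chart(truth, cfg), template)
        gray = pp.to_grayscale(chart.pixels)
        row = gray[900].astype(float)
        for t in ic.SLOT_TIMES:
            x = template.slot_x(0, t)
            window = row[int(x) - 6 : int(x) + 7]
            dark = np.where(window < 140)[0]
            assert dark.size, f"no gridline near slot {t}"
            center = int(x) - 6 + dark.mean()
            assert abs(center - x) <= 2.0

    def test_scale_invariance_of_canonical_output(self, template):
        """Scans at different resolutions yield matching canonical charts."""
        centers = {}
        for scale in (1.0, 0.6):
            truth = make_truth((15, 18, 17, 14, 16))
            cfg = ic.RenderConfig.noiseless(seed=9, scale=scale)
            chart = preprocess_scan(ic.render_chart(truth, cfg), template)
            row = pp.to_grayscale(chart.pixels)[900].astype(float)
            for t in ic.SLOT_TIMES:
                x = template.slot_x(0, t)
                w = row[int(x) - 6 : int(x) + 7]
                dark = np.where(w < 140)[0]
                centers.setdefault(t, []).append(int(x) - 6 + dark.mean())
        for t, (a, b) in centers.items():
            assert abs(a - b) <= 2.0, f"slot {t}: {a} vs {b}"

    def test_degenerate_frame_raises(self, template):
        scan = ic.RawScan(pixels=np.full((400, 400, 3), 255, dtype=np.uint8))
        tiny = ic.Quadrilateral(
            corners=((10.0, 10.0), (40.0, 10.0), (40.0, 40.0), (10.0, 40.0))
        )
        with pytest.raises(FrameNotFound):
            pp.crop_to_canonical(scan, tiny, template)
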