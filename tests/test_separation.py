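import numpy as np
import pytest

from axotrace import (
    CutLine,
    EllipseFit,
    EllipseFitError,
    apply_cuts,
    fit_ellipse,
    fit_line,
    fit_line_tls,
    normalize_line,
)
from axotrace.detection import SegmentationResult
from axotrace.separation import insert_border, watershed_split
from axotrace.tracking import FrameAssignment


def ellipse_mask(cy, cx, a, b, theta=0.0, shape=(64, 64)):
    """Rasterize a filled ellipse with semi-axes (a, b) rotated by theta."""
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    x, y = cols - cx, rows - cy
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def two_gaussian_image(c1=(32, 20), c2=(32, 40), sigma=6.0, shape=(64, 64)):
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape)
    for cy, cx in (c1, c2):
        img += np.exp(-(((rows - cy) ** 2 + (cols - cx) ** 2)
                        / (2 * sigma**2)))
    return img / img.max()


class TestFitEllipse:
    def test_axis_aligned_ellipse_recovered(self):
        mask = ellipse_mask(32, 32, 10, 5)
        e = fit_ellipse(mask)
        assert e.w == pytest.approx(10, abs=1.0)
        assert e.h == pytest.approx(5, abs=1.0)
        assert abs(np.degrees(e.theta)) < 5
        np.testing.assert_allclose(e.center, [32, 32], atol=1.0)

    def test_rotated_ellipse_angle_recovered(self):
        theta = np.deg2rad(30)
        mask = ellipse_mask(32, 32, 12, 5, theta=theta)
        e = fit_ellipse(mask)
        assert np.degrees(e.theta) == pytest.approx(30, abs=5)

    def test_circle_has_equal_axes(self):
        mask = ellipse_mask(32, 32, 8, 8)
        e = fit_ellipse(mask)
        assert e.w == pytest.approx(e.h, abs=0.5)

    def test_degenerate_contour_rejected(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10, 5:25] = True  # collinear pixels
        with pytest.raises(EllipseFitError):
            fit_ellipse(mask)

    def test_too_few_pixels_rejected(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(EllipseFitError, match="contour"):
            fit_ellipse(mask)


class TestLineNormalization:
    def test_unit_circle_is_identity(self):
        e = EllipseFit(center=(0.0, 0.0), w=1.0, h=1.0, theta=0.0)
        line = CutLine(n=(0.6, 0.8), d=2.5)
        out = normalize_line(line, e)
        np.testing.assert_allclose(out.n, line.n, atol=1e-12)
        assert out.d == pytest.approx(2.5)
        back = fit_line(line, e)
        np.testing.assert_allclose(back.n, line.n, atol=1e-12)
        assert back.d == pytest.approx(2.5)

    def test_tangent_at_wide_end_maps_to_unit_tangent(self):
        e = EllipseFit(center=(0.0, 0.0), w=2.0, h=1.0, theta=0.0)
        line = CutLine(n=(1.0, 0.0), d=2.0)  # tangent at x = w
        out = normalize_line(line, e)
        np.testing.assert_allclose(out.n, [1.0, 0.0], atol=1e-12)
        assert out.d == pytest.approx(1.0)
        # and the inverse recovers the image-space tangent
        back = fit_line(out, e)
        np.testing.assert_allclose(back.n, [1.0, 0.0], atol=1e-12)
        assert back.d == pytest.approx(2.0)

    def test_tangency_preserved_for_random_ellipses(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            e = EllipseFit(
                center=rng.uniform(-20, 20, 2),
                w=rng.uniform(1, 30),
                h=rng.uniform(1, 30),
                theta=rng.uniform(-np.pi / 2 + 1e-9, np.pi / 2),
            )
            # tangent line at parametric point t
            t = rng.uniform(0, 2 * np.pi)
            rot = np.array([
                [np.cos(e.theta), -np.sin(e.theta)],
                [np.sin(e.theta), np.cos(e.theta)],
            ])
            point = e.center + rot @ np.array(
                [e.w * np.cos(t), e.h * np.sin(t)]
            )
            normal = rot @ np.array(
                [np.cos(t) / e.w, np.sin(t) / e.h]
            )
            normal = normal / np.linalg.norm(normal)
            line = CutLine(n=normal, d=float(normal @ point))
            out = normalize_line(line, e)
            assert abs(out.d) == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_identity_many_random_pairs(self):
        rng = np.random.default_rng(1)
        max_d_err = 0.0
        max_n_err = 0.0
        for _ in range(1000):
            n = rng.normal(size=2)
            n /= np.linalg.norm(n)
            line = CutLine(n=n, d=float(rng.uniform(-60, 60)))
            e = EllipseFit(
                center=rng.uniform(0, 64, 2),
                w=rng.uniform(1, 50),
                h=rng.uniform(1, 50),
                theta=rng.uniform(-np.pi / 2 + 1e-9, np.pi / 2),
            )
            rt = fit_line(normalize_line(line, e), e)
            max_d_err = max(max_d_err, abs(rt.d - line.d))
            max_n_err = max(max_n_err, abs(abs(rt.n @ line.n) - 1.0))
            rt2 = normalize_line(fit_line(line, e), e)
            max_d_err = max(max_d_err, abs(rt2.d - line.d))
        assert max_d_err < 1e-9
        assert max_n_err < 1e-12

    def test_printed_variant_divides_by_center(self):
        e = EllipseFit(center=(0.0, 0.0), w=2.0, h=1.0, theta=0.0)
        line = CutLine(n=(1.0, 0.0), d=2.0)
        with pytest.raises(ZeroDivisionError):
            normalize_line(line, e, variant="printed")


class TestFitLineTLS:
    def test_vertical_border_pixels(self):
        pts = np.array([[30.0, y] for y in range(10, 20)])
        line = fit_line_tls(pts)
        assert abs(line.n[1]) < 1e-9  # normal points along x
        assert abs(abs(line.d) - 30.0) < 1e-9

    def test_diagonal_points(self):
        pts = np.array([[t, t] for t in np.linspace(0, 10, 11)])
        line = fit_line_tls(pts)
        np.testing.assert_allclose(abs(line.n @ [1, 1] / np.sqrt(2)), 0,
                                   atol=1e-9)


class TestWatershedSplit:
    def test_single_gaussian_has_no_cut(self):
        rows, cols = np.mgrid[:64, :64]
        img = np.exp(-(((rows - 32) ** 2 + (cols - 32) ** 2) / 50.0))
        mask = img > 0.2
        assert watershed_split(img, mask) is None

    def test_two_equal_gaussians_split_near_midline(self):
        img = two_gaussian_image(c1=(32, 20), c2=(32, 40))
        mask = img > 0.3  # single merged component
        seg = SegmentationResult.from_mask(mask)
        assert seg.n_rois == 1
        labels = watershed_split(img, mask)
        assert labels is not None
        ids = np.unique(labels[labels > 0])
        assert len(ids) == 2
        bordered = insert_border(labels)
        border_cols = np.nonzero((bordered == 0) & mask)[1]
        assert abs(border_cols.mean() - 30) <= 2

    def test_low_intensity_maxima_discarded(self):
        # peaks at 0.02, 0.04 and 0.2: only the 0.2 peak survives the
        # >= 0.05 rule, so there is nothing to split
        rows, cols = np.mgrid[:64, :64]
        img = np.zeros((64, 64))
        for amp, cx in [(0.02, 12), (0.04, 32), (0.2, 52)]:
            img += amp * np.exp(-(((rows - 32) ** 2 + (cols - cx) ** 2) / 30.0))
        mask = img > 0.005
        assert watershed_split(img, mask) is None


class TestApplyCuts:
    def _make_cut_case(self):
        img = two_gaussian_image()
        mask = img > 0.3
        parent_ellipse = fit_ellipse(mask)
        # a vertical cut at the watershed divide, normalized to the parent
        cut_line_img = CutLine(n=(1.0, 0.0), d=30.0)
        from axotrace.separation import Cut

        cut = Cut(
            parent_axon=0,
            line=normalize_line(cut_line_img, parent_ellipse),
            child_axon=1,
            parent_ellipse=parent_ellipse,
        )
        return img, mask, cut

    def test_children_partition_the_parent(self):
        _, mask, cut = self._make_cut_case()
        seg = SegmentationResult.from_mask(mask)
        assignment = FrameAssignment(roi_to_axon=[0])
        frames = apply_cuts([cut], [assignment], [seg])
        frame = frames[0]
        assert set(frame) == {0, 1}
        parent_pixels = {tuple(p) for p in seg.rois[0].pixels}
        child_union = {tuple(p) for p in frame[0]} | {
            tuple(p) for p in frame[1]
        }
        assert child_union == parent_pixels
        assert not ({tuple(p) for p in frame[0]}
                    & {tuple(p) for p in frame[1]})

    def test_no_cuts_leaves_assignments_unchanged(self):
        img = two_gaussian_image()
        seg = SegmentationResult.from_mask(img > 0.3)
        assignment = FrameAssignment(roi_to_axon=[0])
        frames = apply_cuts([], [assignment], [seg])
        assert set(frames[0]) == {0}
        np.testing.assert_array_equal(frames[0][0], seg.rois[0].pixels)

    def test_split_fractions_stable_under_translation_and_scale(self):
        img, mask, cut = self._make_cut_case()
        seg0 = SegmentationResult.from_mask(mask)
        frames0 = apply_cuts([cut], [FrameAssignment([0])], [seg0])
        frac0 = len(frames0[0][1]) / (len(frames0[0][0]) + len(frames0[0][1]))

        # same double blob, translated by (6, -4) and scaled x1.5
        big = two_gaussian_image(c1=(38 - 6, 26 + 4), c2=(38 - 6, 56 + 4),
                                 sigma=9.0, shape=(96, 96))
        big_mask = np.roll(big > 0.3, (6, -4), axis=(0, 1))
        seg1 = SegmentationResult.from_mask(big_mask)
        assert seg1.n_rois == 1
        frames1 = apply_cuts([cut], [FrameAssignment([0])], [seg1])
        frac1 = len(frames1[0][1]) / (len(frames1[0][0]) + len(frames1[0][1]))
        assert frac1 == pytest.approx(frac0, abs=0.1)

    def test_failed_frame_ellipse_skips_cut(self):
        _, _, cut = self._make_cut_case()
        thin = np.zeros((64, 64), dtype=bool)
        thin[32, 10:40] = True  # collinear ROI: ellipse fit must fail
        seg = SegmentationResult.from_mask(thin)
        frames = apply_cuts([cut], [FrameAssignment([0])], [seg])
        assert set(frames[0]) == {0}  # child missing in this frame
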