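import itertools
from fractions import Fraction

import numpy as np
import pytest

from axotrace import (
    AxonModel,
    MatchCostConfig,
    TrackerTemplate,
    dummy_cost,
    init_template,
    inner_cost,
    match_frame,
    outer_cost,
    track_stack,
)
from axotrace.detection import ROI, SegmentationResult

from conftest import stack_from_gray

CFG = MatchCostConfig()
H = W = 100


def make_roi(row, col, area):
    roi = ROI.from_coords(np.array([[int(row), int(col)]]))
    roi.area = area
    roi.centroid = np.array([float(row), float(col)])
    return roi


def make_axon(identity, row, col, area):
    return AxonModel(identity=identity, area=float(area),
                     position=np.array([float(row), float(col)]))


def brute_force_total(cost, dummy):
    """Minimum total cost over all ROI -> axon-or-dummy assignments."""
    n_r, n_a = cost.shape
    best = np.inf
    for choice in itertools.product(list(range(n_a)) + [None], repeat=n_r):
        real = [c for c in choice if c is not None]
        if len(set(real)) != len(real):
            continue
        total = sum(cost[i, c] if c is not None else dummy
                    for i, c in enumerate(choice))
        best = min(best, total)
    return best


class TestInnerCost:
    def test_identical_displacements_and_areas_cost_zero(self):
        c = inner_cost((10, 30), 20, (10, 30), 20, (5, 5), (5, 5), H, W, CFG)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_pure_area_difference(self):
        c = inner_cost((10, 30), 25, (10, 30), 20, (5, 5), (5, 5), H, W, CFG)
        assert c == pytest.approx(0.5)  # w_area * 5

    def test_hand_computed_displacement_case(self):
        # k at origin, k' 50 px right; ROI displacement 60 px right,
        # equal areas: only the distance term survives (angles equal).
        # cost' = (w_dist / min(H,W)) * 10 * H / (H + row(k'))
        c = inner_cost(
            roi_pos=(0, 60), roi_area=10,
            axon_pos=(0, 50), axon_area=10,
            matched_roi_pos=(0, 0), matched_axon_pos=(0, 0),
            height=H, width=W, config=CFG,
        )
        expected = (1.0 / 100) * 10 * (100 / (100 + 0))
        assert c == pytest.approx(expected)

    def test_printed_height_attenuation_uses_axon_row(self):
        lo = inner_cost((40, 60), 10, (40, 50), 10, (40, 0), (40, 0), H, W, CFG)
        hi = inner_cost((0, 60), 10, (0, 50), 10, (0, 0), (0, 0), H, W, CFG)
        # same geometry shifted down the image: the printed form attenuates
        assert lo == pytest.approx(hi * 100 / (100 + 40))

    def test_relative_height_attenuation_variant(self):
        cfg = MatchCostConfig(height_term="relative")
        lo = inner_cost((40, 60), 10, (40, 50), 10, (40, 0), (40, 0), H, W, cfg)
        hi = inner_cost((0, 60), 10, (0, 50), 10, (0, 0), (0, 0), H, W, cfg)
        assert lo == pytest.approx(hi)  # no vertical separation in either

    def test_coincident_axons_use_arctan_limit(self):
        # x_k' == x_k: eta_theta falls back to pi/2 instead of dividing by 0
        c = inner_cost((0, 10), 10, (0, 0), 10, (0, 0), (0, 0), H, W, CFG)
        assert np.isfinite(c)


class TestOuterCost:
    def test_single_roi_equal_areas(self):
        rois = [make_roi(10, 10, 20)]
        axons = [make_axon(0, 12, 12, 20)]
        assert outer_cost(0, 0, rois, axons, H, W, CFG) == pytest.approx(0.0)

    def test_single_roi_area_difference(self):
        rois = [make_roi(10, 10, 23)]
        axons = [make_axon(0, 12, 12, 20)]
        assert outer_cost(0, 0, rois, axons, H, W, CFG) == pytest.approx(0.3)

    def test_perfect_geometric_correspondence_has_zero_inner_term(self):
        rois = [make_roi(10, 10, 20), make_roi(40, 40, 33)]
        axons = [make_axon(0, 10, 10, 22), make_axon(1, 40, 40, 33)]
        c = outer_cost(0, 0, rois, axons, H, W, CFG)
        assert c == pytest.approx(CFG.w_area * 2)


class TestDummyCost:
    def test_floor_applies_at_zero_min(self):
        assert dummy_cost(np.array([[0.0, 2.0]])) == pytest.approx(0.3)

    def test_margin_above_floor(self):
        assert dummy_cost(np.array([[1.0, 2.0]])) == pytest.approx(1.1)

    def test_floor_beats_small_margin(self):
        assert dummy_cost(np.array([[0.2, 2.0]])) == pytest.approx(0.3)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            dummy_cost(np.empty((0, 0)))


class TestMatchFrame:
    def test_identity_match_costs_zero(self):
        axons = [make_axon(k, 10 + 20 * k, 15, 20 + 5 * k) for k in range(3)]
        rois = [make_roi(10 + 20 * k, 15, 20 + 5 * k) for k in range(3)]
        a = match_frame(rois, TrackerTemplate(axons=axons), H, W, CFG)
        assert a.roi_to_axon == [0, 1, 2]
        assert a.total_cost == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        from axotrace.tracking import dummy_cost as dc

        rng = np.random.default_rng(11)
        for _ in range(150):
            n_r = int(rng.integers(1, 5))
            n_a = int(rng.integers(1, 5))
            rois = [make_roi(rng.integers(0, H), rng.integers(0, W),
                             int(rng.integers(5, 60))) for _ in range(n_r)]
            axons = [make_axon(k, rng.integers(0, H), rng.integers(0, W),
                               int(rng.integers(5, 60))) for k in range(n_a)]
            cost = np.array([[outer_cost(i, k, rois, axons, H, W, CFG)
                              for k in range(n_a)] for i in range(n_r)])
            expected = brute_force_total(cost, dc(cost, CFG))
            a = match_frame(rois, TrackerTemplate(axons=axons), H, W, CFG)
            assert a.total_cost == pytest.approx(expected, abs=1e-9)

    def test_spurious_roi_left_unmatched(self):
        axons = [make_axon(0, 20, 20, 30)]
        rois = [make_roi(20, 20, 30), make_roi(90, 90, 200)]
        a = match_frame(rois, TrackerTemplate(axons=axons), H, W, CFG)
        assert a.roi_to_axon == [0, None]

    def test_empty_frame_gives_empty_assignment(self):
        a = match_frame([], TrackerTemplate(axons=[make_axon(0, 5, 5, 20)]),
                        H, W, CFG)
        assert a.roi_to_axon == []


class TestRunningAverage:
    def test_area_two_then_four(self):
        axon = make_axon(0, 10, 10, 2)
        axon.update(make_roi(10, 10, 2))
        assert axon.area == pytest.approx(2.0)
        axon.update(make_roi(10, 10, 4))
        assert axon.area == pytest.approx(8 / 3)
        assert axon.n_updates == 3

    def test_always_matched_axon_area_telescopes_to_mean(self):
        rng = np.random.default_rng(5)
        areas = [int(a) for a in rng.integers(18, 25, size=12)]
        axon = make_axon(0, 10, 10, areas[0])
        for a in areas[1:]:
            axon.update(make_roi(10, 10, a))
        exact = Fraction(sum(areas), len(areas))
        assert axon.area == pytest.approx(float(exact), abs=1e-12)


class TestTrackStack:
    def _static_case(self):
        frames = np.zeros((4, 50, 50))
        segs = []
        for t in range(4):
            mask = np.zeros((50, 50), dtype=bool)
            mask[10:14, 10:14] = True
            mask[30:36, 30:36] = True
            segs.append(SegmentationResult.from_mask(mask))
        return stack_from_gray(frames), segs

    def test_static_rois_keep_identities_every_frame(self):
        stack, segs = self._static_case()
        template = init_template(stack, segs)
        assignments, frozen = track_stack(stack, segs, template)
        first = assignments[0].roi_to_axon
        assert None not in first and len(set(first)) == 2
        for a in assignments[1:]:
            assert a.roi_to_axon == first
        assert frozen.frozen

    def test_pass_two_is_frame_order_independent(self, static_stack):
        from axotrace import match_frame, segment_stack_cv

        stack, _ = static_stack
        segs = segment_stack_cv(stack)
        template = init_template(stack, segs)
        assignments, frozen = track_stack(stack, segs, template)
        h, w = stack.frame_shape
        # re-match in reverse order against the frozen template
        reversed_matches = [match_frame(seg.rois, frozen, h, w)
                            for seg in segs[::-1]][::-1]
        for a, b in zip(assignments, reversed_matches):
            assert a.roi_to_axon == b.roi_to_axon


class TestInitTemplate:
    def test_finetune_segmentation_copied_directly(self, overlap_stack):
        from axotrace import cluster_similar_frames, finetune_target

        stack, _ = overlap_stack
        cluster = cluster_similar_frames(stack)
        ft = finetune_target(stack, cluster)
        template = init_template(stack, [], finetune=ft)
        assert template.n_axons == ft.segmentation.n_rois
        for axon, roi in zip(template.axons, ft.segmentation.rois):
            assert axon.area == roi.area
            np.testing.assert_allclose(axon.position, roi.centroid)
            assert axon.n_updates == 1

    def test_modal_roi_count_frame_selection(self):
        # three 2-ROI frames and one 3-ROI frame: candidates are the three;
        # among them, the one equal to the temporal average is selected
        pat = np.zeros((40, 40))
        pat[10:14, 10:14] = 1.0
        pat[30:34, 30:34] = 0.8
        odd = pat.copy()
        odd[20:24, 20:24] = 0.9
        rng = np.random.default_rng(8)
        noisy = np.clip(pat + rng.normal(0, 0.05, pat.shape), 0, None)
        frames = [noisy, pat, pat, odd]
        segs = []
        for f in frames:
            segs.append(SegmentationResult.from_mask(f > 0.5))
        stack = stack_from_gray(frames)
        template = init_template(stack, segs)
        assert template.n_axons == 2
        # frames 1 and 2 are identical and equal to the candidate average
        np.testing.assert_array_equal(template.reference_image, pat)

    def test_no_rois_anywhere_rejected(self):
        stack = stack_from_gray(np.zeros((3, 16, 16)))
        segs = [SegmentationResult.from_mask(np.zeros((16, 16), bool))
                for _ in range(3)]
        with pytest.raises(ValueError, match="no frame"):
            init_template(stack, segs)
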