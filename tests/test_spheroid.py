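import math

import numpy as np
import pytest

from clonemorph.io import ZStack
from clonemorph.spheroid import (
    SpheroidMeasurement,
    binarize,
    detect_dissemination,
    detect_protrusions,
    invasion_score,
    measure_spheroid,
    measure_stack,
    project_stack,
)
from clonemorph.synthetic import SyntheticSpheroidSpec, generate_spheroid_stack
from conftest import rasterize_disc


def _stack_of_constants(n=15, value_fn=lambda i: float(i)):
    slices = np.stack([np.full((8, 8), value_fn(i), dtype=float) for i in range(n)])
    return ZStack(slices, z_spacing=5.0, pixel_size=2.0)


def _star_mask(radius_px=60, arm_len_px=(125, 125, 150, 150), arm_half_w=6, size=384):
    c = (size - 1) / 2
    rr, cc = np.mgrid[0:size, 0:size]
    mask = (rr - c) ** 2 + (cc - c) ** 2 <= radius_px ** 2
    for k, L in enumerate(arm_len_px):
        ang = k * math.pi / 2
        u = np.array([math.cos(ang), math.sin(ang)])
        t = np.clip(((rr - c) * u[0] + (cc - c) * u[1]) / L, 0, 1)
        d2 = (rr - c - t * L * u[0]) ** 2 + (cc - c - t * L * u[1]) ** 2
        mask |= d2 <= arm_half_w ** 2
    return mask


class TestProjectStack:
    def test_max_identity_on_constant_slices(self):
        stack = _stack_of_constants()
        proj = project_stack(stack, center=7)
        assert np.all(proj == 14.0)  # max of the window is the top slice

    def test_fifteen_slices_at_5um_use_all(self):
        stack = _stack_of_constants(n=15, value_fn=lambda i: float(i))
        # window 75 µm / 5 µm = 15 slices -> whole stack regardless of center
        proj = project_stack(stack, center=0)
        assert np.all(proj == 14.0)

    def test_too_thin_stack_rejected(self):
        with pytest.raises(ValueError):
            project_stack(_stack_of_constants(n=10))

    def test_projection_area_matches_planted_cross_section(self, star_spheroid):
        stack, truth = star_spheroid
        proj = project_stack(stack)
        mask = binarize(proj, pixel_size=stack.pixel_size)
        area = mask.sum() * stack.pixel_size ** 2
        assert area == pytest.approx(truth.cross_section_um2, rel=0.02)


class TestBinarize:
    def test_two_level_image_exact(self):
        img = np.full((64, 64), 10.0)
        img[20:40, 20:40] = 200.0
        mask = binarize(img, pixel_size=1.0)
        np.testing.assert_array_equal(mask, img > 100)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((32, 32)))

    def test_noisy_projection_jaccard(self, star_spheroid):
        stack, truth = star_spheroid
        mask = binarize(project_stack(stack), pixel_size=stack.pixel_size)
        inter = (mask & truth.mask).sum()
        union = (mask | truth.mask).sum()
        assert inter / union >= 0.95


class TestMeasureSpheroid:
    def test_disc_shape_properties(self):
        mask = rasterize_disc(200.0, pixel_size=2.0)
        area, circ, solidity = measure_spheroid(mask, pixel_size=2.0)
        assert area == pytest.approx(math.pi * 200 ** 2, rel=0.02)
        assert 0.98 <= solidity <= 1.0
        assert circ > 0.95

    def test_star_solidity_below_convex_body(self):
        mask = _star_mask()
        _, _, solidity = measure_spheroid(mask, pixel_size=2.0)
        assert solidity < 0.8
        # oracle: exhaustive convex-hull pixel count via the hull image
        from skimage.morphology import convex_hull_image

        hull = convex_hull_image(mask)
        assert solidity == pytest.approx(mask.sum() / hull.sum(), abs=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_spheroid(np.zeros((16, 16), dtype=bool), 1.0)


class TestDetectProtrusions:
    def test_plain_disc_has_none(self):
        mask = rasterize_disc(150.0, pixel_size=2.0)
        n_p, lengths = detect_protrusions(mask, pixel_size=2.0)
        assert n_p == 0 and lengths == []

    def test_planted_star_recovered(self, star_spheroid):
        stack, truth = star_spheroid
        mask = binarize(project_stack(stack), pixel_size=stack.pixel_size)
        n_p, lengths = detect_protrusions(mask, pixel_size=stack.pixel_size)
        assert n_p == truth.n_protrusions
        np.testing.assert_allclose(sorted(lengths), sorted(truth.protrusion_lengths_um),
                                   atol=2 * stack.pixel_size)

    def test_short_arm_not_counted(self):
        # one arm with ~10 µm radial extent stays below the 20 µm minimum
        mask = _star_mask(radius_px=60, arm_len_px=(66,), arm_half_w=4)
        n_p, _ = detect_protrusions(mask, pixel_size=2.0)
        assert n_p == 0


class TestDetectDissemination:
    def test_single_component_mask(self):
        mask = rasterize_disc(100.0, pixel_size=2.0)
        n_c, areas, dists = detect_dissemination(mask, pixel_size=2.0)
        assert n_c == 0 and areas == [] and dists == []

    def test_three_planted_blobs_closed_form_mean(self, star_spheroid):
        stack, truth = star_spheroid
        mask = binarize(project_stack(stack), pixel_size=stack.pixel_size)
        n_c, areas, dists = detect_dissemination(mask, pixel_size=stack.pixel_size)
        assert n_c == truth.n_disseminated
        np.testing.assert_allclose(sorted(dists), sorted(truth.disseminated_distances_um),
                                   atol=2 * stack.pixel_size)
        assert np.mean(dists) == pytest.approx(
            np.mean(truth.disseminated_distances_um), abs=2 * stack.pixel_size)

    def test_blob_below_min_area_excluded(self):
        mask = rasterize_disc(60.0, pixel_size=2.0, pad=60).copy()
        mask[5:7, 5:7] = True  # 4 px = 16 µm² < 50 µm²
        n_c, _, _ = detect_dissemination(mask, pixel_size=2.0, min_area_um2=50.0)
        assert n_c == 0

    def test_partition_with_protrusions(self, star_spheroid):
        # every foreground pixel is body (incl. protrusions) or a counted region
        stack, truth = star_spheroid
        mask = binarize(project_stack(stack), pixel_size=stack.pixel_size)
        from scipy import ndimage

        labeled, n = ndimage.label(mask)
        sizes = np.bincount(labeled.ravel())[1:]
        n_c, areas, _ = detect_dissemination(mask, pixel_size=stack.pixel_size)
        body_px = sizes.max()
        region_px = sum(a / stack.pixel_size ** 2 for a in areas)
        assert body_px + region_px == pytest.approx(mask.sum(), abs=1)


class TestMeasureStack:
    def test_full_pipeline_on_planted_stack(self, star_spheroid):
        stack, truth = star_spheroid
        m = measure_stack(stack, clone_id="cl1")
        assert m.n_p == truth.n_protrusions and m.n_c == truth.n_disseminated
        assert m.max_p == pytest.approx(300.0, abs=2 * stack.pixel_size)
        assert m.avg_c == pytest.approx(300.0, abs=2 * stack.pixel_size)
        assert 0 < m.solidity <= 1 and m.avg_p <= m.max_p


def _measurement(clone, n_p, avg_p, max_p, n_c, avg_c, max_c):
    # build explicit lists realizing the requested summary stats
    if n_p == 0:
        lengths = []
    elif n_p == 1:
        lengths = [max_p]
        avg_p = max_p
    else:
        rest = (avg_p * n_p - max_p) / (n_p - 1)
        lengths = [rest] * (n_p - 1) + [max_p]
    if n_c == 0:
        dists = []
    elif n_c == 1:
        dists = [max_c]
    else:
        rest = (avg_c * n_c - max_c) / (n_c - 1)
        dists = [rest] * (n_c - 1) + [max_c]
    return SpheroidMeasurement(
        spheroid_id=f"s-{clone}", clone_id=clone, area_um2=1e4, circularity=0.9,
        solidity=0.9, n_p=n_p, protrusion_lengths_um=lengths,
        n_c=n_c, region_areas_um2=[100.0] * n_c, region_distances_um=dists)


class TestInvasionScore:
    def fixture_measurements(self):
        return [
            _measurement("lo", n_p=1, avg_p=100, max_p=100, n_c=1, avg_c=150, max_c=150),
            _measurement("mid", n_p=3, avg_p=150, max_p=200, n_c=2, avg_c=200, max_c=250),
            _measurement("hi", n_p=5, avg_p=200, max_p=300, n_c=3, avg_c=250, max_c=350),
        ]

    def test_extremes_map_to_0_and_1(self):
        scores = {s.clone_id: s for s in invasion_score(self.fixture_measurements())}
        assert scores["hi"].invasion3d == pytest.approx(1.0)
        assert scores["lo"].invasion3d == pytest.approx(0.0)

    def test_hand_computed_normalization(self):
        scores = {s.clone_id: s for s in invasion_score(self.fixture_measurements())}
        mid = scores["mid"]
        # hand min-max arithmetic per metric
        expected = np.mean([
            (3 - 1) / (5 - 1),       # n_p
            (150 - 100) / (200 - 100),  # avg_p
            (200 - 100) / (300 - 100),  # max_p
            (2 - 1) / (3 - 1),       # n_c
            (200 - 150) / (250 - 150),  # avg_c
            (250 - 150) / (350 - 150),  # max_c
        ])
        assert mid.invasion3d == pytest.approx(expected, abs=1e-12)

    def test_affine_rescaling_of_one_metric_is_invariant(self):
        base = self.fixture_measurements()
        rescaled = []
        for m in base:
            rescaled.append(SpheroidMeasurement(
                spheroid_id=m.spheroid_id, clone_id=m.clone_id, area_um2=m.area_um2,
                circularity=m.circularity, solidity=m.solidity, n_p=m.n_p,
                protrusion_lengths_um=[3.0 * x + 50.0 for x in m.protrusion_lengths_um],
                n_c=m.n_c, region_areas_um2=m.region_areas_um2,
                region_distances_um=m.region_distances_um))
        s1 = {s.clone_id: s.invasion3d for s in invasion_score(base)}
        s2 = {s.clone_id: s.invasion3d for s in invasion_score(rescaled)}
        for cid in s1:
            assert s1[cid] == pytest.approx(s2[cid], abs=1e-12)

    def test_replicates_averaged_before_normalization(self):
        ms = self.fixture_measurements()
        ms.append(_measurement("hi", n_p=1, avg_p=100, max_p=100, n_c=1, avg_c=150, max_c=150))
        scores = {s.clone_id: s for s in invasion_score(ms)}
        # the weak replicate pulls clone 'hi' down to the per-clone mean
        # n_p = (5+1)/2 = 3, so the normalization max is 3, not 5
        assert scores["hi"].normalization_bounds["n_p"] == (1.0, 3.0)
        assert scores["hi"].normalized["max_p"] == pytest.approx(1.0)  # (300+100)/2 = 200 = max
        assert scores["mid"].invasion3d == pytest.approx(1.0)  # ties 'hi' after averaging

    def test_constant_metric_warns_and_zeroes(self):
        ms = [
            _measurement("a", n_p=2, avg_p=100, max_p=100, n_c=1, avg_c=150, max_c=150),
            _measurement("b", n_p=2, avg_p=200, max_p=300, n_c=2, avg_c=250, max_c=350),
        ]
        with pytest.warns(UserWarning, match="constant"):
            scores = {s.clone_id: s for s in invasion_score(ms)}
        assert scores["a"].normalized["n_p"] == 0.0
        assert scores["b"].normalized["n_p"] == 0.0

    def test_single_clone_rejected(self):
        with pytest.raises(ValueError):
            invasion_score([_measurement("only", 1, 100, 100, 1, 150, 150)])
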