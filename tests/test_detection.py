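import numpy as np
import pytest
from scipy import ndimage

from bfmap.detection import (
    DetectionParams,
    DetectionResult,
    SectionImage,
    apply_reject_mask,
    compute_ridges,
    detect_axons,
    filter_components,
    intensity_mask,
)
from bfmap.synthetic import AxonSpec, NoiseSpec, make_atlas, make_section_image, render_axon


def bar_image(length=100, width=3.0, shape=(120, 500), amplitude=100.0):
    img = np.zeros(shape)
    y = shape[0] / 2
    render_axon(img, np.array([[50.0, y], [50.0 + length, y]]), width, amplitude)
    return img, y


class TestComputeRidges:
    def test_constant_image_yields_nothing(self):
        assert compute_ridges(np.full((64, 64), 7.0)).sum() == 0

    def test_bar_count_and_centerline_accuracy(self):
        """Width-3, length-100 bar: count ~length, skeleton on the centerline."""
        img, y = bar_image(100, 3.0)
        sk = compute_ridges(img)
        n = sk.sum()
        assert 90 <= n <= 110
        ys, xs = np.nonzero(sk)
        assert np.mean(np.abs(ys - y) <= 1.0) >= 0.90

    def test_count_independent_of_thickness(self):
        """The defining ridge property: pixels track length, not width."""
        n3 = compute_ridges(bar_image(100, 3.0)[0]).sum()
        n7 = compute_ridges(bar_image(100, 7.0)[0]).sum()
        assert abs(n7 - n3) / n3 <= 0.15

    def test_rejects_non_finite(self):
        img = np.zeros((64, 64))
        img[5, 5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            compute_ridges(img)

    def test_length_proportionality(self):
        """Skeleton count regresses on bar length with R^2 >= 0.98."""
        lengths = np.array([50, 100, 200, 400])
        counts = np.array(
            [compute_ridges(bar_image(L, 3.0)[0]).sum() for L in lengths], dtype=float
        )
        r = np.corrcoef(lengths, counts)[0, 1]
        assert r**2 >= 0.98

    def test_thickness_invariance_ratio(self):
        counts = [compute_ridges(bar_image(200, w)[0]).sum() for w in (1, 3, 5, 7)]
        assert max(counts) / min(counts) <= 1.2


class TestIntensityMask:
    def test_percentile_zero_keeps_everything_above_min(self):
        img = np.arange(64 * 64, dtype=float).reshape(64, 64)
        mask = intensity_mask(img, 0.0)
        assert mask.sum() == img.size - 1  # only the minimum itself excluded

    def test_constant_image_all_false(self):
        assert not intensity_mask(np.full((64, 64), 3.0), 50.0).any()

    def test_counting_oracle_top_percent(self):
        """1% of pixels at 100, rest at 1: the 99th-percentile mask is that 1%."""
        rng = np.random.default_rng(0)
        img = np.ones(10000)
        hot = rng.choice(10000, 100, replace=False)
        img[hot] = 100.0
        mask = intensity_mask(img.reshape(100, 100), 99.0)
        assert mask.sum() == 100
        assert set(np.flatnonzero(mask.ravel())) == set(hot)

    def test_mean_std_strategy(self):
        img = np.zeros((64, 64))
        img[10, 10] = 1000.0
        assert intensity_mask(img, strategy="mean_std", k=2.0).sum() == 1


def _flood_fill_sizes(grid, connectivity):
    """Brute-force component sizes by BFS (independent of scipy labeling)."""
    grid = grid.astype(bool)
    seen = np.zeros_like(grid)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = []
    h, w = grid.shape
    for sy, sx in zip(*np.nonzero(grid)):
        if seen[sy, sx]:
            continue
        stack, size = [(sy, sx)], 0
        seen[sy, sx] = True
        while stack:
            y, x = stack.pop()
            size += 1
            for dy, dx in nbrs:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and grid[ny, nx] and not seen[ny, nx]:
                    seen[ny, nx] = True
                    stack.append((ny, nx))
        sizes.append(size)
    return sorted(sizes)


class TestFilterComponents:
    def test_empty_grid(self):
        out, stats = filter_components(np.zeros((32, 32), bool), 5)
        assert out.sum() == 0 and len(stats) == 0

    def test_component_just_below_threshold_removed(self):
        grid = np.zeros((32, 32), bool)
        grid[5, 5:15] = True  # 10 pixels
        out, stats = filter_components(grid, 11)
        assert out.sum() == 0 and len(stats) == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_planted_sizes_vs_flood_fill_oracle(self, connectivity):
        grid = np.zeros((64, 64), bool)
        grid[2, 2:5] = True                      # 3 px
        grid[10:15, 10:20] = True                # 50 px
        grid[30:40, 30:50] = True                # 200 px
        assert _flood_fill_sizes(grid, connectivity) == [3, 50, 200]
        out, stats = filter_components(grid, 20, connectivity)
        assert sorted(stats["n_pixels"]) == [50, 200]
        assert _flood_fill_sizes(out, connectivity) == [50, 200]


class TestDetectAxons:
    def test_disjoint_axons_counted_exactly(self):
        img = np.zeros((200, 200))
        for k in range(5):
            y = 20.0 + 35 * k
            render_axon(img, np.array([[20.0, y], [170.0, y]]), 2.0, 100.0)
        res = detect_axons(img, DetectionParams(mask_percentile=50.0))
        assert res.n_components == 5

    def test_noisy_sections_recall_precision(self):
        """SNR-5 speckled sections: centerline recall/precision >= 0.9 at 2 px."""
        field, _ = make_atlas(n_sections=1, shape=(256, 256))
        rec, prec = [], []
        for s in range(5):
            img, gt = make_section_image(
                field, 0, AxonSpec(n_axons=6),
                noise_spec=NoiseSpec(snr=5.0, speckle_fraction=0.001), seed=s,
            )
            res = detect_axons(img, DetectionParams())
            gt_mask = np.zeros(img.shape, bool)
            gt_mask[gt.centerline_pixels[:, 1], gt.centerline_pixels[:, 0]] = True
            d_gt = ndimage.distance_transform_edt(~gt_mask)
            d_det = ndimage.distance_transform_edt(~res.ridge)
            rec.append((d_det[gt_mask] <= 2).mean())
            prec.append((d_gt[res.ridge] <= 2).mean())
        assert np.mean(rec) >= 0.9
        assert np.mean(prec) >= 0.9

    def test_refinement_schedule_monotone(self):
        field, _ = make_atlas(n_sections=1, shape=(256, 256))
        img, _ = make_section_image(field, 0, seed=1)
        schedule = [DetectionParams(min_component_size=40),
                    DetectionParams(min_component_size=80)]
        res = detect_axons(img, DetectionParams(), schedule)
        pix = [e["n_pixels"] for e in res.log if e["stage"].startswith("refine")]
        assert pix == sorted(pix, reverse=True)

    @pytest.mark.parametrize("knob, lo, hi", [
        ("mask_percentile", 80.0, 95.0),
        ("min_component_size", 10, 50),
    ])
    def test_stricter_params_never_add_pixels(self, knob, lo, hi):
        field, _ = make_atlas(n_sections=1, shape=(256, 256))
        img, _ = make_section_image(field, 0, seed=2)
        n_lo = detect_axons(img, DetectionParams(**{knob: lo})).n_pixels
        n_hi = detect_axons(img, DetectionParams(**{knob: hi})).n_pixels
        assert n_hi <= n_lo

    def test_bit_identical_rerun(self):
        field, _ = make_atlas(n_sections=1, shape=(256, 256))
        img, _ = make_section_image(field, 0, seed=3)
        a = detect_axons(img, DetectionParams())
        b = detect_axons(img, DetectionParams())
        assert np.array_equal(a.ridge, b.ridge)
        assert a.components.equals(b.components)


class TestApplyRejectMask:
    @pytest.fixture()
    def result(self):
        img = np.zeros((128, 128))
        render_axon(img, np.array([[10.0, 30.0], [110.0, 30.0]]), 2.0, 100.0)
        render_axon(img, np.array([[10.0, 90.0], [110.0, 90.0]]), 2.0, 100.0)
        return detect_axons(img, DetectionParams(mask_percentile=50.0))

    def test_empty_mask_is_identity(self, result):
        out = apply_reject_mask(result, np.zeros_like(result.ridge))
        assert np.array_equal(out.ridge, result.ridge)
        assert out.n_components == result.n_components

    def test_rejecting_whole_component(self, result):
        mask = np.zeros_like(result.ridge)
        mask[:60, :] = True  # covers the first axon entirely
        out = apply_reject_mask(result, mask)
        assert out.n_components == result.n_components - 1

    def test_random_mask_matches_set_difference(self, result):
        rng = np.random.default_rng(5)
        mask = rng.random(result.ridge.shape) < 0.3
        out = apply_reject_mask(result, mask)
        expected = set(map(tuple, np.argwhere(result.ridge))) - set(
            map(tuple, np.argwhere(mask))
        )
        assert set(map(tuple, np.argwhere(out.ridge))) == expected

    def test_shape_mismatch(self, result):
        with pytest.raises(ValueError, match="shape"):
            apply_reject_mask(result, np.zeros((5, 5), bool))


def test_section_image_validation():
    with pytest.raises(ValueError, match="32x32"):
        SectionImage(np.zeros((10, 10)))
    with pytest.raises(ValueError, match="finite"):
        SectionImage(np.full((64, 64), np.inf))


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(scales=())
    with pytest.raises(ValueError):
        DetectionParams(mask_percentile=101)
    with pytest.raises(ValueError):
        DetectionParams(min_component_size=0)
    with pytest.raises(ValueError):
        DetectionParams(connectivity=6)
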