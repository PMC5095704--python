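import numpy as np
import pandas as pd
import pytest

from bfmap.detection import DetectionParams, detect_axons
from bfmap.quantify import fractions_from_region_counts
from bfmap.registration import PlanarTransform, fit_transform
from bfmap.synthetic import (
    AxonSpec,
    NoiseSpec,
    default_profiles,
    make_atlas,
    make_cell_populations,
    make_landmarks,
    make_sample_distributions,
    make_section_image,
    perturb_profile,
)


class TestMakeAtlas:
    def test_minimal_two_region_atlas(self):
        field, onto = make_atlas(n_sections=1, shape=(64, 64), n_subdivisions=1,
                                 areas_per_subdivision=(2,))
        # root + subdivision + 2 named areas + 1 unnamed remainder
        assert len(onto) == 5
        assert len(onto.named_areas) == 2
        labels = set(np.unique(field.labels[0])) - {0}
        assert {r.id for r in onto.named_areas} <= labels

    def test_default_spec_counts(self, atlas12):
        field, onto = atlas12
        assert len(onto.top_subdivisions) == 12
        assert len(onto.named_areas) == 53
        assert field.n_sections == 40
        assert np.allclose(np.diff(field.ap_mm), -0.09)

    def test_same_seed_identical(self):
        f1, _ = make_atlas(n_sections=2, seed=3)
        f2, _ = make_atlas(n_sections=2, seed=3)
        assert np.array_equal(f1.labels[0], f2.labels[0])
        assert np.array_equal(f1.ap_mm, f2.ap_mm)

    def test_too_many_areas_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_atlas(shape=(40, 40), areas_per_subdivision=(60,) * 12)


class TestMakeLandmarks:
    def test_noiseless_landmarks_invert_to_truth(self):
        true = PlanarTransform(theta=0.2, s_ml=1.05, s_dv=0.95, tx=3.0, ty=-2.0)
        fit, _ = fit_transform(make_landmarks(true, 6, 0.0, seed=0))
        assert np.max(np.abs(fit.params() - true.params())) <= 1e-6

    def test_identity_transform_atlas_equals_image(self):
        lm = make_landmarks(PlanarTransform(), 5, 0.0, seed=1)
        assert np.array_equal(lm.image_points, lm.atlas_points)

    def test_same_seed_identical(self):
        a = make_landmarks(PlanarTransform(), 6, 0.5, seed=2)
        b = make_landmarks(PlanarTransform(), 6, 0.5, seed=2)
        assert np.array_equal(a.image_points, b.image_points)
        assert np.array_equal(a.atlas_points, b.atlas_points)


class TestMakeSectionImage:
    def test_silent_image_is_pure_background(self, atlas12):
        field, _ = atlas12
        img, gt = make_section_image(
            field, 0, AxonSpec(n_axons=0),
            noise_spec=NoiseSpec(background=20.0, snr=None, speckle_fraction=0.0),
            seed=0,
        )
        assert np.allclose(img, 20.0)
        assert len(gt.centerlines) == 0

    def test_disjoint_axons_detected_exactly(self, atlas12):
        field, _ = atlas12
        img, gt = make_section_image(
            field, 0, AxonSpec(n_axons=5, length_range=(60, 80)),
            noise_spec=NoiseSpec(snr=None, speckle_fraction=0.0), seed=4,
        )
        res = detect_axons(img, DetectionParams(mask_percentile=75.0))
        assert res.n_components == len(gt.centerlines)

    def test_requested_region_shares_rendered(self, two_region_atlas):
        """Render-then-count: 60/40 placement weights appear in centerline pixels."""
        field, onto = two_region_atlas
        a1, a2 = (r.id for r in onto.named_areas)
        labels = field.labels[0]
        tot = {a1: 0, a2: 0}
        for s in range(200):
            _, gt = make_section_image(
                field, 0,
                AxonSpec(n_axons=10, length_range=(100, 100),
                         region_weights={a1: 0.6, a2: 0.4}),
                noise_spec=NoiseSpec(snr=None, speckle_fraction=0.0), seed=s,
            )
            for line in gt.centerlines:
                pix = np.unique(np.rint(line).astype(int), axis=0)
                rids = labels[pix[:, 1], pix[:, 0]]
                tot[a1] += int((rids == a1).sum())
                tot[a2] += int((rids == a2).sum())
        share = tot[a1] / (tot[a1] + tot[a2])
        assert abs(share - 0.6) <= 0.02

    def test_same_seed_identical(self, atlas12):
        field, _ = atlas12
        a, _ = make_section_image(field, 1, seed=9)
        b, _ = make_section_image(field, 1, seed=9)
        assert np.array_equal(a, b)


class TestMakeCellPopulations:
    def test_zero_perturbation_returns_profile_exactly(self, atlas12):
        _, onto = atlas12
        prof = default_profiles(onto)["PV"]
        rng = np.random.default_rng(0)
        assert perturb_profile(prof, 0.0, rng).equals(prof)

    def test_zero_perturbation_sample_fractions_near_profile(self, atlas12,
                                                             true_transforms,
                                                             injection_site):
        field, onto = atlas12
        prof = default_profiles(onto)
        cells, gt = make_cell_populations(
            field, onto, true_transforms, injection_site,
            n_samples={"ChAT": 1}, n_cells_range=(20000, 20000), perturbation=0.0,
            n_contamination=0, seed=11,
        )
        counts = gt[~gt.is_contamination].groupby("true_region_id").size()
        inputs = cells["role"] == "input"
        emp, _ = fractions_from_region_counts(counts.to_dict(), onto, 2)
        true_fr, _ = fractions_from_region_counts(
            {int(r): v for r, v in prof["ChAT"].items()}, onto, 2)
        assert 0.5 * np.abs(emp - true_fr).sum() <= 0.05

    def test_contamination_count_planted(self, populated_cells):
        cells, gt = populated_cells
        per_sample = gt[gt.is_contamination].join(cells["sample_id"]).groupby("sample_id").size()
        assert (per_sample == 200).all()

    def test_zero_contralateral_probability(self, atlas12, true_transforms,
                                            injection_site):
        field, onto = atlas12
        cells, _ = make_cell_populations(
            field, onto, true_transforms, injection_site,
            n_samples={"SOM": 1}, n_cells_range=(500, 500),
            p_contralateral=0.0, seed=12,
        )
        assert (cells["laterality"] == "ipsi").all()

    def test_same_seed_identical(self, atlas12, true_transforms, injection_site):
        field, onto = atlas12
        kwargs = dict(n_samples={"PV": 1}, n_cells_range=(300, 500), seed=13)
        a, _ = make_cell_populations(field, onto, true_transforms, injection_site, **kwargs)
        b, _ = make_cell_populations(field, onto, true_transforms, injection_site, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_profile_rejected(self, atlas12, true_transforms, injection_site):
        field, onto = atlas12
        prof = default_profiles(onto)
        prof["ChAT"] = prof["ChAT"] * 2
        with pytest.raises(ValueError, match="sum to 1"):
            make_cell_populations(field, onto, true_transforms, injection_site,
                                  profiles=prof, seed=0)


class TestDesignedStatisticalStructure:
    def test_within_type_closer_than_across_type(self, atlas12):
        """Generating profiles: within-type draws are closer than across-type."""
        _, onto = atlas12
        profiles = default_profiles(onto)
        rng = np.random.default_rng(21)
        draws = {
            ct: [perturb_profile(p, 1 / 300, rng) for _ in range(4)]
            for ct, p in profiles.items()
        }
        within, across = [], []
        cts = list(draws)
        for i, a in enumerate(cts):
            for j, b in enumerate(cts):
                for x in draws[a]:
                    for y in draws[b]:
                        d = 0.5 * np.abs(x - y).sum()
                        if d == 0:
                            continue
                        (within if i == j else across).append(d)
        assert np.mean(within) < np.mean(across)

    def test_sample_distributions_deterministic(self, atlas12):
        _, onto = atlas12
        a = make_sample_distributions(onto, seed=5)
        b = make_sample_distributions(onto, seed=5)
        for x, y in zip(a, b):
            assert x.fractions.equals(y.fractions)
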