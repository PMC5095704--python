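import numpy as np
import pandas as pd
import pytest

from bfmap.atlas import UNASSIGNED, lookup_region
from bfmap.quantify import (
    DistributionVector,
    InjectionSite,
    aggregate_distribution,
    apply_exclusion_zone,
    assign_regions,
    axon_pixels_by_region,
    convergence_index,
    fractions_from_region_counts,
    input_fractions,
    projection_fractions,
    qc_sample,
    region_bins,
)
from bfmap.registration import PlanarTransform, apply_transform
from bfmap.synthetic import default_profiles, make_landmarks


def _cell_row(sec=0, ix=50.0, iy=50.0, role="input", sid="s1", lat="ipsi", ct="ChAT"):
    return dict(sample_id=sid, cell_type=ct, role=role, section_index=sec,
                ix=ix, iy=iy, laterality=lat)


class TestAssignRegions:
    def test_landmark_consistency(self, atlas12, true_transforms):
        """A cell at a landmark's image point lands on that landmark's atlas label."""
        field, _ = atlas12
        lm = make_landmarks(true_transforms[0], 6, 0.0, seed=1, span=(20, 140))
        cells = pd.DataFrame([
            _cell_row(0, ix, iy) for ix, iy in lm.image_points
        ])
        out = assign_regions(cells, true_transforms, field)
        for (ax, ay), rid in zip(lm.atlas_points, out["region_id"]):
            assert rid == lookup_region(field, 0, ax, ay)

    def test_outside_brain_unassigned(self, atlas12, true_transforms):
        field, _ = atlas12
        cells = pd.DataFrame([_cell_row(0, -500.0, -500.0)])
        out = assign_regions(cells, true_transforms, field)
        assert out["region_id"].iloc[0] == UNASSIGNED

    def test_missing_transform_listed(self, atlas12):
        field, _ = atlas12
        cells = pd.DataFrame([_cell_row(sec=4)])
        with pytest.raises(ValueError, match=r"\[4\]"):
            assign_regions(cells, {0: PlanarTransform()}, field)

    def test_matches_composed_oracle(self, atlas12, true_transforms):
        """500 random cells: pipeline assignment == manual map-then-lookup."""
        field, _ = atlas12
        rng = np.random.default_rng(11)
        h, w = field.shape
        cells = pd.DataFrame([
            _cell_row(int(rng.integers(0, field.n_sections)),
                      rng.uniform(0, w), rng.uniform(0, h))
            for _ in range(500)
        ])
        out = assign_regions(cells, true_transforms, field)
        for _, row in out.iterrows():
            sec = int(row["section_index"])
            ax, ay = apply_transform(true_transforms[sec], np.array([row["ix"], row["iy"]]))
            assert row["region_id"] == lookup_region(field, sec, ax, ay)


class TestExclusionZone:
    def _cells(self, site):
        """One cell per scenario, with ap_mm/region_id preassigned."""
        rows = [
            # input at 500 um -> removed (zone)
            dict(**_cell_row(), ap_mm=site.ap_mm + 0.5, region_id=1000),
            # input at 900 um, innocuous region -> kept
            dict(**_cell_row(), ap_mm=site.ap_mm + 0.9, region_id=1000),
            # input at 1200 um but inside the excluded diagonal-band region -> removed
            dict(**_cell_row(), ap_mm=site.ap_mm + 1.2,
                 region_id=site.excluded_region_ids[0]),
            # starter inside the zone -> never removed
            dict(**_cell_row(role="starter"), ap_mm=site.ap_mm + 0.1, region_id=1000),
            # tie at exactly 850 um -> excluded (strict > rule)
            dict(**_cell_row(), ap_mm=site.ap_mm + 0.85, region_id=1000),
        ]
        return pd.DataFrame(rows)

    def test_rules(self, injection_site):
        # site at AP 0 so the 850 um tie is exact in floating point
        site = InjectionSite(ap_mm=0.0, exclusion_um=850.0,
                             excluded_region_ids=injection_site.excluded_region_ids)
        kept, removed = apply_exclusion_zone(self._cells(site), site)
        assert len(kept) == 2 and len(removed) == 3
        assert set(removed["reason"]) == {"exclusion_zone", "excluded_region"}
        assert (kept["role"] == "starter").sum() == 1

    def test_planted_contamination_removed_exactly(self, populated_cells, atlas12,
                                                   true_transforms, injection_site):
        field, _ = atlas12
        cells, gt = populated_cells
        assigned = assign_regions(cells, true_transforms, field)
        _, removed = apply_exclusion_zone(assigned, injection_site)
        assert set(removed.index) == set(gt.index[gt["is_contamination"]])


class TestQC:
    @pytest.mark.parametrize("n_inputs, included", [(150, False), (199, False),
                                                    (200, True), (900, True)])
    def test_threshold_is_strict_less_than_200(self, n_inputs, included):
        cells = pd.DataFrame([_cell_row() for _ in range(n_inputs)])
        ok, n = qc_sample(cells)
        assert ok is included and n == n_inputs

    def test_starters_do_not_count_toward_qc(self):
        cells = pd.DataFrame([_cell_row(role="starter") for _ in range(300)])
        ok, n = qc_sample(cells)
        assert not ok and n == 0


class TestConvergenceIndex:
    def test_values(self):
        assert convergence_index(100, 20) == 5.0
        assert convergence_index(0, 10) == 0.0
        assert convergence_index(777, 10) == pytest.approx(77.7)

    def test_zero_starters(self):
        with pytest.raises(ValueError):
            convergence_index(100, 0)


class TestInputFractions:
    def _assigned(self, region_ids, lat=None, sid="s1"):
        lat = lat or ["ipsi"] * len(region_ids)
        df = pd.DataFrame([_cell_row(sid=sid, lat=l) for l in lat])
        df["region_id"] = region_ids
        df["ap_mm"] = 2.0
        return df

    def test_single_area(self, atlas12):
        _, onto = atlas12
        dv = input_fractions(self._assigned([1000] * 50), onto, level=2)
        area = onto[1000].acronym
        assert dv.fractions[area] == 1.0
        assert dv.denominator == 50

    def test_two_area_split(self, atlas12):
        _, onto = atlas12
        dv = input_fractions(self._assigned([1000] * 25 + [1050] * 75), onto, level=2)
        assert dv.fractions[onto[1000].acronym] == 0.25
        assert dv.fractions[onto[1050].acronym] == 0.75

    def test_multinomial_recovery_within_tv_bound(self, atlas12):
        """n=5000 multinomial draw recovers generating weights, TV <= 0.05."""
        _, onto = atlas12
        prof = default_profiles(onto)["VGLUT2"]
        rng = np.random.default_rng(2)
        counts = rng.multinomial(5000, prof.to_numpy())
        fr, _ = fractions_from_region_counts(
            {int(r): int(c) for r, c in zip(prof.index, counts)}, onto, 2)
        true_fr, _ = fractions_from_region_counts(
            {int(r): v for r, v in prof.items()}, onto, 2)
        assert 0.5 * np.abs(fr - true_fr).sum() <= 0.05

    def test_zero_cells_undefined(self, atlas12):
        _, onto = atlas12
        df = self._assigned([UNASSIGNED])
        with pytest.raises(ValueError, match="undefined"):
            input_fractions(df, onto)

    def test_contralateral_fraction_reported(self, atlas12):
        _, onto = atlas12
        dv = input_fractions(
            self._assigned([1000] * 10, lat=["contra"] * 2 + ["ipsi"] * 8), onto)
        assert dv.frac_contralateral == pytest.approx(0.2)

    def test_fractions_sum_to_one(self, atlas12):
        _, onto = atlas12
        rng = np.random.default_rng(4)
        leaf_ids = [r.id for r in onto.regions if r.level == 2]
        dv = input_fractions(
            self._assigned(list(rng.choice(leaf_ids, 400))), onto, level=2)
        assert dv.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unnamed_regions_fall_in_other_bucket(self, atlas12):
        _, onto = atlas12
        unnamed = next(r for r in onto.regions if r.acronym == "STR-un")
        dv = input_fractions(self._assigned([unnamed.id] * 10), onto, level=2)
        assert dv.fractions["STR-other"] == 1.0


class TestAxonPixelsByRegion:
    def test_single_region_total(self, atlas12):
        field, onto = atlas12
        ridge = np.zeros(field.shape, bool)
        ys, xs = np.nonzero(field.labels[0] == 1100)
        ridge[ys[:40], xs[:40]] = True
        counts, log = axon_pixels_by_region(ridge, PlanarTransform(), field, 0)
        assert counts == {1100: 40}
        assert log["n_ridge_pixels"] == 40

    def test_excluded_region_contributes_zero(self, atlas12, injection_site):
        field, onto = atlas12
        rid = injection_site.excluded_region_ids[0]
        ridge = np.zeros(field.shape, bool)
        ys, xs = np.nonzero(field.labels[0] == rid)
        ridge[ys[:30], xs[:30]] = True
        counts, log = axon_pixels_by_region(
            ridge, PlanarTransform(), field, 0, injection_site.excluded_region_ids)
        assert counts == {}
        assert log["n_excluded_region"] == 30

    def test_matches_brute_force_tally(self, atlas12, true_transforms):
        """Random ridge vs per-pixel manual tally through the same transform."""
        field, _ = atlas12
        rng = np.random.default_rng(8)
        ridge = rng.random(field.shape) < 0.01
        tr = true_transforms[2]
        counts, _ = axon_pixels_by_region(ridge, tr, field, 2)
        oracle: dict[int, int] = {}
        for y, x in np.argwhere(ridge):
            ax, ay = apply_transform(tr, np.array([float(x), float(y)]))
            rid = lookup_region(field, 2, ax, ay)
            if rid != UNASSIGNED:
                oracle[rid] = oracle.get(rid, 0) + 1
        assert counts == oracle


class TestProjectionFractions:
    def test_single_region(self, atlas12):
        _, onto = atlas12
        dv = projection_fractions({1000: 123}, onto, level=2)
        assert dv.fractions[onto[1000].acronym] == 1.0
        assert dv.modality == "output"

    def test_two_region_split(self, atlas12):
        _, onto = atlas12
        th = next(r.id for r in onto.named_areas if r.acronym == "TH-a1")
        hy = next(r.id for r in onto.named_areas if r.acronym == "HY-a1")
        dv = projection_fractions({th: 300, hy: 700}, onto, level=1)
        assert dv.fractions["TH"] == pytest.approx(0.3)
        assert dv.fractions["HY"] == pytest.approx(0.7)

    def test_zero_pixels_undefined(self, atlas12):
        _, onto = atlas12
        with pytest.raises(ValueError, match="undefined"):
            projection_fractions({}, onto)


def test_aggregation_consistency(atlas12):
    """Leaf-level fractions rolled up to level 1 equal direct computation."""
    _, onto = atlas12
    rng = np.random.default_rng(9)
    leaf_ids = [r.id for r in onto.regions if r.level == 2]
    counts = {rid: int(rng.integers(0, 50)) for rid in leaf_ids}
    fine = projection_fractions(counts, onto, level=2)
    coarse = projection_fractions(counts, onto, level=1)
    rolled = aggregate_distribution(fine, onto, level=1)
    assert np.max(np.abs(rolled.fractions - coarse.fractions)) <= 1e-12


def test_distribution_vector_invariants(atlas12):
    _, onto = atlas12
    bad = pd.Series(0.5, index=region_bins(onto, 1))
    with pytest.raises(ValueError, match="sum"):
        DistributionVector("s", "ChAT", "input", 1, bad, 100)


def test_injection_site_validation():
    with pytest.raises(ValueError):
        InjectionSite(ap_mm=0.0, exclusion_um=0.0)
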