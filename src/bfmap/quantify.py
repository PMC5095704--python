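"""Per-region quantification of input cells and axon projections.

Counts become comparable across brains through per-brain normalization: the
input from each region is the number of labeled presynaptic cells assigned
to it divided by the total counted in that brain, and the output to each
region is the number of axon-occupied ridge pixels divided by the brain-wide
total.  Three study rules shape the counts first:

* **Exclusion zone** — transsynaptic tracing labels cells near the injection
  site independently of connectivity, so input cells are counted only in
  coronal sections more than 850 µm (AP distance) from the injection site,
  and never inside the configured locally-contaminated regions (the
  horizontal limb of the diagonal band, in the study this mirrors).
* **Sample QC** — brains with fewer than 200 input cells remaining after
  exclusion are dropped from analysis.
* **Hierarchy buckets** — fractions are reported at a chosen ontology level;
  counts falling in unnamed descendants of a subdivision accumulate in a
  synthetic ``"<subdivision>-other"`` bucket so fractions always sum to 1.

Cells arrive as coordinate tables (identification is manual upstream); axon
pixels arrive as cleaned ridge images.  Both are mapped to the atlas with
the per-section planar transforms and assigned by label-field lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import UNASSIGNED, AtlasLabelField, RegionOntology, lookup_region
from .detection import DetectionResult
from .registration import PlanarTransform, apply_transform

__all__ = [
    "CELL_COLUMNS",
    "InjectionSite",
    "DistributionVector",
    "assign_regions",
    "apply_exclusion_zone",
    "qc_sample",
    "input_fractions",
    "convergence_index",
    "axon_pixels_by_region",
    "projection_fractions",
    "fractions_from_region_counts",
    "aggregate_distribution",
    "region_bins",
]

#: Required columns of a cell table.
CELL_COLUMNS = ["sample_id", "cell_type", "role", "section_index", "ix", "iy", "laterality"]

CELL_TYPES = ("ChAT", "VGLUT2", "PV", "SOM")


@dataclass(frozen=True)
class InjectionSite:
    """Injection location and the local-contamination exclusion rule."""

    ap_mm: float
    exclusion_um: float = 850.0
    excluded_region_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.exclusion_um <= 0:
            raise ValueError("exclusion half-width must be positive")


@dataclass
class DistributionVector:
    """Normalized per-region fractions for one brain sample and modality."""

    sample_id: str
    cell_type: str
    modality: str  # "input" | "output"
    level: int
    fractions: pd.Series  # indexed by region acronym (incl. "-other" buckets)
    denominator: int
    frac_contralateral: float | None = None

    def __post_init__(self) -> None:
        total = float(self.fractions.sum())
        if self.denominator > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if (self.fractions < -1e-15).any():
            raise ValueError("fractions must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.fractions.to_numpy()


def _validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns {missing}")
    bad_role = set(cells["role"].unique()) - {"input", "starter"}
    if bad_role:
        raise ValueError(f"unknown cell roles {sorted(bad_role)}")
    bad_lat = set(cells["laterality"].unique()) - {"ipsi", "contra"}
    if bad_lat:
        raise ValueError(f"unknown laterality flags {sorted(bad_lat)}")
    return cells


def assign_regions(
    cells: pd.DataFrame,
    transforms: Mapping[int, PlanarTransform],
    field: AtlasLabelField,
) -> pd.DataFrame:
    """Map cells to atlas coordinates and attach region ids and section AP.

    Adds columns ``ax``/``ay`` (atlas pixels), ``ap_mm`` and ``region_id``
    (:data:`~bfmap.atlas.UNASSIGNED` for cells landing outside the brain).
    Raises if any cell's section lacks a fitted transform.
    """
    cells = _validate_cells(cells).copy()
    sections = sorted(set(cells["section_index"].astype(int)))
    missing = [s for s in sections if s not in transforms]
    if missing:
        raise ValueError(f"no fitted transform for sections {missing}")

    cells["ax"] = np.nan
    cells["ay"] = np.nan
    cells["region_id"] = UNASSIGNED
    cells["ap_mm"] = np.nan
    for sec in sections:
        sel = cells["section_index"] == sec
        pts = cells.loc[sel, ["ix", "iy"]].to_numpy(float)
        mapped = apply_transform(transforms[sec], pts)
        cells.loc[sel, "ax"] = mapped[:, 0]
        cells.loc[sel, "ay"] = mapped[:, 1]
        cells.loc[sel, "region_id"] = lookup_region(field, sec, mapped[:, 0], mapped[:, 1])
        cells.loc[sel, "ap_mm"] = field.ap_mm[sec]
    cells["region_id"] = cells["region_id"].astype(int)
    return cells


def apply_exclusion_zone(
    cells: pd.DataFrame,
    site: InjectionSite,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove locally-contaminated input cells; starter cells are untouched.

    Input cells are removed when their section lies within the exclusion
    zone (AP distance <= ``site.exclusion_um``; the strict ">850 µm" rule —
    ties at exactly 850 µm are excluded) or when assigned to one of the
    excluded region ids anywhere in the brain.  Returns (kept, removed) with
    a ``reason`` column on the removed table.
    """
    if "ap_mm" not in cells.columns:
        raise ValueError("cells must carry section AP coordinates (run assign_regions)")
    is_input = cells["role"] == "input"
    dist_mm = (cells["ap_mm"] - site.ap_mm).abs()
    in_zone = is_input & (dist_mm <= site.exclusion_um / 1000.0)
    in_excluded = is_input & cells["region_id"].isin(site.excluded_region_ids)

    removed = cells[in_zone | in_excluded].copy()
    removed["reason"] = np.where(in_zone[in_zone | in_excluded], "exclusion_zone", "excluded_region")
    kept = cells[~(in_zone | in_excluded)].copy()
    return kept, removed


def qc_sample(cells: pd.DataFrame, min_inputs: int = 200) -> tuple[bool, int]:
    """Include/exclude decision for one brain sample.

    ``cells`` are that sample's cells *after* exclusion-zone filtering; the
    sample is excluded when fewer than ``min_inputs`` input cells remain in
    the whole brain (strict ``<``: exactly 200 is included).
    """
    n_inputs = int((cells["role"] == "input").sum())
    return n_inputs >= min_inputs, n_inputs


def convergence_index(n_input: int, n_starter: int) -> float:
    """Input cells per starter cell for one brain sample."""
    if n_starter < 1:
        raise ValueError("convergence index undefined without starter cells")
    return n_input / n_starter


# -- hierarchy binning -----------------------------------------------------

def region_bins(ontology: RegionOntology, level: int) -> list[str]:
    """Ordered region labels at an ontology level, with "-other" buckets.

    Level 1 is the major subdivisions.  At deeper levels the bins are the
    named analysis areas at that level (ontology order) followed by one
    ``"<subdivision>-other"`` bucket per subdivision for counts in unnamed
    descendants.
    """
    if level < 1:
        raise ValueError("binning level must be >= 1")
    subs = [r.acronym for r in ontology.top_subdivisions]
    if level == 1:
        return subs
    named = [r.acronym for r in ontology.named_areas if r.level == level]
    return named + [f"{s}-other" for s in subs]


def _bin_label(ontology: RegionOntology, region_id: int, level: int) -> str:
    node = ontology[region_id]
    sub = ontology.ancestor_at_level(region_id, 1)
    if level == 1:
        return sub.acronym
    if node.level >= level:
        anc = ontology.ancestor_at_level(region_id, level)
        if anc.named_area:
            return anc.acronym
    return f"{sub.acronym}-other"


def fractions_from_region_counts(
    counts: Mapping[int, float],
    ontology: RegionOntology,
    level: int = 1,
) -> tuple[pd.Series, float]:
    """Normalize per-leaf-region counts into fractions at an ontology level.

    Returns (fractions over :func:`region_bins`, total count).  Counts keyed
    by :data:`~bfmap.atlas.UNASSIGNED` are ignored.
    """
    bins = region_bins(ontology, level)
    acc = pd.Series(0.0, index=bins)
    total = 0.0
    for rid, cnt in counts.items():
        if rid == UNASSIGNED or cnt == 0:
            continue
        acc[_bin_label(ontology, int(rid), level)] += cnt
        total += cnt
    if total > 0:
        acc = acc / total
    return acc, total


def input_fractions(
    cells: pd.DataFrame,
    ontology: RegionOntology,
    level: int = 1,
) -> DistributionVector:
    """Per-region input fractions for one brain sample.

    ``cells`` is one sample's table after :func:`assign_regions` and
    :func:`apply_exclusion_zone`.  Only input cells enter the counts;
    unassigned cells are excluded from the denominator.  The denominator
    includes both hemispheres; the contralateral share is reported on the
    returned vector.
    """
    inputs = cells[cells["role"] == "input"]
    assigned = inputs[inputs["region_id"] != UNASSIGNED]
    if len(assigned) == 0:
        raise ValueError("no assigned input cells: distribution undefined")
    sample_ids = assigned["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError(f"expected one sample, got {list(sample_ids)}")
    counts = assigned.groupby("region_id").size().to_dict()
    fractions, total = fractions_from_region_counts(counts, ontology, level)
    frac_contra = float((assigned["laterality"] == "contra").mean())
    return DistributionVector(
        sample_id=str(sample_ids[0]),
        cell_type=str(assigned["cell_type"].iloc[0]),
        modality="input",
        level=level,
        fractions=fractions,
        denominator=int(total),
        frac_contralateral=frac_contra,
    )


def axon_pixels_by_region(
    result: DetectionResult | np.ndarray,
    transform: PlanarTransform,
    field: AtlasLabelField,
    section_index: int,
    excluded_region_ids: Sequence[int] = (),
) -> tuple[dict[int, int], dict[str, int]]:
    """Tally cleaned ridge pixels per atlas region for one section.

    Each ridge pixel is mapped to the atlas and assigned by label lookup.
    Pixels landing in the excluded regions (injection site, known major
    fiber tracts) or outside the brain contribute nothing; the second return
    value logs how many were excluded and why.
    """
    ridge = result.ridge if isinstance(result, DetectionResult) else np.asarray(result)
    ys, xs = np.nonzero(ridge)
    log = {"n_ridge_pixels": int(len(xs)), "n_unassigned": 0, "n_excluded_region": 0}
    if len(xs) == 0:
        return {}, log
    mapped = apply_transform(transform, np.column_stack([xs, ys]).astype(float))
    rids = lookup_region(field, section_index, mapped[:, 0], mapped[:, 1])
    rids = np.atleast_1d(rids)
    log["n_unassigned"] = int((rids == UNASSIGNED).sum())
    excl = np.isin(rids, np.asarray(excluded_region_ids, dtype=int))
    log["n_excluded_region"] = int((excl & (rids != UNASSIGNED)).sum())
    keep = (rids != UNASSIGNED) & ~excl
    vals, cnts = np.unique(rids[keep], return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnts)}, log


def projection_fractions(
    counts: Mapping[int, float],
    ontology: RegionOntology,
    level: int = 1,
    sample_id: str = "",
    cell_type: str = "",
) -> DistributionVector:
    """Axon-output fractions from per-region pixel counts summed over sections."""
    fractions, total = fractions_from_region_counts(counts, ontology, level)
    if total == 0:
        raise ValueError("no included axon pixels: distribution undefined")
    return DistributionVector(
        sample_id=sample_id,
        cell_type=cell_type,
        modality="output",
        level=level,
        fractions=fractions,
        denominator=int(total),
    )


def aggregate_distribution(
    dv: DistributionVector, ontology: RegionOntology, level: int = 1
) -> DistributionVector:
    """Roll a finer-level distribution up to a coarser level.

    Named-area fractions map to their subdivision ancestors; ``"-other"``
    buckets map to their own subdivision.  Conservation: the rolled-up
    vector equals the one computed directly at the coarser level.
    """
    if level >= dv.level:
        raise ValueError("target level must be coarser (smaller) than the source level")
    by_acr = {r.acronym: r.id for r in ontology.regions}
    bins = region_bins(ontology, level)
    acc = pd.Series(0.0, index=bins)
    for label, frac in dv.fractions.items():
        if label.endswith("-other"):
            sub_acr = label[: -len("-other")]
            target = _bin_label(ontology, by_acr[sub_acr], level)
        else:
            target = _bin_label(ontology, by_acr[label], level)
        acc[target] += frac
    return DistributionVector(
        sample_id=dv.sample_id,
        cell_type=dv.cell_type,
        modality=dv.modality,
        level=level,
        fractions=acc,
        denominator=dv.denominator,
        frac_contralateral=dv.frac_contralateral,
    )
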