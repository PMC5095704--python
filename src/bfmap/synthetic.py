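"""Synthetic study data with full ground truth.

The study this package models deposited no machine-readable images or cell
tables, so every pipeline input is emulated here, seeded and reproducible:

* a hierarchical atlas (12 major subdivisions, 53 named areas by default,
  plus unnamed remainder regions) with a per-section integer label field;
* fluorescence sections with curvilinear bright axons of known centerline,
  length and width over noisy background (plus point-like somata and
  speckle), for testing ridge detection against ground truth;
* cell populations with cell-type-specific region profiles whose
  within-type variability is smaller than across-type differences, a planted
  local-contamination population inside the injection-site exclusion zone,
  and explicit laterality;
* landmark pairs generated from known planar transforms.

Everything derives from a single root seed that fans out to per-stage child
seeds, so any stage can be regenerated independently and bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import AtlasLabelField, Region, RegionOntology
from .quantify import CELL_TYPES, InjectionSite, fractions_from_region_counts, DistributionVector
from .registration import LandmarkSet, PlanarTransform, apply_transform

__all__ = [
    "SUBDIVISIONS",
    "AxonSpec",
    "NoiseSpec",
    "SomaSpec",
    "SectionGroundTruth",
    "make_atlas",
    "make_landmarks",
    "random_transform",
    "make_section_image",
    "make_cell_populations",
    "make_sample_distributions",
    "default_profiles",
    "child_rng",
]

#: Acronyms of the 12 major brain subdivisions (mouse-brain convention).
SUBDIVISIONS = (
    "Isocortex", "OLF", "HPF", "CTXsp", "STR", "PAL",
    "TH", "HY", "MB", "P", "MY", "CB",
)

#: Named areas per subdivision summing to 53.
_AREAS_PER_SUBDIVISION = (5, 5, 4, 4, 5, 5, 5, 5, 5, 4, 3, 3)

#: Acronym of the diagonal-band-like area excluded from input counting
#: (locally contaminated part of the injection target).
EXCLUDED_AREA_ACRONYM = "NDB"


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def make_atlas(
    n_sections: int = 40,
    shape: tuple[int, int] = (160, 224),
    n_subdivisions: int = 12,
    areas_per_subdivision: Sequence[int] | None = None,
    ap_start_mm: float = 2.2,
    ap_step_mm: float = -0.09,
    pixel_size_um: float = 25.0,
    margin: int = 6,
    seed: int = 0,
) -> tuple[AtlasLabelField, RegionOntology]:
    """Block-structured label field plus matching hierarchical ontology.

    The brain occupies the grid minus a ``margin`` border of zeros.  Each
    subdivision is a vertical strip, split into horizontal bands: its named
    areas plus one unnamed remainder band (so "-other" bucket accounting is
    exercised).  Every section carries the same in-plane label grid; AP
    coordinates are spaced at the imaged-section interval (default 0.09 mm —
    one of every three 30 µm sections).

    One area of the PAL strip is acronym ``NDB``, the diagonal-band-like
    injection-target region excluded from input counting by default.
    """
    if n_subdivisions < 1 or n_sections < 1:
        raise ValueError("need at least one subdivision and one section")
    if areas_per_subdivision is None:
        if n_subdivisions == 12:
            areas_per_subdivision = _AREAS_PER_SUBDIVISION
        else:
            areas_per_subdivision = tuple([4] * n_subdivisions)
    if len(areas_per_subdivision) != n_subdivisions:
        raise ValueError("areas_per_subdivision length must match n_subdivisions")

    h, w = shape
    inner_w = w - 2 * margin
    inner_h = h - 2 * margin
    if inner_w < n_subdivisions or inner_h < max(areas_per_subdivision) + 1:
        raise ValueError("grid too small to host the requested regions")

    sub_names = (
        SUBDIVISIONS if n_subdivisions == 12 else tuple(f"SUB{i+1}" for i in range(n_subdivisions))
    )
    regions: list[Region] = [Region(8, "root", "brain root", None, 0)]
    grid = np.zeros((h, w), dtype=np.int64)
    strip_edges = margin + np.round(np.linspace(0, inner_w, n_subdivisions + 1)).astype(int)
    for i, (sub, k_areas) in enumerate(zip(sub_names, areas_per_subdivision)):
        sub_id = 100 + i
        regions.append(Region(sub_id, sub, f"{sub} subdivision", 8, 1))
        c0, c1 = strip_edges[i], strip_edges[i + 1]
        band_edges = margin + np.round(np.linspace(0, inner_h, k_areas + 2)).astype(int)
        for j in range(k_areas):
            area_id = 1000 + 50 * i + j
            if sub == "PAL" and j == 0:
                acr = EXCLUDED_AREA_ACRONYM
                name = "diagonal band analog"
            else:
                acr = f"{sub}-a{j + 1}"
                name = f"{sub} area {j + 1}"
            regions.append(Region(area_id, acr, name, sub_id, 2, named_area=True))
            grid[band_edges[j]:band_edges[j + 1], c0:c1] = area_id
        un_id = 5000 + i
        regions.append(Region(un_id, f"{sub}-un", f"{sub} unnamed remainder", sub_id, 2))
        grid[band_edges[k_areas]:band_edges[k_areas + 1], c0:c1] = un_id

    ontology = RegionOntology(regions)
    ap = ap_start_mm + ap_step_mm * np.arange(n_sections)
    field = AtlasLabelField(
        labels=[grid.copy() for _ in range(n_sections)],
        ap_mm=ap,
        pixel_size_um=pixel_size_um,
        ontology=ontology,
    )
    return field, ontology


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def make_landmarks(
    true_transform: PlanarTransform,
    n_pairs: int = 6,
    noise_sigma: float = 0.0,
    seed: int = 0,
    section_index: int = 0,
    span: tuple[float, float] = (10.0, 200.0),
) -> LandmarkSet:
    """Non-collinear image points with atlas counterparts from a known map.

    Atlas points are the transformed image points plus isotropic Gaussian
    noise of the given standard deviation.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 landmark pairs")
    rng = child_rng(seed, 11, section_index)
    lo, hi = span
    while True:
        pts = rng.uniform(lo, hi, size=(n_pairs, 2))
        centered = pts - pts.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[-1] > 1e-3 * (hi - lo):
            break
    atlas_pts = apply_transform(true_transform, pts)
    if noise_sigma > 0:
        atlas_pts = atlas_pts + rng.normal(0.0, noise_sigma, size=atlas_pts.shape)
    return LandmarkSet(image_points=pts, atlas_points=atlas_pts, section_index=section_index)


def random_transform(
    rng: np.random.Generator,
    scale_range: tuple[float, float] = (0.7, 1.3),
    max_theta_deg: float = 25.0,
    max_shift: float = 20.0,
) -> PlanarTransform:
    """Random plausible section-to-atlas transform (used for simulation)."""
    return PlanarTransform(
        theta=math.radians(rng.uniform(-max_theta_deg, max_theta_deg)),
        s_ml=rng.uniform(*scale_range),
        s_dv=rng.uniform(*scale_range),
        tx=rng.uniform(-max_shift, max_shift),
        ty=rng.uniform(-max_shift, max_shift),
    )


# ---------------------------------------------------------------------------
# Section images with axons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxonSpec:
    """Geometry of simulated axons (all units in image pixels)."""

    n_axons: int = 6
    length_range: tuple[float, float] = (60.0, 200.0)
    width_range: tuple[float, float] = (1.0, 5.0)
    curvature: float = 0.06  # heading std per 1-px step, radians
    amplitude: float = 100.0
    region_weights: Mapping[int, float] | None = None  # leaf region id -> weight


@dataclass(frozen=True)
class SomaSpec:
    n_somata: int = 0
    radius_px: float = 4.0
    amplitude: float = 150.0


@dataclass(frozen=True)
class NoiseSpec:
    """Background model: constant offset + Gaussian noise + speckle.

    ``snr`` is the axon peak amplitude divided by the Gaussian noise sigma;
    ``snr=None`` or 0 disables noise.  Speckle sets a fraction of pixels to
    bright salt values (0.5-1.5x the axon amplitude).
    """

    background: float = 20.0
    snr: float | None = 5.0
    speckle_fraction: float = 0.001


@dataclass
class SectionGroundTruth:
    centerlines: list[np.ndarray]  # per-axon (n, 2) image-frame (x, y) points
    widths: list[float]
    centerline_pixels: np.ndarray  # (m, 2) unique integer (x, y) image pixels
    region_pixel_counts: dict[int, int]  # atlas region id -> centerline px count
    soma_centers: np.ndarray  # (k, 2) image-frame (x, y)


def _wiggly_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    length: float,
    curvature: float,
    bounds: tuple[int, int],
    inside: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-step random-heading polyline, bouncing off bounds/region edges."""
    h, w = bounds
    pts = [start.astype(float)]
    heading = rng.uniform(0, 2 * math.pi)
    for _ in range(int(round(length))):
        heading += rng.normal(0.0, curvature)
        for attempt in range(8):
            nxt = pts[-1] + np.array([math.cos(heading), math.sin(heading)])
            xi, yi = int(round(nxt[0])), int(round(nxt[1]))
            ok = 1 <= xi < w - 1 and 1 <= yi < h - 1
            if ok and inside is not None:
                ok = bool(inside[yi, xi])
            if ok:
                break
            heading += math.pi / 2 + rng.normal(0.0, 0.2)
        else:
            break
        pts.append(nxt)
    return np.asarray(pts)


def render_axon(
    canvas: np.ndarray, polyline: np.ndarray, width_px: float, amplitude: float
) -> None:
    """Add one axon with Gaussian cross-section (FWHM = width) to ``canvas``.

    Dense centerline samples are splatted bilinearly and blurred, scaled so
    the ridge peak is ~``amplitude``; pixel mass along the line is
    proportional to arc length, not width.
    """
    sigma = max(width_px / 2.3548, 0.3)
    step = 0.25
    # resample polyline at uniform arc length
    seg = np.diff(polyline, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    if total <= 0:
        return
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    t = np.arange(0.0, total, step)
    xs = np.interp(t, s, polyline[:, 0])
    ys = np.interp(t, s, polyline[:, 1])
    mass = amplitude * math.sqrt(2 * math.pi) * sigma * step
    h, w = canvas.shape
    # blur only a padded window around the axon
    pad = int(math.ceil(4 * sigma)) + 2
    r0 = max(int(np.floor(ys.min())) - pad, 0)
    r1 = min(int(np.ceil(ys.max())) + pad + 1, h)
    c0 = max(int(np.floor(xs.min())) - pad, 0)
    c1 = min(int(np.ceil(xs.max())) + pad + 1, w)
    splat = np.zeros((r1 - r0, c1 - c0))
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx, fy = xs - x0, ys - y0
    for dx, dy, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi, yi = x0 + dx - c0, y0 + dy - r0
        ok = (xi >= 0) & (xi < c1 - c0) & (yi >= 0) & (yi < r1 - r0)
        np.add.at(splat, (yi[ok], xi[ok]), mass * wgt[ok])
    canvas[r0:r1, c0:c1] += ndimage.gaussian_filter(splat, sigma, mode="constant")


def make_section_image(
    field: AtlasLabelField,
    section_index: int,
    axon_spec: AxonSpec = AxonSpec(),
    soma_spec: SomaSpec = SomaSpec(),
    noise_spec: NoiseSpec = NoiseSpec(),
    true_transform: PlanarTransform = PlanarTransform(),
    seed: int = 0,
) -> tuple[np.ndarray, SectionGroundTruth]:
    """Render one fluorescence section plus its full ground truth.

    Axon start regions are drawn from ``axon_spec.region_weights`` (uniform
    over the brain when absent); centerlines are generated in the atlas
    frame (bouncing off their region's boundary so requested per-region
    pixel shares are approximately respected), mapped to the image frame
    through the inverse of ``true_transform``, and rendered with Gaussian
    cross-sections.  Ground truth records image-frame centerlines and the
    atlas-region tally of centerline pixels.
    """
    rng = child_rng(seed, 23, section_index)
    labels = field.labels[section_index]
    h, w = labels.shape
    # image-frame canvas matches the atlas grid size (transforms are modest)
    canvas = np.zeros((h, w), dtype=float)

    if axon_spec.region_weights:
        rids = np.array(list(axon_spec.region_weights), dtype=int)
        wts = np.array([axon_spec.region_weights[r] for r in rids], dtype=float)
        wts = wts / wts.sum()
    else:
        rids = wts = None

    centerlines: list[np.ndarray] = []
    widths: list[float] = []
    all_pix: list[np.ndarray] = []
    for _ in range(axon_spec.n_axons):
        if rids is not None:
            rid = int(rng.choice(rids, p=wts))
            inside = labels == rid
        else:
            inside = labels > 0
        ys, xs = np.nonzero(inside)
        if len(xs) == 0:
            continue
        k = rng.integers(len(xs))
        start = np.array([xs[k], ys[k]], dtype=float)
        length = rng.uniform(*axon_spec.length_range)
        width = rng.uniform(*axon_spec.width_range)
        atlas_line = _wiggly_polyline(
            rng, start, length, axon_spec.curvature, (h, w), inside
        )
        if len(atlas_line) < 2:
            continue
        image_line = apply_transform(true_transform, atlas_line, inverse=True)
        render_axon(canvas, image_line, width, axon_spec.amplitude)
        centerlines.append(image_line)
        widths.append(width)
        all_pix.append(np.rint(image_line).astype(int))

    soma_centers = np.empty((0, 2))
    if soma_spec.n_somata > 0:
        ys, xs = np.nonzero(labels > 0)
        ks = rng.integers(len(xs), size=soma_spec.n_somata)
        atlas_pts = np.column_stack([xs[ks], ys[ks]]).astype(float)
        soma_centers = apply_transform(true_transform, atlas_pts, inverse=True)
        yy, xx = np.mgrid[0:h, 0:w]
        for cx, cy in soma_centers:
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= soma_spec.radius_px**2
            canvas[disk] += soma_spec.amplitude

    img = canvas + noise_spec.background
    if noise_spec.snr:
        img = img + rng.normal(0.0, axon_spec.amplitude / noise_spec.snr, size=img.shape)
    if noise_spec.speckle_fraction > 0:
        n_spec = int(round(noise_spec.speckle_fraction * img.size))
        if n_spec:
            flat = rng.choice(img.size, size=n_spec, replace=False)
            img.ravel()[flat] += rng.uniform(
                0.5 * axon_spec.amplitude, 1.5 * axon_spec.amplitude, size=n_spec
            )
    img = np.clip(img, 0.0, None)

    if all_pix:
        pix = np.unique(np.concatenate(all_pix), axis=0)
    else:
        pix = np.empty((0, 2), dtype=int)
    # tally ground-truth centerline pixels per atlas region
    region_counts: dict[int, int] = {}
    if len(pix):
        atlas_pix = apply_transform(true_transform, pix.astype(float))
        xi = np.rint(atlas_pix[:, 0]).astype(int)
        yi = np.rint(atlas_pix[:, 1]).astype(int)
        ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        vals, cnts = np.unique(labels[yi[ok], xi[ok]], return_counts=True)
        region_counts = {int(v): int(c) for v, c in zip(vals, cnts) if v != 0}

    gt = SectionGroundTruth(
        centerlines=centerlines,
        widths=widths,
        centerline_pixels=pix,
        region_pixel_counts=region_counts,
        soma_centers=soma_centers,
    )
    return img, gt


# ---------------------------------------------------------------------------
# Cell populations
# ---------------------------------------------------------------------------

def default_profiles(ontology: RegionOntology) -> dict[str, pd.Series]:
    """Deterministic per-cell-type region weight profiles over named areas.

    Loosely patterned on basal-forebrain input statistics — striatum and
    hypothalamus heaviest, medulla/cerebellum near zero — with cell-type
    specific emphases large relative to the generator's within-type
    perturbation, so the comparison stage has real structure to find.  The
    diagonal-band analog area carries zero weight (it is excluded from input
    counting anyway).
    """
    base = {
        "Isocortex": 8.0, "OLF": 4.0, "HPF": 4.0, "CTXsp": 6.0,
        "STR": 25.0, "PAL": 8.0, "TH": 10.0, "HY": 20.0,
        "MB": 9.0, "P": 4.0, "MY": 1.2, "CB": 0.4,
    }
    tweaks = {
        "ChAT": {"STR": 1.8, "Isocortex": 1.5, "TH": 0.6},
        "VGLUT2": {"HY": 1.7, "MB": 1.6, "STR": 0.7},
        "PV": {"PAL": 2.0, "TH": 1.8, "HY": 0.7},
        "SOM": {"CTXsp": 2.0, "OLF": 1.8, "HPF": 1.6, "STR": 0.8},
    }
    profiles: dict[str, pd.Series] = {}
    for ct in CELL_TYPES:
        weights: dict[int, float] = {}
        for sub in ontology.top_subdivisions:
            if sub.acronym not in base:
                sub_w = 1.0
            else:
                sub_w = base[sub.acronym] * tweaks[ct].get(sub.acronym, 1.0)
            areas = [a for a in ontology.named_areas if
                     ontology.subdivision_of(a.id).id == sub.id]
            # graded split across areas, steeper for later areas
            raw = np.array([1.0 / (j + 1) for j in range(len(areas))])
            for a, r in zip(areas, raw):
                weights[a.id] = 0.0 if a.acronym == EXCLUDED_AREA_ACRONYM else sub_w * r
        s = pd.Series(weights, dtype=float)
        profiles[ct] = s / s.sum()
    return profiles


def perturb_profile(
    profile: pd.Series, perturbation: float, rng: np.random.Generator
) -> pd.Series:
    """Dirichlet perturbation with component variance ~ perturbation * p(1-p).

    ``perturbation`` is the inverse Dirichlet concentration; 0 returns the
    profile unchanged.  Zero-weight areas stay at exactly zero.
    """
    if perturbation <= 0:
        return profile.copy()
    pos = profile[profile > 0]
    drawn = rng.dirichlet(pos.to_numpy() / perturbation)
    out = pd.Series(0.0, index=profile.index)
    out[pos.index] = drawn
    return out


DEFAULT_PERTURBATION = 1.0 / 300.0


def make_cell_populations(
    field: AtlasLabelField,
    ontology: RegionOntology,
    transforms: Mapping[int, PlanarTransform],
    injection_site: InjectionSite,
    profiles: Mapping[str, pd.Series] | None = None,
    n_samples: Mapping[str, int] | None = None,
    n_cells_range: tuple[int, int] = (900, 14631),
    perturbation: float = DEFAULT_PERTURBATION,
    n_contamination: int = 300,
    n_starters_range: tuple[int, int] = (100, 400),
    p_contralateral: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated input + starter cell tables in image coordinates.

    Per sample: a Dirichlet-perturbed copy of its cell type's profile, a
    multinomial draw of input cells over the named areas (placed at random
    pixels of their area in sections strictly outside the exclusion zone,
    then mapped to image coordinates through the inverse true transform),
    ``n_contamination`` connection-independent cells planted inside the
    850 µm zone, and starter cells at the injection target.  Laterality is
    contralateral with probability ``p_contralateral``.

    Returns (cells, ground_truth) aligned on index; ground truth carries the
    true area id and an ``is_contamination`` flag per cell.
    """
    if profiles is None:
        profiles = default_profiles(ontology)
    if n_samples is None:
        n_samples = {"ChAT": 5, "VGLUT2": 5, "PV": 3, "SOM": 4}
    for ct, prof in profiles.items():
        if abs(prof.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile for {ct!r} does not sum to 1")

    labels = field.labels[0]
    pix_by_region = {
        r.id: np.column_stack(np.nonzero(labels == r.id)[::-1])  # (x, y)
        for r in ontology.regions
        if r.level == 2
    }
    dist_um = np.abs(field.ap_mm - injection_site.ap_mm) * 1000.0
    outside = np.flatnonzero(dist_um > injection_site.exclusion_um)
    inside = np.flatnonzero(dist_um <= injection_site.exclusion_um)
    if outside.size == 0 or inside.size == 0:
        raise ValueError("atlas AP range must straddle the exclusion-zone boundary")

    injection_region_ids = [
        r.id for r in ontology.regions
        if r.level == 2 and ontology.subdivision_of(r.id).acronym == "PAL"
    ]

    frames: list[pd.DataFrame] = []
    gt_frames: list[pd.DataFrame] = []

    def _place_batch(
        rng: np.random.Generator, rids: np.ndarray, secs: np.ndarray
    ) -> np.ndarray:
        """Image-frame (ix, iy) for cells with given true areas and sections."""
        atlas_pts = np.empty((len(rids), 2), dtype=float)
        for rid in np.unique(rids):
            sel = rids == rid
            pool = pix_by_region[int(rid)]
            atlas_pts[sel] = pool[rng.integers(len(pool), size=int(sel.sum()))]
        atlas_pts += rng.uniform(-0.4, 0.4, size=atlas_pts.shape)
        img_pts = np.empty_like(atlas_pts)
        for sec in np.unique(secs):
            sel = secs == sec
            img_pts[sel] = apply_transform(
                transforms[int(sec)], atlas_pts[sel], inverse=True
            )
        return img_pts

    def _frame(sid, ct, role, secs, pts, lat, rids, contam) -> None:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "cell_type": ct,
                    "role": role,
                    "section_index": secs,
                    "ix": pts[:, 0],
                    "iy": pts[:, 1],
                    "laterality": lat,
                }
            )
        )
        gt_frames.append(
            pd.DataFrame({"true_region_id": rids, "is_contamination": contam})
        )

    zone_regions = np.array([r for r in pix_by_region if len(pix_by_region[r])])
    sample_no = 0
    for ct in profiles:
        for rep in range(n_samples.get(ct, 0)):
            sample_no += 1
            sid = f"{ct}-{rep + 1}"
            rng = child_rng(seed, 37, sample_no)
            prof = perturb_profile(profiles[ct], perturbation, rng)
            # exclude locally-contaminated region ids from genuine placement
            mask = ~prof.index.isin(injection_site.excluded_region_ids)
            prof = prof[mask] / prof[mask].sum()
            n_cells = int(rng.integers(n_cells_range[0], n_cells_range[1] + 1))
            counts = rng.multinomial(n_cells, prof.to_numpy())
            rids = np.repeat(prof.index.to_numpy(int), counts)
            secs = rng.choice(outside, size=n_cells)
            pts = _place_batch(rng, rids, secs)
            lat = np.where(rng.random(n_cells) < p_contralateral, "contra", "ipsi")
            _frame(sid, ct, "input", secs, pts, lat, rids, False)

            # planted contamination inside the exclusion zone
            c_secs = rng.choice(inside, size=n_contamination)
            c_rids = rng.choice(zone_regions, size=n_contamination)
            c_pts = _place_batch(rng, c_rids, c_secs)
            _frame(sid, ct, "input", c_secs, c_pts, "ipsi", c_rids, True)

            # starter cells at the injection target
            n_start = int(rng.integers(n_starters_range[0], n_starters_range[1] + 1))
            s_secs = rng.choice(inside, size=n_start)
            s_rids = rng.choice(np.array(injection_region_ids), size=n_start)
            s_pts = _place_batch(rng, s_rids, s_secs)
            _frame(sid, ct, "starter", s_secs, s_pts, "ipsi", s_rids, False)

    cells = pd.concat(frames, ignore_index=True)
    gt = pd.concat(gt_frames, ignore_index=True)
    return cells, gt


def make_sample_distributions(
    ontology: RegionOntology,
    profiles: Mapping[str, pd.Series] | None = None,
    n_samples: Mapping[str, int] | None = None,
    n_cells_range: tuple[int, int] = (900, 14631),
    perturbation: float = DEFAULT_PERTURBATION,
    level: int = 1,
    modality: str = "input",
    seed: int = 0,
) -> list[DistributionVector]:
    """Region-count-only samples (no spatial placement) for comparison tests.

    Statistically identical to the distributions :func:`make_cell_populations`
    induces — Dirichlet-perturbed type profile, multinomial counts over named
    areas, normalized at the requested ontology level — but cheap enough for
    many replicates.
    """
    if profiles is None:
        profiles = default_profiles(ontology)
    if n_samples is None:
        n_samples = {"ChAT": 5, "VGLUT2": 5, "PV": 3, "SOM": 4}
    out: list[DistributionVector] = []
    sample_no = 0
    for ct in profiles:
        for rep in range(n_samples.get(ct, 0)):
            sample_no += 1
            rng = child_rng(seed, 53, sample_no)
            prof = perturb_profile(profiles[ct], perturbation, rng)
            n_cells = int(rng.integers(n_cells_range[0], n_cells_range[1] + 1))
            counts = rng.multinomial(n_cells, prof.to_numpy())
            count_map = {int(r): int(c) for r, c in zip(prof.index, counts)}
            fr, total = fractions_from_region_counts(count_map, ontology, level)
            out.append(
                DistributionVector(
                    sample_id=f"{ct}-{rep + 1}",
                    cell_type=ct,
                    modality=modality,
                    level=level,
                    fractions=fr,
                    denominator=int(total),
                )
            )
    return out
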