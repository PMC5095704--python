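"""End-to-end orchestration: simulate -> register -> detect -> quantify -> compare.

Each stage is a function over a run directory, so stages can be re-run
individually (the CLI maps one subcommand to each) or chained with
:func:`run_pipeline`.  All outputs are plain TIFF/CSV/JSON; a manifest
records the resolved configuration, its hash, the seed, and a checksum of
every output file, so every number is traceable to (config, seed).

All samples share one synthetic atlas and one set of per-section true
transforms; input (cell) samples and output (axon) samples are separate
simulated brains of the four cell types.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import atlas as atlas_mod
from . import compare as compare_mod
from . import detection as det_mod
from . import heatmap as heat_mod
from . import quantify as quant_mod
from . import registration as reg_mod
from . import synthetic as syn_mod

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Defaults follow the study conventions where one exists: 850 µm
    exclusion half-width, <200-input sample QC, 0.24 mm AP bins for starter
    density, comparison at the 12-subdivision ontology level, sections
    imaged at 0.09 mm spacing.
    """

    seed: int = 0
    # atlas
    n_sections: int = 40
    grid_shape: tuple[int, int] = (160, 224)
    ap_start_mm: float = 2.2
    ap_step_mm: float = -0.09
    pixel_size_um: float = 25.0
    # registration simulation
    landmark_pairs: int = 6
    landmark_noise_px: float = 0.0
    # injection / exclusion
    injection_ap_mm: float = 0.45
    exclusion_um: float = 850.0
    # cells
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"ChAT": 5, "VGLUT2": 5, "PV": 3, "SOM": 4}
    )
    n_cells_range: tuple[int, int] = (900, 14631)
    perturbation: float = syn_mod.DEFAULT_PERTURBATION
    n_contamination: int = 300
    n_starters_range: tuple[int, int] = (100, 400)
    p_contralateral: float = 0.03
    qc_min_inputs: int = 200
    # axons
    n_axon_samples: dict[str, int] = field(
        default_factory=lambda: {"ChAT": 3, "VGLUT2": 3, "PV": 3, "SOM": 3}
    )
    axon_sections: int = 6  # imaged sections per output sample
    axons_per_section: int = 6
    axon_width_range: tuple[float, float] = (1.0, 5.0)
    axon_length_range: tuple[float, float] = (60.0, 200.0)
    snr: float = 5.0
    speckle_fraction: float = 0.001
    detection: dict[str, Any] = field(default_factory=dict)
    # analysis
    comparison_level: int = 1
    heatmap_bin_mm: float = 0.24
    heatmap_bandwidth_px: float = 2.0
    heatmap_upsample: int = 4

    # -- construction ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("grid_shape", "n_cells_range", "n_starters_range",
                    "axon_width_range", "axon_length_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def detection_params(self) -> det_mod.DetectionParams:
        d = dict(self.detection)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return det_mod.DetectionParams(**d)


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _load_atlas(run_dir: Path) -> tuple[atlas_mod.AtlasLabelField, atlas_mod.RegionOntology]:
    onto = atlas_mod.load_ontology(run_dir / "atlas" / "ontology.json")
    field_ = atlas_mod.AtlasLabelField.load(run_dir / "atlas" / "atlas_manifest.csv", onto)
    return field_, onto


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    """Generate atlas, true transforms, landmarks, cells and axon imagery."""
    run_dir = Path(run_dir)
    field_, onto = syn_mod.make_atlas(
        n_sections=cfg.n_sections,
        shape=cfg.grid_shape,
        ap_start_mm=cfg.ap_start_mm,
        ap_step_mm=cfg.ap_step_mm,
        pixel_size_um=cfg.pixel_size_um,
        seed=cfg.seed,
    )
    (run_dir / "atlas").mkdir(parents=True, exist_ok=True)
    (run_dir / "truth").mkdir(parents=True, exist_ok=True)
    onto.save(run_dir / "atlas" / "ontology.json")
    field_.save(run_dir / "atlas")

    rng = syn_mod.child_rng(cfg.seed, 5)
    true_tr = {
        sec: syn_mod.random_transform(rng, scale_range=(0.85, 1.15), max_theta_deg=10.0,
                                      max_shift=8.0)
        for sec in range(cfg.n_sections)
    }
    reg_mod.save_transforms(true_tr, run_dir / "truth" / "true_transforms.json")

    landmarks = {
        sec: syn_mod.make_landmarks(
            true_tr[sec], n_pairs=cfg.landmark_pairs,
            noise_sigma=cfg.landmark_noise_px, seed=cfg.seed, section_index=sec,
        )
        for sec in range(cfg.n_sections)
    }
    reg_mod.save_landmarks(landmarks, run_dir / "landmarks.csv")

    site = _injection_site(cfg, onto)
    cells, cells_gt = syn_mod.make_cell_populations(
        field_, onto, true_tr, site,
        n_samples=cfg.n_samples,
        n_cells_range=cfg.n_cells_range,
        perturbation=cfg.perturbation,
        n_contamination=cfg.n_contamination,
        n_starters_range=cfg.n_starters_range,
        p_contralateral=cfg.p_contralateral,
        seed=cfg.seed,
    )
    cells.to_csv(run_dir / "cells.csv", index=False)
    cells_gt.to_csv(run_dir / "truth" / "cells_gt.csv", index=False)

    # output (axon) samples
    profiles = syn_mod.default_profiles(onto)
    sec_dir = run_dir / "sections"
    gt_counts: dict[str, dict[str, dict[int, int]]] = {}
    imaged = _axon_section_indices(cfg)
    sample_no = 0
    for ct, n in cfg.n_axon_samples.items():
        for rep in range(n):
            sample_no += 1
            sid = f"{ct}-ax{rep + 1}"
            sdir = sec_dir / sid
            sdir.mkdir(parents=True, exist_ok=True)
            gt_counts[sid] = {}
            for sec in imaged:
                img, gt = syn_mod.make_section_image(
                    field_, sec,
                    axon_spec=syn_mod.AxonSpec(
                        n_axons=cfg.axons_per_section,
                        length_range=cfg.axon_length_range,
                        width_range=cfg.axon_width_range,
                        region_weights=profiles[ct].to_dict(),
                    ),
                    noise_spec=syn_mod.NoiseSpec(
                        snr=cfg.snr, speckle_fraction=cfg.speckle_fraction
                    ),
                    true_transform=true_tr[sec],
                    seed=int(syn_mod.child_rng(cfg.seed, 67, sample_no).integers(2**31)),
                )
                tifffile.imwrite(sdir / f"sec_{sec:04d}.tif", img.astype(np.float32))
                gt_counts[sid][str(sec)] = gt.region_pixel_counts
    _write_json(run_dir / "truth" / "axon_gt_counts.json", gt_counts)
    _write_json(run_dir / "truth" / "imaged_sections.json", list(imaged))


def _injection_site(cfg: RunConfig, onto: atlas_mod.RegionOntology) -> quant_mod.InjectionSite:
    excluded = tuple(
        r.id for r in onto.regions if r.acronym == syn_mod.EXCLUDED_AREA_ACRONYM
    )
    return quant_mod.InjectionSite(
        ap_mm=cfg.injection_ap_mm,
        exclusion_um=cfg.exclusion_um,
        excluded_region_ids=excluded,
    )


def _axon_section_indices(cfg: RunConfig) -> list[int]:
    return list(
        np.unique(np.linspace(0, cfg.n_sections - 1, cfg.axon_sections).astype(int))
    )


def stage_register(cfg: RunConfig, run_dir: Path) -> None:
    """Fit the 5-parameter planar transform per section from landmarks."""
    run_dir = Path(run_dir)
    landmarks = reg_mod.load_landmarks(run_dir / "landmarks.csv")
    transforms, rms = {}, {}
    for sec, lm in landmarks.items():
        tr, report = reg_mod.fit_transform(lm)
        transforms[sec] = tr
        rms[sec] = report.rms
    reg_mod.save_transforms(transforms, run_dir / "transforms.json", rms=rms)


def stage_detect(cfg: RunConfig, run_dir: Path) -> None:
    """Ridge-detect axons on every simulated output section."""
    run_dir = Path(run_dir)
    params = cfg.detection_params()
    det_dir = run_dir / "detection"
    logs: dict[str, list] = {}
    for sdir in sorted((run_dir / "sections").iterdir()):
        sid = sdir.name
        odir = det_dir / sid
        odir.mkdir(parents=True, exist_ok=True)
        logs[sid] = []
        for tif in sorted(sdir.glob("sec_*.tif")):
            img = tifffile.imread(tif).astype(float)
            res = det_mod.detect_axons(img, params)
            tifffile.imwrite(
                odir / tif.name.replace("sec_", "ridge_"),
                (res.ridge * np.uint8(255)),
            )
            res.components.to_csv(
                odir / tif.name.replace("sec_", "components_").replace(".tif", ".csv"),
                index=False,
            )
            logs[sid].append({"section": tif.stem, "log": res.log})
    _write_json(det_dir / "detection_log.json", logs)


def stage_quantify_cells(cfg: RunConfig, run_dir: Path) -> None:
    """Assign, exclude, QC and normalize the input-cell distributions."""
    run_dir = Path(run_dir)
    field_, onto = _load_atlas(run_dir)
    transforms = reg_mod.load_transforms(run_dir / "transforms.json")
    cells = pd.read_csv(run_dir / "cells.csv")
    site = _injection_site(cfg, onto)

    assigned = quant_mod.assign_regions(cells, transforms, field_)
    kept, removed = quant_mod.apply_exclusion_zone(assigned, site)

    qdir = run_dir / "quant"
    qdir.mkdir(parents=True, exist_ok=True)
    meta: dict[str, Any] = {
        "exclusion_um": cfg.exclusion_um,
        "n_removed_zone": int((removed["reason"] == "exclusion_zone").sum()),
        "n_removed_region": int((removed["reason"] == "excluded_region").sum()),
        "qc": {},
        "denominators": {},
        "contralateral_fraction": {},
    }
    dists1, dists2, conv_rows = [], [], []
    for sid, grp in kept.groupby("sample_id"):
        ok, n_inputs = quant_mod.qc_sample(grp, cfg.qc_min_inputs)
        n_starters = int((cells.loc[cells["sample_id"] == sid, "role"] == "starter").sum())
        meta["qc"][sid] = {"included": bool(ok), "n_inputs": n_inputs}
        if n_starters > 0:
            conv_rows.append(
                {
                    "sample_id": sid,
                    "n_inputs": n_inputs,
                    "n_starters": n_starters,
                    "convergence_index": quant_mod.convergence_index(n_inputs, n_starters),
                }
            )
        if not ok:
            continue
        dv1 = quant_mod.input_fractions(grp, onto, level=1)
        dv2 = quant_mod.input_fractions(grp, onto, level=2)
        dists1.append(dv1)
        dists2.append(dv2)
        meta["denominators"][sid] = dv1.denominator
        meta["contralateral_fraction"][sid] = dv1.frac_contralateral

    _distributions_to_csv(dists1).to_csv(qdir / "input_fractions_level1.csv")
    _distributions_to_csv(dists2).to_csv(qdir / "input_fractions_level2.csv")
    pd.DataFrame(conv_rows).to_csv(qdir / "convergence.csv", index=False)
    _write_json(qdir / "input_meta.json", meta)
    kept.to_csv(qdir / "cells_included.csv", index=False)
    removed.to_csv(qdir / "cells_removed.csv", index=False)


def _distributions_to_csv(dists: list[quant_mod.DistributionVector]) -> pd.DataFrame:
    if not dists:
        return pd.DataFrame()
    return pd.DataFrame({d.sample_id: d.fractions for d in dists})


def stage_quantify_axons(cfg: RunConfig, run_dir: Path) -> None:
    """Per-region axon pixel tallies and normalized output distributions."""
    run_dir = Path(run_dir)
    field_, onto = _load_atlas(run_dir)
    transforms = reg_mod.load_transforms(run_dir / "transforms.json")
    site = _injection_site(cfg, onto)
    qdir = run_dir / "quant"
    qdir.mkdir(parents=True, exist_ok=True)

    dists, meta = [], {"excluded_region_ids": list(site.excluded_region_ids), "logs": {}}
    for sdir in sorted((run_dir / "detection").iterdir()):
        if not sdir.is_dir():
            continue
        sid = sdir.name
        totals: dict[int, int] = {}
        meta["logs"][sid] = []
        for tif in sorted(sdir.glob("ridge_*.tif")):
            sec = int(tif.stem.split("_")[1])
            ridge = tifffile.imread(tif) > 0
            counts, log = quant_mod.axon_pixels_by_region(
                ridge, transforms[sec], field_, sec, site.excluded_region_ids
            )
            log["section"] = sec
            meta["logs"][sid].append(log)
            for rid, c in counts.items():
                totals[rid] = totals.get(rid, 0) + c
        if not totals:
            continue
        ct = sid.split("-")[0]
        dists.append(
            quant_mod.projection_fractions(totals, onto, level=1, sample_id=sid, cell_type=ct)
        )
    _distributions_to_csv(dists).to_csv(qdir / "output_fractions_level1.csv")
    _write_json(qdir / "output_meta.json", meta)


def _read_distributions(path: Path, modality: str, level: int) -> list[quant_mod.DistributionVector]:
    if not path.exists():
        return []
    df = pd.read_csv(path, index_col=0)
    out = []
    for sid in df.columns:
        out.append(
            quant_mod.DistributionVector(
                sample_id=sid,
                cell_type=sid.split("-")[0],
                modality=modality,
                level=level,
                fractions=df[sid],
                denominator=1,
            )
        )
    return out


def stage_compare(cfg: RunConfig, run_dir: Path) -> None:
    """CC matrices and within/across-type sample statistics."""
    run_dir = Path(run_dir)
    qdir = run_dir / "quant"
    cdir = run_dir / "compare"
    cdir.mkdir(parents=True, exist_ok=True)
    level = cfg.comparison_level
    inputs = _read_distributions(qdir / f"input_fractions_level{level}.csv", "input", level)
    outputs = _read_distributions(qdir / "output_fractions_level1.csv", "output", 1)

    if not inputs:
        _write_json(cdir / "within_across.json", {"status": "no samples"})
        return

    def _means(dists):
        by_type: dict[str, list] = {}
        for d in dists:
            by_type.setdefault(d.cell_type, []).append(d)
        return {ct: compare_mod.mean_distribution(ds) for ct, ds in sorted(by_type.items())}

    in_means = _means(inputs)
    compare_mod.celltype_cc_matrix(in_means, modality_pair=("input", "input"),
                                   level=level).values.to_csv(cdir / "cc_input.csv")
    if outputs:
        out_means = _means(outputs)
        compare_mod.celltype_cc_matrix(out_means, modality_pair=("output", "output"),
                                       level=1).values.to_csv(cdir / "cc_output.csv")
        common = {ct: in_means[ct] for ct in in_means if ct in out_means}
        if common and level == 1:
            compare_mod.celltype_cc_matrix(
                common, {ct: out_means[ct] for ct in common},
                modality_pair=("input", "output"), level=1,
            ).values.to_csv(cdir / "cc_input_output.csv")

    wa = compare_mod.within_across_cc(inputs, "input")
    _write_json(
        cdir / "within_across.json",
        {
            "within_mean": wa.within_mean,
            "within_sem": wa.within_sem,
            "across_mean": wa.across_mean,
            "across_sem": wa.across_sem,
            "t": wa.t,
            "p": wa.p,
            "n_within": wa.n_within,
            "n_across": wa.n_across,
        },
    )


def stage_heatmap(cfg: RunConfig, run_dir: Path) -> None:
    """Starter-cell density heat maps per cell type."""
    run_dir = Path(run_dir)
    field_, onto = _load_atlas(run_dir)
    transforms = reg_mod.load_transforms(run_dir / "transforms.json")
    cells = pd.read_csv(run_dir / "cells.csv")
    starters = cells[cells["role"] == "starter"]
    hdir = run_dir / "heatmap"
    hdir.mkdir(parents=True, exist_ok=True)

    ap_min, ap_max = field_.ap_mm.min(), field_.ap_mm.max()
    centers = np.arange(ap_min, ap_max + 1e-9, cfg.heatmap_bin_mm)
    for ct, grp in starters.groupby("cell_type"):
        assigned = quant_mod.assign_regions(grp, transforms, field_)
        binned, n_dropped = heat_mod.bin_cells_ap(assigned, centers, cfg.heatmap_bin_mm)
        dmap = heat_mod.density_map(
            binned, centers, field_.shape, cell_type=str(ct),
            bandwidth_px=cfg.heatmap_bandwidth_px,
        )
        if cfg.heatmap_upsample > 1:
            dmap = heat_mod.upsample_bicubic(dmap, cfg.heatmap_upsample)
        dmap.save(hdir)


def stage_manifest(cfg: RunConfig, run_dir: Path) -> None:
    run_dir = Path(run_dir)
    files = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(run_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    from . import __version__

    _write_json(
        run_dir / "manifest.json",
        {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "files": files,
        },
    )


_STAGES = [
    ("simulate", stage_simulate),
    ("register", stage_register),
    ("detect", stage_detect),
    ("quantify-cells", stage_quantify_cells),
    ("quantify-axons", stage_quantify_axons),
    ("compare", stage_compare),
    ("heatmap", stage_heatmap),
]


def run_pipeline(cfg: RunConfig, run_dir: str | Path) -> Path:
    """Execute every stage in order and write the provenance manifest.

    Any stage error aborts the run with a :class:`StageError` naming the
    stage.  Rerunning with an unchanged config rewrites identical bytes.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _write_json(run_dir / "config.json", cfg.to_dict())
    for name, fn in _STAGES:
        try:
            fn(cfg, run_dir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, str(exc)) from exc
    stage_manifest(cfg, run_dir)
    return run_dir
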