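"""Starter-cell density heat maps.

The spatial extent of the starter population determines what a tracing
experiment actually samples, so each cell type's starter cells are rendered
as a normalized density map: cells are binned along the anterior–posterior
axis into 0.24 mm slabs centered on the reference slice coordinates, the
per-slab 2D (atlas-frame) histograms are pooled over all samples of the
cell type, optionally Gaussian-smoothed, max-normalized so the hottest bin
of a cell type equals 1, and bicubically upsampled for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = ["DensityMap", "bin_cells_ap", "density_map", "upsample_bicubic"]

#: Default AP slab thickness in mm.
AP_BIN_MM = 0.24


@dataclass
class DensityMap:
    """Per-AP-bin density grids in the atlas frame."""

    grids: np.ndarray  # (n_bins, h, w), max-normalized
    bin_centers_mm: np.ndarray
    cell_type: str
    norm_constant: float  # pre-normalization maximum
    bandwidth_px: float = 0.0
    upsample_factor: int = 1

    def save(self, directory: str | Path, prefix: str | None = None) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix or f"starter_density_{self.cell_type}"
        tifffile.imwrite(directory / f"{prefix}.tif", self.grids.astype(np.float32))
        manifest = {
            "cell_type": self.cell_type,
            "bin_centers_mm": list(map(float, self.bin_centers_mm)),
            "norm_constant": self.norm_constant,
            "bandwidth_px": self.bandwidth_px,
            "upsample_factor": self.upsample_factor,
        }
        path = directory / f"{prefix}.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return path


def bin_cells_ap(
    cells: pd.DataFrame,
    bin_centers_mm: np.ndarray,
    bin_width_mm: float = AP_BIN_MM,
) -> tuple[dict[int, pd.DataFrame], int]:
    """Assign cells to AP slabs centered on the given coordinates.

    Each cell joins the bin whose half-open interval
    ``[center - w/2, center + w/2)`` contains its AP coordinate, so no cell
    is double-counted; a cell exactly midway between two centers falls in
    the more anterior bin.  Cells outside every bin are dropped; their count
    is returned alongside the per-bin tables.
    """
    centers = np.sort(np.asarray(bin_centers_mm, dtype=float))
    half = bin_width_mm / 2.0
    ap = cells["ap_mm"].to_numpy(float)
    lower = centers - half
    idx = np.searchsorted(lower, ap, side="right") - 1
    in_bin = (idx >= 0) & (ap < np.where(idx < 0, -np.inf, centers[np.clip(idx, 0, None)] + half))
    binned: dict[int, pd.DataFrame] = {}
    for k in range(len(centers)):
        sel = in_bin & (idx == k)
        if sel.any():
            binned[k] = cells[sel]
    n_dropped = int((~in_bin).sum())
    return binned, n_dropped


def density_map(
    binned: dict[int, pd.DataFrame],
    bin_centers_mm: np.ndarray,
    grid_shape: tuple[int, int],
    cell_type: str = "",
    bandwidth_px: float = 2.0,
    per_sample_average: bool = False,
) -> DensityMap:
    """Pooled, smoothed, max-normalized starter density.

    Cells (columns ``ax``/``ay`` in atlas pixels) are histogrammed per AP
    bin on the atlas grid and Gaussian-smoothed with reflective boundaries,
    which conserves total mass for any bandwidth (bandwidth 0 = no
    smoothing).  By default cells of all samples are pooled before
    normalizing; ``per_sample_average`` instead normalizes each sample's
    histogram by its cell count and averages, weighting samples equally.
    The final map is scaled so its maximum over all bins is exactly 1.
    """
    centers = np.sort(np.asarray(bin_centers_mm, dtype=float))
    h, w = grid_shape
    grids = np.zeros((len(centers), h, w), dtype=float)
    any_cells = False
    for k, cells in binned.items():
        any_cells = any_cells or len(cells) > 0
        if per_sample_average:
            hists = []
            for _, sample_cells in cells.groupby("sample_id"):
                hist = _hist2d(sample_cells, h, w)
                hists.append(hist / max(len(sample_cells), 1))
            grids[k] = np.mean(hists, axis=0) if hists else 0.0
        else:
            grids[k] = _hist2d(cells, h, w)
        if bandwidth_px > 0:
            grids[k] = ndimage.gaussian_filter(grids[k], bandwidth_px, mode="reflect")
    if not any_cells:
        import warnings

        warnings.warn("no starter cells: density map is empty", stacklevel=2)
        norm = 0.0
    else:
        norm = float(grids.max())
        if norm > 0:
            grids = grids / norm
    return DensityMap(
        grids=grids,
        bin_centers_mm=centers,
        cell_type=cell_type,
        norm_constant=norm,
        bandwidth_px=bandwidth_px,
    )


def _hist2d(cells: pd.DataFrame, h: int, w: int) -> np.ndarray:
    ax = np.rint(cells["ax"].to_numpy(float)).astype(int)
    ay = np.rint(cells["ay"].to_numpy(float)).astype(int)
    inside = (ax >= 0) & (ax < w) & (ay >= 0) & (ay < h)
    hist = np.zeros((h, w), dtype=float)
    np.add.at(hist, (ay[inside], ax[inside]), 1.0)
    return hist


def upsample_bicubic(dmap: DensityMap, factor: int) -> DensityMap:
    """Bicubic upsampling that preserves values at the original lattice.

    Output grids have shape ``((h-1)*factor + 1, (w-1)*factor + 1)`` so
    every original node coincides with an output node; cubic-spline
    interpolation reproduces node values exactly, and negative overshoot
    between nodes is clipped to 0.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return dmap
    n, h, w = dmap.grids.shape
    oh, ow = (h - 1) * factor + 1, (w - 1) * factor + 1
    rows = np.arange(oh) / factor
    cols = np.arange(ow) / factor
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((n, oh, ow), dtype=float)
    for k in range(n):
        out[k] = ndimage.map_coordinates(dmap.grids[k], [rr, cc], order=3, mode="nearest")
    np.clip(out, 0.0, None, out=out)
    return DensityMap(
        grids=out,
        bin_centers_mm=dmap.bin_centers_mm,
        cell_type=dmap.cell_type,
        norm_constant=dmap.norm_constant,
        bandwidth_px=dmap.bandwidth_px,
        upsample_factor=dmap.upsample_factor * factor,
    )
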