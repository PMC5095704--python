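"""Hierarchical brain-region ontology and atlas label-field lookup.

Quantification in this package mirrors how whole-brain tracing studies count
labeled cells and axon pixels: every detected object is assigned the integer
label of the atlas voxel it lands on, and counts are then rolled up a region
hierarchy (leaf areas -> major brain subdivisions -> root).  The two classes
here carry that structure:

``RegionOntology``
    A validated tree of brain regions (one root, unique ids).  Level-1 nodes
    are the major brain subdivisions (12 in the mouse-brain convention this
    package follows); a subset of deeper nodes are flagged as *named analysis
    areas* (the finer areas quantified individually — 53 in that convention).
    Descendants of a subdivision that are not named areas accumulate into a
    synthetic ``"<subdivision>-other"`` bucket, because named-area counts need
    not sum to the subdivision total.

``AtlasLabelField``
    A stack of per-section integer label images (label = region id, 0 =
    outside the brain) with a pixel size in µm and an anterior–posterior (AP)
    coordinate in mm per section (bregma-referenced, positive anterior).

Coordinates are 0-based in-plane pixels: row = dorsoventral (increasing
ventrally), column = mediolateral (increasing laterally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Region",
    "RegionOntology",
    "AtlasLabelField",
    "OntologyFormatError",
    "UNASSIGNED",
    "load_ontology",
    "lookup_region",
    "ancestor_at_level",
]

#: Sentinel region id for points that fall outside the brain (label 0) or off
#: the label grid entirely.
UNASSIGNED: int = -1


class OntologyFormatError(ValueError):
    """Raised when an ontology file violates the tree invariants."""


@dataclass(frozen=True)
class Region:
    id: int
    acronym: str
    name: str
    parent: int | None
    level: int
    #: True if this region is one of the named analysis areas.
    named_area: bool = False


class RegionOntology:
    """Validated hierarchical region tree.

    Parameters
    ----------
    regions:
        Iterable of :class:`Region` records.  ``level`` on each record is
        recomputed from the parent chain and validated, not trusted.
    """

    def __init__(self, regions: Iterable[Region]):
        nodes: dict[int, Region] = {}
        for r in regions:
            if r.id in nodes:
                raise OntologyFormatError(f"duplicate region id {r.id} ({r.acronym!r})")
            nodes[r.id] = r

        roots = [r for r in nodes.values() if r.parent is None]
        if len(roots) != 1:
            raise OntologyFormatError(
                f"expected exactly one root region, found {len(roots)}: "
                f"{[r.acronym for r in roots]}"
            )
        for r in nodes.values():
            if r.parent is not None and r.parent not in nodes:
                raise OntologyFormatError(
                    f"region {r.id} ({r.acronym!r}) references absent parent {r.parent}"
                )

        # Recompute depth from the parent chain; detect cycles on the way.
        depth: dict[int, int] = {}

        def _depth(rid: int, trail: set[int]) -> int:
            if rid in depth:
                return depth[rid]
            if rid in trail:
                raise OntologyFormatError(f"cycle through region {rid}")
            node = nodes[rid]
            d = 0 if node.parent is None else _depth(node.parent, trail | {rid}) + 1
            depth[rid] = d
            return d

        for rid in nodes:
            _depth(rid, set())

        self._nodes = {
            rid: Region(r.id, r.acronym, r.name, r.parent, depth[rid], r.named_area)
            for rid, r in nodes.items()
        }
        self._children: dict[int, list[int]] = {rid: [] for rid in nodes}
        for r in self._nodes.values():
            if r.parent is not None:
                self._children[r.parent].append(r.id)
        self.root: Region = next(r for r in self._nodes.values() if r.parent is None)

    # -- basic access ------------------------------------------------------
    def __contains__(self, rid: int) -> bool:
        return rid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __getitem__(self, rid: int) -> Region:
        try:
            return self._nodes[rid]
        except KeyError:
            raise KeyError(f"unknown region id {rid}") from None

    @property
    def regions(self) -> list[Region]:
        """All regions in insertion order."""
        return list(self._nodes.values())

    @property
    def top_subdivisions(self) -> list[Region]:
        """The level-1 regions (major brain subdivisions)."""
        return [r for r in self._nodes.values() if r.level == 1]

    @property
    def named_areas(self) -> list[Region]:
        """The finer named analysis areas."""
        return [r for r in self._nodes.values() if r.named_area]

    def children(self, rid: int) -> list[Region]:
        return [self._nodes[c] for c in self._children[self[rid].id]]

    def leaves(self, rid: int | None = None) -> list[Region]:
        """Leaf regions of the subtree rooted at ``rid`` (default: whole tree)."""
        start = self.root.id if rid is None else self[rid].id
        out: list[Region] = []
        stack = [start]
        while stack:
            cur = stack.pop()
            kids = self._children[cur]
            if kids:
                stack.extend(reversed(kids))
            else:
                out.append(self._nodes[cur])
        return out

    def ancestors(self, rid: int) -> list[Region]:
        """Ancestor chain from the region itself up to the root."""
        chain = [self[rid]]
        while chain[-1].parent is not None:
            chain.append(self._nodes[chain[-1].parent])
        return chain

    def ancestor_at_level(self, rid: int, level: int) -> Region:
        """The unique ancestor of ``rid`` at the requested depth.

        Returns the region itself if it already sits at that depth.  Raises
        ``ValueError`` if the region is shallower than ``level``.
        """
        node = self[rid]
        if level < 0:
            raise ValueError(f"level must be >= 0, got {level}")
        if node.level < level:
            raise ValueError(
                f"region {node.acronym!r} is at level {node.level}, "
                f"shallower than requested level {level}"
            )
        while node.level > level:
            node = self._nodes[node.parent]  # type: ignore[index]
        return node

    def subdivision_of(self, rid: int) -> Region:
        """Major-subdivision (level-1) ancestor of a region."""
        return self.ancestor_at_level(rid, 1)

    # -- serialization -----------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "id": r.id,
                "acronym": r.acronym,
                "name": r.name,
                "parent": r.parent,
                "level": r.level,
                "named_area": r.named_area,
            }
            for r in self._nodes.values()
        ]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1, sort_keys=True))


def load_ontology(path: str | Path) -> RegionOntology:
    """Load and validate a region ontology from a JSON array of records.

    Each record is ``{id, acronym, name, parent, level[, named_area]}`` with
    ``parent: null`` marking the root.  ``level`` is validated against the
    parent chain; ``named_area`` defaults to false.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise OntologyFormatError("ontology file must contain a JSON array of records")
    regions = []
    for rec in raw:
        try:
            regions.append(
                Region(
                    id=int(rec["id"]),
                    acronym=str(rec["acronym"]),
                    name=str(rec.get("name", rec["acronym"])),
                    parent=None if rec.get("parent") is None else int(rec["parent"]),
                    level=int(rec.get("level", 0)),
                    named_area=bool(rec.get("named_area", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise OntologyFormatError(f"malformed ontology record {rec!r}: {exc}") from exc
    onto = RegionOntology(regions)
    # Validate declared levels when present.
    for rec in raw:
        declared = rec.get("level")
        actual = onto[int(rec["id"])].level
        if declared is not None and int(declared) != actual:
            raise OntologyFormatError(
                f"region {rec['id']} declares level {declared} but sits at depth {actual}"
            )
    return onto


@dataclass
class AtlasLabelField:
    """Per-section integer label grids plus section geometry.

    ``labels`` is a list of 2D integer arrays (one per section, anterior
    first); ``ap_mm`` the AP coordinate of each section in mm relative to
    bregma (strictly monotonic); ``pixel_size_um`` the in-plane pixel size.
    """

    labels: list[np.ndarray]
    ap_mm: np.ndarray
    pixel_size_um: float
    ontology: RegionOntology | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ap_mm = np.asarray(self.ap_mm, dtype=float)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if len(self.labels) != self.ap_mm.size:
            raise ValueError("one AP coordinate required per section")
        diffs = np.diff(self.ap_mm)
        if diffs.size and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("AP coordinates must be strictly monotonic")
        if self.ontology is not None:
            known = {r.id for r in self.ontology.regions}
            for k, lab in enumerate(self.labels):
                present = set(np.unique(lab).tolist()) - {0}
                unknown = present - known
                if unknown:
                    raise ValueError(
                        f"section {k} contains labels absent from the ontology: "
                        f"{sorted(unknown)}"
                    )

    @property
    def n_sections(self) -> int:
        return len(self.labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels[0].shape  # type: ignore[return-value]

    def section_index_at(self, ap_mm: float) -> int:
        """Index of the section whose AP coordinate is nearest ``ap_mm``."""
        return int(np.argmin(np.abs(self.ap_mm - ap_mm)))

    # -- I/O ---------------------------------------------------------------
    def save(self, directory: str | Path, prefix: str = "atlas") -> Path:
        """Write one 16-bit TIFF per section plus a CSV manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for k, lab in enumerate(self.labels):
            fname = f"{prefix}_{k:04d}.tif"
            tifffile.imwrite(directory / fname, lab.astype(np.uint16))
            rows.append(
                {
                    "section_index": k,
                    "ap_mm": self.ap_mm[k],
                    "pixel_size_um": self.pixel_size_um,
                    "filename": fname,
                }
            )
        manifest = directory / f"{prefix}_manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    @classmethod
    def load(
        cls, manifest: str | Path, ontology: RegionOntology | None = None
    ) -> "AtlasLabelField":
        manifest = Path(manifest)
        df = pd.read_csv(manifest).sort_values("section_index")
        labels = [
            tifffile.imread(manifest.parent / fname).astype(np.int64)
            for fname in df["filename"]
        ]
        return cls(
            labels=labels,
            ap_mm=df["ap_mm"].to_numpy(),
            pixel_size_um=float(df["pixel_size_um"].iloc[0]),
            ontology=ontology,
        )


def lookup_region(
    field: AtlasLabelField,
    section_index: int,
    x: float | np.ndarray,
    y: float | np.ndarray,
) -> int | np.ndarray:
    """Region id at the nearest label pixel, or :data:`UNASSIGNED`.

    ``x`` is the in-plane column (mediolateral) and ``y`` the row
    (dorsoventral) in atlas pixels.  Points landing on label 0 or off the
    grid map to :data:`UNASSIGNED`.  Vectorized over ``x``/``y``.
    """
    if not 0 <= section_index < field.n_sections:
        raise IndexError(
            f"section index {section_index} outside stack of {field.n_sections}"
        )
    lab = field.labels[section_index]
    xi = np.rint(np.asarray(x, dtype=float)).astype(int)
    yi = np.rint(np.asarray(y, dtype=float)).astype(int)
    scalar = xi.ndim == 0
    xi, yi = np.atleast_1d(xi), np.atleast_1d(yi)
    out = np.full(xi.shape, UNASSIGNED, dtype=np.int64)
    inside = (xi >= 0) & (xi < lab.shape[1]) & (yi >= 0) & (yi < lab.shape[0])
    vals = lab[yi[inside], xi[inside]]
    out[inside] = np.where(vals == 0, UNASSIGNED, vals)
    return int(out[0]) if scalar else out


def ancestor_at_level(ontology: RegionOntology, region_id: int, level: int) -> int:
    """Id of the unique ancestor of ``region_id`` at the requested depth."""
    return ontology.ancestor_at_level(region_id, level).id
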