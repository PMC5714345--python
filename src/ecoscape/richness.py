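"""Species richness from range polygons via a presence-absence matrix.

Each species contributes one column of a binary cells x species matrix bound
to a 1-km grid: a cell is a presence when the species' range polygon overlaps
it by more than ``min_cover`` of the cell area (default: any positive-area
overlap; mere boundary touching never counts).  Summing columns under a
metadata filter yields stratified richness grids — IUCN-listed conservation
dependent species (CR, EN, VU, NT) and endemics are the two strata of
interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .grids import Grid

__all__ = [
    "IUCN_CATEGORIES",
    "THREATENED_CATEGORIES",
    "SpeciesRange",
    "PresenceAbsenceMatrix",
    "build_pam",
    "richness_grid",
    "iucn_listed",
    "is_endemic",
]

IUCN_CATEGORIES = ("CR", "EN", "VU", "NT", "LC")
THREATENED_CATEGORIES = ("CR", "EN", "VU", "NT")


@dataclass
class SpeciesRange:
    """One species' geographical range with Red List status and endemism."""

    species_id: str
    geometry: BaseGeometry
    iucn_status: str = "LC"
    endemic: bool = False
    effects: dict = field(default_factory=dict)  # generator ground truth, if any

    def __post_init__(self) -> None:
        if self.iucn_status not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {self.iucn_status!r}")
        if not self.geometry.is_valid:
            raise ValueError(f"species {self.species_id}: invalid polygon")


@dataclass
class PresenceAbsenceMatrix:
    """Binary cells x species table bound to a 1-km grid template.

    Rows follow row-major cell order of the template grid.
    """

    grid: Grid
    matrix: np.ndarray
    species: list

    def __post_init__(self) -> None:
        n_cells = self.grid.n_rows * self.grid.n_cols
        if self.matrix.shape != (n_cells, len(self.species)):
            raise ValueError("PAM shape must be (cells, species)")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("PAM entries must be binary")


def iucn_listed(sp: SpeciesRange) -> bool:
    """Conservation-dependent stratum: CR, EN, VU or NT."""
    return sp.iucn_status in THREATENED_CATEGORIES


def is_endemic(sp: SpeciesRange) -> bool:
    return bool(sp.endemic)


def build_pam(ranges: list[SpeciesRange], template: Grid,
              min_cover: float = 0.0) -> PresenceAbsenceMatrix:
    """Rasterize species ranges into a presence-absence matrix.

    Presence in a cell requires the intersection area with the (closed,
    rectangular) cell to exceed ``min_cover`` times the cell area; with the
    default ``min_cover = 0`` any positive-area overlap counts.
    """
    if not math.isclose(template.cell_size, 1000.0, rel_tol=1e-9):
        raise ValueError("presence-absence template must be a 1-km grid")
    nr, nc = template.shape
    xs = template.origin_x + np.arange(nc) * template.cell_size
    ys = template.origin_y - np.arange(nr) * template.cell_size
    xx, yy = np.meshgrid(xs, ys)
    boxes = shapely.box(
        xx.ravel(), yy.ravel() - template.cell_size,
        xx.ravel() + template.cell_size, yy.ravel(),
    )
    tree = STRtree(boxes)
    cell_area = template.cell_size**2
    threshold = max(min_cover, 0.0) * cell_area

    matrix = np.zeros((boxes.size, len(ranges)), dtype=np.uint8)
    for s, sp in enumerate(ranges):
        if sp.geometry.is_empty:
            continue
        if not sp.geometry.is_valid:
            raise ValueError(f"species {sp.species_id}: invalid polygon")
        candidates = tree.query(sp.geometry)
        if candidates.size == 0:
            continue
        areas = shapely.area(shapely.intersection(boxes[candidates], sp.geometry))
        hits = candidates[areas > max(threshold, 1e-9)]
        matrix[hits, s] = 1
    return PresenceAbsenceMatrix(grid=template, matrix=matrix, species=list(ranges))


def richness_grid(pam: PresenceAbsenceMatrix,
                  filter: Callable[[SpeciesRange], bool] | None = None) -> Grid:
    """Per-cell count of present species passing the metadata filter."""
    if filter is None:
        keep = np.ones(len(pam.species), dtype=bool)
    else:
        keep = np.array([bool(filter(sp)) for sp in pam.species])
    counts = pam.matrix[:, keep].sum(axis=1).astype(float)
    return pam.grid.like(counts.reshape(pam.grid.shape), nodata=-9999.0)
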