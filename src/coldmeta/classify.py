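"""Stratum assignment: soil depth bins, latitude bands, MAT/MAP biomes.

Depth measurements are snapped to the nearest of the 5/10/15 cm categories
(ties round down, i.e. toward the shallower bin); anything deeper than 15 cm
falls in BELOW15 and missing depths get UNKNOWN. Latitude bands use strict
thresholds at +-50 degrees. Biomes follow a configurable MAT-MAP region map
with a dry-site override: below the desert precipitation cutoff, vegetation
cover decides between tundra and grassland on MAT alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import yaml

from .errors import ClassificationError, InvalidInputError
from .types import Biome, DepthBin, LatitudeBand, StratumLabels, StudyRecord, _is_missing

_DEPTH_CATEGORIES = ((5.0, DepthBin.D5), (10.0, DepthBin.D10), (15.0, DepthBin.D15))


def classify_depth(depth_cm: Optional[float]) -> DepthBin:
    """Snap a sampling depth (cm) to its depth bin.

    Missing -> UNKNOWN (excluded from depth contrasts, kept elsewhere);
    > 15 cm -> BELOW15; otherwise the nearest of 5/10/15 with ties rounded
    down.
    """
    if _is_missing(depth_cm):
        return DepthBin.UNKNOWN
    d = float(depth_cm)
    if d < 0 or not math.isfinite(d):
        raise InvalidInputError(f"depth_cm must be finite and >= 0, got {depth_cm}")
    if d > 15.0:
        return DepthBin.BELOW15
    best = None
    best_dist = math.inf
    for center, bin_ in _DEPTH_CATEGORIES:
        dist = abs(d - center)
        # strict '<' keeps the first (shallower) category on exact ties
        if dist < best_dist:
            best, best_dist = bin_, dist
    return best


def classify_latitude(latitude_deg: float) -> LatitudeBand:
    """Band a signed latitude: >50 N, 50 N..50 S, or >50 S (strict at 50)."""
    if _is_missing(latitude_deg):
        raise InvalidInputError("latitude_deg is missing")
    lat = float(latitude_deg)
    if not math.isfinite(lat) or abs(lat) > 90.0:
        raise InvalidInputError(f"latitude_deg must be in [-90, 90], got {latitude_deg}")
    if lat > 50.0:
        return LatitudeBand.HIGH_N
    if lat < -50.0:
        return LatitudeBand.HIGH_S
    return LatitudeBand.INTERMEDIATE


@dataclass(frozen=True)
class BiomeBoundaries:
    """Parametric MAT-MAP region boundaries for the biome classifier.

    Regions (for MAP >= ``desert_map_mm``):

    * tundra:    MAT < ``tundra_mat_c``
    * grassland: MAP below the forest line
      ``grassland_map_intercept_mm + grassland_map_slope_mm_per_c * (MAT - tundra_mat_c)``
    * boreal:    above the forest line with MAT < ``boreal_mat_c``
    * temperate: above the forest line with MAT >= ``boreal_mat_c``

    Below ``desert_map_mm`` the dry-site override applies: tundra when
    MAT < ``desert_tundra_mat_c``, grassland otherwise. All boundaries are
    editable via YAML so alternative region maps can be swapped in.
    """

    desert_map_mm: float = 260.0
    desert_tundra_mat_c: float = -5.0
    tundra_mat_c: float = -5.0
    boreal_mat_c: float = 3.0
    grassland_map_intercept_mm: float = 300.0
    grassland_map_slope_mm_per_c: float = 25.0

    def forest_line_mm(self, mat_c: float) -> float:
        return self.grassland_map_intercept_mm + self.grassland_map_slope_mm_per_c * (
            mat_c - self.tundra_mat_c
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "BiomeBoundaries":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


DEFAULT_BOUNDARIES = BiomeBoundaries()


def classify_biome(mat_c: float, map_mm: float,
                   boundaries: BiomeBoundaries = DEFAULT_BOUNDARIES) -> Biome:
    """Assign a biome from mean annual temperature (degC) and precipitation (mm)."""
    if _is_missing(mat_c) or _is_missing(map_mm):
        raise ClassificationError(f"MAT/MAP missing for point (MAT={mat_c}, MAP={map_mm})")
    mat, prec = float(mat_c), float(map_mm)
    if not (math.isfinite(mat) and math.isfinite(prec)) or prec < 0:
        raise ClassificationError(
            f"cannot classify point (MAT={mat_c}, MAP={map_mm}): non-finite or negative MAP"
        )
    if prec < boundaries.desert_map_mm:
        return Biome.TUNDRA if mat < boundaries.desert_tundra_mat_c else Biome.GRASSLAND
    if mat < boundaries.tundra_mat_c:
        return Biome.TUNDRA
    if prec < boundaries.forest_line_mm(mat):
        return Biome.GRASSLAND
    return Biome.BOREAL if mat < boundaries.boreal_mat_c else Biome.TEMPERATE


def label_record(record: StudyRecord,
                 boundaries: BiomeBoundaries = DEFAULT_BOUNDARIES) -> StratumLabels:
    """Attach all three stratum labels to a record.

    Raises with the name of the missing metadata field when latitude or
    MAT/MAP are absent; a missing depth is legal and maps to UNKNOWN.
    """
    for name in ("latitude_deg", "mat_c", "map_mm"):
        if _is_missing(getattr(record, name)):
            raise ClassificationError(
                f"record {record.ref}: missing metadata field '{name}'"
            )
    return StratumLabels(
        depth_bin=classify_depth(record.depth_cm),
        latitude_band=classify_latitude(record.latitude_deg),
        biome=classify_biome(record.mat_c, record.map_mm, boundaries),
    )
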