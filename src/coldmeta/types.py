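"""Core domain types shared across the pipeline."""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np


class DepthBin(str, enum.Enum):
    D5 = "D5"
    D10 = "D10"
    D15 = "D15"
    BELOW15 = "BELOW15"
    UNKNOWN = "UNKNOWN"


class LatitudeBand(str, enum.Enum):
    HIGH_N = "HIGH_N"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH_S = "HIGH_S"


class Biome(str, enum.Enum):
    TUNDRA = "TUNDRA"
    BOREAL = "BOREAL"
    TEMPERATE = "TEMPERATE"
    GRASSLAND = "GRASSLAND"


class CIMethod(str, enum.Enum):
    WALD = "WALD"
    BCA = "BCA"
    NONE = "NONE"


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class StudyRecord:
    """One warmed-vs-control comparison: arm summaries, site metadata, moderators.

    A study contributing sites in several biomes appears once per biome under
    distinct ``dataset_id`` values. Rows that reuse one control group share a
    ``control_cluster`` id and must carry identical control-arm statistics.
    """

    study_id: str
    dataset_id: str
    response: str
    mean_w: float
    n_w: int
    mean_c: float
    n_c: int
    latitude_deg: float
    mat_c: float
    map_mm: float
    control_cluster: str
    sd_w: Optional[float] = None
    sd_c: Optional[float] = None
    se_w: Optional[float] = None
    se_c: Optional[float] = None
    depth_cm: Optional[float] = None
    delta_t: Optional[float] = None
    duration_yr: Optional[float] = None
    moisture_effect: Optional[float] = None

    @property
    def key(self) -> tuple:
        return (self.dataset_id, self.response, self.depth_cm)

    @property
    def ref(self) -> str:
        return f"{self.dataset_id}/{self.response}"

    def is_normalized(self) -> bool:
        """True when both arms carry an SD (SE already converted)."""
        return not _is_missing(self.sd_w) and not _is_missing(self.sd_c)


@dataclass(frozen=True)
class StratumLabels:
    depth_bin: DepthBin
    latitude_band: LatitudeBand
    biome: Biome


@dataclass
class EffectSize:
    """A standardized mean difference ``y`` with sampling variance ``v``."""

    y: float
    v: float
    record_ref: str
    labels: Optional[StratumLabels]
    n_w: int
    n_c: int
    control_cluster: str
    response: str = ""
    moderators: dict = field(default_factory=dict)

    def moderator(self, name: str):
        return self.moderators.get(name)


@dataclass
class EffectCovariance:
    """Symmetric sampling covariance over an ordered list of effects.

    Off-diagonal entries are nonzero only within shared-control clusters.
    """

    effects: list
    V: np.ndarray
    jitter: float = 0.0

    @property
    def k(self) -> int:
        return len(self.effects)

    @property
    def clusters(self) -> np.ndarray:
        return np.asarray([e.control_cluster for e in self.effects], dtype=object)


@dataclass
class MetaFit:
    """Pooled fixed-effect estimate for one (response, stratum) cell."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    k: int
    ci_method: CIMethod
    stratum: str = "overall"
    response: str = ""

    @property
    def significant(self) -> Optional[bool]:
        """CI excludes zero; ``None`` when no CI could be computed (k = 1)."""
        if self.ci_method is CIMethod.NONE:
            return None
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass
class MetaRegressionFit:
    """Moderator regression of effect sizes under the effect covariance."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    k: int
    design_note: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        lens = {len(self.terms), len(self.beta), len(self.se), len(self.z), len(self.p)}
        if len(lens) != 1:
            raise ValueError("terms/beta/se/z/p must have equal length")

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.p[self.terms.index(term)])


def record_fields() -> list:
    """Canonical CSV column order for StudyRecord tables."""
    return [f.name for f in fields(StudyRecord)]
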