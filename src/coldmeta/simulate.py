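"""Synthetic study tables with known truth.

The generator emits tables that satisfy the study-table schema and
classification rules by construction: site climate is drawn inside the
target biome's MAT-MAP region, arm summaries come from normal / scaled-chi
sampling distributions at small integer n, moderators drive effect-size
heterogeneity through configurable slopes, and a tunable fraction of rows
reuses an earlier row's control arm, forming shared-control clusters.

Also houses the printed worked-example arm values used in the discussion
fixtures (their n is never printed, so callers must supply one, and must
decide whether the printed dispersion is an SD or an SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .classify import DEFAULT_BOUNDARIES, BiomeBoundaries, classify_biome
from .errors import LookupError_, ScenarioError
from .types import Biome, StudyRecord


class WorkedExample(NamedTuple):
    """Printed control/warmed arm values; ``dispersion`` is SD-or-SE agnostic."""
    mean_c: float
    dispersion_c: float
    mean_w: float
    dispersion_w: float
    units: str


_WORKED_EXAMPLES: Dict[str, WorkedExample] = {
    # gross N mineralization, 2 yr warming, shrub tundra
    "biasi_nmin": WorkedExample(0.23, 0.04, 0.34, 0.03, "g N m-2 d-1"),
    # dissolved organic N at the same site
    "biasi_don": WorkedExample(2.1, 0.3, 4.9, 1.7, "g/m2"),
    # alpine meadow root N concentration (top 10 cm)
    "chang_rootconc": WorkedExample(14.7, 0.5, 10.7, 1.2, "g/kg"),
    "chang_rootbiomass": WorkedExample(890.0, 114.0, 1576.0, 136.0, "g/m2"),
    "chang_rootN": WorkedExample(13.1, 2.5, 16.7, 0.8, "g/m2"),
    # subarctic tundra heath fungal biomass under OTC warming
    "rousk_fungal": WorkedExample(23.0, 1.0, 27.0, 0.7, "nmol/g"),
}


def make_worked_example(name: str) -> WorkedExample:
    """Look up the printed arm values for a named worked example."""
    try:
        return _WORKED_EXAMPLES[name]
    except KeyError:
        raise LookupError_(
            f"unknown worked example {name!r}; known: {sorted(_WORKED_EXAMPLES)}"
        ) from None


DEFAULT_TRUE_SMD: Dict[Tuple[str, str], float] = {}


@dataclass
class SimScenario:
    """Configuration for :func:`generate_study_table`."""

    k_studies: int = 50
    responses: Sequence[str] = ("N mineralization",)
    #: (response, biome-name) -> true standardized effect; missing keys -> default_smd
    true_smd: Dict[Tuple[str, str], float] = field(default_factory=dict)
    default_smd: float = 0.0
    #: moderator name -> slope on the centered moderator
    moderator_slopes: Dict[str, float] = field(default_factory=dict)
    n_range: Tuple[int, int] = (3, 10)
    delta_t_range: Tuple[float, float] = (0.0, 4.0)
    duration_range: Tuple[float, float] = (0.05, 22.0)
    shared_control_prob: float = 0.0
    sd_scale: float = 1.0
    #: correlation between warming magnitude and the moisture moderator
    moisture_rho: float = -0.4
    seed: int = 0

    def validate(self) -> None:
        if self.k_studies < 0:
            raise ScenarioError(f"k_studies must be >= 0, got {self.k_studies}")
        if self.k_studies and not self.responses:
            raise ScenarioError("at least one response label is required")
        lo, hi = self.n_range
        if lo < 2 or hi < lo:
            raise ScenarioError(f"n_range must satisfy 2 <= lo <= hi, got {self.n_range}")
        for name, rng_ in (("delta_t_range", self.delta_t_range),
                           ("duration_range", self.duration_range)):
            if rng_[1] <= rng_[0]:
                raise ScenarioError(f"{name} must be non-degenerate, got {rng_}")
        if not (0.0 <= self.shared_control_prob <= 1.0):
            raise ScenarioError(f"shared_control_prob must be in [0,1], got {self.shared_control_prob}")
        if self.sd_scale <= 0:
            raise ScenarioError(f"sd_scale must be > 0, got {self.sd_scale}")
        if not (-1.0 <= self.moisture_rho <= 1.0):
            raise ScenarioError(f"moisture_rho must be in [-1,1], got {self.moisture_rho}")


# MAT (degC) and MAP (mm) sampling boxes that land inside each biome region
# of the default boundary configuration; latitude ranges are typical of where
# warming experiments in that biome sit.
def _draw_site(rng: np.random.Generator, biome: Biome,
               boundaries: BiomeBoundaries) -> Tuple[float, float, float]:
    if biome is Biome.TUNDRA:
        mat = rng.uniform(-15.0, -5.5)
        prec = rng.uniform(80.0, 900.0)
        lat = -rng.uniform(55.0, 75.0) if rng.random() < 0.05 else rng.uniform(55.0, 78.0)
    elif biome is Biome.BOREAL:
        mat = rng.uniform(-4.5, 2.5)
        line = boundaries.forest_line_mm(mat)
        prec = rng.uniform(line + 20.0, line + 700.0)
        lat = rng.uniform(50.5, 68.0)
    elif biome is Biome.TEMPERATE:
        mat = rng.uniform(3.0, 5.0)
        line = boundaries.forest_line_mm(mat)
        prec = rng.uniform(line + 20.0, line + 800.0)
        lat = rng.uniform(38.0, 50.0)
    else:  # grassland: dry override region keeps it simple
        mat = rng.uniform(-4.5, 5.0)
        prec = rng.uniform(30.0, boundaries.desert_map_mm - 1.0)
        lat = rng.uniform(30.0, 48.0)
    return lat, mat, prec


def _sample_arm(rng: np.random.Generator, mu: float, sigma: float, n: int
                ) -> Tuple[float, float]:
    """Observed mean and SD of n iid normal draws (via their exact sampling
    distributions)."""
    mean = rng.normal(mu, sigma / np.sqrt(n))
    sd = sigma * np.sqrt(rng.chisquare(n - 1) / (n - 1))
    return float(mean), float(sd)


def generate_study_table(scenario: SimScenario,
                         boundaries: BiomeBoundaries = DEFAULT_BOUNDARIES,
                         ) -> List[StudyRecord]:
    """Simulate a normalized study table with known true effects.

    Fully deterministic for a fixed ``scenario.seed``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    biome_cycle = list(Biome)
    records: List[StudyRecord] = []
    clusters: List[dict] = []  # reusable control draws

    dt_lo, dt_hi = scenario.delta_t_range
    du_lo, du_hi = scenario.duration_range
    dt_mid = (dt_lo + dt_hi) / 2.0
    du_mid = (du_lo + du_hi) / 2.0
    rho = scenario.moisture_rho

    for i in range(scenario.k_studies):
        response = scenario.responses[int(rng.integers(len(scenario.responses)))]
        reuse = bool(clusters) and rng.random() < scenario.shared_control_prob
        if reuse:
            cluster = clusters[int(rng.integers(len(clusters)))]
        else:
            biome = biome_cycle[i % len(biome_cycle)]
            lat, mat, prec = _draw_site(rng, biome, boundaries)
            assert classify_biome(mat, prec, boundaries) is biome
            n_c = int(rng.integers(scenario.n_range[0], scenario.n_range[1] + 1))
            mu_c = rng.normal(10.0, 2.0)
            sigma = scenario.sd_scale
            mean_c, sd_c = _sample_arm(rng, mu_c, sigma, n_c)
            cluster = dict(
                id=f"cl{len(clusters):04d}", study=f"study{len(clusters):04d}",
                biome=biome, lat=lat, mat=mat, prec=prec,
                n_c=n_c, mu_c=mu_c, sigma=sigma, mean_c=mean_c, sd_c=sd_c,
                members=0,
            )
            clusters.append(cluster)
        cluster["members"] += 1

        delta_t = rng.uniform(dt_lo, dt_hi)
        duration = rng.uniform(du_lo, du_hi)
        dt_std = (delta_t - dt_mid) / max(dt_hi - dt_lo, 1e-12) * np.sqrt(12.0)
        moisture = rho * dt_std + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.normal()

        biome = cluster["biome"]
        delta = scenario.true_smd.get((response, biome.value), scenario.default_smd)
        delta += scenario.moderator_slopes.get("delta_t", 0.0) * (delta_t - dt_mid)
        delta += scenario.moderator_slopes.get("duration_yr", 0.0) * (duration - du_mid)
        delta += scenario.moderator_slopes.get("moisture_effect", 0.0) * moisture

        n_w = int(rng.integers(scenario.n_range[0], scenario.n_range[1] + 1))
        mu_w = cluster["mu_c"] + delta * cluster["sigma"]
        mean_w, sd_w = _sample_arm(rng, mu_w, cluster["sigma"], n_w)

        records.append(StudyRecord(
            study_id=cluster["study"],
            dataset_id=f"{cluster['study']}-{biome.value.lower()}-{cluster['members']:02d}",
            response=response,
            mean_w=mean_w, sd_w=sd_w, n_w=n_w,
            mean_c=cluster["mean_c"], sd_c=cluster["sd_c"], n_c=cluster["n_c"],
            latitude_deg=float(cluster["lat"]),
            mat_c=float(cluster["mat"]), map_mm=float(cluster["prec"]),
            depth_cm=float(rng.choice([2.0, 5.0, 10.0, 15.0, 25.0])),
            delta_t=float(delta_t), duration_yr=float(duration),
            moisture_effect=float(moisture),
            control_cluster=cluster["id"],
        ))
    return records
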