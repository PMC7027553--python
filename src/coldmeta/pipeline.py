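"""End-to-end orchestration: study table -> effects -> covariance ->
pooled fits, subgroup fits and meta-regressions, all as flat CSV plus a
JSON run manifest.

Outputs are deterministic given (input bytes, config, seed): all bootstrap
seeds are derived arithmetically from the base seed and no timestamps are
written, so a rerun is byte-identical. Every CSV opens with a
``# manifest: <run_id>`` comment line tying it to the manifest that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import BiomeBoundaries, DEFAULT_BOUNDARIES
from .effects import build_vcov, compute_effects
from .errors import ColdMetaError
from .inference import (DEFAULT_SUBGROUP_EXCEPTIONS, SUBGROUP_FACTORS,
                        fit_fixed_effect, subgroup_analysis)
from .io import read_study_table
from .metareg import MODERATORS, marginal_flags, meta_regress
from .types import Biome, DepthBin, EffectSize, LatitudeBand, MetaFit, StratumLabels

log = logging.getLogger(__name__)

EFFECT_COLUMNS = ["record_ref", "response", "y", "v", "n_w", "n_c",
                  "control_cluster", "depth_bin", "latitude_band", "biome",
                  "delta_t", "duration_yr", "moisture_effect"]

FIT_COLUMNS = ["response", "stratum", "estimate", "se", "ci_low", "ci_high",
               "z", "p", "k", "ci_method", "significant"]


@dataclass
class PipelineConfig:
    seed: int = 0
    B: int = 10000
    level: float = 0.95
    min_k: int = 10
    subgroup_exceptions: Sequence[str] = DEFAULT_SUBGROUP_EXCEPTIONS
    moderators: Sequence[str] = MODERATORS
    interactions: bool = True
    hedges: bool = False
    covariance_formula: str = "avg_total"
    boundaries: BiomeBoundaries = field(default_factory=BiomeBoundaries)

    def snapshot(self) -> dict:
        raw = asdict(self)
        raw["subgroup_exceptions"] = list(self.subgroup_exceptions)
        raw["moderators"] = list(self.moderators)
        return raw


@dataclass
class RunManifest:
    run_id: str
    input_path: str
    input_sha256: str
    config: dict
    seed: int
    version: str
    counts: Dict[str, int]
    outputs: List[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, run_id: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# manifest: {run_id}\n")
        frame.to_csv(fh, index=False)


def effects_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append({
            "record_ref": e.record_ref, "response": e.response,
            "y": e.y, "v": e.v, "n_w": e.n_w, "n_c": e.n_c,
            "control_cluster": e.control_cluster,
            "depth_bin": e.labels.depth_bin.value,
            "latitude_band": e.labels.latitude_band.value,
            "biome": e.labels.biome.value,
            **{m: e.moderators.get(m) for m in MODERATORS},
        })
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def read_effects_table(path) -> List[EffectSize]:
    """Rebuild EffectSize objects from an effects.csv written by the pipeline."""
    frame = pd.read_csv(path, comment="#")
    effects = []
    for row in frame.itertuples(index=False):
        moderators = {}
        for m in MODERATORS:
            value = getattr(row, m, None)
            moderators[m] = None if value is None or (
                isinstance(value, float) and math.isnan(value)) else float(value)
        effects.append(EffectSize(
            y=float(row.y), v=float(row.v), record_ref=str(row.record_ref),
            labels=StratumLabels(DepthBin(row.depth_bin),
                                 LatitudeBand(row.latitude_band),
                                 Biome(row.biome)),
            n_w=int(row.n_w), n_c=int(row.n_c),
            control_cluster=str(row.control_cluster),
            response=str(row.response), moderators=moderators,
        ))
    return effects


def read_vcov_table(path) -> np.ndarray:
    frame = pd.read_csv(path, comment="#", index_col=0)
    return frame.to_numpy(dtype=float)


def _fit_row(fit: MetaFit) -> dict:
    sig = fit.significant
    return {
        "response": fit.response, "stratum": fit.stratum,
        "estimate": fit.estimate, "se": fit.se,
        "ci_low": fit.ci_low, "ci_high": fit.ci_high,
        "z": fit.z, "p": fit.p, "k": fit.k,
        "ci_method": fit.ci_method.value,
        "significant": "not_evaluable" if sig is None else str(bool(sig)),
    }


def run_pipeline(studies_path, outdir, config: Optional[PipelineConfig] = None,
                 ) -> RunManifest:
    """Run the full analysis and write all artifacts under ``outdir``.

    Returns the manifest; any stage failure still leaves a manifest
    recording progress up to the failing stage.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    studies_path = Path(studies_path)

    payload = json.dumps(config.snapshot(), sort_keys=True).encode()
    input_sha = _sha256(studies_path)
    run_id = hashlib.sha256(input_sha.encode() + payload).hexdigest()[:16]
    manifest = RunManifest(run_id=run_id, input_path=str(studies_path),
                           input_sha256=input_sha, config=config.snapshot(),
                           seed=config.seed, version=__version__,
                           counts={})
    manifest_path = outdir / "manifest.json"
    try:
        records = read_study_table(studies_path)
        manifest.counts["read"] = len(records)

        effects, rejects = compute_effects(records, hedges=config.hedges,
                                           boundaries=config.boundaries)
        manifest.counts["analyzed"] = len(effects)
        manifest.counts["rejected"] = len(rejects)

        cov = build_vcov(effects, formula=config.covariance_formula)

        responses = sorted({e.response for e in effects})
        fit_rows: List[dict] = []
        metareg_rows: List[dict] = []
        for r_index, response in enumerate(responses):
            idx = np.asarray([i for i, e in enumerate(effects)
                              if e.response == response])
            sub = [effects[i] for i in idx]
            V = cov.V[np.ix_(idx, idx)]
            seed_base = config.seed + 100_003 * (r_index + 1)
            overall = fit_fixed_effect(sub, V, level=config.level, B=config.B,
                                       seed=seed_base, response=response,
                                       stratum="overall")
            fit_rows.append(_fit_row(overall))
            for f_index, factor in enumerate(SUBGROUP_FACTORS):
                fits = subgroup_analysis(
                    sub, V, factor=factor, min_k=config.min_k,
                    exceptions=config.subgroup_exceptions, level=config.level,
                    B=config.B, seed=seed_base + 1000 * (f_index + 1))
                fit_rows.extend(_fit_row(f) for f in fits)
            moderators = [m for m in config.moderators
                          if any(e.moderator(m) is not None for e in sub)]
            n_terms = 1 + len(moderators)
            if config.interactions:
                n_terms += len(moderators) * (len(moderators) - 1) // 2
            if moderators and len(sub) > n_terms:
                try:
                    mfit = meta_regress(sub, V, moderators=moderators,
                                        interactions=config.interactions)
                except ColdMetaError as exc:
                    log.info("meta-regression skipped for %r: %s", response, exc)
                else:
                    flags = marginal_flags(mfit)
                    for t_index, term in enumerate(mfit.terms):
                        metareg_rows.append({
                            "response": response, "term": term,
                            "beta": float(mfit.beta[t_index]),
                            "se": float(mfit.se[t_index]),
                            "z": float(mfit.z[t_index]),
                            "p": float(mfit.p[t_index]),
                            "flag": flags[term], "k": mfit.k,
                            "n_dropped": mfit.n_dropped,
                        })

        refs = [e.record_ref for e in effects]
        vcov_frame = pd.DataFrame(cov.V, index=refs, columns=refs)
        _write_csv(effects_frame(effects), outdir / "effects.csv", run_id)
        with open(outdir / "vcov.csv", "w", encoding="utf-8") as fh:
            fh.write(f"# manifest: {run_id}\n")
            vcov_frame.to_csv(fh)
        _write_csv(pd.DataFrame(fit_rows, columns=FIT_COLUMNS),
                   outdir / "fits.csv", run_id)
        _write_csv(pd.DataFrame(metareg_rows,
                                columns=["response", "term", "beta", "se", "z",
                                         "p", "flag", "k", "n_dropped"]),
                   outdir / "metareg.csv", run_id)
        _write_csv(pd.DataFrame([asdict(r) for r in rejects],
                                columns=["record_ref", "reason"]),
                   outdir / "rejects.csv", run_id)
        manifest.outputs = ["effects.csv", "vcov.csv", "fits.csv",
                            "metareg.csv", "rejects.csv"]
    finally:
        manifest.write(manifest_path)
    return manifest
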