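"""Standardized mean differences, sampling variances, and the shared-control
variance-covariance matrix.

For a warmed/control comparison with arm means ``m_w, m_c``, SDs
``s_w, s_c`` and sizes ``n_w, n_c``::

    sp = sqrt(((n_w - 1) s_w^2 + (n_c - 1) s_c^2) / (n_w + n_c - 2))
    y  = (m_w - m_c) / sp
    v  = 1/n_w + 1/n_c + y^2 / (2 (n_w + n_c))

Comparisons that reuse a control group are sampling-correlated; their
covariance is ``1/n_c + y_i y_j / (2 n~)`` where ``n~`` is, by default, the
average total sample size of the two comparisons (``n_c + (n_wi + n_wj)/2``),
matching the total-n convention used in ``v``. The alternative
``n~ = n_c + n_wi + n_wj`` is available for sensitivity checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .classify import BiomeBoundaries, DEFAULT_BOUNDARIES, label_record
from .errors import (DataIntegrityError, DegreesOfFreedomError,
                     InvalidInputError, ZeroVarianceError)
from .types import EffectCovariance, EffectSize, StudyRecord, _is_missing

log = logging.getLogger(__name__)

MODERATOR_NAMES = ("delta_t", "duration_yr", "moisture_effect")


def pooled_sd(sd_w: float, n_w: int, sd_c: float, n_c: int) -> float:
    """Degrees-of-freedom-weighted pooled standard deviation of the two arms."""
    if sd_w < 0 or sd_c < 0:
        raise InvalidInputError(f"arm SDs must be >= 0, got {sd_w}, {sd_c}")
    if n_w + n_c - 2 < 1:
        raise DegreesOfFreedomError(
            f"pooled SD needs n_w + n_c >= 3, got n_w={n_w}, n_c={n_c}"
        )
    if sd_w == 0 and sd_c == 0:
        raise ZeroVarianceError("both arm SDs are zero; effect size undefined")
    num = (n_w - 1) * sd_w ** 2 + (n_c - 1) * sd_c ** 2
    return math.sqrt(num / (n_w + n_c - 2))


def smd(mean_w: float, mean_c: float, sp: float) -> float:
    """Standardized mean difference (warmed minus control, in pooled-SD units)."""
    if sp <= 0 or not math.isfinite(sp):
        raise InvalidInputError(f"pooled SD must be > 0, got {sp}")
    return (mean_w - mean_c) / sp


def smd_variance(y: float, n_w: int, n_c: int) -> float:
    """Large-sample sampling variance of an SMD; total-n convention for the
    quadratic term."""
    if n_w < 1 or n_c < 1:
        raise InvalidInputError(f"arm sizes must be >= 1, got n_w={n_w}, n_c={n_c}")
    return 1.0 / n_w + 1.0 / n_c + y * y / (2.0 * (n_w + n_c))


def hedges_correction(n_w: int, n_c: int) -> float:
    """Small-sample bias factor J(m) ~ 1 - 3/(4m - 1), m = n_w + n_c - 2."""
    m = n_w + n_c - 2
    return 1.0 - 3.0 / (4.0 * m - 1.0)


def percent_change(mean_c: float, mean_w: float) -> float:
    """Percent change of the warmed mean relative to control."""
    if mean_c == 0:
        raise InvalidInputError("percent change undefined for a zero control mean")
    return 100.0 * (mean_w - mean_c) / mean_c


@dataclass
class RejectedRecord:
    record_ref: str
    reason: str


def compute_effect(record: StudyRecord, *, hedges: bool = False,
                   boundaries: BiomeBoundaries = DEFAULT_BOUNDARIES) -> EffectSize:
    """Compute (y, v) for one normalized record, carrying labels and moderators."""
    if not record.is_normalized():
        raise InvalidInputError(f"record {record.ref} is not normalized (missing SD)")
    sp = pooled_sd(record.sd_w, record.n_w, record.sd_c, record.n_c)
    y = smd(record.mean_w, record.mean_c, sp)
    if hedges:
        y *= hedges_correction(record.n_w, record.n_c)
    v = smd_variance(y, record.n_w, record.n_c)
    labels = label_record(record, boundaries)
    moderators = {name: getattr(record, name) for name in MODERATOR_NAMES}
    return EffectSize(
        y=y, v=v, record_ref=record.ref, labels=labels,
        n_w=record.n_w, n_c=record.n_c,
        control_cluster=record.control_cluster,
        response=record.response, moderators=moderators,
    )


def compute_effects(records: Iterable[StudyRecord], *, hedges: bool = False,
                    boundaries: BiomeBoundaries = DEFAULT_BOUNDARIES,
                    ) -> Tuple[List[EffectSize], List[RejectedRecord]]:
    """Batch version of :func:`compute_effect`.

    Per-row failures never abort the batch; offending rows land in the
    rejects list with the failure reason.
    """
    effects: List[EffectSize] = []
    rejects: List[RejectedRecord] = []
    for record in records:
        try:
            effects.append(compute_effect(record, hedges=hedges, boundaries=boundaries))
        except Exception as exc:  # per-row collection is the contract
            log.warning("rejecting %s: %s", record.ref, exc)
            rejects.append(RejectedRecord(record_ref=record.ref, reason=str(exc)))
    return effects, rejects


def shared_control_covariance(effect_i: EffectSize, effect_j: EffectSize,
                              formula: str = "avg_total") -> float:
    """Sampling covariance of two SMDs computed against the same control arm."""
    n_c = effect_i.n_c
    if formula == "avg_total":
        n_tilde = n_c + (effect_i.n_w + effect_j.n_w) / 2.0
    elif formula == "sum":
        n_tilde = n_c + effect_i.n_w + effect_j.n_w
    else:
        raise InvalidInputError(f"unknown covariance formula {formula!r}")
    return 1.0 / n_c + (effect_i.y * effect_j.y) / (2.0 * n_tilde)


def build_vcov(effects: Sequence[EffectSize], formula: str = "avg_total",
               max_jitter: float = 1e-10) -> EffectCovariance:
    """Assemble the effect-size variance-covariance matrix.

    Diagonal entries are the sampling variances; within a shared-control
    cluster the off-diagonals come from :func:`shared_control_covariance`;
    everything else is zero. If round-off leaves the matrix marginally
    indefinite, a diagonal jitter of at most ``max_jitter`` is added and
    logged.
    """
    effects = list(effects)
    k = len(effects)
    V = np.zeros((k, k))
    by_cluster = {}
    for idx, effect in enumerate(effects):
        V[idx, idx] = effect.v
        by_cluster.setdefault(effect.control_cluster, []).append(idx)
    for cluster, members in by_cluster.items():
        n_cs = {effects[i].n_c for i in members}
        if len(n_cs) != 1:
            raise DataIntegrityError(
                f"control cluster {cluster!r} has inconsistent control arm sizes {sorted(n_cs)}"
            )
        for a, i in enumerate(members):
            for j in members[a + 1:]:
                cov = shared_control_covariance(effects[i], effects[j], formula)
                V[i, j] = V[j, i] = cov
    jitter = 0.0
    if k:
        min_eig = float(np.linalg.eigvalsh(V)[0])
        if min_eig < 0:
            jitter = min(-min_eig + 1e-15, max_jitter)
            V[np.diag_indices_from(V)] += jitter
            log.warning("covariance not PSD (min eig %.3e); applied diagonal jitter %.3e",
                        min_eig, jitter)
    return EffectCovariance(effects=effects, V=V, jitter=jitter)
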