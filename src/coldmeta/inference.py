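"""Fixed-effect pooling under the effect covariance, with Wald or
cluster-aware BCa-bootstrap confidence intervals.

CI method selection follows the study-count rules: a single effect gets no
CI at all; 2-14 effects get a bias-corrected and accelerated bootstrap
interval; 15 or more get the normal-theory Wald interval. An effect is
called significant when its CI excludes zero.
"""

from __future__ import annotations

import logging
import warnings
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import (EmptySetError, InvalidInputError, NumericalError)
from .types import CIMethod, EffectCovariance, EffectSize, MetaFit

log = logging.getLogger(__name__)

#: responses analysed across strata even below the study-count threshold
DEFAULT_SUBGROUP_EXCEPTIONS = ("N fixation", "N2O emission")

SUBGROUP_FACTORS = ("depth_bin", "latitude_band", "biome")

#: study-count cutoff below which CIs are bootstrapped (strict)
BOOTSTRAP_K_CUTOFF = 15


def _as_matrix(V, k: int) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        if V.shape[0] != k:
            raise InvalidInputError(f"variance vector length {V.shape[0]} != k={k}")
        return np.diag(V)
    if V.shape != (k, k):
        raise InvalidInputError(f"V must be ({k},{k}), got {V.shape}")
    return V


def _unpack(effects, V):
    """Accept (list[EffectSize], V|None) or (array, V)."""
    if len(effects) and isinstance(effects[0], EffectSize):
        y = np.asarray([e.y for e in effects], dtype=float)
        clusters = np.asarray([e.control_cluster for e in effects], dtype=object)
        if V is None:
            from .effects import build_vcov
            V = build_vcov(effects).V
        elif isinstance(V, EffectCovariance):
            V = V.V
        return y, _as_matrix(V, len(y)), clusters
    y = np.asarray(effects, dtype=float)
    if V is None:
        raise InvalidInputError("V is required when effects are given as an array")
    if isinstance(V, EffectCovariance):
        V = V.V
    return y, _as_matrix(V, len(y)), None


def gls_pooled(y: np.ndarray, V: np.ndarray) -> Tuple[float, float]:
    """Generalized-least-squares pooled mean and its standard error.

    ``estimate = (1' V^-1 y) / (1' V^-1 1)``, ``se = sqrt(1 / (1' V^-1 1))``;
    reduces to the inverse-variance weighted mean for diagonal ``V``.
    """
    ones = np.ones_like(y)
    try:
        Vinv_ones = np.linalg.solve(V, ones)
        Vinv_y = np.linalg.solve(V, y)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular effect covariance: {exc}") from exc
    denom = float(ones @ Vinv_ones)
    if denom <= 0 or not np.isfinite(denom):
        raise NumericalError(f"non-positive precision total {denom}; V is not PD")
    estimate = float(ones @ Vinv_y) / denom
    return estimate, float(np.sqrt(1.0 / denom))


def wald_ci(estimate: float, se: float, level: float = 0.95) -> Tuple[float, float]:
    """Symmetric normal-theory interval ``estimate -+ z * se``."""
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"level must be in (0,1), got {level}")
    if se <= 0:
        raise InvalidInputError(f"se must be > 0, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


def _cluster_groups(clusters: Optional[np.ndarray], k: int) -> List[np.ndarray]:
    if clusters is None:
        return [np.array([i]) for i in range(k)]
    groups = {}
    for i, c in enumerate(clusters):
        groups.setdefault(c, []).append(i)
    return [np.asarray(ix) for ix in groups.values()]


def _block_diag_subset(V: np.ndarray, groups: List[np.ndarray],
                       choice: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rows and block-diagonal covariance for a resample of cluster indices.

    Repeated draws of one cluster become independent copies: their
    cross-covariances are dropped even though the rows coincide.
    """
    rows = np.concatenate([groups[c] for c in choice])
    n = rows.size
    Vb = np.zeros((n, n))
    offset = 0
    for c in choice:
        g = groups[c]
        m = g.size
        Vb[offset:offset + m, offset:offset + m] = V[np.ix_(g, g)]
        offset += m
    return rows, Vb


def bca_ci(effects: Union[Sequence[EffectSize], np.ndarray], V=None, *,
           B: int = 10000, seed: Optional[int] = None, level: float = 0.95,
           clusters: Optional[np.ndarray] = None) -> Tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for the pooled estimate.

    Resampling is cluster-aware: all rows of a shared-control cluster are
    drawn jointly and the covariance is reassembled block-diagonally for
    each resample, so the dependence encoded in ``V`` survives resampling.
    Bias correction ``z0`` comes from the fraction of resample statistics
    below the point estimate (ties counted half); acceleration ``a`` from
    the leave-one-cluster-out jackknife. Deterministic for a fixed seed.
    """
    y, V, eff_clusters = _unpack(effects, V)
    if clusters is None:
        clusters = eff_clusters
    k = y.size
    if k < 2:
        raise InvalidInputError(f"BCa bootstrap needs k >= 2 effects, got {k}")
    if B < 100:
        raise InvalidInputError(f"B must be >= 100, got {B}")
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"level must be in (0,1), got {level}")
    rng = np.random.default_rng(seed)
    estimate, _ = gls_pooled(y, V)
    groups = _cluster_groups(clusters, k)
    m = len(groups)
    if m < 2:
        raise InvalidInputError("BCa bootstrap needs at least 2 resampling units")

    diag_only = all(g.size == 1 for g in groups) and not np.any(V - np.diag(np.diag(V)))
    if diag_only:
        w = 1.0 / np.diag(V)
        idx = rng.integers(0, k, size=(B, k))
        wb = w[idx]
        stat = (wb * y[idx]).sum(axis=1) / wb.sum(axis=1)
    else:
        stat = np.empty(B)
        for b in range(B):
            choice = rng.integers(0, m, size=m)
            rows, Vb = _block_diag_subset(V, groups, choice)
            stat[b], _ = gls_pooled(y[rows], Vb)

    if np.ptp(stat) == 0.0:
        warnings.warn("degenerate bootstrap distribution; returning point interval")
        return float(stat[0]), float(stat[0])

    # bias correction: strictly-below convention, ties at the estimate count half
    p_less = ((stat < estimate).sum() + 0.5 * (stat == estimate).sum()) / B
    p_less = min(max(p_less, 0.5 / B), 1.0 - 0.5 / B)
    z0 = stats.norm.ppf(p_less)

    # acceleration from the leave-one-cluster-out jackknife
    theta_jack = np.empty(m)
    all_rows = np.arange(k)
    for i, g in enumerate(groups):
        keep = np.setdiff1d(all_rows, g, assume_unique=True)
        theta_jack[i], _ = gls_pooled(y[keep], V[np.ix_(keep, keep)])
    diffs = theta_jack.mean() - theta_jack
    denom = (diffs ** 2).sum() ** 1.5
    a = float((diffs ** 3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    endpoints = []
    for tail in (alpha / 2.0, 1.0 - alpha / 2.0):
        z_tail = stats.norm.ppf(tail)
        adj = z0 + (z0 + z_tail) / (1.0 - a * (z0 + z_tail))
        endpoints.append(float(np.quantile(stat, float(stats.norm.cdf(adj)))))
    return endpoints[0], endpoints[1]


def choose_ci_method(k: int) -> CIMethod:
    """Single study -> no CI; k < 15 -> BCa bootstrap; otherwise Wald."""
    if k == 1:
        return CIMethod.NONE
    return CIMethod.BCA if k < BOOTSTRAP_K_CUTOFF else CIMethod.WALD


def fit_fixed_effect(effects: Union[Sequence[EffectSize], np.ndarray], V=None, *,
                     level: float = 0.95, ci_method: str = "auto",
                     B: int = 10000, seed: Optional[int] = None,
                     response: str = "", stratum: str = "overall") -> MetaFit:
    """Fit the fixed-effect pooled estimate and attach a confidence interval.

    ``ci_method`` may be ``"auto"`` (study-count rules), ``"wald"``,
    ``"bca"`` or ``"none"``. A seed is mandatory whenever the BCa bootstrap
    is used so every bootstrap run is reproducible and loggable.
    """
    y, V, clusters = _unpack(effects, V)
    k = y.size
    if k == 0:
        raise EmptySetError("cannot pool zero effects")
    estimate, se = gls_pooled(y, V)
    z = estimate / se
    p = float(2.0 * stats.norm.sf(abs(z)))

    method = CIMethod(ci_method.upper()) if ci_method != "auto" else choose_ci_method(k)
    if method is CIMethod.NONE or k == 1:
        method = CIMethod.NONE
        ci_low = ci_high = float("nan")
    elif method is CIMethod.BCA:
        if seed is None:
            raise InvalidInputError("a seed is required for BCa bootstrap CIs")
        ci_low, ci_high = bca_ci(y, V, B=B, seed=seed, level=level, clusters=clusters)
    else:
        ci_low, ci_high = wald_ci(estimate, se, level)
    if not response and len(effects) and isinstance(effects[0], EffectSize):
        response = effects[0].response
    return MetaFit(estimate=estimate, se=se, ci_low=ci_low, ci_high=ci_high,
                   z=z, p=p, k=k, ci_method=method, stratum=stratum,
                   response=response)


def significance(fit: MetaFit) -> Optional[bool]:
    """CI-excludes-zero rule; ``None`` (not evaluable) when there is no CI."""
    return fit.significant


def subgroup_analysis(effects: Sequence[EffectSize], V=None, *,
                      factor: str, min_k: int = 10,
                      exceptions: Sequence[str] = DEFAULT_SUBGROUP_EXCEPTIONS,
                      level: float = 0.95, B: int = 10000,
                      seed: Optional[int] = None) -> List[MetaFit]:
    """Per-level pooled fits for one response across a stratum factor.

    The across-stratum comparison runs only when the response has strictly
    more than ``min_k`` effects, unless the response sits on the exception
    list. Depth-UNKNOWN rows are excluded from depth contrasts only.
    """
    if factor not in SUBGROUP_FACTORS:
        raise InvalidInputError(f"unknown factor {factor!r}; expected one of {SUBGROUP_FACTORS}")
    effects = list(effects)
    if not effects:
        raise EmptySetError("no effects for subgroup analysis")
    y, V, _ = _unpack(effects, V)
    response = effects[0].response
    k_total = len(effects)
    if k_total <= min_k and response not in exceptions:
        log.info("response %r: k=%d <= %d and not excepted; subgroups suppressed",
                 response, k_total, min_k)
        return []
    levels = {}
    for idx, effect in enumerate(effects):
        value = getattr(effect.labels, factor).value
        if factor == "depth_bin" and value == "UNKNOWN":
            continue
        levels.setdefault(value, []).append(idx)
    fits = []
    for value, idx in sorted(levels.items()):
        idx = np.asarray(idx)
        sub = [effects[i] for i in idx]
        sub_seed = None if seed is None else seed + len(fits)
        fits.append(fit_fixed_effect(sub, V[np.ix_(idx, idx)], level=level,
                                     B=B, seed=sub_seed, response=response,
                                     stratum=f"{factor}={value}"))
    return fits
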