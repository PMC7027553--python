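"""Meta-regression of effect sizes on warming magnitude, experiment
duration, and soil-moisture change, with optional pairwise interactions.

The design always contains an intercept; moderators are mean-centered
before interaction products are formed, which leaves slope inference
untouched while taming collinearity between main effects and products.
Rows missing any requested moderator are dropped listwise per model.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, Optional, Sequence, Union

import numpy as np
from scipy import linalg, stats

from .errors import (CollinearityError, InsufficientDataError,
                     InvalidInputError, NumericalError)
from .types import EffectCovariance, EffectSize, MetaRegressionFit

MODERATORS = ("delta_t", "duration_yr", "moisture_effect")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def gls_regress(y: np.ndarray, V: np.ndarray, X: np.ndarray,
                terms: Sequence[str]) -> MetaRegressionFit:
    """Generalized least squares: ``beta = (X' V^-1 X)^-1 X' V^-1 y``."""
    k, p = X.shape
    if k <= p:
        raise InsufficientDataError(f"k={k} effects cannot identify {p} design columns")
    # rank check via pivoted QR; aliased columns are those beyond the numerical rank
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        aliased = [terms[i] for i in piv[rank:]]
        raise CollinearityError(aliased)
    try:
        Vinv_X = np.linalg.solve(V, X)
        Vinv_y = np.linalg.solve(V, y)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular effect covariance: {exc}") from exc
    XtVinvX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    cov = np.linalg.inv(XtVinvX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    return MetaRegressionFit(terms=list(terms), beta=beta, se=se, z=z,
                             p=p_values, k=k)


def meta_regress(effects: Sequence[EffectSize],
                 V: Union[np.ndarray, EffectCovariance, None] = None, *,
                 moderators: Sequence[str] = MODERATORS,
                 interactions: bool = False) -> MetaRegressionFit:
    """Regress effect sizes on study-level moderators under the effect
    covariance.

    With ``interactions=True`` the three pairwise products of the centered
    moderators join the design; the three-way product never does. An
    intercept-only call (``moderators=()``) reproduces the fixed-effect
    pooled estimate exactly.
    """
    for name in moderators:
        if name not in MODERATORS:
            raise InvalidInputError(f"unknown moderator {name!r}; expected subset of {MODERATORS}")
    effects = list(effects)
    if isinstance(V, EffectCovariance):
        V = V.V
    if V is None:
        from .effects import build_vcov
        V = build_vcov(effects).V
    V = np.asarray(V, dtype=float)

    keep = [i for i, e in enumerate(effects)
            if not any(_missing(e.moderator(name)) for name in moderators)]
    n_dropped = len(effects) - len(keep)
    if not keep:
        raise InsufficientDataError("all rows lack at least one requested moderator")
    idx = np.asarray(keep)
    y = np.asarray([effects[i].y for i in idx], dtype=float)
    Vs = V[np.ix_(idx, idx)]

    columns: Dict[str, np.ndarray] = {"intercept": np.ones(len(idx))}
    centered: Dict[str, np.ndarray] = {}
    for name in moderators:
        values = np.asarray([float(effects[i].moderator(name)) for i in idx])
        centered[name] = values - values.mean()
        columns[name] = centered[name]
    if interactions:
        for a, b in combinations(moderators, 2):
            columns[f"{a}:{b}"] = centered[a] * centered[b]

    terms = list(columns)
    X = np.column_stack([columns[t] for t in terms])
    fit = gls_regress(y, Vs, X, terms)
    fit.n_dropped = n_dropped
    fit.design_note = (
        f"intercept + centered moderators {list(moderators)}"
        + (" + pairwise interactions" if interactions else "")
        + f"; {n_dropped} row(s) dropped for missing moderators"
    )
    return fit


def marginal_flags(fit: MetaRegressionFit, alpha: float = 0.05,
                   marginal: float = 0.10) -> Dict[str, str]:
    """Label each term significant (p < alpha), marginal (alpha <= p <
    marginal), or ns."""
    if not (0 < alpha < marginal <= 1):
        raise InvalidInputError(f"need 0 < alpha < marginal <= 1, got {alpha}, {marginal}")
    labels = {}
    for term, p in zip(fit.terms, fit.p):
        if p < alpha:
            labels[term] = "significant"
        elif p < marginal:
            labels[term] = "marginal"
        else:
            labels[term] = "ns"
    return labels
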