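"""Bivariate NPEM: presence/absence + nonzero-count channels with a chi-square test.

Zero-inflated taxon counts break a single Gaussian kernel: the point mass
at zero shrinks the bandwidth and distorts the density.  The bivariate
measure decomposes each taxon into a binary occupancy channel Z
(Aitchison-Aitken kernel) and a continuous abundance channel M'
(log1p-transformed nonzero counts, Gaussian kernel).  Each candidate gets
a pair of contributed-information scores (C_Z, C_M'); the pair furthest
from the pool in Mahalanobis distance is tested against chi-square with
2 df (upper tail exp(-MD/2)), the bivariate analogue of the univariate
ESD step.  The pool mean and covariance are re-estimated from the current
unselected candidates at every step.

Because the Mahalanobis distance is direction-blind, unusually *low*
score pairs could be selected; by default only candidates with at least
one channel above its pool mean are eligible (``require_positive``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .entropy import MICache
from .univariate import SelectionStep, SelectionTrace

__all__ = [
    "BivariateDecomposition",
    "decompose_taxon",
    "mahalanobis_distance",
    "chi2_step",
    "bivariate_scores",
    "greedy_select_bv",
    "greedy_select_bvs",
]

#: ids of the two channels of a decomposed taxon in an MICache
Channels = tuple[int, int]
#: a candidate or target: a single cache id, or a (Z, M') channel pair
Entity = int | Channels


@dataclass(frozen=True)
class BivariateDecomposition:
    """Presence/absence and transformed nonzero-count channels of one taxon."""

    presence: np.ndarray  # binary, 1 where the raw count is positive
    nonzero_values: np.ndarray  # log1p(count) at nonzero positions, fill at zeros


def decompose_taxon(
    counts: np.ndarray,
    nonzero_transform: Literal["log1p", "identity"] = "log1p",
    zero_fill: Literal["zero", "mean"] = "zero",
) -> BivariateDecomposition:
    """Split a nonnegative integer count vector into (Z, M') channels.

    Z_i = 1 iff count_i > 0.  M' carries ``log1p`` (default) or raw counts
    at nonzero positions; zero positions are filled with 0 (default) or the
    mean of the nonzero channel values.  Z carries the zero pattern, so the
    fill value has limited influence.
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    z = (c > 0).astype(int)
    vals = np.log1p(c.astype(float)) if nonzero_transform == "log1p" else c.astype(float)
    m = np.where(z == 1, vals, 0.0)
    if zero_fill == "mean" and z.any() and not z.all():
        m = np.where(z == 1, vals, vals[z == 1].mean())
    return BivariateDecomposition(presence=z, nonzero_values=m)


def mahalanobis_distance(
    pair: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> float:
    """Squared Mahalanobis distance (c - mu)' Sigma^-1 (c - mu).

    The squared-distance convention matches the chi-square(2) reference.
    A singular covariance is ridge-regularised with 1e-8 * trace; if still
    singular, falls back to the squared z-score of the higher-variance
    channel.
    """
    d = np.asarray(pair, float) - np.asarray(mu, float)
    s = np.asarray(sigma, float)
    try:
        md = float(d @ np.linalg.solve(s, d))
        if np.isfinite(md) and md >= 0:
            return md
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-8 * max(np.trace(s), 1e-300)
    s_r = s + ridge * np.eye(2)
    try:
        md = float(d @ np.linalg.solve(s_r, d))
        if np.isfinite(md) and md >= 0:
            return md
    except np.linalg.LinAlgError:
        pass
    # degenerate pool: score along the dominant channel only
    k = int(np.argmax(np.diag(s)))
    var = s[k, k]
    if var <= 0:
        return 0.0
    return float(d[k] ** 2 / var)


def chi2_step(md: float) -> float:
    """Upper-tail chi-square(2) p-value, closed form exp(-md/2)."""
    if md < 0:
        raise ValueError("Mahalanobis distance must be nonnegative")
    return float(np.exp(-md / 2.0))


def _channel(entity: Entity, ch: int) -> int:
    return entity if isinstance(entity, int) else entity[ch]


def bivariate_scores(
    cache: MICache,
    candidates: Sequence[Entity],
    target: Entity,
    prior: Sequence[Entity],
    penalty_norm: Literal["card", "card_squared"] = "card",
) -> np.ndarray:
    """(k, 2) contributed-information pairs for the unselected candidates.

    Channel 0 pairs the presence/absence sides of decomposed entities,
    channel 1 the nonzero-count sides; an undecomposed entity (a gene, the
    outcome) supplies the same variable to both channels, so the prior
    penalty is channel-matched where the prior is decomposed and shared
    where it is not.
    """
    out = np.empty((len(candidates), 2))
    for ch in (0, 1):
        t = _channel(target, ch)
        w = [_channel(p, ch) for p in prior]
        for i, c in enumerate(candidates):
            out[i, ch] = cache.contributed(_channel(c, ch), t, w, penalty_norm)
    return out


def _greedy_bv(
    cache: MICache,
    candidates: Sequence[Entity],
    target: Entity,
    threshold: float,
    stop_on_fail: bool,
    penalty_norm: Literal["card", "card_squared"],
    require_positive: bool,
) -> SelectionTrace:
    cand = list(candidates)
    k = len(cand)
    if k < 3:
        return SelectionTrace([], np.ones(k), [])
    unsel = list(range(k))
    prior: list[Entity] = []
    steps: list[SelectionStep] = []
    p_values = np.ones(k)
    selected: list[int] = []
    while len(unsel) >= 3:
        pairs = bivariate_scores(
            cache, [cand[i] for i in unsel], target, prior, penalty_norm
        )
        mu = pairs.mean(axis=0)
        sigma = np.cov(pairs, rowvar=False, ddof=1)
        md = np.array([mahalanobis_distance(p, mu, sigma) for p in pairs])
        if require_positive:
            eligible = (pairs[:, 0] > mu[0]) | (pairs[:, 1] > mu[1])
        else:
            eligible = np.ones(len(unsel), dtype=bool)
        if not eligible.any():
            break
        masked = np.where(eligible, md, -np.inf)
        top_pos = int(np.argmax(masked))
        p = chi2_step(float(md[top_pos]))
        accept = p < threshold
        steps.append(
            SelectionStep(
                feature=unsel[top_pos],
                score=float(md[top_pos]),
                phi=float(md.mean()),
                statistic=float(md[top_pos]),
                df=len(unsel),
                p_value=p,
                selected=accept or not stop_on_fail,
            )
        )
        if stop_on_fail and not accept:
            break
        p_values[unsel[top_pos]] = p
        if accept:
            selected.append(unsel[top_pos])
        prior.append(cand[unsel[top_pos]])
        unsel.pop(top_pos)
    return SelectionTrace(steps, p_values, selected)


def greedy_select_bv(
    cache: MICache,
    candidates: Sequence[Entity],
    target: Entity,
    alpha_threshold: float = 0.05,
    penalty_norm: Literal["card", "card_squared"] = "card",
    require_positive: bool = True,
) -> SelectionTrace:
    """Sequential bivariate greedy selection (NPEM:BV).

    Per step: score pairs for all unselected candidates, Mahalanobis
    distance of each pair from the pool, chi-square(2) test of the largest;
    stop at the first failed test or when two or fewer candidates remain.
    """
    return _greedy_bv(
        cache, candidates, target, alpha_threshold, True, penalty_norm, require_positive
    )


def greedy_select_bvs(
    cache: MICache,
    candidates: Sequence[Entity],
    target: Entity,
    alpha_threshold: float = 0.05,
    penalty_norm: Literal["card", "card_squared"] = "card",
    require_positive: bool = True,
) -> SelectionTrace:
    """Single-test bivariate variant (NPEM:BVS): full ordering, post-hoc tests."""
    return _greedy_bv(
        cache, candidates, target, alpha_threshold, False, penalty_norm, require_positive
    )
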