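"""Univariate NPEM: greedy contributed-information selection with the ESD test.

Each taxon (or the outcome) is treated as a single Gaussian-kernel target.
At every step of the greedy search the contributed information C_i of each
unselected candidate is recomputed given the current prior set W, the
largest C is compared to the pool mean in standard-deviation units
(a one-sided extreme studentized deviate / Grubbs statistic), and the top
candidate is moved into W when the test rejects.  The mean of the pool is
the conservative finite-sample bias estimate phi: for independent
variables the plug-in MI is positive purely through estimation bias, and
most candidates are assumed null, so an extreme C signals a real
relationship.

Two variants: the sequential test (UV) stops at the first failed test; the
single-test variant (UVS) completes the full greedy ordering and keeps the
p-value recorded at each step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .entropy import MICache

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "expected_bias",
    "esd_step",
    "greedy_select_uv",
    "greedy_select_uvs",
]


@dataclass(frozen=True)
class SelectionStep:
    """One iteration of a greedy search."""

    feature: int  # candidate index (position in the candidate list)
    score: float  # top contributed information (or Mahalanobis distance)
    phi: float  # pool mean = conservative bias estimate
    statistic: float  # G (univariate) or MD (bivariate)
    df: int  # number of scores in the pool at this step
    p_value: float
    selected: bool


@dataclass
class SelectionTrace:
    """Ordered record of a greedy search over a fixed candidate list.

    ``p_values[k]`` is the raw p-value of candidate k: the p recorded at
    the step where k was the top feature, or 1.0 if k was never tested.
    """

    steps: list[SelectionStep]
    p_values: np.ndarray
    selected: list[int]

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def expected_bias(scores: Sequence[float]) -> float:
    """Mean contributed information over the unselected candidates (phi)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("expected_bias needs at least one score")
    return float(s.mean())


def esd_step(scores: Sequence[float]) -> tuple[float, float]:
    """One-sided ESD (Grubbs) test of the maximum score against the pool.

    G = (max - mean) / sd with the sample (ddof=1) standard deviation;
    the p-value is the upper tail of t with df-2 degrees of freedom,
    df being the number of scores.  A zero sd returns p = 1 (no outlier
    is detectable in a constant pool).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        raise ValueError("ESD step needs at least 3 scores")
    sd = float(np.std(s, ddof=1))
    if sd == 0.0:
        return 0.0, 1.0
    g = float((s.max() - s.mean()) / sd)
    p = float(stats.t.sf(g, df=s.size - 2))
    return g, p


def _greedy_uv(
    cache: MICache,
    candidates: Sequence[int],
    target: int,
    threshold: float,
    stop_on_fail: bool,
    penalty_norm: Literal["card", "card_squared"],
) -> SelectionTrace:
    cand = list(candidates)
    k = len(cand)
    if k < 3:
        return SelectionTrace([], np.ones(k), [])
    unsel = list(range(k))
    prior: list[int] = []  # cache ids of selected variables
    steps: list[SelectionStep] = []
    p_values = np.ones(k)
    selected: list[int] = []
    while len(unsel) >= 3:
        scores = np.array(
            [cache.contributed(cand[i], target, prior, penalty_norm) for i in unsel]
        )
        top_pos = int(np.argmax(scores))  # ties: lowest index wins
        g, p = esd_step(scores)
        accept = p < threshold
        step = SelectionStep(
            feature=unsel[top_pos],
            score=float(scores[top_pos]),
            phi=float(scores.mean()),
            statistic=g,
            df=scores.size,
            p_value=p,
            selected=accept or not stop_on_fail,
        )
        steps.append(step)
        if stop_on_fail and not accept:
            break
        p_values[unsel[top_pos]] = p
        if accept:
            selected.append(unsel[top_pos])
        prior.append(cand[unsel[top_pos]])
        unsel.pop(top_pos)
    return SelectionTrace(steps, p_values, selected)


def greedy_select_uv(
    cache: MICache,
    candidates: Sequence[int],
    target: int,
    alpha_threshold: float = 0.05,
    penalty_norm: Literal["card", "card_squared"] = "card",
) -> SelectionTrace:
    """Sequential greedy selection with an ESD test at every step (NPEM:UV).

    ``candidates`` and ``target`` are variable ids in ``cache``.  Stops at
    the first step whose test fails, or when two or fewer candidates
    remain; never-tested candidates keep p = 1.
    """
    return _greedy_uv(cache, candidates, target, alpha_threshold, True, penalty_norm)


def greedy_select_uvs(
    cache: MICache,
    candidates: Sequence[int],
    target: int,
    alpha_threshold: float = 0.05,
    penalty_norm: Literal["card", "card_squared"] = "card",
) -> SelectionTrace:
    """Single-test variant (NPEM:UVS): complete the greedy ordering first.

    The ordering is identical to UV's (largest contributed information at
    each step) but runs to the two-remaining stop regardless of test
    outcomes; each ordered candidate keeps the ESD p-value of the score
    vector recorded at its own step.
    """
    return _greedy_uv(cache, candidates, target, alpha_threshold, False, penalty_norm)
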