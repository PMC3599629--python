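"""Bootstrap confidence intervals and permutation nulls for scalabilities.

With ~60 respondents the sampling distribution of Loevinger's H is not well
approximated by textbook asymptotics, so inference here is resampling-based:
percentile bootstrap intervals over persons (rows), and a permutation null
for a single item's H_i obtained by shuffling that item's responses across
persons while holding the remaining items fixed.

Replicate-level RNGs are derived from (seed, replicate counter), so results
are reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import ResponseMatrix, complete_cases
from .exceptions import (
    DegenerateItemError,
    DegeneratePairError,
    PreconditionError,
    ResampleError,
)
from . import mokken

__all__ = [
    "ResampleInterval",
    "bootstrap_ci",
    "permutation_null_ci",
    "h_total_statistic",
    "h_item_statistic",
    "alpha_statistic",
]

_DEGENERATE = (DegenerateItemError, DegeneratePairError, PreconditionError)


@dataclass
class ResampleInterval:
    """Point estimate with a percentile interval from B replicates."""

    point: float
    lower: float
    upper: float
    level: float
    B: int
    seed: int
    kind: str  # "bootstrap" | "permutation"
    n_degenerate: int = 0
    warning: str | None = None
    covered: bool | None = None  # permutation only: point inside the null interval

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _percentile_interval(reps: np.ndarray, level: float) -> tuple[float, float]:
    """Percentile interval whose endpoints are order statistics of the replicates."""
    alpha = (1 - level) / 2
    lo = float(np.quantile(reps, alpha, method="closest_observation"))
    hi = float(np.quantile(reps, 1 - alpha, method="closest_observation"))
    return lo, hi


# -- named statistics -------------------------------------------------------

def h_total_statistic(R: ResponseMatrix) -> float:
    """Total scalability H of the instrument."""
    comp = mokken.pairwise_scalability(R)
    h, _ = mokken.total_scalability(comp)
    return h


def h_item_statistic(item: str | int) -> Callable[[ResponseMatrix], float]:
    """Factory: single-item scalability H_i as a scalar statistic."""

    def stat(R: ResponseMatrix) -> float:
        comp = mokken.pairwise_scalability(R)
        j = comp.item_ids.index(R.item_ids[R.item_index(item)])
        return float(mokken.item_scalability(comp)[j])

    return stat


def alpha_statistic(R: ResponseMatrix) -> float:
    """Cronbach's alpha on complete cases."""
    from .evaluate import cronbach_alpha

    return cronbach_alpha(R)


def bootstrap_ci(
    R: ResponseMatrix,
    statistic: Callable[[ResponseMatrix], float],
    B: int = 1000,
    level: float = 0.90,
    seed: int = 0,
) -> ResampleInterval:
    """Percentile bootstrap over persons for any scalar statistic.

    Replicates where the statistic is degenerate (e.g. a resampled matrix
    with a constant item) are dropped and counted; more than 20% degenerate
    replicates is recorded as a warning, all-degenerate raises.
    """
    point = statistic(R)
    n = R.n_persons
    reps = []
    n_degenerate = 0
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        rows = rng.integers(0, n, size=n)
        try:
            reps.append(statistic(R.select_persons(rows)))
        except _DEGENERATE:
            n_degenerate += 1
    if not reps:
        raise ResampleError("all bootstrap replicates were degenerate")
    lo, hi = _percentile_interval(np.asarray(reps), level)
    warning = None
    if n_degenerate > 0.2 * B:
        warning = f"{n_degenerate}/{B} degenerate replicates dropped"
    return ResampleInterval(
        point=float(point),
        lower=lo,
        upper=hi,
        level=level,
        B=B,
        seed=seed,
        kind="bootstrap",
        n_degenerate=n_degenerate,
        warning=warning,
    )


def permutation_null_ci(
    R: ResponseMatrix,
    item: str | int,
    B: int = 500,
    level: float = 0.90,
    seed: int = 0,
) -> ResampleInterval:
    """Permutation null distribution of one item's H_i.

    The chosen item's responses are permuted across persons B times with the
    other items fixed; each permutation leaves both marginals untouched, so
    the Covmax denominator of H_i is constant and only the covariance with
    the rest of the scale varies. The percentile interval of the permuted
    H_i values is the null band; ``covered`` flags whether the observed H_i
    lies inside it.
    """
    comp = mokken.pairwise_scalability(R)
    C, _ = complete_cases(R)
    j = comp.item_ids.index(C.item_ids[C.item_index(item)])
    x = C.values[:, j].astype(float)
    if np.unique(x).size < 2:
        raise DegenerateItemError(f"item {item!r} has zero variance")
    others = np.delete(np.arange(C.n_items), j)
    rest = C.values[:, others].astype(float).sum(axis=1)
    denominator = comp.covmax[j, others].sum()
    observed = float(comp.cov[j, others].sum() / denominator)

    n = x.size
    rest_c = rest - rest.mean()
    xbar = x.mean()
    null = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        xp = x[rng.permutation(n)]
        # Cov(x_perm, rest) = mean(x_perm * rest_centered) since rest is centered
        null[b] = (xp - xbar) @ rest_c / n / denominator
    lo, hi = _percentile_interval(null, level)
    return ResampleInterval(
        point=observed,
        lower=lo,
        upper=hi,
        level=level,
        B=B,
        seed=seed,
        kind="permutation",
        covered=bool(lo <= observed <= hi),
    )
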