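"""Nonparametric Mokken scale analysis for polytomous items.

Loevinger-style scalability coefficients are ratios of observed to
maximum-possible covariance between item scores. For a pair of items the
maximum covariance given the two observed marginal distributions is attained
by the comonotonic coupling: sort both score vectors descending and pair them
rank by rank (rearrangement inequality). Perfect Guttman data therefore gets
H = 1 exactly, and independent items get H near 0.

All Step-1 computations run on listwise-complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import ResponseMatrix, complete_cases
from .exceptions import (
    DegenerateItemError,
    DegeneratePairError,
    PreconditionError,
)

__all__ = [
    "PairwiseComponents",
    "ScalabilityResult",
    "ScalePartition",
    "MonotonicityReport",
    "IIOReport",
    "pairwise_scalability",
    "item_scalability",
    "total_scalability",
    "scalability",
    "classify_h",
    "aisp",
    "check_monotonicity",
    "check_iio",
]


# ---------------------------------------------------------------------------
# Pairwise components
# ---------------------------------------------------------------------------

@dataclass
class PairwiseComponents:
    """Cov and Covmax for every unordered item pair (population covariances).

    ``h_pair`` is the symmetric H_ij matrix with NaN on the diagonal.
    """

    cov: np.ndarray
    covmax: np.ndarray
    h_pair: np.ndarray
    item_ids: list[str]
    n_used: int


@dataclass
class ScalabilityResult:
    """Item and total scalabilities with the conventional classification."""

    h_pair: np.ndarray
    h_item: np.ndarray
    h_total: float
    n_used: int
    classification: str
    item_ids: list[str]
    components: PairwiseComponents


@dataclass
class ScalePartition:
    """AISP output: ordered scales (lists of item ids) plus unscalable items."""

    scales: list[list[str]]
    unscalable: list[str]
    lowerbound: float
    alpha_sig: float


def _covmax_sorted(x: np.ndarray, y: np.ndarray) -> float:
    """Covariance of the comonotonic coupling of the two observed marginals."""
    xs = np.sort(x)[::-1].astype(float)
    ys = np.sort(y)[::-1].astype(float)
    return float(xs @ ys / xs.size - xs.mean() * ys.mean())


def pairwise_scalability(R: ResponseMatrix) -> PairwiseComponents:
    """Compute Cov_ij, Covmax_ij and H_ij on listwise-complete cases."""
    if R.n_items < 2:
        raise PreconditionError("scalability needs at least 2 items")
    C, _ = complete_cases(R)
    if C.n_persons < 3:
        raise PreconditionError(
            f"only {C.n_persons} complete cases; at least 3 required"
        )
    X = C.values.astype(float)
    for j in range(C.n_items):
        if np.unique(X[:, j]).size < 2:
            raise DegenerateItemError(
                f"item {C.item_ids[j]!r} has zero variance on complete cases"
            )
    n, p = X.shape
    # dot/n - mean*mean, matching _covmax_sorted's arithmetic so that
    # comonotonic (perfect Guttman) data yields H = 1 bit-exactly
    means = X.mean(axis=0)
    cov = X.T @ X / n - np.outer(means, means)
    covmax = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            covmax[i, j] = covmax[j, i] = _covmax_sorted(X[:, i], X[:, j])
    h = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i + 1, p):
            if covmax[i, j] <= 0:
                raise DegeneratePairError(
                    f"Covmax = 0 for pair ({C.item_ids[i]!r}, {C.item_ids[j]!r})"
                )
            h[i, j] = h[j, i] = cov[i, j] / covmax[i, j]
    return PairwiseComponents(
        cov=cov, covmax=covmax, h_pair=h, item_ids=list(C.item_ids), n_used=n
    )


def item_scalability(components: PairwiseComponents) -> np.ndarray:
    """H_i = sum_{j != i} Cov_ij / sum_{j != i} Covmax_ij."""
    p = len(components.item_ids)
    off = ~np.eye(p, dtype=bool)
    num = np.where(off, components.cov, 0.0).sum(axis=1)
    den = np.where(off, components.covmax, 0.0).sum(axis=1)
    return num / den


def total_scalability(components: PairwiseComponents) -> tuple[float, str]:
    """Total H over all pairs plus the weak/medium/strong classification."""
    p = len(components.item_ids)
    iu = np.triu_indices(p, k=1)
    h = float(components.cov[iu].sum() / components.covmax[iu].sum())
    return h, classify_h(h)


def classify_h(h: float) -> str:
    """Conventional cutoffs: <0.3 unscalable, then weak / medium / strong."""
    if h < 0.3:
        return "unscalable"
    if h < 0.4:
        return "weak"
    if h < 0.5:
        return "medium"
    return "strong"


def scalability(R: ResponseMatrix) -> ScalabilityResult:
    """Convenience wrapper: pairwise + item + total scalability in one result."""
    comp = pairwise_scalability(R)
    h_item = item_scalability(comp)
    h_total, cls = total_scalability(comp)
    return ScalabilityResult(
        h_pair=comp.h_pair,
        h_item=h_item,
        h_total=h_total,
        n_used=comp.n_used,
        classification=cls,
        item_ids=list(comp.item_ids),
        components=comp,
    )


# ---------------------------------------------------------------------------
# Automatic item selection procedure
# ---------------------------------------------------------------------------

def _pairwise_z(X: np.ndarray) -> np.ndarray:
    """One-sided Z for H_ij > 0: correlation scaled by sqrt(n - 1)."""
    n = X.shape[0]
    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.outer(sd, sd)
    return r * np.sqrt(n - 1)


def aisp(
    R: ResponseMatrix, lowerbound: float = 0.3, alpha_sig: float = 0.05
) -> ScalePartition:
    """Greedy bottom-up automatic item selection into Mokken scales.

    A scale is seeded with the unassigned pair of maximal H_ij among pairs
    with H_ij significantly positive; items join while their scalability
    against the provisional scale is at least ``lowerbound`` and
    significantly positive. Ties break toward the lower item index, making
    the output deterministic.
    """
    comp = pairwise_scalability(R)
    C, _ = complete_cases(R)
    X = C.values.astype(float)
    n = comp.n_used
    p = len(comp.item_ids)
    zcrit = stats.norm.ppf(1 - alpha_sig)
    zpair = _pairwise_z(X)

    remaining = list(range(p))
    scales: list[list[int]] = []
    while len(remaining) >= 2:
        seed, best_h = None, -np.inf
        for a_idx, i in enumerate(remaining):
            for j in remaining[a_idx + 1 :]:
                if zpair[i, j] > zcrit and comp.h_pair[i, j] > best_h:
                    seed, best_h = (i, j), comp.h_pair[i, j]
        if seed is None:
            break
        scale = list(seed)
        remaining = [k for k in remaining if k not in scale]
        while remaining:
            best_k, best_scale_h = None, -np.inf
            for k in remaining:
                num = comp.cov[k, scale].sum()
                den = comp.covmax[k, scale].sum()
                h_k = num / den
                rest = X[:, scale].sum(axis=1)
                if np.std(rest) == 0 or np.std(X[:, k]) == 0:
                    continue
                z_k = np.corrcoef(X[:, k], rest)[0, 1] * np.sqrt(n - 1)
                if h_k < lowerbound or z_k <= zcrit:
                    continue
                cand = scale + [k]
                iu = np.array([(a, b) for ai, a in enumerate(cand) for b in cand[ai + 1 :]]).T
                new_h = comp.cov[iu[0], iu[1]].sum() / comp.covmax[iu[0], iu[1]].sum()
                if new_h > best_scale_h:
                    best_k, best_scale_h = k, new_h
            if best_k is None:
                break
            scale.append(best_k)
            remaining = [k for k in remaining if k != best_k]
        scales.append(sorted(scale))
    ids = comp.item_ids
    return ScalePartition(
        scales=[[ids[i] for i in s] for s in scales],
        unscalable=[ids[i] for i in remaining],
        lowerbound=lowerbound,
        alpha_sig=alpha_sig,
    )


# ---------------------------------------------------------------------------
# Restscore diagnostics: monotonicity and invariant item ordering
# ---------------------------------------------------------------------------

@dataclass
class ItemMonotonicity:
    item: str
    group_sizes: list[int]
    group_rest_ranges: list[tuple[float, float]]
    active_comparisons: int
    violations: int
    max_violation: float
    significant_violations: int
    insufficient: bool = False


@dataclass
class MonotonicityReport:
    items: dict[str, ItemMonotonicity]
    minsize: int
    minvi: float

    @property
    def total_violations(self) -> int:
        return sum(i.violations for i in self.items.values())

    @property
    def total_significant(self) -> int:
        return sum(i.significant_violations for i in self.items.values())


@dataclass
class PairIIO:
    items: tuple[str, str]  # (higher-mean item, lower-mean item)
    violations: int
    max_violation: float
    significant_violations: int
    insufficient: bool = False


@dataclass
class IIOReport:
    pairs: list[PairIIO]
    per_item_significant: dict[str, int]
    minsize: int
    tolerance: float


def _restscore_groups(rest: np.ndarray, minsize: int) -> list[np.ndarray]:
    """Merge adjacent raw rest scores left-to-right into groups of >= minsize.

    A trailing remainder smaller than ``minsize`` joins the last full group.
    """
    values = np.sort(np.unique(rest))
    groups: list[list[float]] = []
    current: list[float] = []
    count = 0
    for v in values:
        current.append(float(v))
        count += int((rest == v).sum())
        if count >= minsize:
            groups.append(current)
            current, count = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    return [np.isin(rest, g) for g in groups]


def check_monotonicity(
    R: ResponseMatrix, minsize: int = 15, minvi: float = 0.03
) -> MonotonicityReport:
    """Manifest-monotonicity check of each item against restscore groups.

    For each item step ``k >= 1`` the estimated P(X_i >= k | restscore group)
    must not decrease from a lower to a higher group by more than ``minvi``;
    decreases beyond that are violations, tested one-sided at 5% with a
    two-proportion z-test.
    """
    C, _ = complete_cases(R)
    X = C.values
    total = X.sum(axis=1)
    out: dict[str, ItemMonotonicity] = {}
    for j, item in enumerate(C.item_ids):
        rest = total - X[:, j]
        groups = _restscore_groups(rest, minsize)
        if len(groups) < 2:
            out[item] = ItemMonotonicity(
                item=item,
                group_sizes=[int(g.sum()) for g in groups],
                group_rest_ranges=[
                    (float(rest[g].min()), float(rest[g].max())) for g in groups
                ],
                active_comparisons=0,
                violations=0,
                max_violation=0.0,
                significant_violations=0,
                insufficient=True,
            )
            continue
        sizes = np.array([int(g.sum()) for g in groups])
        steps = range(1, int(C.n_categories[j]))
        active = 0
        violations = 0
        sig = 0
        max_vi = 0.0
        for k in steps:
            phat = np.array([float((X[g, j] >= k).mean()) for g in groups])
            hits = np.array([int((X[g, j] >= k).sum()) for g in groups])
            for lo in range(len(groups)):
                for hi in range(lo + 1, len(groups)):
                    active += 1
                    diff = phat[lo] - phat[hi]
                    if diff > minvi:
                        violations += 1
                        max_vi = max(max_vi, float(diff))
                        pooled = (hits[lo] + hits[hi]) / (sizes[lo] + sizes[hi])
                        se = np.sqrt(
                            pooled * (1 - pooled) * (1 / sizes[lo] + 1 / sizes[hi])
                        )
                        if se > 0 and diff / se > stats.norm.ppf(0.95):
                            sig += 1
        out[item] = ItemMonotonicity(
            item=item,
            group_sizes=sizes.tolist(),
            group_rest_ranges=[
                (float(rest[g].min()), float(rest[g].max())) for g in groups
            ],
            active_comparisons=active,
            violations=violations,
            max_violation=max_vi,
            significant_violations=sig,
        )
    return MonotonicityReport(items=out, minsize=minsize, minvi=minvi)


def check_iio(
    R: ResponseMatrix, minsize: int = 15, tolerance: float | None = None
) -> IIOReport:
    """Invariant item ordering (non-intersection) by the restscore method.

    Items in each pair are ordered by their overall sample means; within each
    restscore group (rest excludes both items) the conditional means must keep
    that order. A reversal larger than ``tolerance`` (default 0.03 x the
    maximum category code) counts as a violation; significance is a paired
    one-sided t-test at 5%.
    """
    C, _ = complete_cases(R)
    X = C.values
    if tolerance is None:
        tolerance = 0.03 * float(C.max_codes.max())
    total = X.sum(axis=1)
    means = X.mean(axis=0)
    pairs: list[PairIIO] = []
    per_item = {item: 0 for item in C.item_ids}
    p = C.n_items
    for i in range(p):
        for j in range(i + 1, p):
            hi, lo = (i, j) if means[i] >= means[j] else (j, i)
            rest = total - X[:, i] - X[:, j]
            groups = _restscore_groups(rest, minsize)
            if len(groups) < 2 and (not groups or groups[0].sum() < minsize):
                pairs.append(
                    PairIIO(
                        items=(C.item_ids[hi], C.item_ids[lo]),
                        violations=0,
                        max_violation=0.0,
                        significant_violations=0,
                        insufficient=True,
                    )
                )
                continue
            violations = 0
            sig = 0
            max_vi = 0.0
            for g in groups:
                d = X[g, lo].astype(float) - X[g, hi].astype(float)
                reversal = float(d.mean())
                if reversal > tolerance:
                    violations += 1
                    max_vi = max(max_vi, reversal)
                    if d.size > 1 and d.std(ddof=1) > 0:
                        t = reversal / (d.std(ddof=1) / np.sqrt(d.size))
                        if stats.t.sf(t, df=d.size - 1) < 0.05:
                            sig += 1
            pairs.append(
                PairIIO(
                    items=(C.item_ids[hi], C.item_ids[lo]),
                    violations=violations,
                    max_violation=max_vi,
                    significant_violations=sig,
                )
            )
            per_item[C.item_ids[hi]] += sig
            per_item[C.item_ids[lo]] += sig
    return IIOReport(
        pairs=pairs, per_item_significant=per_item, minsize=minsize, tolerance=tolerance
    )
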