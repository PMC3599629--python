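"""Classical comparator, ranking analysis, aberrant-profile flags, and the
orchestrated 3-step evaluation pipeline.

The pipeline mirrors how a small-sample instrument evaluation proceeds:

* **Step 1** (always): nonparametric scalability with bootstrap intervals,
  permutation nulls for suspect items, automatic item selection, restscore
  monotonicity / invariant-item-ordering checks, and Cronbach's alpha as the
  classical-test-theory comparator.
* **Step 2** (gated on Step 1): a rating-scale Rasch structure — worth keeping
  even when it fails, because it corresponds to using the raw sum score — and
  a likelihood-ratio gate on equal item discriminations.
* **Step 3**: the free-discrimination graded response model with item
  locations, information shares, person measures, coverage and profile flags.

Skipped stages always record the rule that triggered the skip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .data import ResponseMatrix, complete_cases
from .exceptions import DegenerateItemError, PreconditionError
from . import irt, mokken, resample

__all__ = [
    "PipelineConfig",
    "RankInterval",
    "PersonFlag",
    "InstrumentReport",
    "EvaluationReport",
    "cronbach_alpha",
    "cronbach_alpha_values",
    "rank_interval",
    "rank_concordance",
    "flag_profiles",
    "run_three_step",
    "evaluate_battery",
]


# ---------------------------------------------------------------------------
# Classical comparator
# ---------------------------------------------------------------------------

def cronbach_alpha_values(values: np.ndarray) -> float:
    """Cronbach's alpha from a complete persons x items score matrix.

    ``alpha = I/(I-1) * (1 - sum var_i / var_total)`` with unbiased variances.
    """
    values = np.asarray(values, dtype=float)
    n, I = values.shape
    if I < 2:
        raise PreconditionError("alpha needs at least 2 items")
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateItemError("total score has zero variance")
    item_var = values.var(axis=0, ddof=1).sum()
    return float(I / (I - 1) * (1 - item_var / total_var))


def cronbach_alpha(R: ResponseMatrix) -> float:
    """Cronbach's alpha on listwise-complete cases."""
    C, _ = complete_cases(R)
    return cronbach_alpha_values(C.values)


# ---------------------------------------------------------------------------
# Rank analysis
# ---------------------------------------------------------------------------

@dataclass
class RankInterval:
    person: int
    rank: int
    n_scored: int
    rank_lo: int
    rank_hi: int
    relative_lo: int
    relative_hi: int
    relative_rank: int
    level: float


def _rank_of_value(x: float, theta_others: np.ndarray) -> int:
    """1 + number of other scored persons strictly below x.

    The person under examination is excluded from the count, so that as
    SE -> 0 both interval endpoints collapse onto the person's own rank.
    """
    return 1 + int(np.sum(theta_others < x))


def rank_interval(
    scores: irt.PersonScores, person: int, level: float = 0.95
) -> RankInterval:
    """Rank interval from the person's Wald CI on the latent scale.

    The CI ``theta_p +/- z * SE_p`` is mapped to ranks by counting scored
    persons strictly below each endpoint; the person's own rank breaks ties
    by person index (earlier index ranks lower). Relative ranks are
    ``100 * rank / n_scored`` rounded to integers.
    """
    if not scores.scored[person]:
        raise PreconditionError(f"person {person} has no score")
    theta = scores.theta[scores.scored]
    order_index = np.where(scores.scored)[0]
    n = theta.size
    if n < 2:
        raise PreconditionError("need at least 2 scored persons")
    tp, sp = float(scores.theta[person]), float(scores.se[person])
    z = stats.norm.ppf((1 + level) / 2)
    own = 1 + int(np.sum(theta < tp)) + int(
        np.sum((theta == tp) & (order_index < person))
    )
    others = theta[order_index != person]
    lo = _rank_of_value(tp - z * sp, others)
    hi = _rank_of_value(tp + z * sp, others)
    return RankInterval(
        person=person,
        rank=own,
        n_scored=n,
        rank_lo=lo,
        rank_hi=hi,
        relative_lo=round(100 * lo / n),
        relative_hi=round(100 * hi / n),
        relative_rank=round(100 * own / n),
        level=level,
    )


def rank_concordance(
    scores_a: irt.PersonScores,
    scores_b: irt.PersonScores,
    threshold: int = 15,
) -> tuple[float, float]:
    """Spearman correlation of person ranks plus a discordance fraction.

    The discordance fraction is the share of commonly scored persons whose
    ranks on the two instruments differ by ``threshold`` units or more.
    """
    common = scores_a.scored & scores_b.scored
    if common.sum() < 3:
        raise PreconditionError("need at least 3 commonly scored persons")
    ta = scores_a.theta[common]
    tb = scores_b.theta[common]
    rho = float(stats.spearmanr(ta, tb).statistic)
    ra = stats.rankdata(ta, method="ordinal")
    rb = stats.rankdata(tb, method="ordinal")
    frac = float(np.mean(np.abs(ra - rb) >= threshold))
    return rho, frac


# ---------------------------------------------------------------------------
# Aberrant profiles
# ---------------------------------------------------------------------------

@dataclass
class PersonFlag:
    person: int
    reason: str  # "constant" | "low_person_fit"
    value: float


def flag_profiles(
    R: ResponseMatrix, fit: irt.GRMFit, cutoff: float = -2.0
) -> list[PersonFlag]:
    """Advisory flags for constant responders and low person-fit profiles.

    Person fit is the standardised log-likelihood of the response pattern at
    the person's EAP estimate: ``z = (l - E[l]) / sqrt(Var[l])`` with moments
    taken under the fitted model. Flagged persons are reported, never
    removed.
    """
    scores = irt.score_persons(fit, R)
    obs = ~R.missing_mask
    flags: list[PersonFlag] = []
    for p in range(R.n_persons):
        x = R.values[p, obs[p]]
        if obs[p].sum() >= 2 and np.unique(x).size == 1:
            flags.append(PersonFlag(person=p, reason="constant", value=float(x[0])))

    theta = scores.theta
    for p in range(R.n_persons):
        if not scores.scored[p]:
            continue
        P = irt.grm_category_probs(fit, np.array([theta[p]]))[:, 0, :]  # (I, K)
        logP = np.log(P)
        items = np.where(obs[p])[0]
        if items.size < 2:
            continue
        l = sum(logP[i, min(R.values[p, i], P.shape[1] - 1)] for i in items)
        e = sum((P[i] * logP[i]).sum() for i in items)
        v = sum(
            (P[i] * logP[i] ** 2).sum() - (P[i] * logP[i]).sum() ** 2 for i in items
        )
        if v <= 0:
            continue
        z = (l - e) / np.sqrt(v)
        if z < cutoff:
            flags.append(PersonFlag(person=p, reason="low_person_fit", value=float(z)))
    return flags


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    lowerbound: float = 0.3
    minsize: int = 15
    minvi: float = 0.03
    bootstrap_B: int = 1000
    permutation_B: int = 500
    ci_level: float = 0.90
    rank_level: float = 0.95
    quadrature: int = 41
    alpha_sig: float = 0.05
    lr_alpha: float = 0.05
    max_a_ratio: float = 3.0
    rank_threshold: int = 15
    seed: int = 0
    compute_se: bool = True


@dataclass
class StepGate:
    outcome: str  # "proceed" | "stop"
    rule: str


@dataclass
class InstrumentReport:
    name: str
    scalability: mokken.ScalabilityResult
    h_total_ci: resample.ResampleInterval
    alpha: float
    partition: mokken.ScalePartition
    monotonicity: mokken.MonotonicityReport
    iio: mokken.IIOReport
    permutation_tests: dict[str, resample.ResampleInterval]
    step1_gate: StepGate
    rsm: irt.RSMFit | None = None
    rsm_skip_rule: str | None = None
    lr_test: irt.LRTestResult | None = None
    step2_gate: StepGate | None = None
    grm: irt.GRMFit | None = None
    information: irt.InformationGrid | None = None
    scores: irt.PersonScores | None = None
    coverage: dict | None = None
    flags: list[PersonFlag] = field(default_factory=list)


@dataclass
class EvaluationReport:
    instruments: dict[str, InstrumentReport]
    rank_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    discordance_fractions: dict[tuple[str, str], float] = field(default_factory=dict)
    config: PipelineConfig | None = None


def _coverage_summary(scores: irt.PersonScores, fit: irt.GRMFit) -> dict:
    """Numeric coverage: person-measure quantiles vs item location/threshold range."""
    theta = scores.theta[scores.scored]
    finite = fit.thresholds[np.isfinite(fit.thresholds)]
    qs = [5, 25, 50, 75, 95]
    return {
        "person_quantiles": {q: float(np.percentile(theta, q)) for q in qs},
        "item_location_range": (float(fit.b.min()), float(fit.b.max())),
        "threshold_range": (float(finite.min()), float(finite.max())),
        "persons_below_lowest_location": float(np.mean(theta < fit.b.min())),
        "persons_above_highest_location": float(np.mean(theta > fit.b.max())),
    }


def run_three_step(
    R: ResponseMatrix, config: PipelineConfig | None = None, name: str = "instrument"
) -> InstrumentReport:
    """Run the full 3-step evaluation on one instrument.

    Step 1 always runs. Step 2 runs iff the Step-1 gate passes (total H above
    the lowerbound and all item H_i positive). Step 3 fits the
    free-discrimination graded response model whenever Step 2 ran,
    regardless of the Step-2 gate, since its purpose is diagnostic.
    """
    cfg = config or PipelineConfig()

    # ----- Step 1: nonparametric -----
    scal = mokken.scalability(R)
    h_ci = resample.bootstrap_ci(
        R, resample.h_total_statistic, B=cfg.bootstrap_B, level=cfg.ci_level,
        seed=cfg.seed,
    )
    alpha = cronbach_alpha(R)
    partition = mokken.aisp(R, lowerbound=cfg.lowerbound, alpha_sig=cfg.alpha_sig)
    mono = mokken.check_monotonicity(R, minsize=cfg.minsize, minvi=cfg.minvi)
    iio = mokken.check_iio(R, minsize=cfg.minsize)
    permutation_tests = {}
    for item, h_i in zip(scal.item_ids, scal.h_item):
        if h_i < cfg.lowerbound:
            permutation_tests[item] = resample.permutation_null_ci(
                R, item, B=cfg.permutation_B, level=cfg.ci_level, seed=cfg.seed,
            )

    if scal.h_total > cfg.lowerbound and np.all(scal.h_item > 0):
        gate1 = StepGate("proceed", f"H = {scal.h_total:.3f} > {cfg.lowerbound} and all H_i > 0")
    else:
        gate1 = StepGate(
            "stop",
            f"H = {scal.h_total:.3f} (must exceed {cfg.lowerbound}) "
            f"with min H_i = {scal.h_item.min():.3f} (must be positive)",
        )
    report = InstrumentReport(
        name=name, scalability=scal, h_total_ci=h_ci, alpha=alpha,
        partition=partition, monotonicity=mono, iio=iio,
        permutation_tests=permutation_tests, step1_gate=gate1,
    )
    if gate1.outcome == "stop":
        return report

    # ----- Step 2: rating-scale structure and the equal-discrimination gate -----
    common_k = np.unique(R.n_categories).size == 1
    if common_k:
        report.rsm = irt.fit_rsm(R, n_quadrature=cfg.quadrature)
        thr = "common"
    else:
        report.rsm_skip_rule = "unequal category counts; rating scale model skipped"
        thr = "free"
    fit_eq = irt.fit_grm(
        R, thresholds=thr, discrimination="equal", n_quadrature=cfg.quadrature,
        compute_se=False,
    )
    fit_free = irt.fit_grm(
        R, thresholds=thr, discrimination="free", n_quadrature=cfg.quadrature,
        compute_se=cfg.compute_se,
    )
    report.lr_test = lr = irt.lr_test_equal_discrimination(fit_eq, fit_free)
    ratio = float(fit_free.a.max() / fit_free.a.min())
    if lr.p < cfg.lr_alpha or ratio > cfg.max_a_ratio:
        report.step2_gate = StepGate(
            "stop",
            f"equal discrimination rejected: LR p = {lr.p:.3g} (alpha {cfg.lr_alpha}) "
            f"or max/min discrimination = {ratio:.2f} > {cfg.max_a_ratio}",
        )
    else:
        report.step2_gate = StepGate(
            "proceed", f"LR p = {lr.p:.3g} and max/min discrimination = {ratio:.2f}"
        )

    # ----- Step 3: graded response model diagnostics -----
    report.grm = fit_free
    info = irt.item_information(fit_free)
    report.information = irt.relative_information(info)
    report.scores = irt.score_persons(fit_free, R, recenter=True)
    report.coverage = _coverage_summary(report.scores, fit_free)
    report.flags = flag_profiles(R, fit_free)
    return report


def evaluate_battery(
    instruments: Mapping[str, ResponseMatrix], config: PipelineConfig | None = None
) -> EvaluationReport:
    """Evaluate several instruments and compare their person rankings."""
    cfg = config or PipelineConfig()
    reports = {
        name: run_three_step(R, cfg, name=name) for name, R in instruments.items()
    }
    out = EvaluationReport(instruments=reports, config=cfg)
    names = [n for n, r in reports.items() if r.scores is not None]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rho, frac = rank_concordance(
                reports[a].scores, reports[b].scores, threshold=cfg.rank_threshold
            )
            out.rank_correlations[(a, b)] = rho
            out.discordance_fractions[(a, b)] = frac
    return out
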