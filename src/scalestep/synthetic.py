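"""Synthetic response generators with the statistical structure the analysis assumes.

Every generator returns the truth it used (latent traits, item parameters,
aberrant-person flags), is bit-reproducible given its seed, and masks
missing cells completely at random. ``generate_study_like`` emulates the
kind of small clinical battery the package targets: 61 respondents answering
three blocks — a 9-item / 5-category self-rating depression subscale, a
9-item / 4-category questionnaire, and a 10-item / 7-category observer
scale with sparse top categories — driven by one shared severity dimension,
with one constant and one random responder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import ResponseMatrix
from .exceptions import SchemaError

__all__ = [
    "GeneratorConfig",
    "generate_grm",
    "generate_rsm",
    "generate_multidim",
    "generate_study_like",
]


@dataclass
class GeneratorConfig:
    """Parameters of a synthetic instrument.

    For graded-response generation supply ``a`` and either ``b`` + shared
    ``t`` or a full ``thresholds`` matrix; for rating-scale generation supply
    ``beta`` and ``tau``. Aberrant responders are appended after the
    ``n_persons`` coherent ones and flagged in the returned truth.
    """

    n_persons: int = 61
    a: np.ndarray | None = None
    b: np.ndarray | None = None
    t: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    beta: np.ndarray | None = None
    tau: np.ndarray | None = None
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    missing_rate: float = 0.0
    n_constant: int = 0
    n_random: int = 0
    seed: int = 0
    item_prefix: str = "item"

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise SchemaError("missing_rate must be in [0, 1)")
        if self.a is not None and np.any(np.asarray(self.a) <= 0):
            raise SchemaError("discriminations must be positive")
        if self.t is not None and np.any(np.diff(np.asarray(self.t)) <= 0):
            raise SchemaError("thresholds must be strictly increasing")


def _grm_thresholds(config: GeneratorConfig) -> np.ndarray:
    if config.thresholds is not None:
        D = np.asarray(config.thresholds, dtype=float)
    else:
        if config.a is None or config.b is None or config.t is None:
            raise SchemaError("supply a and (b, t) or a thresholds matrix")
        D = np.asarray(config.b, float)[:, None] + np.asarray(config.t, float)[None, :]
    if np.any(np.diff(np.where(np.isfinite(D), D, np.inf), axis=1) <= 0):
        bad = ~np.all(np.diff(np.where(np.isfinite(D), D, np.inf), axis=1) > 0, axis=1)
        if np.any(bad & np.all(np.isfinite(D), axis=1)):
            raise SchemaError("per-item thresholds must be strictly increasing")
    return D


def _draw_grm(
    a: np.ndarray, D: np.ndarray, theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One uniform per person-item; category = number of thresholds passed."""
    pstar = expit(a[None, :, None] * (theta[:, None, None] - D[None, :, :]))
    pstar = np.where(np.isfinite(D)[None, :, :], pstar, 0.0)
    u = rng.random((theta.size, a.size))
    return (u[:, :, None] < pstar).sum(axis=2)


def _append_aberrant(
    X: np.ndarray, n_cat: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    rows, kinds = [], []
    for _ in range(config.n_constant):
        c = int(rng.integers(0, n_cat.min()))
        rows.append(np.full(X.shape[1], c))
        kinds.append("constant")
    for _ in range(config.n_random):
        rows.append(rng.integers(0, n_cat))
        kinds.append("random")
    if rows:
        X = np.vstack([X, np.array(rows)])
    return X, kinds


def _finalize(
    X: np.ndarray, n_cat: np.ndarray, config: GeneratorConfig,
    rng: np.random.Generator, truth: dict,
) -> tuple[ResponseMatrix, dict]:
    X, kinds = _append_aberrant(X, n_cat, config, rng)
    mask = rng.random(X.shape) < config.missing_rate
    # a fully masked person would be meaningless; keep one observed cell
    full = mask.all(axis=1)
    mask[full, 0] = False
    R = ResponseMatrix(
        values=np.where(mask, 0, X),
        missing_mask=mask,
        item_ids=[f"{config.item_prefix}{i + 1}" for i in range(X.shape[1])],
        n_categories=n_cat,
    )
    truth["aberrant"] = {
        config.n_persons + i: kind for i, kind in enumerate(kinds)
    }
    truth["config"] = config
    return R, truth


def generate_grm(config: GeneratorConfig) -> tuple[ResponseMatrix, dict]:
    """Simulate graded-response data; returns (matrix, truth)."""
    D = _grm_thresholds(config)
    a = np.asarray(config.a, float)
    rng = np.random.default_rng(config.seed)
    theta = config.latent_mean + config.latent_sd * rng.standard_normal(config.n_persons)
    X = _draw_grm(a, D, theta, rng)
    n_cat = (np.isfinite(D).sum(axis=1) + 1).astype(int)
    truth = {"theta": theta, "a": a, "thresholds": D, "b": config.b, "t": config.t}
    return _finalize(X, n_cat, config, rng, truth)


def generate_rsm(config: GeneratorConfig) -> tuple[ResponseMatrix, dict]:
    """Simulate rating-scale (adjacent-category Rasch) data; returns (matrix, truth)."""
    if config.beta is None or config.tau is None:
        raise SchemaError("rating-scale generation needs beta and tau")
    beta = np.asarray(config.beta, float)
    tau = np.asarray(config.tau, float)
    K = tau.size + 1
    rng = np.random.default_rng(config.seed)
    theta = config.latent_mean + config.latent_sd * rng.standard_normal(config.n_persons)
    k = np.arange(K)
    Tk = np.concatenate([[0.0], np.cumsum(tau)])
    u = (
        k[None, None, :] * theta[:, None, None]
        - k[None, None, :] * beta[None, :, None]
        - Tk[None, None, :]
    )
    u -= u.max(axis=2, keepdims=True)
    P = np.exp(u)
    P /= P.sum(axis=2, keepdims=True)
    cum = P.cumsum(axis=2)
    draws = rng.random((config.n_persons, beta.size, 1))
    X = (draws > cum).sum(axis=2)
    n_cat = np.full(beta.size, K)
    truth = {"theta": theta, "beta": beta, "tau": tau}
    return _finalize(X, n_cat, config, rng, truth)


def generate_multidim(
    config: GeneratorConfig, n_blocks: int = 2, items_per_block: int = 5,
    block_corr: float = 0.0,
) -> tuple[ResponseMatrix, dict]:
    """Blocks of items driven by distinct (optionally correlated) latent traits.

    ``config.a``/``config.b``/``config.t`` describe one block and are reused
    for every block; with ``n_blocks == 1`` this collapses to
    :func:`generate_grm`.
    """
    if n_blocks < 1:
        raise SchemaError("n_blocks must be >= 1")
    if n_blocks == 1:
        return generate_grm(config)
    D = _grm_thresholds(config)
    a = np.asarray(config.a, float)
    if a.size != items_per_block:
        a = np.resize(a, items_per_block)
        D = np.resize(D, (items_per_block, D.shape[1]))
    rng = np.random.default_rng(config.seed)
    cov = np.full((n_blocks, n_blocks), block_corr) + (1 - block_corr) * np.eye(n_blocks)
    thetas = rng.multivariate_normal(
        np.full(n_blocks, config.latent_mean),
        config.latent_sd**2 * cov,
        size=config.n_persons,
        method="cholesky",
    )
    blocks = [
        _draw_grm(a, D, thetas[:, bidx], rng) for bidx in range(n_blocks)
    ]
    X = np.hstack(blocks)
    n_cat = np.tile((np.isfinite(D).sum(axis=1) + 1).astype(int), n_blocks)
    truth = {
        "theta": thetas,
        "a": np.tile(a, n_blocks),
        "thresholds": np.tile(D, (n_blocks, 1)),
        "blocks": [
            list(range(bidx * items_per_block, (bidx + 1) * items_per_block))
            for bidx in range(n_blocks)
        ],
    }
    return _finalize(X, n_cat, config, rng, truth)


# ---------------------------------------------------------------------------
# Study-like battery
# ---------------------------------------------------------------------------

# Item parameters of the three emulated blocks: discriminations spanning
# ~0.27-2.85 and locations ~-0.6..1.8, with block-specific threshold spreads
# chosen so marginal category frequencies resemble a moderately depressed
# outpatient sample (mass concentrated in low categories, sparse top
# categories on the 7-category observer scale).
_AS18_A = np.array([0.574, 2.845, 0.923, 1.256, 1.751, 0.861, 1.313, 1.102, 1.710])
_AS18_B = np.array([0.902, 0.096, 0.677, 0.479, 0.299, -0.134, 0.241, 0.635, 1.542])
_AS18_T = np.array([-0.9, -0.15, 0.55, 1.3])
_PHQ_A = np.array([2.425, 1.266, 0.918, 1.209, 0.704, 1.484, 1.245, 0.891, 1.150])
_PHQ_B = np.array([0.055, -0.094, -0.266, -0.114, 0.551, 0.067, -0.393, 0.728, 1.417])
_PHQ_T = np.array([-0.8, 0.0, 0.8])
_MADRS_A = np.array(
    [1.927, 1.425, 1.175, 0.273, 0.712, 0.659, 0.783, 1.065, 0.898, 0.683]
)
_MADRS_B = np.array(
    [0.160, 0.588, -0.252, 1.832, 1.161, -0.582, 0.641, 0.052, -0.178, 1.197]
)
_MADRS_T = np.array([-0.9, -0.3, 0.4, 1.2, 2.6, 4.2])

# Severity spread of the emulated clinical sample. A mixed outpatient
# population (remitted through severely depressed) is wider than a unit
# normal; 1.75 reproduces the qualitative scalability contrast between the
# emulated blocks (two strong self-rating scales, one weak observer scale).
_STUDY_LATENT_SD = 1.75


def generate_study_like(seed: int = 0) -> tuple[ResponseMatrix, dict]:
    """A 61-person battery of three instrument blocks sharing one severity trait.

    Returns a single 28-column matrix; ``truth["blocks"]`` maps block names
    to column slices. Each block gets 0-4 missing cells completely at
    random; person 59 is a constant responder and person 60 answers at
    random (both flagged in the truth).
    """
    rng = np.random.default_rng(seed)
    n_coherent = 59
    theta = _STUDY_LATENT_SD * rng.standard_normal(n_coherent)

    blocks = {
        "AS-18-D": (_AS18_A, _AS18_B[:, None] + _AS18_T[None, :], "AS18D"),
        "PHQ9": (_PHQ_A, _PHQ_B[:, None] + _PHQ_T[None, :], "PHQ9_"),
        "MADRS": (_MADRS_A, _MADRS_B[:, None] + _MADRS_T[None, :], "MADRS"),
    }
    cols: list[np.ndarray] = []
    item_ids: list[str] = []
    n_cat_parts: list[np.ndarray] = []
    slices: dict[str, slice] = {}
    start = 0
    for name, (a, D, prefix) in blocks.items():
        Xb = _draw_grm(a, D, theta, rng)
        cols.append(Xb)
        item_ids.extend(f"{prefix}{i + 1}" for i in range(a.size))
        n_cat_parts.append(np.full(a.size, D.shape[1] + 1))
        slices[name] = slice(start, start + a.size)
        start += a.size
    X = np.hstack(cols)
    n_cat = np.concatenate(n_cat_parts).astype(int)

    # aberrant responders: one constant, one random
    const_row = np.full(X.shape[1], int(rng.integers(0, n_cat.min())))
    rand_row = rng.integers(0, n_cat)
    X = np.vstack([X, const_row, rand_row])

    mask = np.zeros(X.shape, dtype=bool)
    for name, sl in slices.items():
        n_missing = int(rng.integers(0, 5))
        for _ in range(n_missing):
            mask[rng.integers(0, n_coherent), rng.integers(sl.start, sl.stop)] = True

    R = ResponseMatrix(
        values=np.where(mask, 0, X), missing_mask=mask,
        item_ids=item_ids, n_categories=n_cat,
    )
    truth = {
        "theta": theta,
        "blocks": slices,
        "a": {"AS-18-D": _AS18_A, "PHQ9": _PHQ_A, "MADRS": _MADRS_A},
        "b": {"AS-18-D": _AS18_B, "PHQ9": _PHQ_B, "MADRS": _MADRS_B},
        "t": {"AS-18-D": _AS18_T, "PHQ9": _PHQ_T, "MADRS": _MADRS_T},
        "aberrant": {59: "constant", 60: "random"},
        "seed": seed,
    }
    return R, truth
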