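"""Parametric IRT: Rasch rating scale model and graded response models.

Both models are estimated by marginal maximum likelihood with a normal
latent trait integrated over fixed Gauss-Hermite quadrature, maximised by
an EM algorithm (generalised EM: the M-step improves the expected
complete-data log-likelihood with a quasi-Newton inner optimisation, so the
marginal log-likelihood is non-decreasing across iterations; the trace is
kept on the fit object).

Models
------
Rating scale model (RSM): adjacent-category Rasch model,
``P(X_i = k | theta) propto exp(sum_{l<=k} (theta - beta_i - tau_l))`` with a
single set of thresholds ``tau`` (sum-zero) shared by all items, unit slope
and a free latent standard deviation. Under this model the raw sum score is
a sufficient statistic for the person.

Graded response model (GRM): cumulative-logit 2PL,
``P(X_i >= k | theta) = logistic(D_scale * a_i * (theta - b_i - t_k))`` with
common thresholds ``t`` (sum-zero), or ``logistic(a_i (theta - b_ik))`` with
item-specific thresholds. The latent trait is standard normal; the logistic
scaling constant is 1 by default (no 1.7).

Missing responses contribute nothing to a person's likelihood (full
information); only persons with no observed items at all are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .data import ResponseMatrix
from .exceptions import DegenerateItemError, OptimizationError, PreconditionError

__all__ = [
    "RSMFit",
    "GRMFit",
    "PersonScores",
    "InformationGrid",
    "LRTestResult",
    "fit_rsm",
    "fit_grm",
    "lr_test_equal_discrimination",
    "score_persons",
    "item_information",
    "relative_information",
    "grm_category_probs",
]

_PROB_FLOOR = 1e-12


def _gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for integrating against a standard normal density."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _prepare(R: ResponseMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Values, observed mask and the used-row index (rows with >=1 observation)."""
    obs = ~R.missing_mask
    used = np.where(obs.any(axis=1))[0]
    return R.values[used], obs[used], used


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class RSMFit:
    beta: np.ndarray
    tau: np.ndarray  # full set, sum-zero
    latent_sd: float
    loglik: float
    converged: bool
    n_quadrature: int
    item_ids: list[str]
    n_categories: int
    ll_history: list[float] = field(default_factory=list)
    n_persons_used: int = 0


@dataclass
class GRMFit:
    a: np.ndarray  # discriminations, one per item
    b: np.ndarray  # item locations (mean threshold for free-threshold fits)
    thresholds: np.ndarray  # (I, m) cumulative-step locations d_ik; inf-padded
    t: np.ndarray | None  # shared thresholds (common variant only), sum-zero
    model_tag: str  # "{equal|free}_a:{common|free}_t"
    loglik: float
    converged: bool
    n_quadrature: int
    item_ids: list[str]
    n_categories: np.ndarray
    se_a: np.ndarray | None = None
    se_b: np.ndarray | None = None
    d_scale: float = 1.0
    ll_history: list[float] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    heywood: bool = False
    n_persons_used: int = 0
    recode_maps: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        disc, thr = self.model_tag.split(":")
        I = len(self.item_ids)
        n_a = 1 if disc == "equal_a" else I
        if thr == "common_t":
            return n_a + I + (self.thresholds.shape[1] - 1)
        valid = np.isfinite(self.thresholds).sum()
        return n_a + int(valid)

    @classmethod
    def from_parameters(
        cls,
        a: np.ndarray,
        b: np.ndarray | None = None,
        t: np.ndarray | None = None,
        thresholds: np.ndarray | None = None,
        item_ids: list[str] | None = None,
        d_scale: float = 1.0,
    ) -> "GRMFit":
        """Build a fit object from known parameters (no estimation).

        Supply either ``b`` + shared ``t`` (common thresholds) or a full
        ``thresholds`` matrix.
        """
        a = np.asarray(a, dtype=float)
        if thresholds is None:
            if b is None or t is None:
                raise ValueError("need b and t, or a thresholds matrix")
            b = np.asarray(b, dtype=float)
            t = np.asarray(t, dtype=float)
            thresholds = b[:, None] + t[None, :]
            tag = "free_a:common_t"
        else:
            thresholds = np.asarray(thresholds, dtype=float)
            b = np.array([row[np.isfinite(row)].mean() for row in thresholds])
            t = None
            tag = "free_a:free_t"
        ids = item_ids or [f"item{i + 1}" for i in range(a.size)]
        ncat = np.isfinite(thresholds).sum(axis=1) + 1
        return cls(
            a=a,
            b=b,
            thresholds=thresholds,
            t=t,
            model_tag=tag,
            loglik=np.nan,
            converged=True,
            n_quadrature=0,
            item_ids=ids,
            n_categories=ncat,
            d_scale=d_scale,
        )


@dataclass
class PersonScores:
    theta: np.ndarray  # NaN for excluded persons
    se: np.ndarray
    scored: np.ndarray  # bool, False where all items missing
    recentered: bool
    corrected_item_locations: np.ndarray | None = None
    excluded: list[int] = field(default_factory=list)


@dataclass
class InformationGrid:
    theta: np.ndarray
    item_info: np.ndarray  # (I, G)
    total_info: np.ndarray  # (G,)
    item_ids: list[str]
    relative_share: np.ndarray | None = None
    display_bucket: list[str] | None = None
    underflow: bool = False


@dataclass
class LRTestResult:
    statistic: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# GRM likelihood machinery
# ---------------------------------------------------------------------------

def _grm_probs(
    a: np.ndarray, D: np.ndarray, theta: np.ndarray, d_scale: float = 1.0
) -> np.ndarray:
    """Category probabilities (I, Q, K) for cumulative thresholds D (inf-padded)."""
    z = d_scale * a[:, None, None] * (theta[None, :, None] - D[:, None, :])
    z = np.where(np.isfinite(z), z, -np.inf)
    pstar = expit(z)
    I, Q, m = pstar.shape
    pad = np.concatenate(
        [np.ones((I, Q, 1)), pstar, np.zeros((I, Q, 1))], axis=2
    )
    P = -np.diff(pad, axis=2)
    return np.clip(P, _PROB_FLOOR, None)


def grm_category_probs(fit: GRMFit, theta: np.ndarray) -> np.ndarray:
    """Category probabilities (I, len(theta), K) at arbitrary trait values."""
    return _grm_probs(fit.a, fit.thresholds, np.asarray(theta, float), fit.d_scale)


class _GRMModel:
    """Parameter packing and expected complete-data objective for one variant."""

    def __init__(
        self,
        I: int,
        m: int,
        equal_a: bool,
        common_t: bool,
        thr_mask: np.ndarray,
        d_scale: float = 1.0,
    ):
        self.I, self.m = I, m
        self.equal_a, self.common_t = equal_a, common_t
        self.thr_mask = thr_mask  # (I, m) valid-threshold mask
        self.d_scale = d_scale
        self.n_a = 1 if equal_a else I

    def pack(self, a: np.ndarray, D: np.ndarray) -> np.ndarray:
        alpha = np.log(a[:1] if self.equal_a else a)
        if self.common_t:
            b = D.mean(axis=1)
            t = (D - b[:, None]).mean(axis=0)
            gaps = np.maximum(np.diff(t), 1e-3)
            return np.concatenate([alpha, b, np.log(gaps)])
        parts = [alpha]
        for i in range(self.I):
            d = D[i, self.thr_mask[i]]
            parts.append(d[:1])
            if d.size > 1:
                parts.append(np.log(np.maximum(np.diff(d), 1e-3)))
        return np.concatenate(parts)

    def unpack(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = np.exp(params[: self.n_a])
        if self.equal_a:
            a = np.repeat(a, self.I)
        if self.common_t:
            b = params[self.n_a : self.n_a + self.I]
            gaps = np.exp(params[self.n_a + self.I :])
            c = np.concatenate([[0.0], np.cumsum(gaps)])
            t = c - c.mean()
            D = b[:, None] + t[None, :]
        else:
            D = np.full((self.I, self.m), np.inf)
            pos = self.n_a
            for i in range(self.I):
                mi = int(self.thr_mask[i].sum())
                d1 = params[pos]
                gaps = np.exp(params[pos + 1 : pos + mi])
                D[i, :mi] = d1 + np.concatenate([[0.0], np.cumsum(gaps)])
                pos += mi
        return a, D

    def common_t_values(self, params: np.ndarray) -> np.ndarray:
        gaps = np.exp(params[self.n_a + self.I :])
        c = np.concatenate([[0.0], np.cumsum(gaps)])
        return c - c.mean()

    def neg_q(self, params, Rcnt, theta):
        """Negative expected complete-data loglik and its gradient."""
        a, D = self.unpack(params)
        Dz = np.where(self.thr_mask, D, np.inf)
        z = self.d_scale * a[:, None, None] * (theta[None, :, None] - Dz[:, None, :])
        z = np.where(np.isfinite(z), z, -np.inf)
        pstar = expit(z)
        s = pstar * (1 - pstar)
        I, Q, m = pstar.shape
        pad = np.concatenate([np.ones((I, Q, 1)), pstar, np.zeros((I, Q, 1))], axis=2)
        P = np.clip(-np.diff(pad, axis=2), _PROB_FLOOR, None)
        qval = float((Rcnt * np.log(P)).sum())
        C = Rcnt / P
        G = s * (C[..., :-1] - C[..., 1:])  # (I, Q, m)
        G = G * self.thr_mask[:, None, :]
        dD = self.d_scale * a[:, None] * G.sum(axis=1)  # dQ/dD, (I, m)
        diff = np.where(self.thr_mask[:, None, :], theta[None, :, None] - Dz[:, None, :], 0.0)
        da = -self.d_scale * (diff * G).sum(axis=(1, 2))  # dQ/da, (I,)

        grad = np.empty_like(params)
        if self.equal_a:
            grad[0] = float(a[0] * da.sum())
        else:
            grad[: self.I] = a * da
        if self.common_t:
            grad[self.n_a : self.n_a + self.I] = dD.sum(axis=1)
            dt = dD.sum(axis=0)  # (m,)
            gaps = np.exp(params[self.n_a + self.I :])
            for j in range(m - 1):
                grad[self.n_a + self.I + j] = gaps[j] * (
                    dt[j + 1 :].sum() - dt.sum() * (m - (j + 1)) / m
                )
        else:
            pos = self.n_a
            for i in range(self.I):
                mi = int(self.thr_mask[i].sum())
                grad[pos] = dD[i, :mi].sum()
                d = D[i, :mi]
                gaps = np.diff(d)
                for j in range(mi - 1):
                    grad[pos + 1 + j] = gaps[j] * dD[i, j + 1 : mi].sum()
                pos += mi
        return -qval, -grad


def _person_node_loglik(
    logP: np.ndarray, X: np.ndarray, obs: np.ndarray
) -> np.ndarray:
    """A[p, q] = sum of observed-item log category probabilities at node q."""
    n = X.shape[0]
    Q = logP.shape[1]
    A = np.zeros((n, Q))
    for i in range(X.shape[1]):
        A += logP[i][:, X[:, i]].T * obs[:, i][:, None]
    return A


def _e_step(
    logP: np.ndarray, X: np.ndarray, obs: np.ndarray, logw: np.ndarray
) -> tuple[float, np.ndarray]:
    A = _person_node_loglik(logP, X, obs) + logw[None, :]
    ll = float(logsumexp(A, axis=1).sum())
    post = np.exp(A - logsumexp(A, axis=1, keepdims=True))
    return ll, post


def _expected_counts(
    post: np.ndarray, X: np.ndarray, obs: np.ndarray, K: int
) -> np.ndarray:
    """Rcnt[i, q, k] = expected number of persons at node q answering k to item i."""
    I = X.shape[1]
    Q = post.shape[1]
    Rcnt = np.zeros((I, Q, K))
    for i in range(I):
        sel = obs[:, i]
        onehot = np.eye(K)[X[sel, i]]
        Rcnt[i] = post[sel].T @ onehot
    return Rcnt


def _init_thresholds(X: np.ndarray, obs: np.ndarray, K_i: np.ndarray) -> np.ndarray:
    """Starting cumulative-step locations from observed cumulative proportions."""
    I = X.shape[1]
    m = int(K_i.max() - 1)
    D = np.full((I, m), np.inf)
    for i in range(I):
        xi = X[obs[:, i], i]
        n = xi.size
        for k in range(1, K_i[i]):
            p = np.clip((xi >= k).mean(), 0.5 / n, 1 - 0.5 / n)
            D[i, k - 1] = -np.log(p / (1 - p))
        d = D[i, : K_i[i] - 1]
        gaps = np.maximum(np.diff(d), 0.05)
        D[i, : K_i[i] - 1] = d[0] + np.concatenate([[0.0], np.cumsum(gaps)])
    return D


def fit_grm(
    R: ResponseMatrix,
    thresholds: str = "common",
    discrimination: str = "free",
    n_quadrature: int = 41,
    tol: float = 1e-5,
    max_iter: int = 500,
    compute_se: bool = True,
    d_scale: float = 1.0,
) -> GRMFit:
    """Fit a graded response model by MML-EM.

    Parameters
    ----------
    thresholds
        ``"common"`` (shared sum-zero thresholds; requires equal category
        counts) or ``"free"`` (item-specific ordered thresholds; empty
        categories are compressed away per item, logged in ``notes``).
    discrimination
        ``"free"`` (item-specific slopes) or ``"equal"`` (one shared slope,
        the 2PL analogue of a rating-scale Rasch structure).
    """
    if thresholds not in ("common", "free") or discrimination not in ("equal", "free"):
        raise ValueError("thresholds must be common|free, discrimination equal|free")
    X, obs, used = _prepare(R)
    if X.shape[0] < 3:
        raise PreconditionError("need at least 3 persons with observations")
    notes: list[str] = []
    n_cat = R.n_categories.copy()
    recode_maps: dict[int, np.ndarray] = {}

    for j in range(R.n_items):
        if np.unique(X[obs[:, j], j]).size < 2:
            raise DegenerateItemError(f"item {R.item_ids[j]!r} has zero variance")

    if thresholds == "common":
        if np.unique(n_cat).size != 1:
            raise PreconditionError(
                "common thresholds require equal category counts; merge categories first"
            )
        # drop a globally empty top category (no item uses it)
        while n_cat[0] > 2 and not np.any((X == n_cat[0] - 1) & obs):
            n_cat = n_cat - 1
            notes.append(f"top category {n_cat[0]} empty in every item; dropped globally")
    else:
        # compress each item's empty categories, remembering the recode
        X = X.copy()
        for j in range(R.n_items):
            xi = X[obs[:, j], j]
            present = np.unique(xi)
            if present.size < n_cat[j]:
                recode_maps[j] = np.searchsorted(
                    present, np.arange(n_cat[j]).clip(max=int(present.max()))
                )
                X[obs[:, j], j] = np.searchsorted(present, xi)
                n_cat[j] = present.size
                notes.append(
                    f"item {R.item_ids[j]!r}: empty categories dropped "
                    f"({len(present)} remain)"
                )

    I = X.shape[1]
    K = int(n_cat.max())
    m = K - 1
    thr_mask = np.arange(m)[None, :] < (n_cat[:, None] - 1)
    model = _GRMModel(
        I, m, equal_a=(discrimination == "equal"), common_t=(thresholds == "common"),
        thr_mask=thr_mask, d_scale=d_scale,
    )
    theta, w = _gauss_hermite(n_quadrature)
    logw = np.log(w)

    D0 = _init_thresholds(X, obs, n_cat)
    params = model.pack(np.ones(I), D0)

    ll_prev = -np.inf
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        a, D = model.unpack(params)
        logP = np.log(_grm_probs(a, D, theta, d_scale))
        ll, post = _e_step(logP, X, obs, logw)
        history.append(ll)
        if ll - ll_prev < tol and ll >= ll_prev - 1e-8:
            converged = True
            break
        ll_prev = ll
        Rcnt = _expected_counts(post, X, obs, K)
        res = optimize.minimize(
            model.neg_q, params, args=(Rcnt, theta), jac=True,
            method="L-BFGS-B", options={"maxiter": 40},
        )
        params = res.x

    a, D = model.unpack(params)
    tag = f"{'equal' if discrimination == 'equal' else 'free'}_a:" \
          f"{'common' if thresholds == 'common' else 'free'}_t"
    t = model.common_t_values(params) if thresholds == "common" else None
    if thresholds == "common":
        b = params[model.n_a : model.n_a + I].copy()
    else:
        b = np.array([D[i, thr_mask[i]].mean() for i in range(I)])
    heywood = bool(np.any(a > 20))
    if heywood:
        notes.append("Heywood-type discrimination (a > 20); fit flagged")

    fit = GRMFit(
        a=a, b=b, thresholds=np.where(thr_mask, D, np.inf), t=t,
        model_tag=tag, loglik=history[-1], converged=converged and not heywood,
        n_quadrature=n_quadrature, item_ids=list(R.item_ids),
        n_categories=n_cat, d_scale=d_scale, ll_history=history,
        notes=notes, heywood=heywood, n_persons_used=X.shape[0],
        recode_maps=recode_maps,
    )
    if compute_se:
        _grm_standard_errors(fit, model, X, obs, theta, logw)
    return fit


def _grm_standard_errors(fit, model, X, obs, theta, logw, step: float = 1e-4):
    """Finite-difference observed information in natural coordinates.

    Coordinates: discriminations (1 or I), then item locations b (common
    variant, with thresholds t_1..t_{m-1} free and t_m = -sum), or the full
    threshold matrix (free variant). Near-singular information is handled by
    pseudo-inverse and noted on the fit.
    """
    I, m = model.I, model.m
    thr_mask = model.thr_mask

    if model.common_t:
        t_full = fit.t

        def build(v):
            a = v[: model.n_a]
            a = np.repeat(a, I) if model.equal_a else a
            b = v[model.n_a : model.n_a + I]
            tf = v[model.n_a + I :]
            t = np.concatenate([tf, [-tf.sum()]])
            return a, b[:, None] + t[None, :]

        x0 = np.concatenate([
            fit.a[:1] if model.equal_a else fit.a, fit.b, t_full[:-1],
        ])
    else:

        def build(v):
            a = v[: model.n_a]
            a = np.repeat(a, I) if model.equal_a else a
            D = np.full((I, m), np.inf)
            D[thr_mask] = v[model.n_a :]
            return a, D

        x0 = np.concatenate([
            fit.a[:1] if model.equal_a else fit.a, fit.thresholds[thr_mask],
        ])

    def negll(v):
        a, D = build(v)
        logP = np.log(_grm_probs(a, D, theta, model.d_scale))
        ll, _ = _e_step(logP, X, obs, logw)
        return -ll

    p = x0.size
    H = np.empty((p, p))
    f0 = negll(x0)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step
        H[i, i] = (negll(x0 + 2 * ei) - 2 * f0 + negll(x0 - 2 * ei)) / (4 * step**2)
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = step
            H[i, j] = H[j, i] = (
                negll(x0 + ei + ej) - negll(x0 + ei - ej)
                - negll(x0 - ei + ej) + negll(x0 - ei - ej)
            ) / (4 * step**2)

    eigmin = float(np.linalg.eigvalsh(H).min())
    if eigmin <= 1e-10:
        fit.notes.append("observed information near-singular; SEs from pseudo-inverse")
    cov = np.linalg.pinv(H)
    var = np.clip(np.diag(cov), 0.0, None)
    se = np.sqrt(var)
    if model.equal_a:
        fit.se_a = np.repeat(se[0], I)
    else:
        fit.se_a = se[:I]
    if model.common_t:
        fit.se_b = se[model.n_a : model.n_a + I]
    else:
        se_b = np.empty(I)
        pos = model.n_a
        for i in range(I):
            mi = int(thr_mask[i].sum())
            block = cov[pos : pos + mi, pos : pos + mi]
            se_b[i] = np.sqrt(max(block.sum(), 0.0)) / mi
            pos += mi
        fit.se_b = se_b


# ---------------------------------------------------------------------------
# Rating scale model
# ---------------------------------------------------------------------------

def _rsm_logprobs(
    beta: np.ndarray, tau: np.ndarray, sigma: float, z: np.ndarray
) -> np.ndarray:
    """Log category probabilities (I, Q, K) of the adjacent-category RSM."""
    K = tau.size + 1
    theta = sigma * z
    k = np.arange(K)
    Tk = np.concatenate([[0.0], np.cumsum(tau)])
    u = (
        k[None, None, :] * theta[None, :, None]
        - k[None, None, :] * beta[:, None, None]
        - Tk[None, None, :]
    )
    return u - logsumexp(u, axis=2, keepdims=True)


def _rsm_neg_q(params, Rcnt, z, I, K):
    beta = params[:I]
    tau_free = params[I : I + K - 2]
    tau = np.concatenate([tau_free, [-tau_free.sum()]])
    sigma = np.exp(params[-1])
    logP = _rsm_logprobs(beta, tau, sigma, z)
    P = np.exp(logP)
    qval = float((Rcnt * logP).sum())

    k = np.arange(K)
    N = Rcnt.sum(axis=2)  # (I, Q)
    kR = (Rcnt * k[None, None, :]).sum(axis=2)  # (I, Q)
    Ebar = (P * k[None, None, :]).sum(axis=2)  # (I, Q)

    dbeta = (-kR + N * Ebar).sum(axis=1)
    # cumulative tails: P(K >= l) and sum_{k >= l} R
    tailR = np.flip(np.cumsum(np.flip(Rcnt, axis=2), axis=2), axis=2)
    tailP = np.flip(np.cumsum(np.flip(P, axis=2), axis=2), axis=2)
    dtau_full = np.array([
        (-tailR[..., l] + N * tailP[..., l]).sum() for l in range(1, K)
    ])
    dtau = dtau_full[:-1] - dtau_full[-1]
    dsig = float((z[None, :] * (kR - N * Ebar)).sum()) * sigma

    grad = np.concatenate([dbeta, dtau, [dsig]])
    return -qval, -grad


def fit_rsm(
    R: ResponseMatrix,
    n_quadrature: int = 41,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> RSMFit:
    """Fit the Rasch rating scale model by MML-EM.

    All items must share a common category count (merge first if not). The
    latent trait is normal with mean 0 and a freely estimated SD; the slope
    is fixed at 1 so "equal discrimination" is interpretable against the GRM.
    """
    if np.unique(R.n_categories).size != 1:
        raise PreconditionError(
            "rating scale model requires equal category counts across items"
        )
    X, obs, used = _prepare(R)
    if X.shape[0] < 3:
        raise PreconditionError("need at least 3 persons with observations")
    I = X.shape[1]
    K = int(R.n_categories[0])
    z, w = _gauss_hermite(n_quadrature)
    logw = np.log(w)

    means = np.array([X[obs[:, i], i].mean() for i in range(I)])
    params = np.concatenate([(K - 1) / 2 - means, np.zeros(K - 2), [0.0]])

    ll_prev = -np.inf
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        beta = params[:I]
        tau_free = params[I : I + K - 2]
        tau = np.concatenate([tau_free, [-tau_free.sum()]])
        sigma = np.exp(params[-1])
        logP = _rsm_logprobs(beta, tau, sigma, z)
        ll, post = _e_step(logP, X, obs, logw)
        history.append(ll)
        if ll - ll_prev < tol and ll >= ll_prev - 1e-8:
            converged = True
            break
        ll_prev = ll
        Rcnt = _expected_counts(post, X, obs, K)
        res = optimize.minimize(
            _rsm_neg_q, params, args=(Rcnt, z, I, K), jac=True,
            method="L-BFGS-B", options={"maxiter": 40},
        )
        params = res.x

    tau_free = params[I : I + K - 2]
    return RSMFit(
        beta=params[:I].copy(),
        tau=np.concatenate([tau_free, [-tau_free.sum()]]),
        latent_sd=float(np.exp(params[-1])),
        loglik=history[-1],
        converged=converged,
        n_quadrature=n_quadrature,
        item_ids=list(R.item_ids),
        n_categories=K,
        ll_history=history,
        n_persons_used=X.shape[0],
    )


# ---------------------------------------------------------------------------
# Model comparison, scoring, information
# ---------------------------------------------------------------------------

def lr_test_equal_discrimination(
    fit_constrained: GRMFit, fit_free: GRMFit, tol: float = 1e-3
) -> LRTestResult:
    """Likelihood-ratio test of equal item discriminations.

    ``fit_constrained`` (shared slope) is nested in ``fit_free``
    (item-specific slopes) on the same data; df = I - 1.
    """
    if not fit_constrained.model_tag.startswith("equal_a"):
        raise PreconditionError("constrained fit must have equal discriminations")
    if not fit_free.model_tag.startswith("free_a"):
        raise PreconditionError("free fit must have item-specific discriminations")
    stat = 2.0 * (fit_free.loglik - fit_constrained.loglik)
    if stat < -tol:
        raise OptimizationError(
            f"free model loglik below constrained by {-stat / 2:.4g}; optimisation failed"
        )
    stat = max(stat, 0.0)
    df = len(fit_free.item_ids) - 1
    return LRTestResult(statistic=float(stat), df=df, p=float(stats.chi2.sf(stat, df)))


def _fit_logprob_table(fit: RSMFit | GRMFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(theta grid, prior weights, logP (I, Q, K)) for EAP scoring."""
    n_quad = fit.n_quadrature or 41
    z, w = _gauss_hermite(n_quad)
    if isinstance(fit, RSMFit):
        return fit.latent_sd * z, w, _rsm_logprobs(fit.beta, fit.tau, fit.latent_sd, z)
    logP = np.log(_grm_probs(fit.a, fit.thresholds, z, fit.d_scale))
    return z, w, logP


def score_persons(
    fit: RSMFit | GRMFit, R: ResponseMatrix, recenter: bool = False
) -> PersonScores:
    """EAP person estimates (posterior mean and SD) over the quadrature grid.

    Only observed items enter each person's likelihood; persons with no
    observed items are excluded. With ``recenter=True`` the mean estimate is
    subtracted from every theta and from the fit's item locations jointly,
    reported as ``corrected_item_locations``.
    """
    obs = ~R.missing_mask
    theta_grid, w, logP = _fit_logprob_table(fit)
    X = R.values.clip(min=0)
    if isinstance(fit, GRMFit) and fit.recode_maps:
        X = X.copy()
        for j, mapping in fit.recode_maps.items():
            X[obs[:, j], j] = mapping[X[obs[:, j], j]]
    A = _person_node_loglik(logP, X, obs) + np.log(w)[None, :]
    scored = obs.any(axis=1)
    post = np.exp(A - logsumexp(A, axis=1, keepdims=True))
    mean = post @ theta_grid
    var = post @ theta_grid**2 - mean**2
    theta = np.where(scored, mean, np.nan)
    se = np.where(scored, np.sqrt(np.clip(var, 1e-12, None)), np.nan)

    corrected = None
    if recenter:
        shift = float(np.nanmean(theta[scored]))
        theta = theta - shift
        locations = fit.beta if isinstance(fit, RSMFit) else fit.b
        corrected = locations - shift
    return PersonScores(
        theta=theta,
        se=se,
        scored=scored,
        recentered=recenter,
        corrected_item_locations=corrected,
        excluded=np.where(~scored)[0].tolist(),
    )


def item_information(
    fit: GRMFit, grid: tuple[float, float, float] = (-4.0, 4.0, 0.05)
) -> InformationGrid:
    """Samejima graded-model item information functions on a theta grid.

    ``I_i(theta) = a_i^2 sum_k (w_ik - w_{i,k+1})^2 / P_ik`` with
    ``w_ik = P*_ik (1 - P*_ik)`` for the cumulative probabilities
    (``P*_0 = 1``, ``P*_{m+1} = 0``); the total is the pointwise sum.
    """
    lo, hi, step = grid
    theta = np.arange(lo, hi + step / 2, step)
    z = fit.d_scale * fit.a[:, None, None] * (theta[None, :, None] - fit.thresholds[:, None, :])
    z = np.where(np.isfinite(z), z, -np.inf)
    pstar = expit(z)
    I_, G, m = pstar.shape
    wstar = pstar * (1 - pstar)
    wpad = np.concatenate([np.zeros((I_, G, 1)), wstar, np.zeros((I_, G, 1))], axis=2)
    ppad = np.concatenate([np.ones((I_, G, 1)), pstar, np.zeros((I_, G, 1))], axis=2)
    P = -np.diff(ppad, axis=2)
    underflow = bool(np.any(P < _PROB_FLOOR))
    P = np.clip(P, _PROB_FLOOR, None)
    info = (fit.d_scale * fit.a[:, None]) ** 2 * (
        (-np.diff(wpad, axis=2)) ** 2 / P
    ).sum(axis=2)
    return InformationGrid(
        theta=theta,
        item_info=info,
        total_info=info.sum(axis=0),
        item_ids=list(fit.item_ids),
        underflow=underflow,
    )


def relative_information(info: InformationGrid) -> InformationGrid:
    """Per-item share (%) of the integrated information, with display buckets.

    The share is the trapezoidal integral of ``I_i`` over the grid divided by
    the integral of the total, times 100. Display buckets round to the
    nearest 5 with a ``"<5"`` floor (the raw share is always retained).
    """
    areas = np.trapezoid(info.item_info, info.theta, axis=1)
    total = float(np.trapezoid(info.total_info, info.theta))
    if total <= 0:
        raise DegenerateItemError("total information is zero over the grid")
    share = 100.0 * areas / total
    buckets = [
        "<5" if s < 5 else str(int(5 * round(s / 5))) for s in share
    ]
    info.relative_share = share
    info.display_bucket = buckets
    return info
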