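"""Latent class analysis for binary indicators.

The model is a finite mixture of K multivariate Bernoulli components with
conditional independence of the J items given class membership:

    P(y_i) = sum_c  pi_c * prod_j  rho_cj^{y_ij} * (1 - rho_cj)^{1 - y_ij}

``pi`` is the vector of class prevalences and ``rho`` the K x J matrix of
item-response probabilities.  Fitting is by multi-start EM; model fit is
summarized by the deviance G^2 against the saturated model over observed
response patterns, the information criteria AIC / BIC / CAIC / SABIC
derived from it, and the relative-entropy classification statistic.

All latent-class indices are 0-based (classes are reported as LC0, LC1, ...,
with LC0 the most prevalent class after canonical reordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .containers import IndicatorMatrix
from .errors import DegenerateClassError, FitError, ValidationError

#: Item-response probabilities are clamped to [EPS, 1 - EPS] to keep the
#: log-likelihood finite at the boundary.
EPS = 1e-6

#: Posterior mass below which a class is treated as degenerate in the M-step.
MIN_CLASS_MASS = 1e-8


@dataclass(frozen=True)
class LCAParams:
    """Parameters of a K-class binary-indicator latent class model."""

    class_prevalence: np.ndarray  # (K,)
    item_response: np.ndarray  # (K, J), clamped to [EPS, 1-EPS]

    def __post_init__(self) -> None:
        pi = np.asarray(self.class_prevalence, dtype=float)
        rho = np.asarray(self.item_response, dtype=float)
        if pi.ndim != 1:
            raise ValidationError("class_prevalence must be a vector")
        if rho.ndim != 2 or rho.shape[0] != pi.shape[0]:
            raise ValidationError(
                f"item_response must be K x J with K={pi.shape[0]} rows, got {rho.shape}"
            )
        if (pi < 0).any() or (pi > 1).any():
            raise ValidationError("class_prevalence entries must lie in [0, 1]")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValidationError(
                f"class_prevalence must sum to 1 (got {pi.sum():.12f})"
            )
        if (rho < 0).any() or (rho > 1).any():
            raise ValidationError("item_response entries must lie in [0, 1]")
        object.__setattr__(self, "class_prevalence", pi)
        object.__setattr__(self, "item_response", np.clip(rho, EPS, 1.0 - EPS))

    @property
    def n_classes(self) -> int:
        return int(self.class_prevalence.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.item_response.shape[1])

    def permuted(self, order: np.ndarray) -> "LCAParams":
        """Return a copy with classes reordered by ``order``."""
        order = np.asarray(order)
        return LCAParams(self.class_prevalence[order], self.item_response[order])


@dataclass(frozen=True)
class LCAFit:
    """A fitted latent class model plus its fit statistics."""

    params: LCAParams
    posteriors: np.ndarray  # (N, K), rows sum to 1
    log_likelihood: float
    g_squared: float
    n_params: int
    aic: float
    bic: float
    caic: float
    sabic: float
    entropy: float  # relative entropy in [0, 1]; NaN when K = 1
    converged: bool
    n_iter: int
    n_starts_used: int
    best_start_seed: int
    modal_classes: np.ndarray = field(repr=False, default=None)

    @property
    def n_classes(self) -> int:
        return self.params.n_classes


def count_params(n_classes: int, n_items: int) -> int:
    """Free parameters of a K-class, J-item model: K*J + (K - 1)."""
    if n_classes < 1 or n_items < 1:
        raise ValidationError("n_classes and n_items must be >= 1")
    return n_classes * n_items + (n_classes - 1)


def _check_items(params: LCAParams, data: IndicatorMatrix) -> None:
    if params.n_items != data.n_items:
        raise ValidationError(
            f"item axis mismatch: params have J={params.n_items}, "
            f"data has J={data.n_items}"
        )


def _log_components(params: LCAParams, values: np.ndarray) -> np.ndarray:
    """(N, K) matrix of log f_c(y_i) under conditional independence."""
    rho = params.item_response
    y = np.asarray(values, dtype=float)
    return y @ np.log(rho).T + (1.0 - y) @ np.log1p(-rho).T


def log_likelihood(params: LCAParams, data: IndicatorMatrix) -> float:
    """Observed-data log-likelihood, computed by log-sum-exp over classes."""
    _check_items(params, data)
    lj = _log_components(params, data.values) + np.log(params.class_prevalence)
    return float(logsumexp(lj, axis=1).sum())


def e_step(params: LCAParams, data: IndicatorMatrix) -> np.ndarray:
    """Posterior class-membership probabilities p_ic (N x K, rows sum to 1)."""
    _check_items(params, data)
    lj = _log_components(params, data.values) + np.log(params.class_prevalence)
    return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))


def m_step(posteriors: np.ndarray, data: IndicatorMatrix) -> LCAParams:
    """Closed-form maximizer of the expected complete-data log-likelihood.

    pi_c  = mean_i p_ic
    rho_cj = sum_i p_ic y_ij / sum_i p_ic
    """
    post = np.asarray(posteriors, dtype=float)
    if post.shape[0] != data.n_subjects:
        raise ValidationError("posteriors and data disagree on the subject axis")
    mass = post.sum(axis=0)
    if (mass < MIN_CLASS_MASS).any():
        empty = np.flatnonzero(mass < MIN_CLASS_MASS).tolist()
        raise DegenerateClassError(
            f"class(es) {empty} carry total posterior mass < {MIN_CLASS_MASS:g}"
        )
    pi = mass / post.shape[0]
    pi = pi / pi.sum()
    rho = (post.T @ data.values) / mass[:, None]
    return LCAParams(pi, rho)


def _run_em(
    params: LCAParams,
    data: IndicatorMatrix,
    tol: float,
    max_iter: int,
) -> tuple[LCAParams, float, bool, int]:
    """Iterate EM to convergence; enforce monotone log-likelihood."""
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lj = _log_components(params, data.values) + np.log(params.class_prevalence)
        row_ll = logsumexp(lj, axis=1)
        ll = float(row_ll.sum())
        if ll < ll_old - 1e-9 * (1.0 + abs(ll_old)):
            raise FitError(
                f"EM log-likelihood decreased ({ll_old:.10g} -> {ll:.10g})"
            )
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
        post = np.exp(lj - row_ll[:, None])
        params = m_step(post, data)
    ll = log_likelihood(params, data)
    return params, ll, converged, n_iter


def _random_start(
    rng: np.random.Generator, n_classes: int, n_items: int
) -> LCAParams:
    """rho ~ U(0.2, 0.8), pi ~ Dirichlet(5): mild starts away from boundaries."""
    pi = rng.dirichlet(np.full(n_classes, 5.0))
    rho = rng.uniform(0.2, 0.8, size=(n_classes, n_items))
    return LCAParams(pi, rho)


def canonical_order(class_prevalence: np.ndarray) -> np.ndarray:
    """Class permutation sorting prevalences in descending order (stable)."""
    return np.argsort(-np.asarray(class_prevalence), kind="stable")


def fit_lca(
    data: IndicatorMatrix,
    n_classes: int,
    *,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> LCAFit:
    """Fit a K-class model by the best of ``n_starts`` random EM starts.

    Classes are reordered canonically (descending prevalence) before the fit
    is returned, so the most prevalent class is always class 0.  The same
    ``seed`` and data yield an identical fit.
    """
    if n_classes < 1:
        raise ValidationError("n_classes must be >= 1")
    if data.n_subjects <= n_classes:
        raise ValidationError(
            f"need more subjects ({data.n_subjects}) than classes ({n_classes})"
        )
    best: tuple[float, LCAParams, bool, int, int] | None = None
    n_used = 0
    for start in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), start]))
        init = _random_start(rng, n_classes, data.n_items)
        try:
            params, ll, converged, n_iter = _run_em(init, data, tol, max_iter)
        except DegenerateClassError:
            continue
        n_used += 1
        if best is None or ll > best[0]:
            best = (ll, params, converged, n_iter, start)
        if n_classes == 1:
            break  # the one-class MLE is exact; further starts are identical
    if best is None:
        raise FitError(
            f"all {n_starts} EM starts degenerated for K={n_classes}; "
            "increase n_starts or reduce the number of classes"
        )
    ll, params, converged, n_iter, best_seed = best
    params = params.permuted(canonical_order(params.class_prevalence))
    post = e_step(params, data)
    g2 = deviance_g2(params, data)
    p = count_params(n_classes, data.n_items)
    aic, bic, caic, sabic = information_criteria(g2, p, data.n_subjects)
    return LCAFit(
        params=params,
        posteriors=post,
        log_likelihood=ll,
        g_squared=g2,
        n_params=p,
        aic=aic,
        bic=bic,
        caic=caic,
        sabic=sabic,
        entropy=relative_entropy(post),
        converged=converged,
        n_iter=n_iter,
        n_starts_used=n_used,
        best_start_seed=best_seed,
        modal_classes=modal_assign(post),
    )


def deviance_g2(fit_or_params: LCAFit | LCAParams, data: IndicatorMatrix) -> float:
    """Deviance G^2 against the saturated model over observed patterns.

    G^2 = 2 * sum_s n_s * ln( n_s / (N * Phat(s)) ), the sum running over the
    distinct observed response patterns only (the full 2^J table is never
    enumerated).
    """
    params = getattr(fit_or_params, "params", fit_or_params)
    _check_items(params, data)
    patterns, counts = np.unique(data.values, axis=0, return_counts=True)
    lj = _log_components(params, patterns) + np.log(params.class_prevalence)
    log_phat = logsumexp(lj, axis=1)
    n = data.n_subjects
    return float(2.0 * np.sum(counts * (np.log(counts / n) - log_phat)))


def information_criteria(
    g_squared: float, n_params: int, n_subjects: int
) -> tuple[float, float, float, float]:
    """G^2-based AIC, BIC, CAIC and sample-size-adjusted BIC.

    AIC   = G^2 + 2p
    BIC   = G^2 + ln(N) p
    CAIC  = G^2 + (ln(N) + 1) p      (so CAIC - BIC = p exactly)
    SABIC = G^2 + ln((N + 2) / 24) p

    N is the number of analyzed rows.
    """
    if n_params < 1 or n_subjects < 2:
        raise ValidationError("need n_params >= 1 and n_subjects >= 2")
    p = float(n_params)
    aic = g_squared + 2.0 * p
    bic = g_squared + np.log(n_subjects) * p
    caic = bic + p
    sabic = g_squared + np.log((n_subjects + 2.0) / 24.0) * p
    return float(aic), float(bic), float(caic), float(sabic)


def relative_entropy(posteriors: np.ndarray) -> float:
    """Normalized classification certainty, 1 - sum(-p ln p) / (N ln K).

    1 means perfectly separated (degenerate) posteriors, 0 means uniform
    posteriors.  Undefined for a one-class model: returns NaN.
    """
    post = np.asarray(posteriors, dtype=float)
    n, k = post.shape
    if k == 1:
        return float("nan")
    plogp = np.where(post > 0, post * np.log(np.where(post > 0, post, 1.0)), 0.0)
    ent = -plogp.sum()
    return float(np.clip(1.0 - ent / (n * np.log(k)), 0.0, 1.0))


def modal_assign(posteriors: np.ndarray) -> np.ndarray:
    """Per-subject class with the highest posterior probability.

    Ties are broken deterministically toward the lowest class index.
    """
    return np.argmax(np.asarray(posteriors), axis=1)
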