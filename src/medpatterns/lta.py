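"""Latent transition analysis for two-phase binary panels.

The model extends the cross-sectional latent class model with a first-order
Markov structure across two study phases:

    P(y1_i, y2_i) = sum_{c1} sum_{c2} delta_{c1} tau_{c1 c2}
                      f_{c1}(y1_i; rho1) f_{c2}(y2_i; rho2)

``delta`` is the phase-1 class distribution, ``tau`` the K x K row-stochastic
transition matrix, and ``rho1`` / ``rho2`` the phase-specific item-response
probabilities.  Under longitudinal measurement invariance the two rho
matrices are constrained equal; the constrained and free models are compared
with a likelihood-ratio test on K*J degrees of freedom.

Fitting is by EM over the K^2 joint class states, initialized from the two
phase-wise LCA fits (classes matched across phases by minimal mean absolute
difference of item-response profiles) plus random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import chi2

from . import lca
from .containers import IndicatorMatrix
from .errors import (
    AlignmentError,
    DegenerateClassError,
    FitError,
    ValidationError,
)
from .lca import EPS, MIN_CLASS_MASS, LCAParams


@dataclass(frozen=True)
class LTAParams:
    """Parameters of a two-phase, K-class latent transition model."""

    initial_prevalence: np.ndarray  # delta, (K,)
    transition_matrix: np.ndarray  # tau, (K, K) row-stochastic
    item_response_p1: np.ndarray  # rho1, (K, J)
    item_response_p2: np.ndarray  # rho2, (K, J)
    invariant: bool = False

    def __post_init__(self) -> None:
        delta = np.asarray(self.initial_prevalence, dtype=float)
        tau = np.asarray(self.transition_matrix, dtype=float)
        rho1 = np.asarray(self.item_response_p1, dtype=float)
        rho2 = np.asarray(self.item_response_p2, dtype=float)
        k = delta.shape[0]
        if delta.ndim != 1 or (delta < 0).any() or abs(delta.sum() - 1.0) > 1e-10:
            raise ValidationError("initial_prevalence must be a probability vector")
        if tau.shape != (k, k) or (tau < 0).any():
            raise ValidationError(f"transition_matrix must be {k} x {k} nonnegative")
        if np.abs(tau.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValidationError("transition_matrix rows must each sum to 1")
        if rho1.shape != rho2.shape or rho1.ndim != 2 or rho1.shape[0] != k:
            raise ValidationError(
                "item_response_p1/p2 must both be K x J matrices"
            )
        for name, rho in (("item_response_p1", rho1), ("item_response_p2", rho2)):
            if (rho < 0).any() or (rho > 1).any():
                raise ValidationError(f"{name} entries must lie in [0, 1]")
        rho1 = np.clip(rho1, EPS, 1.0 - EPS)
        rho2 = np.clip(rho2, EPS, 1.0 - EPS)
        if self.invariant:
            if not np.allclose(rho1, rho2, atol=1e-12):
                raise ValidationError(
                    "invariant=True requires item_response_p1 == item_response_p2"
                )
            rho2 = rho1
        object.__setattr__(self, "initial_prevalence", delta)
        object.__setattr__(self, "transition_matrix", tau)
        object.__setattr__(self, "item_response_p1", rho1)
        object.__setattr__(self, "item_response_p2", rho2)

    @property
    def n_classes(self) -> int:
        return int(self.initial_prevalence.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.item_response_p1.shape[1])

    def permuted(self, order: np.ndarray) -> "LTAParams":
        order = np.asarray(order)
        return LTAParams(
            self.initial_prevalence[order],
            self.transition_matrix[np.ix_(order, order)],
            self.item_response_p1[order],
            self.item_response_p2[order],
            invariant=self.invariant,
        )


@dataclass(frozen=True)
class LTAFit:
    """A fitted latent transition model."""

    params: LTAParams
    log_likelihood: float
    n_params: int
    posteriors_joint: np.ndarray  # (N, K, K): phase-1 class x phase-2 class
    converged: bool
    n_iter: int
    n_starts_used: int

    @property
    def n_classes(self) -> int:
        return self.params.n_classes


@dataclass(frozen=True)
class InvarianceResult:
    """Likelihood-ratio test of longitudinal measurement invariance."""

    g2_delta: float
    df_delta: int
    p_value: float


def count_lta_params(n_classes: int, n_items: int, invariant: bool) -> int:
    """(K-1) initial probabilities + K(K-1) transitions + (1 or 2) K*J rho's."""
    k, j = n_classes, n_items
    return (k - 1) + k * (k - 1) + (1 if invariant else 2) * k * j


def align_phases(
    data1: IndicatorMatrix, data2: IndicatorMatrix
) -> tuple[IndicatorMatrix, IndicatorMatrix]:
    """Return the two matrices with identical subject order.

    Raises :class:`AlignmentError` (listing offending identifiers) if the
    subject sets differ; reorders phase 2 if only the order differs.
    """
    ids1 = data1.subject_ids
    ids2 = data2.subject_ids
    if np.array_equal(ids1, ids2):
        return data1, data2
    set1, set2 = set(ids1.tolist()), set(ids2.tolist())
    if set1 != set2:
        only1 = sorted(set1 - set2)[:10]
        only2 = sorted(set2 - set1)[:10]
        raise AlignmentError(
            f"subject sets differ between phases; only in phase 1: {only1}, "
            f"only in phase 2: {only2}"
        )
    pos = {s: i for i, s in enumerate(ids2.tolist())}
    order = np.array([pos[s] for s in ids1.tolist()])
    return data1, IndicatorMatrix(
        ids2[order], data2.item_names, data2.values[order]
    )


def _log_joint(
    params: LTAParams, values1: np.ndarray, values2: np.ndarray
) -> np.ndarray:
    """(N, K, K) array of log delta_{c1} tau_{c1 c2} f_{c1}(y1) f_{c2}(y2)."""
    lf1 = lca._log_components(
        LCAParams(params.initial_prevalence, params.item_response_p1), values1
    )
    unif = np.full(params.n_classes, 1.0 / params.n_classes)
    lf2 = lca._log_components(LCAParams(unif, params.item_response_p2), values2)
    m = np.log(params.initial_prevalence)[:, None] + np.log(
        np.clip(params.transition_matrix, 1e-300, None)
    )
    return lf1[:, :, None] + lf2[:, None, :] + m[None, :, :]


def lta_log_likelihood(
    params: LTAParams, data1: IndicatorMatrix, data2: IndicatorMatrix
) -> float:
    """Observed-data log-likelihood, log-sum-exp over the K^2 joint states."""
    data1, data2 = align_phases(data1, data2)
    if params.n_items != data1.n_items or params.n_items != data2.n_items:
        raise ValidationError(
            f"item axis mismatch: params have J={params.n_items}, data have "
            f"J={data1.n_items} / J={data2.n_items}"
        )
    a = _log_joint(params, data1.values, data2.values)
    n = a.shape[0]
    return float(logsumexp(a.reshape(n, -1), axis=1).sum())


def _lta_m_step(
    r: np.ndarray,
    values1: np.ndarray,
    values2: np.ndarray,
    invariant: bool,
) -> LTAParams:
    """M-step from joint responsibilities r (N, K, K)."""
    n = r.shape[0]
    w1 = r.sum(axis=2)  # (N, K) phase-1 class weights
    w2 = r.sum(axis=1)  # (N, K) phase-2 class weights
    mass1 = w1.sum(axis=0)
    mass2 = w2.sum(axis=0)
    if (mass1 < MIN_CLASS_MASS).any() or (mass2 < MIN_CLASS_MASS).any():
        raise DegenerateClassError("a joint class margin lost all posterior mass")
    delta = mass1 / n
    delta = delta / delta.sum()
    tau = r.sum(axis=0) / mass1[:, None]
    tau = tau / tau.sum(axis=1, keepdims=True)
    if invariant:
        rho = (w1.T @ values1 + w2.T @ values2) / (mass1 + mass2)[:, None]
        rho1 = rho2 = rho
    else:
        rho1 = (w1.T @ values1) / mass1[:, None]
        rho2 = (w2.T @ values2) / mass2[:, None]
    return LTAParams(delta, tau, rho1, rho2, invariant=invariant)


def _run_lta_em(
    params: LTAParams,
    data1: IndicatorMatrix,
    data2: IndicatorMatrix,
    tol: float,
    max_iter: int,
) -> tuple[LTAParams, float, bool, int]:
    v1, v2 = data1.values, data2.values
    n = v1.shape[0]
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        a = _log_joint(params, v1, v2)
        row_ll = logsumexp(a.reshape(n, -1), axis=1)
        ll = float(row_ll.sum())
        if ll < ll_old - 1e-9 * (1.0 + abs(ll_old)):
            raise FitError(
                f"LTA EM log-likelihood decreased ({ll_old:.10g} -> {ll:.10g})"
            )
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
        r = np.exp(a - row_ll[:, None, None])
        params = _lta_m_step(r, v1, v2, params.invariant)
    ll = lta_log_likelihood(params, data1, data2)
    return params, ll, converged, n_iter


def match_classes(rho_ref: np.ndarray, rho_other: np.ndarray) -> np.ndarray:
    """Permutation aligning ``rho_other`` rows to ``rho_ref`` rows.

    Solves the K x K assignment problem on mean absolute profile difference,
    so ``rho_other[perm]`` is the best row-wise match to ``rho_ref``.
    """
    cost = np.abs(rho_ref[:, None, :] - rho_other[None, :, :]).mean(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(cols)
    perm[rows] = cols
    return perm


def _init_from_lca(
    data1: IndicatorMatrix,
    data2: IndicatorMatrix,
    n_classes: int,
    invariant: bool,
    seed: int,
    lca_starts: int,
) -> LTAParams:
    """Warm start: phase-wise LCA fits with cross-phase class matching."""
    fit1 = lca.fit_lca(data1, n_classes, n_starts=lca_starts, seed=seed, tol=1e-7)
    fit2 = lca.fit_lca(
        data2, n_classes, n_starts=lca_starts, seed=seed + 1, tol=1e-7
    )
    perm = match_classes(fit1.params.item_response, fit2.params.item_response)
    rho1 = fit1.params.item_response
    rho2 = fit2.params.item_response[perm]
    modal2 = perm.argsort()[fit2.modal_classes]  # relabel phase-2 classes
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (fit1.modal_classes, modal2), 1.0)
    tau = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    if invariant:
        rho1 = rho2 = 0.5 * (rho1 + rho2)
    return LTAParams(
        fit1.params.class_prevalence, tau, rho1, rho2, invariant=invariant
    )


def _random_lta_start(
    rng: np.random.Generator, n_classes: int, n_items: int, invariant: bool
) -> LTAParams:
    delta = rng.dirichlet(np.full(n_classes, 5.0))
    tau = rng.dirichlet(np.full(n_classes, 5.0), size=n_classes)
    rho1 = rng.uniform(0.2, 0.8, size=(n_classes, n_items))
    rho2 = rho1 if invariant else rng.uniform(0.2, 0.8, size=(n_classes, n_items))
    return LTAParams(delta, tau, rho1, rho2, invariant=invariant)


def fit_lta(
    data1: IndicatorMatrix,
    data2: IndicatorMatrix,
    n_classes: int,
    *,
    invariant: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    lca_starts: int = 10,
) -> LTAFit:
    """Fit the two-phase model; best of an LCA-warm start plus random restarts.

    Start 0 is built from the two cross-sectional LCA fits (classes matched
    across phases); the remaining ``n_starts - 1`` starts are random.
    Classes are canonically reordered by descending initial prevalence.
    """
    if n_classes < 1:
        raise ValidationError("n_classes must be >= 1")
    data1, data2 = align_phases(data1, data2)
    if data1.n_items != data2.n_items:
        raise ValidationError("the two phases must share the same items")
    best: tuple[float, LTAParams, bool, int] | None = None
    n_used = 0
    for start in range(max(n_starts, 1)):
        try:
            if start == 0:
                init = _init_from_lca(
                    data1, data2, n_classes, invariant, int(seed), lca_starts
                )
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), 1_000_000 + start])
                )
                init = _random_lta_start(rng, n_classes, data1.n_items, invariant)
            params, ll, converged, n_iter = _run_lta_em(
                init, data1, data2, tol, max_iter
            )
        except DegenerateClassError:
            continue
        n_used += 1
        if best is None or ll > best[0]:
            best = (ll, params, converged, n_iter)
    if best is None:
        raise FitError(
            f"all {n_starts} LTA starts degenerated for K={n_classes}; "
            "increase n_starts or reduce the number of classes"
        )
    ll, params, converged, n_iter = best
    params = params.permuted(lca.canonical_order(params.initial_prevalence))
    a = _log_joint(params, data1.values, data2.values)
    n = a.shape[0]
    row_ll = logsumexp(a.reshape(n, -1), axis=1)
    r = np.exp(a - row_ll[:, None, None])
    return LTAFit(
        params=params,
        log_likelihood=ll,
        n_params=count_lta_params(n_classes, data1.n_items, params.invariant),
        posteriors_joint=r,
        converged=converged,
        n_iter=n_iter,
        n_starts_used=n_used,
    )


def invariance_test(fit_free: LTAFit, fit_constrained: LTAFit) -> InvarianceResult:
    """Likelihood-ratio test of measurement invariance across phases.

    The constrained model (equal item-response probabilities in both phases)
    is nested in the free model; the test statistic
    ``2 * (ll_free - ll_constrained)`` is referred to a chi-square with
    ``K * J`` degrees of freedom.  ``delta`` and ``tau`` are free in both
    models.
    """
    if fit_free.params.invariant or not fit_constrained.params.invariant:
        raise ValidationError(
            "expected a free fit (invariant=False) and a constrained fit "
            "(invariant=True)"
        )
    if (
        fit_free.n_classes != fit_constrained.n_classes
        or fit_free.params.n_items != fit_constrained.params.n_items
    ):
        raise ValidationError("the two fits must share K and J")
    k, j = fit_free.n_classes, fit_free.params.n_items
    g2_delta = 2.0 * (fit_free.log_likelihood - fit_constrained.log_likelihood)
    if g2_delta < -1e-6 * (1.0 + abs(fit_free.log_likelihood)):
        raise FitError(
            "constrained log-likelihood exceeds the free log-likelihood beyond "
            "tolerance; one of the fits has not converged to its optimum"
        )
    g2_delta = max(g2_delta, 0.0)
    df = k * j
    return InvarianceResult(
        g2_delta=float(g2_delta),
        df_delta=df,
        p_value=float(chi2.sf(g2_delta, df)),
    )
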