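"""Brute-force enumeration oracles, independent of the package internals.

Everything here works in plain probability space with explicit Python loops
over classes and items, so it is only usable for tiny problems (J <= ~6,
N <= ~50) — which is the point: it provides reference values the vectorized
log-space implementation must reproduce.
"""

import math

import numpy as np


def pattern_prob(pi, rho, y):
    """P(y) = sum_c pi_c prod_j rho_cj^y_j (1-rho_cj)^(1-y_j)."""
    total = 0.0
    for c in range(len(pi)):
        p = pi[c]
        for j in range(len(y)):
            p *= rho[c][j] if y[j] == 1 else 1.0 - rho[c][j]
        total += p
    return total


def lca_loglik(pi, rho, Y):
    return sum(math.log(pattern_prob(pi, rho, y)) for y in Y)


def lca_posteriors(pi, rho, Y):
    out = []
    for y in Y:
        weights = []
        for c in range(len(pi)):
            p = pi[c]
            for j in range(len(y)):
                p *= rho[c][j] if y[j] == 1 else 1.0 - rho[c][j]
            weights.append(p)
        s = sum(weights)
        out.append([w / s for w in weights])
    return np.array(out)


def _component_prob(rho_row, y):
    p = 1.0
    for j in range(len(y)):
        p *= rho_row[j] if y[j] == 1 else 1.0 - rho_row[j]
    return p


def lta_loglik(delta, tau, rho1, rho2, Y1, Y2):
    """Joint two-phase log-likelihood by direct summation over K^2 states."""
    k = len(delta)
    ll = 0.0
    for y1, y2 in zip(Y1, Y2):
        total = 0.0
        for c1 in range(k):
            f1 = _component_prob(rho1[c1], y1)
            for c2 in range(k):
                total += delta[c1] * tau[c1][c2] * f1 * _component_prob(rho2[c2], y2)
        ll += math.log(total)
    return ll


def lta_joint_posteriors(delta, tau, rho1, rho2, Y1, Y2):
    k = len(delta)
    out = np.zeros((len(Y1), k, k))
    for i, (y1, y2) in enumerate(zip(Y1, Y2)):
        for c1 in range(k):
            f1 = _component_prob(rho1[c1], y1)
            for c2 in range(k):
                out[i, c1, c2] = (
                    delta[c1] * tau[c1][c2] * f1 * _component_prob(rho2[c2], y2)
                )
        out[i] /= out[i].sum()
    return out


def relative_entropy_direct(posteriors):
    """Straight re-evaluation of 1 - sum(-p ln p) / (N ln K) with loops."""
    n, k = posteriors.shape
    total = 0.0
    for i in range(n):
        for c in range(k):
            p = posteriors[i, c]
            if p > 0:
                total += -p * math.log(p)
    return 1.0 - total / (n * math.log(k))
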