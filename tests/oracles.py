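"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning machinery: likelihoods and
marginals are computed by exhaustive enumeration over internal-node states,
and discrete-gamma class means by adaptive numerical quadrature.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist


def enumerate_site(tree, model, leaf_states: dict[int, int | None], rate: float):
    """Exhaustive site likelihood and per-internal-node marginals.

    ``leaf_states`` maps leaf node id -> state code (None = missing data).
    Returns (total likelihood, {internal node -> unnormalized marginal}).
    Transition matrices come from scipy's expm, independent of the package's
    eigendecomposition route.
    """
    Q = model.Q
    P = {
        v: expm(Q * tree.length[v] * rate)
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    n_states = Q.shape[0]
    total = 0.0
    marg = {v: np.zeros(n_states) for v in internals}
    for states in itertools.product(range(n_states), repeat=len(internals)):
        assign = dict(zip(internals, states))
        p = model.pi[assign[tree.root]] if tree.root in assign else 1.0
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            par = assign[tree.parent[v]]
            if tree.is_leaf(v):
                s = leaf_states[v]
                p *= 1.0 if s is None else P[v][par, s]
            else:
                p *= P[v][par, assign[v]]
        total += p
        for v in internals:
            marg[v][assign[v]] += p
    return total, marg


def enumerate_mixture_site(tree, model, leaf_states, mix):
    """Mixture site likelihood and marginals by enumeration over categories."""
    total = 0.0
    marg = None
    for w, r in zip(mix.weights, mix.rates):
        t, m = enumerate_site(tree, model, leaf_states, float(r))
        total += w * t
        if marg is None:
            marg = {v: w * mv for v, mv in m.items()}
        else:
            for v in m:
                marg[v] += w * m[v]
    return total, marg


def enumerate_presence_posterior(tree, leaf_presence: dict[int, int], pi1: float,
                                 scale: float = 1.0):
    """2-state marginal posterior of presence at every internal node."""
    pi0 = 1.0 - pi1
    s = 1.0 / (2.0 * pi0 * pi1)
    Q = np.array([[-s * pi1, s * pi1], [s * pi0, -s * pi0]])
    P = {
        v: expm(Q * tree.length[v] * scale)
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    pi = np.array([pi0, pi1])
    marg = {v: np.zeros(2) for v in internals}
    for states in itertools.product(range(2), repeat=len(internals)):
        assign = dict(zip(internals, states))
        p = pi[assign[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            par = assign[tree.parent[v]]
            s_v = leaf_presence[v] if tree.is_leaf(v) else assign[v]
            p *= P[v][par, s_v]
        for v in internals:
            marg[v][assign[v]] += p
    return {v: m / m.sum() for v, m in marg.items()}


def gamma_class_means_quadrature(alpha: float, K: int) -> np.ndarray:
    """Class means of the discretized mean-1 gamma by adaptive integration."""
    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], dist.ppf(np.arange(1, K) / K), [np.inf]])
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(lambda x: x * dist.pdf(x), lo, hi, limit=200)
        means.append(val * K)
    return np.array(means)


def welch_t(a, b):
    """Textbook Welch t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    return (a.mean() - b.mean()) / np.sqrt(va / a.size + vb / b.size)
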