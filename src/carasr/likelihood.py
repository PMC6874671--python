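"""Felsenstein pruning likelihood with +I+Gamma mixtures, rate-parameter
fitting and AIC model ranking.

The pruning sweep keeps per-site conditional likelihood arrays of shape
``(n_sites, 20)`` at every node, rescaling per site to avoid underflow;
log-scalers are carried alongside.  The same machinery serves scalar
category rates (a ``(20, 20)`` transition matrix per edge) and per-site rate
profiles (a ``(n_sites, 20, 20)`` tensor per edge), which is what the
Ancescon-style reconstruction needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment import MSA
from .models import N_STATES, RateMixture, SubstitutionModel, discretize_gamma
from .trees import RootedTree

ALPHA_BOUNDS = (0.02, 100.0)
PINV_BOUNDS = (0.0, 0.99)
SCALE_BOUNDS = (1e-3, 1e3)


class BindingError(ValueError):
    """Tree leaves and alignment rows do not match."""


def bind_leaves(msa: MSA, tree: RootedTree) -> dict[int, np.ndarray]:
    """Map leaf node id -> integer-coded alignment row; ids must match 1:1."""
    labels = set(tree.leaf_labels())
    ids = set(msa.ids)
    if labels != ids:
        missing = sorted(labels - ids)
        extra = sorted(ids - labels)
        raise BindingError(
            f"leaf/alignment mismatch; leaves without rows: {missing}; "
            f"rows without leaves: {extra}"
        )
    codes = msa.codes()
    row_of = {sid: i for i, sid in enumerate(msa.ids)}
    return {leaf: codes[row_of[tree.label[leaf]]] for leaf in tree.leaves()}


def _leaf_partial(code_row: np.ndarray) -> np.ndarray:
    """One-hot leaf conditionals; gap and X are missing data (all ones)."""
    n = code_row.shape[0]
    F = np.zeros((n, N_STATES))
    obs = code_row < N_STATES
    F[np.arange(n)[obs], code_row[obs]] = 1.0
    F[~obs] = 1.0
    return F


def _apply_P_down(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Message to the parent: M[s_par] = sum_s P[s_par, s] F[s]."""
    if P.ndim == 2:
        return F @ P.T
    return np.einsum("sij,sj->si", P, F)


def _apply_P_up(P: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Outside propagation: G_child[s] = sum_sp H[s_par] P[s_par, s]."""
    if P.ndim == 2:
        return H @ P
    return np.einsum("si,sij->sj", H, P)


def _rescale(F: np.ndarray, ls: np.ndarray):
    m = F.max(axis=1)
    m[m == 0.0] = 1.0
    return F / m[:, None], ls + np.log(m)


@dataclass
class CategorySweep:
    """Inside quantities of one rate category: conditionals, scalers, messages."""

    F: dict[int, np.ndarray]
    logscale: dict[int, np.ndarray]
    message: dict[int, np.ndarray]  # child id -> message to its parent
    P: dict[int, np.ndarray]  # child id -> transition on the edge above it

    def site_log_likelihood(self, pi: np.ndarray, root: int = 0) -> np.ndarray:
        lik = self.F[root] @ pi
        with np.errstate(divide="ignore"):
            return np.log(lik) + self.logscale[root]


def category_sweep(
    leaf_codes: dict[int, np.ndarray],
    tree: RootedTree,
    model: SubstitutionModel,
    rate,
    branch_scale: float = 1.0,
) -> CategorySweep:
    """Postorder pruning pass for one rate category.

    ``rate`` is a scalar category rate or a per-site rate vector.
    """
    n_sites = next(iter(leaf_codes.values())).shape[0]
    per_site = np.ndim(rate) == 1
    F: dict[int, np.ndarray] = {}
    ls: dict[int, np.ndarray] = {}
    message: dict[int, np.ndarray] = {}
    Ps: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            Fv = _leaf_partial(leaf_codes[v])
            lsv = np.zeros(n_sites)
        else:
            Fv = np.ones((n_sites, N_STATES))
            lsv = np.zeros(n_sites)
            for c in tree.children[v]:
                Fv = Fv * message[c]
                lsv = lsv + ls[c]
            Fv, lsv = _rescale(Fv, lsv)
        F[v] = Fv
        ls[v] = lsv
        if v != tree.root:
            t = tree.length[v] * branch_scale
            if per_site:
                P = model.transition_tensor(t, np.asarray(rate))
            else:
                P = model.transition_matrix(t, float(rate))
            Ps[v] = P
            message[v] = _apply_P_down(P, Fv)
    return CategorySweep(F, ls, message, Ps)


def outside_sweep(
    sweep: CategorySweep, tree: RootedTree, pi: np.ndarray
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Outside (above-the-node) arrays G with log-scalers, root prior = pi."""
    n_sites = sweep.F[tree.root].shape[0]
    G = {tree.root: np.tile(pi, (n_sites, 1))}
    gls = {tree.root: np.zeros(n_sites)}
    for v in tree.preorder():
        kids = tree.children[v]
        for c in kids:
            H = G[v].copy()
            hls = gls[v].copy()
            for b in kids:
                if b is not c:
                    H = H * sweep.message[b]
                    hls = hls + sweep.logscale[b]
            Gc = _apply_P_up(sweep.P[c], H)
            Gc, hls = _rescale(Gc, hls)
            G[c] = Gc
            gls[c] = hls
    return G, gls


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods and their total."""

    per_site: np.ndarray
    total: float

    @classmethod
    def from_sites(cls, per_site: np.ndarray) -> "SiteLikelihoods":
        return cls(per_site, float(per_site.sum()))


def tree_log_likelihood(
    msa: MSA,
    tree: RootedTree,
    model: SubstitutionModel,
    mix: RateMixture,
    branch_scale: float = 1.0,
) -> SiteLikelihoods:
    """Mixture log-likelihood of the alignment on the rooted tree.

    Gaps and ``X`` at leaves are missing data; the invariant class is the
    zero-rate category of the mixture, which reduces to the usual
    "equilibrium frequency of the shared residue" term.
    """
    leaf_codes = bind_leaves(msa, tree)
    per_cat = []
    for r in mix.rates:
        sweep = category_sweep(leaf_codes, tree, model, r, branch_scale)
        per_cat.append(sweep.site_log_likelihood(model.pi, tree.root))
    stacked = np.stack(per_cat)  # (n_cat, n_sites)
    with np.errstate(divide="ignore"):
        logw = np.log(mix.weights)
    per_site = logsumexp(stacked + logw[:, None], axis=0)
    return SiteLikelihoods.from_sites(per_site)


def _has_variable_column(msa: MSA) -> bool:
    codes = msa.codes()
    for j in range(codes.shape[1]):
        col = codes[:, j]
        res = np.unique(col[col < N_STATES])
        if res.size > 1:
            return True
    return False


@dataclass
class RateFit:
    """Fitted rate mixture (and optional global branch-length scale)."""

    mix: RateMixture
    branch_scale: float
    log_likelihood: float
    n_parameters: int
    warnings: list[str] = field(default_factory=list)


def fit_rate_parameters(
    msa: MSA,
    tree: RootedTree,
    model: SubstitutionModel,
    K: int = 8,
    fit_alpha: bool = True,
    fit_pinv: bool = False,
    fit_branch_scale: bool = False,
    init_alpha: float = 1.0,
    init_pinv: float = 0.1,
    init_scale: float = 1.0,
) -> RateFit:
    """Maximize the tree likelihood over (alpha, p_inv, global branch scale).

    Bounded quasi-Newton optimization in log coordinates for alpha and the
    scale.  An alignment with no variable column leaves alpha (and p_inv)
    unidentifiable: the fit returns the alpha upper bound with an
    ``unidentifiable`` warning instead of raising.
    """
    if not (fit_alpha or fit_pinv or fit_branch_scale):
        raise ValueError("at least one of the fitting flags must be set")

    warns: list[str] = []
    if fit_alpha and not _has_variable_column(msa):
        mix = RateMixture.gamma(ALPHA_BOUNDS[1], K, init_pinv if fit_pinv else 0.0)
        ll = tree_log_likelihood(msa, tree, model, mix, init_scale).total
        warns.append("unidentifiable: alignment has no variable column; alpha at upper bound")
        return RateFit(mix, init_scale, ll, 0, warns)

    names = []
    x0 = []
    bounds = []
    if fit_alpha:
        names.append("alpha")
        x0.append(np.log(init_alpha))
        bounds.append(tuple(np.log(ALPHA_BOUNDS)))
    if fit_pinv:
        names.append("pinv")
        x0.append(init_pinv)
        bounds.append(PINV_BOUNDS)
    if fit_branch_scale:
        names.append("scale")
        x0.append(np.log(init_scale))
        bounds.append(tuple(np.log(SCALE_BOUNDS)))

    def unpack(x):
        vals = dict(zip(names, x))
        alpha = float(np.exp(vals.get("alpha", np.log(init_alpha)))) if fit_alpha else init_alpha
        pinv = float(vals.get("pinv", 0.0)) if fit_pinv else 0.0
        scale = float(np.exp(vals.get("scale", 0.0))) if fit_branch_scale else init_scale
        return alpha, pinv, scale

    def neg_ll(x):
        alpha, pinv, scale = unpack(x)
        mix = RateMixture.gamma(alpha, K, pinv)
        return -tree_log_likelihood(msa, tree, model, mix, scale).total

    f0 = neg_ll(np.asarray(x0))
    res = minimize(neg_ll, np.asarray(x0), method="L-BFGS-B", bounds=bounds)
    if res.fun <= f0:
        xbest, fbest = res.x, res.fun
    else:  # optimizer wandered; keep the starting point (monotonicity contract)
        xbest, fbest = np.asarray(x0), f0
        warns.append("optimizer failed to improve on the starting point")
    alpha, pinv, scale = unpack(xbest)
    mix = RateMixture.gamma(alpha, K, pinv)
    return RateFit(mix, scale, -float(fbest), len(names), warns)


def select_best_model(
    msa: MSA,
    tree: RootedTree,
    candidates: list[SubstitutionModel],
    with_inv: bool = True,
    with_gamma: bool = True,
    K: int = 4,
    fit_branch_scale: bool = False,
) -> pd.DataFrame:
    """Rank substitution models (x rate options) by AIC.

    AIC = -2 lnL + 2 k, with k counting the fitted parameters (alpha, p_inv,
    branch scale as applicable).  Ties in AIC break toward fewer parameters.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    rate_options = [("", False, False)]
    if with_gamma:
        rate_options.append(("+G", True, False))
    if with_inv:
        rate_options.append(("+I", False, True))
    if with_gamma and with_inv:
        rate_options.append(("+I+G", True, True))

    rows = []
    for model in candidates:
        for suffix, fa, fp in rate_options:
            if not (fa or fp or fit_branch_scale):
                mix = RateMixture.single_rate()
                ll = tree_log_likelihood(msa, tree, model, mix).total
                fit = RateFit(mix, 1.0, ll, 0)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_rate_parameters(
                        msa,
                        tree,
                        model,
                        K=K if fa else 1,
                        fit_alpha=fa,
                        fit_pinv=fp,
                        fit_branch_scale=fit_branch_scale,
                    )
            k = int(fa) + int(fp) + int(fit_branch_scale)
            rows.append(
                dict(
                    model=model.name + suffix,
                    lnL=fit.log_likelihood,
                    k=k,
                    AIC=-2.0 * fit.log_likelihood + 2.0 * k,
                    alpha=fit.mix.alpha if fa else np.nan,
                    p_inv=fit.mix.p_inv if fp else np.nan,
                    branch_scale=fit.branch_scale,
                )
            )
    df = pd.DataFrame(rows).sort_values(["AIC", "k"], kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df
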