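"""Marginal ancestral sequence reconstruction at a target internal node.

Three algorithm styles are provided, emulating the configurations of the
common marginal-reconstruction tools:

* style ``P`` — discrete-gamma mixture (K = 8 by default) with fitted shape,
  model equilibrium frequencies (PAML-like);
* style ``F`` — as ``P`` plus a fitted global branch-length scale, and binary
  maximum-likelihood presence/absence reconstruction of gap characters
  (FastML-like);
* style ``A`` — single rate class with per-site maximum-likelihood rate
  factors and alignment-derived equilibrium frequencies (Ancescon-like).

All styles share one empirical-Bayes marginal: per site, the posterior over
the 20 states at the node combines the inside (subtree) and outside (rest of
tree) conditional likelihoods, with the rate category shared across the
whole tree at that site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AA_ORDER, MSA, GAP_CODE
from .likelihood import (
    CategorySweep,
    bind_leaves,
    category_sweep,
    fit_rate_parameters,
    outside_sweep,
)
from .models import (
    N_STATES,
    RateMixture,
    SubstitutionModel,
    alignment_frequencies,
)
from .trees import RootedTree

logger = logging.getLogger("carasr.asr")

RATE_BOUNDS = (1e-3, 100.0)

STYLES = ("P", "F", "A")


@dataclass
class AncestralPosterior:
    """Per-site 20-state marginal posterior at one internal node."""

    node: int
    probs: np.ndarray  # (n_sites, 20), rows sum to 1
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """PAML rst-like table: one row per column, 20 probabilities."""
        df = pd.DataFrame(np.round(self.probs, 6), columns=list(AA_ORDER))
        df.insert(0, "column", np.arange(self.n_sites))
        return df


@dataclass
class AncestorSequence:
    """MAP residues over alignment columns plus per-column presence calls."""

    residues: str
    presence: np.ndarray  # bool per column
    method: str
    map_prob: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if len(self.residues) != self.presence.shape[0]:
            raise ValueError("residues and presence tracks differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.residues)

    def gapped(self) -> str:
        return "".join(
            c if p else "-" for c, p in zip(self.residues, self.presence)
        )

    def ungapped(self) -> str:
        return "".join(c for c, p in zip(self.residues, self.presence) if p)


@dataclass
class SiteRateProfile:
    """Per-site ML rate factors plus the equilibrium vector used."""

    rates: np.ndarray
    pi: np.ndarray
    pi_source: str
    flagged_sites: list[int] = field(default_factory=list)


def marginal_posteriors(
    msa: MSA,
    tree: RootedTree,
    model: SubstitutionModel,
    mix: RateMixture,
    node: int,
    branch_scale: float = 1.0,
    method: str = "custom",
) -> AncestralPosterior:
    """Empirical-Bayes marginal posterior at an internal node.

    For each site, P(state s) is proportional to
    sum_k w_k inside_k(node, s) outside_k(node, s) — the rate category is
    shared across the whole tree at a site, and the zero-rate invariant
    class contributes like any other category.
    """
    if tree.is_leaf(node):
        raise ValueError("marginal reconstruction targets an internal node")
    leaf_codes = bind_leaves(msa, tree)
    n_sites = msa.n_columns
    contrib = []  # (log-offset (n_sites,), unnormalized (n_sites, 20))
    for w, r in zip(mix.weights, mix.rates):
        if w == 0.0:
            continue
        sweep = category_sweep(leaf_codes, tree, model, r, branch_scale)
        G, gls = outside_sweep(sweep, tree, model.pi)
        M = sweep.F[node] * G[node]
        off = sweep.logscale[node] + gls[node] + np.log(w)
        contrib.append((off, M))
    offs = np.stack([c[0] for c in contrib])  # (n_cat, n_sites)
    Ms = np.stack([c[1] for c in contrib])  # (n_cat, n_sites, 20)
    ref = offs.max(axis=0)
    total = np.einsum("ks,ksj->sj", np.exp(offs - ref[None, :]), Ms)
    probs = total / total.sum(axis=1, keepdims=True)
    return AncestralPosterior(node=node, probs=probs, method=method, meta={"mix": mix})


def map_sequence(post: AncestralPosterior) -> AncestorSequence:
    """Most-probable residue per column; exact ties break alphabetically.

    The presence track is an all-true placeholder — whether the ancestor
    actually has a residue at a column is decided by the indel
    reconstruction, not by the residue posterior.
    """
    residues = []
    map_prob = np.empty(post.n_sites)
    ties = []
    order = np.argsort(list(AA_ORDER))  # alphabetical scan order over codes
    for i in range(post.n_sites):
        p = post.probs[i]
        best = p.max()
        cand = [j for j in order if p[j] == best]
        if len(cand) > 1:
            ties.append(i)
        residues.append(AA_ORDER[cand[0]])
        map_prob[i] = best
    if ties:
        logger.info(
            "MAP extraction: %d exact posterior ties broken alphabetically at columns %s",
            len(ties),
            ties[:20],
        )
    return AncestorSequence(
        residues="".join(residues),
        presence=np.ones(post.n_sites, dtype=bool),
        method=post.method,
        map_prob=map_prob,
        meta={"ties": ties},
    )


def _grid_site_logliks(leaf_codes, tree, model, rates_grid, branch_scale=1.0):
    """Site log-likelihood for every (site, grid rate): shape (n_grid, n_sites)."""
    out = []
    for r in rates_grid:
        sweep = category_sweep(leaf_codes, tree, model, float(r), branch_scale)
        out.append(sweep.site_log_likelihood(model.pi, tree.root))
    return np.stack(out)


def fit_site_rate_profile(
    msa: MSA,
    tree: RootedTree,
    model: SubstitutionModel,
    pi_source: str = "alignment",
    n_grid: int = 81,
) -> SiteRateProfile:
    """Per-site ML rate factors on a fixed tree (Ancescon-style).

    Each site's rate maximizes its own single-rate likelihood over
    [1e-3, 100] by a log-spaced grid search with local quadratic refinement.
    With ``pi_source='alignment'`` the equilibrium vector is the observed
    residue frequency with a +1 pseudocount per amino acid.  Columns with at
    most one non-gap character carry no rate signal and are pinned at the
    lower bound (flagged).
    """
    if pi_source not in ("model", "alignment"):
        raise ValueError("pi_source must be 'model' or 'alignment'")
    if pi_source == "alignment":
        model = model.with_frequencies(alignment_frequencies(msa), suffix="+Falign")
    leaf_codes = bind_leaves(msa, tree)
    grid = np.logspace(np.log10(RATE_BOUNDS[0]), np.log10(RATE_BOUNDS[1]), n_grid)
    L = _grid_site_logliks(leaf_codes, tree, model, grid)  # (n_grid, n_sites)
    best = L.argmax(axis=0)
    logg = np.log(grid)
    rates = grid[best].astype(float)
    # quadratic refinement in log-rate where the optimum is interior
    for i in np.where((best > 0) & (best < n_grid - 1))[0]:
        k = best[i]
        y0, y1, y2 = L[k - 1, i], L[k, i], L[k + 1, i]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            x = logg[k] - 0.5 * (logg[k + 1] - logg[k - 1]) / 2 * (y2 - y0) / denom
            rates[i] = float(np.clip(np.exp(x), *RATE_BOUNDS))
    codes = msa.codes()
    occupancy = (codes != GAP_CODE).sum(axis=0)
    flagged = [int(j) for j in np.where(occupancy <= 1)[0]]
    if flagged:
        rates[flagged] = RATE_BOUNDS[0]
        logger.warning(
            "site rate profile: %d zero-signal columns pinned at the lower bound",
            len(flagged),
        )
    return SiteRateProfile(rates=rates, pi=model.pi, pi_source=pi_source, flagged_sites=flagged)


def marginal_posteriors_site_rates(
    msa: MSA,
    tree: RootedTree,
    model: SubstitutionModel,
    profile: SiteRateProfile,
    node: int,
    method: str = "A",
) -> AncestralPosterior:
    """Marginal posterior under a per-site rate profile (K = 1)."""
    if tree.is_leaf(node):
        raise ValueError("marginal reconstruction targets an internal node")
    model = model.with_frequencies(profile.pi, suffix="") if not np.allclose(
        model.pi, profile.pi
    ) else model
    leaf_codes = bind_leaves(msa, tree)
    sweep = category_sweep(leaf_codes, tree, model, profile.rates)
    G, _ = outside_sweep(sweep, tree, model.pi)
    M = sweep.F[node] * G[node]
    probs = M / M.sum(axis=1, keepdims=True)
    return AncestralPosterior(node=node, probs=probs, method=method, meta={"profile": profile})


def reconstruct_with_style(
    msa: MSA,
    tree: RootedTree,
    node: int,
    style: str,
    model: SubstitutionModel | None = None,
    K: int = 8,
    fit_pinv: bool = False,
    indel_granularity: str = "block",
):
    """Run one full reconstruction style and return (posterior, ancestor).

    Styles ``F`` and ``A`` also run the binary ML presence reconstruction and
    install the resulting gap calls on the ancestor; style ``P`` leaves the
    presence track all-true (its gap pattern is supplied later by
    cross-mapping from another style, mirroring how PAML ancestors acquire
    gaps from FastML/Ancescon output).
    """
    from . import indels  # local import to avoid a cycle
    from .models import get_model

    if style not in STYLES:
        raise ValueError(f"style must be one of {STYLES}, got {style!r}")
    if model is None:
        model = get_model("WAG")

    if style == "P":
        fit = fit_rate_parameters(
            msa, tree, model, K=K, fit_alpha=True, fit_pinv=fit_pinv
        )
        post = marginal_posteriors(msa, tree, model, fit.mix, node, method="P")
        post.meta.update(alpha=fit.mix.alpha, p_inv=fit.mix.p_inv)
        anc = map_sequence(post)
    elif style == "F":
        fit = fit_rate_parameters(
            msa, tree, model, K=K, fit_alpha=True, fit_pinv=fit_pinv,
            fit_branch_scale=True,
        )
        post = marginal_posteriors(
            msa, tree, model, fit.mix, node, branch_scale=fit.branch_scale, method="F"
        )
        post.meta.update(
            alpha=fit.mix.alpha, p_inv=fit.mix.p_inv, branch_scale=fit.branch_scale
        )
        anc = map_sequence(post)
        calls = indels.reconstruct_presence(
            indels.encode_indels(msa, granularity=indel_granularity), tree, node
        )
        anc = indels.apply_presence(anc, calls)
    else:  # style A
        profile = fit_site_rate_profile(msa, tree, model, pi_source="alignment")
        post = marginal_posteriors_site_rates(msa, tree, model, profile, node, method="A")
        anc = map_sequence(post)
        calls = indels.reconstruct_presence(
            indels.encode_indels(msa, granularity=indel_granularity), tree, node
        )
        anc = indels.apply_presence(anc, calls)
    anc.meta["style"] = style
    post.meta["style"] = style
    return post, anc
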