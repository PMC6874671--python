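"""Synthetic-data generators with recorded ground truth.

Two families of generators feed the pipeline:

* sequence evolution along a rooted tree under an empirical substitution
  model with discrete-gamma (+ invariant) rate heterogeneity and simple
  indel events — giving leaf alignments together with the true gapped
  sequence at every internal node, so reconstruction accuracy is measurable;
* assay data — NADPH-depletion plate traces from Michaelis–Menten truth
  parameters plus pH / temperature / time / solvent / melt condition
  profiles from their closed-form curves — with additive Gaussian noise and
  the generating parameters recorded.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AA_ORDER, MSA
from .assays import PlateTrace, michaelis_menten, ph_rate_model, substrate_inhibition
from .models import N_STATES, RateMixture, SubstitutionModel
from .trees import RootedTree, read_newick


@dataclass
class SimulationTruth:
    """Everything the generator knew: ancestors, rates, events, parameters."""

    ancestors: dict[int, str]  # node id -> gapped sequence (alignment columns)
    rate_category: dict[int, int]  # column id -> mixture category index
    events: list[dict]
    seed: int
    params: dict = field(default_factory=dict)


def simulate_birth_death_tree(
    n_taxa: int, seed: int, depth: float = 0.3, birth: float = 1.0, death: float = 0.2
) -> RootedTree:
    """A random birth-death tree rescaled to a given mean root-to-tip depth.

    The default depth of 0.3 expected substitutions per site gives leaf
    sequences roughly 65-80% pairwise identical — the divergence regime of a
    well-conserved enzyme family.
    """
    import random

    import dendropy
    from dendropy.simulate import treesim

    dtree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    tree = read_newick(newick)
    depths = []
    for leaf in tree.leaves():
        depths.append(sum(tree.length[v] for v in tree.ancestors(leaf)))
    factor = depth / float(np.mean(depths))
    tree.length = [l * factor for l in tree.length]
    tree.length[tree.root] = 0.0
    return tree


def _sample_states(rng, P: np.ndarray, parents: np.ndarray) -> np.ndarray:
    """Draw child states from the rows of P selected by parent states."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(parents.shape[0])
    return (cum[parents] > u[:, None]).argmax(axis=1)


def simulate_msa(
    tree: RootedTree,
    model: SubstitutionModel,
    mix: RateMixture,
    n_sites: int = 500,
    root: str | None = None,
    indel_rate: float = 0.0,
    mean_indel_length: float = 3.0,
    seed: int = 0,
) -> tuple[MSA, SimulationTruth]:
    """Evolve sequences from the root down the tree, with optional indels.

    Each site draws one mixture category (possibly the zero-rate invariant
    class) used on every edge.  Indels occur on each edge as Poisson events
    — expected count ``indel_rate x branch length x current length``, split
    evenly between deletions and insertions — with geometric lengths.
    Deletions mask contiguous present columns for the whole subtree below;
    insertions add fresh columns (states drawn from the equilibrium
    frequencies) that are gapped everywhere outside the subtree.  The true
    gapped sequence at every node is recorded.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if indel_rate < 0 or mean_indel_length < 1:
        raise ValueError("indel_rate must be >= 0 and mean_indel_length >= 1")
    rng = np.random.default_rng(seed)

    columns: list[int] = list(range(n_sites))
    next_col = n_sites
    rate_cat: dict[int, int] = {}
    states: dict[int, dict[int, int]] = {}
    present: dict[int, set[int]] = {}
    events: list[dict] = []

    cats = rng.choice(len(mix.rates), size=n_sites, p=mix.weights)
    for j in range(n_sites):
        rate_cat[j] = int(cats[j])
    if root is not None:
        if len(root) != n_sites:
            raise ValueError("given root sequence length must equal n_sites")
        root_states = {j: AA_ORDER.index(c) for j, c in enumerate(root)}
    else:
        draws = rng.choice(N_STATES, size=n_sites, p=model.pi)
        root_states = {j: int(s) for j, s in enumerate(draws)}
    states[tree.root] = root_states
    present[tree.root] = set(range(n_sites))

    geom_p = 1.0 / mean_indel_length

    def evolve_edge(parent: int, child: int):
        nonlocal next_col
        t = tree.length[child]
        par_states = states[parent]
        par_present = present[parent]
        child_states: dict[int, int] = {}
        child_present = set(par_present)

        # substitutions, grouped by rate category for vectorized sampling
        cols = sorted(par_present)
        by_cat: dict[int, list[int]] = {}
        for col in cols:
            by_cat.setdefault(rate_cat[col], []).append(col)
        for cat, cat_cols in by_cat.items():
            r = float(mix.rates[cat])
            P = model.transition_matrix(t, r)
            parents_arr = np.array([par_states[c] for c in cat_cols])
            kids = _sample_states(rng, P, parents_arr)
            for c, s in zip(cat_cols, kids):
                child_states[c] = int(s)

        if indel_rate > 0 and par_present:
            mean_events = 0.5 * indel_rate * t * len(par_present)
            n_del = int(rng.poisson(mean_events))
            n_ins = int(rng.poisson(mean_events))
            for _ in range(n_del):
                length = int(rng.geometric(geom_p))
                ordered = [c for c in columns if c in child_present]
                if not ordered:
                    break
                start = int(rng.integers(0, len(ordered)))
                hit = ordered[start : start + length]
                for c in hit:
                    child_present.discard(c)
                    child_states.pop(c, None)
                events.append(
                    dict(kind="deletion", node=child, columns=hit, length=len(hit))
                )
            for _ in range(n_ins):
                length = int(rng.geometric(geom_p))
                pos = int(rng.integers(0, len(columns) + 1))
                new_cols = list(range(next_col, next_col + length))
                next_col += length
                columns[pos:pos] = new_cols
                new_cats = rng.choice(len(mix.rates), size=length, p=mix.weights)
                new_states = rng.choice(N_STATES, size=length, p=model.pi)
                for c, cat, s in zip(new_cols, new_cats, new_states):
                    rate_cat[c] = int(cat)
                    child_states[c] = int(s)
                    child_present.add(c)
                events.append(
                    dict(kind="insertion", node=child, columns=new_cols, length=length)
                )

        states[child] = child_states
        present[child] = child_present
        for grandchild in tree.children[child]:
            evolve_edge(child, grandchild)

    for child in tree.children[tree.root]:
        evolve_edge(tree.root, child)

    def gapped(node: int) -> str:
        st = states[node]
        pr = present[node]
        return "".join(
            AA_ORDER[st[c]] if c in pr else "-" for c in columns
        )

    ids = [tree.label[v] for v in tree.leaves()]
    seqs = [gapped(v) for v in tree.leaves()]
    msa = MSA(ids, seqs, provenance=f"simulated (seed={seed})")
    ancestors = {v: gapped(v) for v in range(tree.n_nodes) if not tree.is_leaf(v)}
    truth = SimulationTruth(
        ancestors=ancestors,
        rate_category={c: rate_cat[c] for c in columns},
        events=events,
        seed=seed,
        params=dict(
            n_sites=n_sites,
            model=model.name,
            alpha=mix.alpha,
            p_inv=mix.p_inv,
            K=mix.K,
            indel_rate=indel_rate,
            mean_indel_length=mean_indel_length,
        ),
    )
    return msa, truth


# ---------------------------------------------------------------------------
# assay generators
# ---------------------------------------------------------------------------


@dataclass
class AssayTruth:
    """Generating parameters for the assay simulators."""

    kcat: float = 340.0  # min⁻¹
    KM: float = 76.8  # in `unit`
    Ki: float | None = None
    enzyme_uM: float = 0.05
    unit: str = "µM"
    nadph0_uM: float = 250.0
    curve_slope: float = 0.005  # A340 per µM NADPH
    curve_intercept: float = 0.04
    noise_sd: float = 0.0  # absorbance units
    blank_drift: float = -0.0005  # A340 per minute of background NADPH decay


def dilution_series(start: float, factor: float = 1.7, n: int = 12) -> np.ndarray:
    """A GraphPad-style dilution series: start, start/f, start/f^2, ..."""
    return start / factor ** np.arange(n)


@dataclass
class PlateAssay:
    """Simulated plate run: traces + blanks + standard-curve points + truth."""

    traces: list[PlateTrace]
    blanks: list[PlateTrace]
    standard_concentrations: np.ndarray
    standard_absorbances: np.ndarray
    truth: AssayTruth


def simulate_plate_assay(
    truth: AssayTruth,
    concentrations,
    time_grid=None,
    n_replicates: int = 3,
    seed: int = 0,
) -> PlateAssay:
    """NADPH-depletion traces at each substrate concentration.

    NADPH falls linearly at the Michaelis–Menten initial rate for the well's
    substrate concentration until exhausted, then stays flat; the absorbance
    is the standard-curve image plus Gaussian noise.  Blanks carry only the
    background drift.
    """
    rng = np.random.default_rng(seed)
    if time_grid is None:
        time_grid = np.arange(0.0, 601.0, 30.0)  # 10 min in 30 s cycles
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size < 4:
        raise ValueError("time grid needs at least 4 points")
    t_min = time_grid / 60.0
    Vmax = truth.kcat * truth.enzyme_uM

    traces = []
    for S in np.asarray(concentrations, dtype=float):
        if truth.Ki is None:
            v = michaelis_menten(S, Vmax, truth.KM)
        else:
            v = substrate_inhibition(S, Vmax, truth.KM, truth.Ki)
        for rep in range(n_replicates):
            nadph = np.clip(truth.nadph0_uM - v * t_min, 0.0, None)
            a340 = (
                truth.curve_slope * nadph
                + truth.curve_intercept
                + truth.blank_drift * t_min
                + rng.normal(0.0, truth.noise_sd, size=t_min.shape)
            )
            traces.append(
                PlateTrace(
                    time_s=time_grid,
                    a340=a340,
                    substrate="S",
                    concentration=float(S),
                    enzyme_uM=truth.enzyme_uM,
                    replicate=rep,
                )
            )
    blanks = []
    for rep in range(n_replicates):
        a340 = (
            truth.curve_slope * truth.nadph0_uM
            + truth.curve_intercept
            + truth.blank_drift * t_min
            + rng.normal(0.0, truth.noise_sd, size=t_min.shape)
        )
        blanks.append(
            PlateTrace(time_s=time_grid, a340=a340, blank=True, replicate=rep)
        )
    std_conc = np.linspace(0.0, truth.nadph0_uM, 12)
    std_abs = (
        truth.curve_slope * std_conc
        + truth.curve_intercept
        + rng.normal(0.0, truth.noise_sd, size=std_conc.shape)
    )
    return PlateAssay(
        traces=traces,
        blanks=blanks,
        standard_concentrations=std_conc,
        standard_absorbances=std_abs,
        truth=truth,
    )


PROFILE_KINDS = ("temperature-A50", "time-decay", "pH", "solvent", "melt")


def simulate_condition_profiles(
    kind: str,
    grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    midpoint: float = 65.1,
    width: float = 1.5,
    decay_k: float = np.log(2.0) / 200.0,
    pK1: float = 5.12,
    pK2: float = 11.11,
    melt_baseline: float = 100.0,
    melt_amplitude: float = 1000.0,
) -> pd.DataFrame:
    """Deterministic mean curve of the named kind plus Gaussian noise.

    * ``temperature-A50`` / ``solvent`` — falling logistic, 100% plateau,
      50% at ``midpoint``;
    * ``time-decay`` — 100·exp(−k·t);
    * ``pH`` — the diprotic bell model (V100 = 100);
    * ``melt`` — rising two-state sigmoid centered at ``midpoint`` (a DSF
      fluorescence curve, not an activity profile).
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"kind must be one of {PROFILE_KINDS}")
    rng = np.random.default_rng(seed)
    x = np.asarray(grid, dtype=float)
    if kind in ("temperature-A50", "solvent"):
        y = 100.0 / (1.0 + np.exp((x - midpoint) / width))
    elif kind == "time-decay":
        y = 100.0 * np.exp(-decay_k * x)
    elif kind == "pH":
        y = ph_rate_model(x, 100.0, pK1, pK2)
    else:  # melt
        y = melt_baseline + melt_amplitude / (1.0 + np.exp(-(x - midpoint) / width))
    y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return pd.DataFrame(dict(condition=x, value=y)).assign(kind=kind)
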