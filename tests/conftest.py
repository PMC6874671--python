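import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from carasr.alignment import MSA
from carasr.models import RateMixture, get_model
from carasr.trees import read_newick


@pytest.fixture(scope="session")
def wag():
    return get_model("WAG")


@pytest.fixture(scope="session")
def poisson():
    return get_model("Poisson")


@pytest.fixture
def quartet_tree():
    return read_newick("((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.2);")


@pytest.fixture
def quartet_msa():
    return MSA(["a", "b", "c", "d"], ["ACW", "ADW", "GCW", "A-W"])


@pytest.fixture
def mix2():
    return RateMixture.gamma(0.6, 2)


@pytest.fixture
def leaf_state_map():
    """leaf node id -> state code for a given MSA column, None for gaps/X."""

    def build(tree, msa, site):
        codes = msa.codes()
        out = {}
        for v in tree.leaves():
            c = codes[msa.ids.index(tree.label[v]), site]
            out[v] = None if c >= 20 else int(c)
        return out

    return build


@pytest.fixture(scope="session")
def recovery_run():
    """The standard 12-taxon / 500-site reconstruction recovery simulation.

    Session-scoped: several tests reuse the same fixed-seed run.
    """
    from carasr.asr import reconstruct_with_style
    from carasr.indels import crossmap_indels
    from carasr.simulate import simulate_birth_death_tree, simulate_msa

    wag = get_model("WAG")
    tree = simulate_birth_death_tree(12, seed=7)
    msa, truth = simulate_msa(
        tree, wag, RateMixture.gamma(1.0, 8), n_sites=500,
        indel_rate=0.05, mean_indel_length=3.0, seed=11,
    )
    node = next(
        c for c in tree.children[tree.root] if not tree.is_leaf(c)
    )
    results = {}
    for style in "PFA":
        results[style] = reconstruct_with_style(msa, tree, node, style)
    ancP = results["P"][1]
    finals = {
        "A": results["A"][1],
        "F": results["F"][1],
        "PA": crossmap_indels(ancP, results["A"][1]),
        "PF": crossmap_indels(ancP, results["F"][1]),
    }
    return dict(
        tree=tree, msa=msa, truth=truth, node=node,
        posteriors={s: results[s][0] for s in "PFA"},
        ancestors={s: results[s][1] for s in "PFA"},
        finals=finals,
    )
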