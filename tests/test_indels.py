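import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carasr.alignment import MSA
from carasr.asr import AncestorSequence
from carasr.indels import (
    apply_presence,
    crossmap_indels,
    encode_indels,
    reconstruct_presence,
)
from carasr.trees import read_newick
from oracles import enumerate_presence_posterior


def make_anc(residues, presence, method="P"):
    return AncestorSequence(
        residues=residues,
        presence=np.asarray(presence, dtype=bool),
        method=method,
        map_prob=np.ones(len(residues)),
    )


class TestEncode:
    def test_column_presence(self):
        msa = MSA(["r", "s"], ["AC--D", "ACC-D"])
        m = encode_indels(msa, granularity="column")
        assert m.matrix[0].tolist() == [1, 1, 0, 0, 1]
        assert m.blocks is None

    def test_block_collapse(self):
        msa = MSA(["r", "s"], ["A--D", "A--D"])
        m = encode_indels(msa, granularity="block")
        assert m.blocks == [(0, 1), (1, 3), (3, 4)]

    def test_gapless_msa_single_block(self):
        msa = MSA(["r", "s"], ["ACD", "ACD"])
        m = encode_indels(msa)
        assert m.matrix.all() and m.blocks == [(0, 3)]

    def test_x_counts_as_presence(self):
        msa = MSA(["r", "s"], ["AX", "A-"])
        assert encode_indels(msa, "column").matrix[0].tolist() == [1, 1]


class TestPresenceReconstruction:
    def test_all_present_column(self):
        tree = read_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        msa = MSA(["a", "b", "c", "d"], ["AC", "AC", "AC", "AC"])
        calls = reconstruct_presence(encode_indels(msa), tree, 1)
        assert (calls.probability > 0.5).all() and calls.call.all()

    def test_zero_branches_uniform_state(self):
        tree = read_newick("((a:0.0,b:0.0):0.0,(c:0.0,d:0.0):0.0);")
        msa = MSA(["a", "b", "c", "d"], ["A-", "A-", "A-", "A-"])
        calls = reconstruct_presence(encode_indels(msa, "column"), tree, 1)
        assert calls.probability[0] == pytest.approx(1.0)
        assert calls.probability[1] == pytest.approx(0.0)

    @pytest.mark.parametrize("ratio,scale", [(1.0, 1.0), (2.0, 0.5), (0.5, 2.0)])
    def test_matches_enumeration_oracle(self, ratio, scale):
        tree = read_newick("((a:0.1,b:0.3):0.2,(c:0.15,d:0.4):0.1);")
        msa = MSA(["a", "b", "c", "d"], ["A-C", "AC-", "-CC", "ACC"])
        pi1 = ratio / (1.0 + ratio)
        calls = reconstruct_presence(
            encode_indels(msa, "column"), tree, 1,
            gain_loss_rate_ratio=ratio, scale=scale,
        )
        codes = (msa.codes() != 20).astype(int)
        for col in range(3):
            leaf_presence = {
                v: int(codes[msa.ids.index(tree.label[v]), col]) for v in tree.leaves()
            }
            oracle = enumerate_presence_posterior(tree, leaf_presence, pi1, scale)
            assert calls.probability[col] == pytest.approx(oracle[1][1], abs=1e-12)

    def test_symmetric_tie_called_absent(self):
        # mirror-symmetric tree and pattern: posterior exactly 1/2 at the root
        tree = read_newick("((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2);")
        msa = MSA(["a", "b", "c", "d"], ["AC", "AC", "-C", "-C"])
        calls = reconstruct_presence(encode_indels(msa, "column"), tree, 0)
        assert calls.probability[0] == pytest.approx(0.5, abs=1e-12)
        assert not calls.call[0]

    def test_block_and_column_agree_for_single_column_gaps(self):
        tree = read_newick("((a:0.1,b:0.3):0.2,(c:0.15,d:0.4):0.1);")
        msa = MSA(["a", "b", "c", "d"], ["A-CWD", "ACC-D", "AC-WD", "ACCWD"])
        col = reconstruct_presence(encode_indels(msa, "column"), tree, 1)
        blk = reconstruct_presence(encode_indels(msa, "block"), tree, 1)
        assert np.abs(col.probability - blk.probability).max() < 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16), st.integers(3, 6))
    def test_pruning_equals_enumeration_property(self, seed, n_leaves):
        """2-state pruning posterior == exhaustive enumeration on random trees."""
        rng = np.random.default_rng(seed)
        # random caterpillar-ish topology with random lengths and pattern
        labels = [f"t{i}" for i in range(n_leaves)]
        newick = labels[0] + f":{rng.uniform(0.05, 0.5):.3f}"
        for l in labels[1:]:
            newick = f"({newick},{l}:{rng.uniform(0.05, 0.5):.3f}):{rng.uniform(0.05, 0.5):.3f}"
        tree = read_newick(f"({newick},out:0.3);")
        pattern = rng.integers(0, 2, size=len(tree.leaves()))
        if pattern.sum() == 0:
            pattern[0] = 1
        leaves = tree.leaves()
        seqs = {tree.label[v]: ("A" if pattern[i] else "-") + "C"
                for i, v in enumerate(leaves)}
        msa = MSA(list(seqs), list(seqs.values()))
        node = tree.children[tree.root][0]
        if tree.is_leaf(node):
            node = tree.root
        calls = reconstruct_presence(encode_indels(msa, "column"), tree, node)
        leaf_presence = {v: int(pattern[i]) for i, v in enumerate(leaves)}
        oracle = enumerate_presence_posterior(tree, leaf_presence, 0.5)
        assert calls.probability[0] == pytest.approx(oracle[node][1], abs=1e-12)


class TestApplyAndCrossmap:
    def test_apply_presence_examples(self):
        anc = make_anc("ACDEF", [1, 1, 1, 1, 1])
        calls_all = reconstruct_presence(
            encode_indels(MSA(["a", "b"], ["ACDEF", "ACDEF"]), "column"),
            read_newick("(a:0.1,b:0.1);"), 0,
        )
        full = apply_presence(anc, calls_all)
        assert full.ungapped() == "ACDEF"

    def test_apply_presence_mask(self):
        anc = make_anc("ACDEF", [1, 1, 1, 1, 1])
        from carasr.indels import PresenceCalls

        calls = PresenceCalls(
            probability=np.array([0.9, 0.9, 0.1, 0.2, 0.8]),
            call=np.array([True, True, False, False, True]),
            method="test",
        )
        out = apply_presence(anc, calls)
        assert out.ungapped() == "ACF"
        # round trip: presence re-extracted from the gapped string matches
        assert [c != "-" for c in out.gapped()] == calls.call.tolist()

    def test_length_mismatch(self):
        from carasr.indels import PresenceCalls

        anc = make_anc("ACD", [1, 1, 1])
        calls = PresenceCalls(np.array([0.9]), np.array([True]), "t")
        with pytest.raises(ValueError, match="columns"):
            apply_presence(anc, calls)

    def test_crossmap_examples(self):
        rec = make_anc("ACDEF", [1, 1, 1, 1, 1], method="P")
        don = make_anc("GGGGG", [1, 0, 1, 1, 0], method="A")
        chim = crossmap_indels(rec, don)
        assert chim.ungapped() == "ADE"
        assert chim.method == "PA"
        assert len(chim.ungapped()) == len(don.ungapped())

    def test_crossmap_self_is_identity(self):
        x = make_anc("ACDEF", [1, 0, 1, 1, 0], method="F")
        assert crossmap_indels(x, x).ungapped() == x.ungapped()

    def test_crossmap_all_present_donor(self):
        rec = make_anc("ACDEF", [1, 0, 1, 0, 1], method="P")
        don = make_anc("WWWWW", [1, 1, 1, 1, 1], method="F")
        assert crossmap_indels(rec, don).ungapped() == "ACDEF"

    def test_crossmap_coordinate_error(self):
        with pytest.raises(ValueError, match="coordinate"):
            crossmap_indels(make_anc("ACD", [1, 1, 1]), make_anc("AC", [1, 1]))
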