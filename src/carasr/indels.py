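"""Binary presence/absence reconstruction of gaps and indel cross-mapping.

Gap characters are recoded as a two-state (present/absent) alignment —
optionally collapsing runs of columns that share one presence pattern into a
single gap-event character — and the ancestral state at the target node is
the marginal posterior under a reversible two-state CTMC run over the same
rooted tree by pruning.  The cross-mapping step transfers one ancestor's gap
pattern onto another's residue states in shared alignment coordinates,
producing the chimeric "recipient residues + donor gaps" ancestors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import MSA, GAP_CODE
from .asr import AncestorSequence
from .likelihood import BindingError
from .trees import RootedTree

logger = logging.getLogger("carasr.indels")


@dataclass
class IndelMatrix:
    """Binary presence matrix derived from an MSA (1 = residue, 0 = gap).

    ``blocks`` partitions columns into gap-event characters under block
    granularity (maximal runs of adjacent columns with identical presence
    pattern across all rows); ``None`` under column granularity.
    """

    matrix: np.ndarray  # (n_rows, n_columns) of {0, 1}
    ids: list[str]
    blocks: list[tuple[int, int]] | None = None

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PresenceCalls:
    """Per-column posterior probability of presence at a node, plus calls.

    The boolean call is ``probability > 0.5``; an exact 0.5 tie is called
    absent (conservative toward shorter ancestors) and logged.
    """

    probability: np.ndarray
    call: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                column=np.arange(self.probability.shape[0]),
                p_present=self.probability,
                call=np.where(self.call, "present", "absent"),
            )
        )


def encode_indels(msa: MSA, granularity: str = "block") -> IndelMatrix:
    """Recode gaps as binary characters (``X`` counts as presence).

    Block granularity collapses maximal runs of adjacent columns whose
    presence pattern is identical across all rows into one character, so a
    multi-column gap event is a single observation rather than several.
    """
    if granularity not in ("column", "block"):
        raise ValueError("granularity must be 'column' or 'block'")
    mat = (msa.codes() != GAP_CODE).astype(np.int8)
    blocks = None
    if granularity == "block":
        blocks = []
        start = 0
        for j in range(1, mat.shape[1] + 1):
            if j == mat.shape[1] or not np.array_equal(mat[:, j], mat[:, start]):
                blocks.append((start, j))
                start = j
    return IndelMatrix(matrix=mat, ids=list(msa.ids), blocks=blocks)


def _two_state_P(t: float, pi1: float) -> np.ndarray:
    """Transition matrix of the reversible 2-state CTMC with mean rate 1."""
    pi0 = 1.0 - pi1
    s = 1.0 / (2.0 * pi0 * pi1)  # decay rate after mean-rate normalization
    e = np.exp(-s * t)
    Pi = np.array([[pi0, pi1], [pi0, pi1]])
    return Pi + (np.eye(2) - Pi) * e


def reconstruct_presence(
    indels: IndelMatrix,
    tree: RootedTree,
    node: int,
    gain_loss_rate_ratio: float = 1.0,
    scale: float = 1.0,
) -> PresenceCalls:
    """Marginal posterior of presence at ``node`` under a 2-state CTMC.

    ``gain_loss_rate_ratio`` is rate(absent→present) / rate(present→absent);
    it implies stationary presence frequency ratio/(1+ratio).  Branch lengths
    are the amino-acid tree lengths times ``scale``.
    """
    if gain_loss_rate_ratio <= 0 or scale <= 0:
        raise ValueError("rates must be positive")
    labels = set(tree.leaf_labels())
    if labels != set(indels.ids):
        raise BindingError(
            f"tree/indel-matrix mismatch: {sorted(labels ^ set(indels.ids))}"
        )
    pi1 = gain_loss_rate_ratio / (1.0 + gain_loss_rate_ratio)
    pi = np.array([1.0 - pi1, pi1])

    # observations per character: one per column, or one per block
    if indels.blocks is not None:
        char_cols = [b[0] for b in indels.blocks]
    else:
        char_cols = list(range(indels.n_columns))
    obs = indels.matrix[:, char_cols]  # (n_rows, n_chars)
    row_of = {sid: i for i, sid in enumerate(indels.ids)}
    n_chars = obs.shape[1]

    P = {
        v: _two_state_P(tree.length[v] * scale, pi1)
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    # inside pass
    F: dict[int, np.ndarray] = {}
    msg: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            states = obs[row_of[tree.label[v]]]
            Fv = np.zeros((n_chars, 2))
            Fv[np.arange(n_chars), states] = 1.0
        else:
            Fv = np.ones((n_chars, 2))
            for c in tree.children[v]:
                Fv = Fv * msg[c]
        F[v] = Fv
        if v != tree.root:
            msg[v] = Fv @ P[v].T
    # outside pass down to the target node only
    G = {tree.root: np.tile(pi, (n_chars, 1))}
    path = tree.ancestors(node)[::-1]  # root ... node
    for v, c in zip(path[:-1], path[1:]):
        H = G[v].copy()
        for b in tree.children[v]:
            if b != c:
                H = H * msg[b]
        G[c] = H @ P[c]
    M = F[node] * G[node]
    prob_char = M[:, 1] / M.sum(axis=1)

    # expand per-character posteriors back to per-column
    prob = np.empty(indels.n_columns)
    if indels.blocks is not None:
        for (a, b), p in zip(indels.blocks, prob_char):
            prob[a:b] = p
    else:
        prob = prob_char
    call = prob > 0.5
    n_ties = int(np.sum(prob == 0.5))
    if n_ties:
        logger.info(
            "presence reconstruction: %d columns at posterior exactly 0.5 called absent",
            n_ties,
        )
    return PresenceCalls(
        probability=prob,
        call=call,
        method=f"2-state ML (ratio={gain_loss_rate_ratio}, scale={scale})",
        meta=dict(node=node, granularity="block" if indels.blocks is not None else "column"),
    )


def apply_presence(anc: AncestorSequence, calls: PresenceCalls) -> AncestorSequence:
    """Install gap calls on an ancestor's presence track."""
    if calls.probability.shape[0] != anc.n_columns:
        raise ValueError(
            f"presence calls cover {calls.probability.shape[0]} columns, "
            f"ancestor has {anc.n_columns}"
        )
    meta = dict(anc.meta)
    meta["presence_method"] = calls.method
    return AncestorSequence(
        residues=anc.residues,
        presence=calls.call.copy(),
        method=anc.method,
        map_prob=anc.map_prob,
        meta=meta,
    )


def crossmap_indels(
    recipient: AncestorSequence, donor: AncestorSequence
) -> AncestorSequence:
    """Transpose the donor's gap pattern onto the recipient's residues.

    Both ancestors must live in the same curated-alignment column space, so
    gaps transfer by shared column index (no re-alignment).  Columns where
    the donor is present but the recipient's own method called a gap take
    the recipient's MAP residue (always defined per column) and are logged.
    """
    if recipient.n_columns != donor.n_columns:
        raise ValueError(
            f"coordinate mismatch: recipient has {recipient.n_columns} columns, "
            f"donor {donor.n_columns}"
        )
    disputed = np.where(donor.presence & ~recipient.presence)[0]
    if disputed.size:
        logger.info(
            "cross-mapping: %d columns present in donor but gap-called by the "
            "recipient; recipient MAP residues used: %s",
            disputed.size,
            disputed[:20].tolist(),
        )
    tag = f"{recipient.method}{donor.method}"
    return AncestorSequence(
        residues=recipient.residues,
        presence=donor.presence.copy(),
        method=tag,
        map_prob=recipient.map_prob,
        meta=dict(
            recipient=recipient.method,
            donor=donor.method,
            disputed_columns=disputed.tolist(),
        ),
    )
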