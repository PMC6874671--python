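"""Posterior-probability alternative ancestors and comparison statistics.

The second-best variant ("P30" at the default 0.30 threshold) replaces the
MAP residue with the runner-up wherever the runner-up's posterior exceeds
the threshold — a probe of whether between-algorithm variation is just
posterior sampling variation.  Comparison statistics cover pairwise percent
identity (with two documented gap policies), the per-column identity
barcode, all-sequence conservation, and the fraction of derived variation
two variants share relative to a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .alignment import AA_ORDER, GAP
from .asr import AncestorSequence, AncestralPosterior

GAP_POLICIES = ("exclude-pair-gaps", "count-gap-mismatch")


@dataclass
class VariantSequence:
    """An alternative ancestor produced by a rank-substitution rule."""

    residues: str
    threshold: float
    rank: int
    substitutions: list[tuple[int, str, str, float, float]]
    # (column, MAP residue, chosen residue, MAP prob, chosen prob)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)


def second_best_variant(
    post: AncestralPosterior, threshold: float = 0.30
) -> VariantSequence:
    """Substitute the second-most-probable residue where it exceeds ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    residues = []
    subs = []
    for i in range(post.n_sites):
        p = post.probs[i]
        order = np.argsort(-p, kind="stable")
        best, second = order[0], order[1]
        if p[second] > threshold:
            residues.append(AA_ORDER[second])
            subs.append(
                (i, AA_ORDER[best], AA_ORDER[second], float(p[best]), float(p[second]))
            )
        else:
            residues.append(AA_ORDER[best])
    return VariantSequence(
        residues="".join(residues), threshold=threshold, rank=2, substitutions=subs
    )


def pairwise_identity(
    a: str, b: str, gap_policy: str = "exclude-pair-gaps"
) -> float:
    """Percent identity between two gapped sequences in shared columns.

    ``exclude-pair-gaps`` (default): columns where both sequences are gaps
    drop out of the denominator; a residue aligned to a gap is a mismatch.
    ``count-gap-mismatch``: the denominator is all columns.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"gap_policy must be one of {GAP_POLICIES}")
    matches = 0
    denom = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            if gap_policy == "count-gap-mismatch":
                denom += 1
                matches += 1  # both gapped: identical characters
            continue
        denom += 1
        if x == y and x != GAP:
            matches += 1
    if denom == 0:
        raise ValueError("no evaluable columns")
    return 100.0 * matches / denom


@dataclass
class ComparisonReport:
    """Identity barcode and summary identity/conservation statistics."""

    names: list[str]
    column_identity: np.ndarray  # mean pairwise same-character indicator per column
    mean_pairwise_identity: float  # mean of pairwise_identity over pairs (%)
    conservation: float  # % of columns identical across all sequences
    pairwise_matrix: pd.DataFrame
    gap_policy: str = "exclude-pair-gaps"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(column=np.arange(self.column_identity.shape[0]),
                 identity=self.column_identity)
        )


def identity_barcode(
    seqs: dict[str, str] | list[str],
    gap_policy: str = "exclude-pair-gaps",
) -> ComparisonReport:
    """Per-column identity track plus summary statistics for >= 2 sequences.

    The per-column identity is the fraction of unordered pairs carrying the
    identical character there (gaps compared literally).  Conservation is the
    percentage of columns where every sequence carries the same character.
    """
    if isinstance(seqs, dict):
        names = list(seqs)
        strings = [seqs[n] for n in names]
    else:
        names = [f"seq{i}" for i in range(len(seqs))]
        strings = list(seqs)
    if len(strings) < 2:
        raise ValueError("identity barcode needs at least two sequences")
    n = len(strings[0])
    if any(len(s) != n for s in strings):
        raise ValueError("sequences must share one column space")

    arr = np.array([list(s) for s in strings])
    pairs = list(combinations(range(len(strings)), 2))
    col_id = np.zeros(n)
    for i, j in pairs:
        col_id += arr[i] == arr[j]
    col_id /= len(pairs)

    conserved = np.all(arr == arr[0], axis=0)
    conservation = 100.0 * conserved.sum() / n

    mat = pd.DataFrame(np.full((len(names), len(names)), 100.0), index=names, columns=names)
    vals = []
    for i, j in pairs:
        pid = pairwise_identity(strings[i], strings[j], gap_policy)
        mat.iloc[i, j] = mat.iloc[j, i] = pid
        vals.append(pid)
    return ComparisonReport(
        names=names,
        column_identity=col_id,
        mean_pairwise_identity=float(np.mean(vals)),
        conservation=float(conservation),
        pairwise_matrix=mat,
        gap_policy=gap_policy,
    )


#: Marker returned for a directional share when the variant has no derived sites.
UNDEFINED = "undefined"


@dataclass
class SharedVariation:
    """Shared derived variation between two variants of one reference."""

    derived_1: list[int]
    derived_2: list[int]
    shared: list[int]
    directional_1: float | str  # % of v1's derived sites shared (or 'undefined')
    directional_2: float | str
    symmetric: float | str  # % of the union shared
    loose_shared: list[int] = field(default_factory=list)
    # sites where both differ from the reference regardless of agreeing state


def shared_derived_variation(reference: str, v1: str, v2: str) -> SharedVariation:
    """How much of two variants' derived variation is the same change.

    Derived sites are columns where a variant differs from the reference
    (gaps compared literally).  A shared site must carry the identical
    character in both variants; the looser "both differ somehow" set is also
    recorded for transparency.
    """
    if not (len(reference) == len(v1) == len(v2)):
        raise ValueError("sequences must share one column space")
    d1 = [i for i, (r, x) in enumerate(zip(reference, v1)) if r != x]
    d2 = [i for i, (r, x) in enumerate(zip(reference, v2)) if r != x]
    both = set(d1) & set(d2)
    shared = sorted(i for i in both if v1[i] == v2[i])
    union = set(d1) | set(d2)

    def frac(num: int, den: int):
        return UNDEFINED if den == 0 else 100.0 * num / den

    return SharedVariation(
        derived_1=d1,
        derived_2=d2,
        shared=shared,
        directional_1=frac(len(shared), len(d1)),
        directional_2=frac(len(shared), len(d2)),
        symmetric=frac(len(shared), len(union)),
        loose_shared=sorted(both),
    )


def plot_barcode(report: ComparisonReport, path) -> None:
    """Render the identity barcode as a bar track (one bar per column)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2))
    x = np.arange(report.column_identity.shape[0])
    ax.bar(x, report.column_identity * 100.0, width=1.0, color="black")
    ax.set_xlabel("alignment column")
    ax.set_ylabel("pairwise identity (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
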