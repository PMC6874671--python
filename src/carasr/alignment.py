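"""Gapped amino-acid alignments and the two curation steps applied before
ancestral reconstruction.

An :class:`MSA` is an ordered, column-addressable view of a protein multiple
sequence alignment.  Curation consists of (i) removing insertion columns
supported by at most a handful of leaves and (ii) a Gblocks-style removal of
divergent, poorly conserved blocks.  Both operations preserve the residue
content of every surviving column, so downstream coordinates always map back
to the input alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

#: Amino acids in the order used by PAML-style rate-matrix files.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"
#: Integer codes: 0..19 amino acids (AA_ORDER), 20 gap, 21 unknown.
GAP_CODE = 20
UNKNOWN_CODE = 21

_CODE_OF = {aa: i for i, aa in enumerate(AA_ORDER)}
_CODE_OF[GAP] = GAP_CODE
_CODE_OF[UNKNOWN] = UNKNOWN_CODE
_CHAR_OF = {v: k for k, v in _CODE_OF.items()}


class AlignmentError(ValueError):
    """Raised for malformed or degenerate alignments."""


@dataclass
class MSA:
    """A gapped amino-acid multiple sequence alignment.

    Rows are ordered; residues are uppercase over the 20-letter alphabet plus
    ``-`` (gap) and ``X`` (unknown).  ``provenance`` is a free-text record of
    the filters already applied.
    """

    ids: list[str]
    seqs: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if not self.ids:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if any(not i for i in self.ids):
            raise AlignmentError("empty sequence id")
        n = len(self.seqs[0])
        if n < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != n:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length {len(s)}, expected {n}"
                )
            bad = set(s) - set(AA_ORDER) - {GAP, UNKNOWN}
            if bad:
                pos = min(s.index(c) for c in bad)
                raise AlignmentError(
                    f"illegal residue {s[pos]!r} in sequence {sid!r} at column {pos}"
                )
            if set(s) <= {GAP}:
                raise AlignmentError(f"sequence {sid!r} is all gaps")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """Integer-coded matrix, shape ``(n_rows, n_columns)``."""
        return np.array(
            [[_CODE_OF[c] for c in s] for s in self.seqs], dtype=np.int8
        )

    def row(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    def take_columns(self, cols, note: str = "") -> "MSA":
        """Sub-alignment over the given column indices (order preserved)."""
        cols = list(cols)
        seqs = ["".join(s[j] for j in cols) for s in self.seqs]
        prov = self.provenance + ("\n" if self.provenance and note else "") + note
        return MSA(list(self.ids), seqs, provenance=prov)


def read_fasta_alignment(path) -> MSA:
    """Read a gapped FASTA alignment.

    Residues are uppercased and ``.`` gap characters normalized to ``-``.
    Ragged rows or illegal residue characters raise :class:`AlignmentError`
    naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper().replace(".", GAP) for r in records]
    return MSA(ids, seqs, provenance=f"read from {path}")


def write_fasta_alignment(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for sid, s in zip(msa.ids, msa.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")


def strip_rare_insertion_columns(msa: MSA, max_support: int = 1):
    """Remove insertion columns supported by at most ``max_support`` rows.

    A column is removed when its non-gap residue count is ``<= max_support``
    (``X`` counts as occupancy).  Returns ``(filtered MSA, removed column
    indices)``.  This parameterizes the manual removal of insertions carried
    by one or very few leaves.
    """
    if not (0 <= max_support < msa.n_rows):
        raise ValueError(
            f"max_support must lie in [0, n_rows), got {max_support} for {msa.n_rows} rows"
        )
    codes = msa.codes()
    support = (codes != GAP_CODE).sum(axis=0)
    removed = [j for j in range(msa.n_columns) if support[j] <= max_support]
    if len(removed) == msa.n_columns:
        raise AlignmentError("rare-insertion stripping would remove every column")
    kept = [j for j in range(msa.n_columns) if support[j] > max_support]
    out = msa.take_columns(
        kept, note=f"stripped {len(removed)} insertion columns (max_support={max_support})"
    )
    return out, removed


# ---------------------------------------------------------------------------
# Gblocks-style conserved-block filtering
# ---------------------------------------------------------------------------

NON_CONSERVED = "non-conserved"
CONSERVED = "conserved"
HIGHLY_CONSERVED = "highly-conserved"
GAP_REJECTED = "gap-rejected"


@dataclass
class BlockReport:
    """Where the surviving blocks live in the *input* coordinate system.

    ``kept_intervals`` are 0-based half-open ``(start, end)`` pairs; the
    per-column ``classes`` track uses the input coordinates too.
    """

    kept_intervals: list[tuple[int, int]]
    classes: list[str]
    parameters: dict = field(default_factory=dict)

    @property
    def kept_columns(self) -> list[int]:
        return [j for a, b in self.kept_intervals for j in range(a, b)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(a, b, b - a) for a, b in self.kept_intervals],
            columns=["start", "end", "length"],
        )


def default_min_id_fraction(n_rows: int) -> float:
    """Identity threshold equal to floor(n/2)+1 sequences, as a fraction."""
    return (n_rows // 2 + 1) / n_rows


def _classify_columns(
    codes: np.ndarray,
    min_id_fraction: float,
    high_id_fraction: float,
    allow_gaps: bool,
) -> list[str]:
    n_rows = codes.shape[0]
    min_count = math.ceil(min_id_fraction * n_rows)
    high_count = math.ceil(high_id_fraction * n_rows)
    classes = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        if not allow_gaps and (col == GAP_CODE).any():
            classes.append(GAP_REJECTED)
            continue
        # gaps never count toward identity; X occupies but matches nothing
        residues = col[col < GAP_CODE]
        m = 0
        if residues.size:
            m = int(np.bincount(residues, minlength=20).max())
        if m < min_count:
            classes.append(NON_CONSERVED)
        elif m >= high_count:
            classes.append(HIGHLY_CONSERVED)
        else:
            classes.append(CONSERVED)
    return classes


def gblocks_filter(
    msa: MSA,
    min_id_fraction: float | None = None,
    high_id_fraction: float = 0.85,
    max_nonconserved_run: int = 8,
    min_block_length: int = 10,
    allow_gaps: bool = False,
):
    """Remove divergent blocks, keeping runs of conserved columns.

    Columns are classified by the count ``m`` of their most frequent residue
    (gaps and ``X`` never match): non-conserved when ``m < ceil(min_id * n)``,
    highly conserved when ``m >= ceil(high_id * n)``, conserved otherwise;
    columns containing gaps are rejected outright unless ``allow_gaps``.
    Runs of more than ``max_nonconserved_run`` contiguous non-conserved
    columns are rejected, surviving stretches are trimmed to
    highly-conserved flanks, and blocks shorter than ``min_block_length``
    are dropped.  Defaults mirror the published defaults of the block
    filter (identity threshold of floor(n/2)+1 sequences, 85% for high
    conservation, runs > 8, blocks >= 10, no gaps).

    Returns ``(filtered MSA, BlockReport)``.
    """
    n = msa.n_rows
    if min_id_fraction is None:
        min_id_fraction = default_min_id_fraction(n)
    if not (0 < min_id_fraction <= 1 and 0 < high_id_fraction <= 1):
        raise ValueError("identity fractions must lie in (0, 1]")
    if min_id_fraction >= high_id_fraction:
        raise ValueError("min_id_fraction must be < high_id_fraction")
    if min_block_length < 2:
        raise ValueError("min_block_length must be >= 2")

    codes = msa.codes()
    classes = _classify_columns(codes, min_id_fraction, high_id_fraction, allow_gaps)
    ncol = msa.n_columns
    keep = [c not in (GAP_REJECTED,) for c in classes]

    # reject over-long runs of contiguous non-conserved columns
    j = 0
    while j < ncol:
        if classes[j] == NON_CONSERVED and keep[j]:
            k = j
            while k < ncol and classes[k] == NON_CONSERVED and keep[k]:
                k += 1
            if k - j > max_nonconserved_run:
                for t in range(j, k):
                    keep[t] = False
            j = k
        else:
            j += 1

    # split into candidate blocks at rejected columns, trim each to
    # highly-conserved flanks, then enforce the minimum block length
    intervals: list[tuple[int, int]] = []
    j = 0
    while j < ncol:
        if keep[j]:
            k = j
            while k < ncol and keep[k]:
                k += 1
            a, b = j, k
            while a < b and classes[a] != HIGHLY_CONSERVED:
                a += 1
            while b > a and classes[b - 1] != HIGHLY_CONSERVED:
                b -= 1
            if b - a >= min_block_length:
                intervals.append((a, b))
            j = k
        else:
            j += 1

    report = BlockReport(
        kept_intervals=intervals,
        classes=classes,
        parameters=dict(
            min_id_fraction=min_id_fraction,
            high_id_fraction=high_id_fraction,
            max_nonconserved_run=max_nonconserved_run,
            min_block_length=min_block_length,
            allow_gaps=allow_gaps,
        ),
    )
    if not intervals:
        err = AlignmentError("no alignment block survived divergent-block filtering")
        err.report = report
        raise err
    out = msa.take_columns(
        report.kept_columns,
        note=f"block filter kept {sum(b - a for a, b in intervals)}/{ncol} columns "
        f"({len(intervals)} blocks)",
    )
    return out, report
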