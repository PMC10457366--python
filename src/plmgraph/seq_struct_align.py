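"""Reconcile a full-length sequence with the fragmentary structure sequence.

Experimental structures routinely miss stretches of residues, so the
sequence derived from the coordinates does not match the deposited
full-length (FASTA) sequence.  Two strategies resolve this before
per-residue embeddings are attached to graph nodes:

``fragment``
    Embed the fragmentary structure-derived sequence directly, as a
    substitute for the full sequence (the default, for simplicity).
``align``
    Globally align the full sequence against the structure sequence
    (Needleman-Wunsch, linear gap penalty) and discard full-sequence
    residues that have no structural counterpart; embeddings computed on
    the full sequence are then projected onto the surviving positions.

Mismatch columns (aligned but non-identical letters, e.g. point variants
or 'X' placeholders) are kept in the mapping; only residues absent from
the structure are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .structure_io import SequenceRecord

__all__ = ["Alignment", "SeqStructMapping", "global_align", "reconcile"]

GAP = "-"

_DIAG, _UP, _LEFT = 0, 1, 2  # traceback preference order


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment: equal-length gapped strings + score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings differ in length")
        if any(x == GAP and y == GAP
               for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValidationError("gap-gap column in alignment")

    def columns(self):
        """Iterate (pos_a, pos_b) over match/mismatch columns, 1-based."""
        ia = ib = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x != GAP:
                ia += 1
            if y != GAP:
                ib += 1
            if x != GAP and y != GAP:
                yield ia, ib


@dataclass(frozen=True)
class SeqStructMapping:
    """1-based position pairs (full_seq_pos, struct_pos), both increasing."""

    pairs: tuple[tuple[int, int], ...]
    mode: str

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(map(tuple, self.pairs)))
        fulls = [p[0] for p in self.pairs]
        structs = [p[1] for p in self.pairs]
        if sorted(set(fulls)) != fulls or sorted(set(structs)) != structs:
            raise ValidationError("mapping positions must be strictly increasing")

    def full_positions(self) -> list[int]:
        return [p[0] for p in self.pairs]


def global_align(
    a: str | SequenceRecord,
    b: str | SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Optimal global alignment under a (match, mismatch, linear-gap) score.

    Ties during traceback prefer diagonal over a gap in ``b`` over a gap
    in ``a``, which fixes one canonical alignment among co-optimal ones.
    The score, not the traceback, is the quantity of scientific interest.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValidationError("global_align requires non-empty sequences")

    n, m = len(sa), len(sb)
    F = np.empty((n + 1, m + 1))
    F[0, :] = gap * np.arange(m + 1)
    F[:, 0] = gap * np.arange(n + 1)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr[0, 1:] = _LEFT
    ptr[1:, 0] = _UP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = F[i - 1, j - 1] + (match if sa[i - 1] == sb[j - 1] else mismatch)
            up = F[i - 1, j] + gap
            left = F[i, j - 1] + gap
            # preference on exact ties: diagonal, then up, then left
            best, which = diag, _DIAG
            if up > best:
                best, which = up, _UP
            if left > best:
                best, which = left, _LEFT
            F[i, j] = best
            ptr[i, j] = which

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        which = ptr[i, j]
        if which == _DIAG:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif which == _UP:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(F[n, m]))


def reconcile(
    full_seq: SequenceRecord | str | None,
    struct_seq: SequenceRecord | str,
    mode: str = "fragment",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> SeqStructMapping:
    """Map full-sequence positions onto structure positions.

    ``fragment`` returns the identity mapping over structure positions:
    the fragmentary sequence itself is what gets embedded, and
    ``full_seq`` is ignored downstream.  ``align`` aligns the two and
    keeps the match/mismatch columns, dropping full-sequence residues
    aligned to gaps (those missing from the structure).
    """
    ss = struct_seq.seq if isinstance(struct_seq, SequenceRecord) else struct_seq
    if not ss:
        raise ValidationError("structure sequence is empty")
    if mode == "fragment":
        pairs = tuple((k, k) for k in range(1, len(ss) + 1))
        return SeqStructMapping(pairs=pairs, mode="fragment")
    if mode == "align":
        if full_seq is None:
            raise ValidationError("mode='align' requires the full sequence")
        fs = full_seq.seq if isinstance(full_seq, SequenceRecord) else full_seq
        aln = global_align(fs, ss, match=match, mismatch=mismatch, gap=gap)
        return SeqStructMapping(pairs=tuple(aln.columns()), mode="align")
    raise ConfigError(f"unknown reconciliation mode {mode!r}; "
                      "expected 'fragment' or 'align'")
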