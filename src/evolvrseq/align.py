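"""Glocal alignment of merged reads to the amplicon and allele pileup.

With a single short reference, exhaustive dynamic programming replaces
index-based read mapping: alignments are global in the read and local in the
reference (free reference end gaps), with affine gap costs. A provably
optimal ungapped fast path handles the overwhelming majority of amplicon
reads (substitutions only); everything else falls through to Biopython's
PairwiseAligner configured with the same scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io import AmpliconReference, Read

MAX_PILEUP_DEPTH = 600_000

#: pileup matrix rows
_ROWS = ("A", "C", "G", "T", "del", "ins", "N")
_ROW_INDEX = {b: i for i, b in enumerate(_ROWS)}
_BASE_ROW = np.full(256, -1, dtype=np.int8)
for _b in "ACGT":
    _BASE_ROW[ord(_b)] = _ROW_INDEX[_b]
_BASE_ROW[ord("N")] = _ROW_INDEX["N"]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scores; a gap of length g costs open + g * extend."""

    match: float = 1.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    min_score_fraction: float = 0.4  # floor: score >= fraction * read length


@dataclass
class ReadAlignment:
    """A read placed on the reference.

    ``cigar`` uses run-length ops over {=, X, I, D}: = match, X mismatch,
    I insertion (read-only bases), D deletion (reference-only bases).
    """

    read_id: str
    seq: str
    ref_start: int
    cigar: tuple[tuple[int, str], ...]
    score: float
    aligned: bool

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for n, op in self.cigar if op in "=XD")

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar)

    def has_indel(self) -> bool:
        return any(op in "ID" for _, op in self.cigar)


def _runs(ops: Sequence[str]) -> tuple[tuple[int, str], ...]:
    out: list[tuple[int, str]] = []
    for op in ops:
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + 1, op)
        else:
            out.append((1, op))
    return tuple(out)


@lru_cache(maxsize=8)
def _pairwise_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score for the first gap base; fold one
    # extension in so a length-g gap costs gap_open + g * gap_extend
    a.open_gap_score = scoring.gap_open + scoring.gap_extend
    a.extend_gap_score = scoring.gap_extend
    # free end gaps in the read row = reference flanks outside the read
    a.open_end_deletion_score = 0.0
    a.extend_end_deletion_score = 0.0
    return a


def _ungapped_scan(read_codes: np.ndarray, ref_codes: np.ndarray) -> tuple[int, int]:
    """Best ungapped placement: returns (offset, mismatch count), leftmost on
    ties. N in the read counts as a mismatch."""
    lr, lf = len(read_codes), len(ref_codes)
    n_off = lf - lr + 1
    windows = np.lib.stride_tricks.sliding_window_view(ref_codes, lr)
    mism = (windows != read_codes[None, :]).sum(axis=1)
    best = int(mism.argmin())
    return best, int(mism[best])


def _alignment_from_coordinates(read: Read, reference: AmpliconReference,
                                coords: np.ndarray, score: float) -> ReadAlignment:
    """Convert a Biopython coordinate matrix into a run-length op string."""
    ref_seq, read_seq = reference.seq, read.seq
    ops: list[str] = []
    ref_start = None
    tpos = coords[0]
    qpos = coords[1]
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(tpos[k]), int(tpos[k + 1])
        q0, q1 = int(qpos[k]), int(qpos[k + 1])
        if q0 == q1 and (q0 == 0 or q0 == len(read_seq)):
            continue  # free reference flank
        if ref_start is None:
            ref_start = t0
        if q0 == q1:  # deletion: reference bases absent from the read
            ops.extend("D" * (t1 - t0))
        elif t0 == t1:  # insertion: read bases absent from the reference
            ops.extend("I" * (q1 - q0))
        else:
            for i in range(t1 - t0):
                ops.append("=" if ref_seq[t0 + i] == read_seq[q0 + i] else "X")
    return ReadAlignment(read.id, read.seq, ref_start or 0, _runs(ops), score, True)


def align_read(read: Read, reference: AmpliconReference,
               scoring: Scoring = Scoring()) -> ReadAlignment:
    """Glocal alignment of one read against the amplicon.

    Fast path: when the best ungapped placement's mismatch penalty is no
    larger than the cheapest possible gap, no gapped alignment can beat it,
    so DP is reserved for reads that genuinely may contain indels. Ties are
    resolved leftmost-on-reference, then indel-last. Reads scoring below
    ``min_score_fraction * len(read)`` are flagged unaligned.
    """
    if not len(read):
        raise ValueError("cannot align an empty read")
    ref_codes = np.frombuffer(reference.seq.encode(), dtype=np.uint8)
    read_codes = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    result: ReadAlignment | None = None
    if len(read) <= len(reference):
        offset, mism = _ungapped_scan(read_codes, ref_codes)
        # ungapped is provably optimal when its mismatch penalty cannot
        # exceed the cheapest possible gap: any gapped alignment scores at
        # most L*match + gap_open + gap_extend
        if mism * (scoring.match - scoring.mismatch) <= -(scoring.gap_open + scoring.gap_extend):
            score = (len(read) - mism) * scoring.match + mism * scoring.mismatch
            ops = [
                "=" if a == b else "X"
                for a, b in zip(read_codes, ref_codes[offset : offset + len(read)])
            ]
            result = ReadAlignment(read.id, read.seq, offset, _runs(ops), score, True)
    if result is None:
        aligner = _pairwise_aligner(scoring)
        alignments = aligner.align(reference.seq, read.seq)
        chosen = _pick_alignment(alignments)
        result = _alignment_from_coordinates(read, reference, chosen.coordinates,
                                             float(chosen.score))
    if result.score < scoring.min_score_fraction * len(read):
        result.aligned = False
    return result


def _pick_alignment(alignments, cap: int = 32):
    """Deterministic tie-break among equal-scoring optima: leftmost reference
    start, then fewest gapped columns (indel-last). Enumeration is capped;
    beyond the cap the aligner's first optimum is kept."""
    first = alignments[0]
    try:
        n = len(alignments)
    except OverflowError:
        return first
    if n <= 1:
        return first
    candidates = [alignments[i] for i in range(min(n, cap))]

    def key(al):
        coords = al.coordinates
        qpos = coords[1]
        starts = [
            int(coords[0][k])
            for k in range(coords.shape[1] - 1)
            if not (qpos[k] == qpos[k + 1] and (qpos[k] == 0 or qpos[k] == qpos[-1]))
        ]
        gap_cols = sum(
            abs((int(coords[0][k + 1]) - int(coords[0][k])) - (int(qpos[k + 1]) - int(qpos[k])))
            for k in range(coords.shape[1] - 1)
        )
        return (starts[0] if starts else 0, gap_cols)

    return min(candidates, key=key)


@dataclass
class PileupTable:
    """Per-position allele counts for one sample.

    ``counts`` is a (7, L) matrix over rows A, C, G, T, del, ins, N. Depth
    is A+C+G+T+del; N and insertion starts are tallied but excluded from
    depth. The depth cap is applied in input order, matching a deterministic
    upstream read order.
    """

    sample_id: str
    reference: AmpliconReference
    counts: np.ndarray
    max_depth: int = MAX_PILEUP_DEPTH

    @property
    def depth(self) -> np.ndarray:
        return self.counts[:5].sum(axis=0)

    def base_count(self, base: str) -> np.ndarray:
        return self.counts[_ROW_INDEX[base]]

    @property
    def ref_count(self) -> np.ndarray:
        ref_rows = _BASE_ROW[np.frombuffer(self.reference.seq.encode(), dtype=np.uint8)]
        return self.counts[ref_rows, np.arange(len(self.reference))]

    def to_frame(self) -> pd.DataFrame:
        length = len(self.reference)
        df = pd.DataFrame({"position": np.arange(1, length + 1),
                           "ref": list(self.reference.seq)})
        for row in _ROWS:
            df[row] = self.counts[_ROW_INDEX[row]]
        df["depth"] = self.depth
        return df


def pileup(alignments: Iterable[ReadAlignment], reference: AmpliconReference,
           max_depth: int = MAX_PILEUP_DEPTH, weights: Iterable[int] | None = None,
           sample_id: str = "sample") -> PileupTable:
    """Accumulate aligned reads into per-position allele counts.

    ``weights`` lets deduplicated reads contribute their multiplicity; the
    per-position depth cap is honored in input order (a read's contribution
    at a saturated position is truncated). Insertions count at the reference
    position following their anchor; N bases are excluded from depth.
    """
    import itertools

    length = len(reference)
    counts = np.zeros((7, length), dtype=np.int64)
    depth = counts[:5]
    n_row = _ROW_INDEX["N"]
    if weights is None:
        weights = itertools.repeat(1)
    for aln, w in zip(alignments, weights):
        if not aln.aligned:
            continue
        rp = aln.ref_start
        qp = 0
        for n, op in aln.cigar:
            if op in "=X":
                pos = np.arange(rp, rp + n)
                rows = _BASE_ROW[np.frombuffer(aln.seq[qp : qp + n].encode(),
                                               dtype=np.uint8)]
                keep = rows >= 0
                pos, rows = pos[keep], rows[keep]
                is_n = rows == n_row
                np.add.at(counts, (rows[is_n], pos[is_n]), w)
                pos_b, rows_b = pos[~is_n], rows[~is_n]
                room = max_depth - depth[:, pos_b].sum(axis=0)
                add = np.clip(np.minimum(w, room), 0, None)
                np.add.at(counts, (rows_b, pos_b), add)
                rp += n
                qp += n
            elif op == "D":
                pos = np.arange(rp, rp + n)
                room = max_depth - depth[:, pos].sum(axis=0)
                add = np.clip(np.minimum(w, room), 0, None)
                np.add.at(counts, (np.full(n, _ROW_INDEX["del"]), pos), add)
                rp += n
            elif op == "I":
                if rp < length:
                    counts[_ROW_INDEX["ins"], rp] += w
                qp += n
    return PileupTable(sample_id, reference, counts, max_depth)


def pileup_deduplicated(seq_counts: dict[str, int], reference: AmpliconReference,
                        scoring: Scoring = Scoring(),
                        max_depth: int = MAX_PILEUP_DEPTH,
                        sample_id: str = "sample") -> tuple[PileupTable, dict[str, ReadAlignment]]:
    """Align each distinct read sequence once and pile up with multiplicity.

    Sequences are processed in descending count then lexicographic order so
    the depth cap is deterministic. Returns the pileup and the per-sequence
    alignments (for read-level analysis downstream).
    """
    order = sorted(seq_counts, key=lambda s: (-seq_counts[s], s))
    alignments: dict[str, ReadAlignment] = {}
    for seq in order:
        alignments[seq] = align_read(Read("u", seq, np.zeros(len(seq), dtype=np.int16)),
                                     reference, scoring)
    table = pileup((alignments[s] for s in order), reference, max_depth=max_depth,
                   weights=(seq_counts[s] for s in order), sample_id=sample_id)
    return table, alignments
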