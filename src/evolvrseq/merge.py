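"""Merge fully overlapping complementary paired-end reads.

The amplicon is short enough that R1 and the reverse complement of R2 span
it jointly; merging scans every relative placement of the two reads and
accepts the largest perfectly matching overlap (by default zero mismatches
are tolerated, N matches nothing). A tie between two distinct placements of
equal maximal overlap is rejected as ambiguous rather than resolved
arbitrarily: under a zero-mismatch policy such a tie signals repetitive
sequence, and a silent choice would bias downstream pileups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .io import MAX_QUAL, Read, revcomp, read_fastq, write_fastq

REJECT_NO_OVERLAP = "no_perfect_overlap"
REJECT_TOO_SHORT = "too_short"
REJECT_AMBIGUOUS = "ambiguous"


@dataclass
class MergeResult:
    status: str  # "merged" | "rejected"
    merged: Read | None = None
    overlap_len: int = 0
    reject_reason: str | None = None


@dataclass
class MergeStats:
    """Per-file merge bookkeeping: every pair is accounted for."""

    total: int = 0
    merged: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)

    def record(self, result: MergeResult) -> None:
        self.total += 1
        if result.status == "merged":
            self.merged += 1
        else:
            reason = result.reject_reason or "unknown"
            self.rejected_by_reason[reason] = self.rejected_by_reason.get(reason, 0) + 1

    @property
    def rejected(self) -> int:
        return self.total - self.merged

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "total_pairs", "count": self.total},
            {"metric": "merged", "count": self.merged},
        ]
        for reason in sorted(self.rejected_by_reason):
            rows.append(
                {"metric": f"rejected_{reason}", "count": self.rejected_by_reason[reason]}
            )
        return pd.DataFrame(rows)


def _mismatches(a: bytes, b: bytes) -> int:
    """Mismatch count between equal-length byte strings; N never matches."""
    if a == b and b"N" not in a:
        return 0
    x = np.frombuffer(a, dtype=np.uint8)
    y = np.frombuffer(b, dtype=np.uint8)
    return int(np.count_nonzero((x != y) | (x == ord("N")) | (y == ord("N"))))


from functools import lru_cache


@lru_cache(maxsize=64)
def _offset_scan_order(n1: int, n2: int, min_overlap: int) -> tuple[tuple[int, int], ...]:
    """(offset, overlap) pairs sorted by decreasing overlap, then offset."""
    pairs = [
        (o, min(n1, o + n2) - max(0, o))
        for o in range(-(n2 - min_overlap), n1 - min_overlap + 1)
    ]
    pairs = [(o, ov) for o, ov in pairs if ov >= min_overlap]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return tuple(pairs)


def merge_pair(r1: Read, r2: Read, min_overlap: int = 20, max_mismatch: int = 0,
               max_qual: int = MAX_QUAL) -> MergeResult:
    """Merge one read pair via exhaustive overlap-offset scan.

    R2 is reverse complemented; an offset (position of R2' start relative to
    R1 start) is valid when its overlap has at most ``max_mismatch``
    mismatching bases (N counts as a mismatch). Among valid offsets the
    largest overlap wins; equal maximal overlaps at two distinct offsets are
    rejected as ambiguous. In the merged read, overlap qualities are the
    per-base maximum of the two reads (capped at ``max_qual``); outside the
    overlap qualities carry through. Dovetail placements (reads running past
    each other) are trimmed to the fragment span.
    """
    if not len(r1) or not len(r2):
        return MergeResult("rejected", reject_reason=REJECT_TOO_SHORT)
    rc2 = revcomp(r2.seq)
    q2 = r2.qual[::-1]
    b1 = r1.seq.encode()
    b2 = rc2.encode()
    n1, n2 = len(b1), len(b2)
    has_n = b"N" in b1 or b"N" in b2
    exact_only = max_mismatch == 0 and not has_n
    best: tuple[int, int] | None = None  # (offset, overlap)
    # offsets sorted by decreasing overlap; within a tie, left to right
    for o, ov in _offset_scan_order(n1, n2, min_overlap):
        if best is not None and ov < best[1]:
            break
        lo = max(0, o)
        sa = b1[lo : lo + ov]
        sb = b2[lo - o : lo - o + ov]
        ok = sa == sb if exact_only else _mismatches(sa, sb) <= max_mismatch
        if ok:
            if best is not None:  # same overlap length at a distinct offset
                return MergeResult("rejected", overlap_len=ov, reject_reason=REJECT_AMBIGUOUS)
            best = (o, ov)
    if best is None:
        return MergeResult("rejected", reject_reason=REJECT_NO_OVERLAP)
    o, ov = best
    lo = max(0, o)
    s1 = np.frombuffer(b1, dtype=np.uint8)
    s2 = np.frombuffer(b2, dtype=np.uint8)
    ov1 = s1[lo : lo + ov]
    ov2 = s2[lo - o : lo - o + ov]
    q_ov1 = r1.qual[lo : lo + ov]
    q_ov2 = q2[lo - o : lo - o + ov]
    # at agreeing bases either read's base works; at tolerated mismatches
    # take the higher-quality call
    take2 = q_ov2 > q_ov1
    cons_seq = np.where(take2, ov2, ov1)
    cons_qual = np.minimum(np.maximum(q_ov1, q_ov2), max_qual)
    if o >= 0:
        seq = np.concatenate([s1[:lo], cons_seq, s2[lo - o + ov :]])
        qual = np.concatenate([r1.qual[:lo], cons_qual, q2[lo - o + ov :]])
    else:  # dovetail: the fragment is the overlap region only
        seq = cons_seq
        qual = cons_qual
    merged = Read(r1.id, seq.tobytes().decode(), qual)
    return MergeResult("merged", merged=merged, overlap_len=ov)


def _pair_key(read_id: str) -> str:
    return read_id.rsplit("/", 1)[0]


def merge_pairs(pairs: Iterable[tuple[Read, Read]], min_overlap: int = 20,
                max_mismatch: int = 0, stats: MergeStats | None = None) -> Iterator[Read]:
    """Merge a stream of synchronized read pairs, yielding merged reads in
    input order; rejections are tallied in ``stats``."""
    stats = stats if stats is not None else MergeStats()
    for r1, r2 in pairs:
        if _pair_key(r1.id) != _pair_key(r2.id):
            raise ValueError(
                f"desynchronized pair: {r1.id!r} vs {r2.id!r}"
            )
        res = merge_pair(r1, r2, min_overlap=min_overlap, max_mismatch=max_mismatch)
        stats.record(res)
        if res.status == "merged":
            yield res.merged


def merge_files(fastq_r1, fastq_r2, merged_out, min_overlap: int = 20,
                max_mismatch: int = 0) -> MergeStats:
    """Merge two pair-synchronized FASTQ files into one merged FASTQ."""
    stats = MergeStats()
    pairs = zip(read_fastq(fastq_r1), read_fastq(fastq_r2), strict=True)
    write_fastq(
        merge_pairs(pairs, min_overlap=min_overlap, max_mismatch=max_mismatch, stats=stats),
        merged_out,
    )
    return stats
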