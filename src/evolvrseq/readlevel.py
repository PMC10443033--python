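"""Read-level diversity: unique-read tallies, Hamming spectra, substitution
spectra.

Merged, aligned reads are projected onto the targeted window and tallied as
unique strings. Reads carrying indels are identified and removed by the
Hamming-vs-edit-distance discrepancy: an indel shows up either as a length
change or as an edit (Levenshtein) distance strictly below the Hamming
distance (compensating insertion + deletion). Surviving reads are filtered
by occurrence count, purged of haplotypes already common in the parental
control, normalized by mean read depth, and summarized as a Hamming-distance
spectrum and a 12-category transition/transversion spectrum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

from .align import ReadAlignment
from .io import AmpliconReference

#: The 12 ordered substitution categories; transitions are A>G, G>A, C>T, T>C.
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})

MIN_OCCURRENCE = 5


def hamming_distance(a: str, b: str) -> int | None:
    """Positionwise mismatch count; undefined (None) for unequal lengths."""
    if len(a) != len(b):
        return None
    if a == b:
        return 0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return int(np.count_nonzero(x != y))


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (substitution, insertion, deletion)."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def trim_to_window(alignment: ReadAlignment, reference: AmpliconReference,
                   window: tuple[int, int] | None = None) -> str | None:
    """Project a read's aligned bases onto reference window coordinates.

    Returns the windowed read string, or None when the alignment does not
    fully span the window (such reads are dropped and counted by the
    caller). Deletions shorten the projected string; insertions anchored
    strictly inside the window lengthen it.
    """
    lo, hi = window or reference.window
    if not alignment.aligned or alignment.ref_start > lo or alignment.ref_end < hi:
        return None
    out: list[str] = []
    rp = alignment.ref_start
    qp = 0
    for n, op in alignment.cigar:
        if op in "=X":
            seg_lo, seg_hi = max(rp, lo), min(rp + n, hi)
            if seg_lo < seg_hi:
                out.append(alignment.seq[qp + (seg_lo - rp) : qp + (seg_hi - rp)])
            rp += n
            qp += n
        elif op == "D":
            rp += n
        elif op == "I":
            if lo < rp < hi:
                out.append(alignment.seq[qp : qp + n])
            qp += n
    return "".join(out)


@dataclass
class UniqueReadTable:
    """Tally of unique windowed read strings for one sample.

    Backed by a DataFrame with columns ``seq``, ``count``, ``hamming``
    (nullable: undefined for length changes), ``edit``, ``has_indel`` and,
    after normalization, ``normalized_abundance``.
    """

    reference_window: str
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_reads(self) -> int:
        return int(self.frame["count"].sum())

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], reference_window: str) -> "UniqueReadTable":
        seqs = sorted(counts, key=lambda s: (-counts[s], s))
        frame = pd.DataFrame({"seq": seqs, "count": [counts[s] for s in seqs]})
        return cls(reference_window, frame)

    @classmethod
    def tally(cls, windowed_reads: Iterable[str], reference_window: str) -> "UniqueReadTable":
        return cls.from_counts(Counter(windowed_reads), reference_window)


def flag_indels(table: UniqueReadTable) -> UniqueReadTable:
    """Compute Hamming/edit distances and set the ``has_indel`` flag.

    A read contains an indel iff its length differs from the reference
    window or its edit distance is strictly below its Hamming distance.
    """
    ref = table.reference_window
    hamming: list[object] = []
    edit: list[int] = []
    indel: list[bool] = []
    for seq in table.frame["seq"]:
        h = hamming_distance(seq, ref)
        e = edit_distance(seq, ref)
        hamming.append(h if h is not None else pd.NA)
        edit.append(e)
        indel.append(h is None or e < h)
    frame = table.frame.copy()
    frame["hamming"] = pd.array(hamming, dtype="Int64")
    frame["edit"] = edit
    frame["has_indel"] = indel
    return UniqueReadTable(ref, frame)


def remove_indel_reads(table: UniqueReadTable) -> tuple[UniqueReadTable, int]:
    """Drop indel-flagged rows; returns the filtered table and the number of
    reads (not rows) removed, for the run log."""
    if "has_indel" not in table.frame.columns:
        table = flag_indels(table)
    removed = int(table.frame.loc[table.frame["has_indel"], "count"].sum())
    frame = table.frame.loc[~table.frame["has_indel"]].reset_index(drop=True)
    return UniqueReadTable(table.reference_window, frame), removed


def filter_occurrence(table: UniqueReadTable, min_count: int = MIN_OCCURRENCE) -> UniqueReadTable:
    """Keep unique reads observed at least ``min_count`` times."""
    frame = table.frame.loc[table.frame["count"] >= min_count].reset_index(drop=True)
    return UniqueReadTable(table.reference_window, frame)


def subtract_parental_reads(table: UniqueReadTable, parental: UniqueReadTable,
                            min_count: int = MIN_OCCURRENCE) -> UniqueReadTable:
    """Remove read strings that are established in the parental control.

    Any unique read with raw occurrence >= ``min_count`` in the parental
    table (the threshold is an occurrence count, so raw counts are used) is
    dropped from the treated table, reference-identical reads included.
    """
    common = set(
        parental.frame.loc[parental.frame["count"] >= min_count, "seq"]
    )
    frame = table.frame.loc[~table.frame["seq"].isin(common)].reset_index(drop=True)
    return UniqueReadTable(table.reference_window, frame)


def read_substitutions(seq: str, ref_window: str) -> list[tuple[int, str, str]]:
    """Positionwise substitutions of an indel-free windowed read
    (position offsets are window-relative)."""
    return [
        (i, r, a)
        for i, (r, a) in enumerate(zip(ref_window, seq))
        if r != a and a != "N"
    ]


@dataclass
class SubstitutionSpectrum:
    """Counts over the 12 ordered ref>alt substitution categories."""

    counts: dict[str, int] = field(default_factory=lambda: {t: 0 for t in SUBSTITUTION_TYPES})

    def add(self, ref: str, alt: str, weight: int = 1) -> None:
        self.counts[f"{ref}>{alt}"] += weight

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, subst_type: str) -> float:
        return self.counts[subst_type] / self.total if self.total else 0.0

    @property
    def transition_fraction(self) -> float:
        ts = sum(v for k, v in self.counts.items() if k in TRANSITIONS)
        return ts / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substitution": list(SUBSTITUTION_TYPES),
                "count": [self.counts[t] for t in SUBSTITUTION_TYPES],
                "transition": [t in TRANSITIONS for t in SUBSTITUTION_TYPES],
            }
        )


@dataclass
class SpectrumSummary:
    """Diversity summaries of a unique-read table.

    ``hamming_spectrum`` maps Hamming distance to depth-normalized
    abundance; ``fraction_mutated`` is the fraction of reads (post indel
    removal and occurrence filtering) carrying at least one substitution;
    ``mean_hamming`` is the count-weighted mean distance over those reads.
    """

    hamming_spectrum: dict[int, float]
    substitution_spectrum: SubstitutionSpectrum
    fraction_mutated: float
    mean_hamming: float
    table: UniqueReadTable

    def hamming_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hamming": sorted(self.hamming_spectrum),
                "normalized_abundance": [
                    self.hamming_spectrum[h] for h in sorted(self.hamming_spectrum)
                ],
            }
        )


def normalize_and_spectrum(table: UniqueReadTable, mean_depth: float) -> SpectrumSummary:
    """Normalize unique-read counts by depth and build both spectra.

    Expects an indel-free table (flag and remove first). Substitutions are
    obtained by positionwise comparison to the reference window, valid
    precisely because indel-bearing reads were removed.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if "has_indel" not in table.frame.columns:
        table = flag_indels(table)
    if bool(table.frame["has_indel"].any()):
        raise ValueError("table still contains indel-flagged reads")
    frame = table.frame.copy()
    frame["normalized_abundance"] = frame["count"] / mean_depth
    spectrum: dict[int, float] = {}
    subst = SubstitutionSpectrum()
    total = int(frame["count"].sum())
    mutated = 0
    weighted_distance = 0
    for row in frame.itertuples():
        h = int(row.hamming)
        spectrum[h] = spectrum.get(h, 0.0) + row.normalized_abundance
        weighted_distance += h * row.count
        if h > 0:
            mutated += row.count
            for _, ref, alt in read_substitutions(row.seq, table.reference_window):
                subst.add(ref, alt, weight=row.count)
    return SpectrumSummary(
        hamming_spectrum=spectrum,
        substitution_spectrum=subst,
        fraction_mutated=mutated / total if total else 0.0,
        mean_hamming=weighted_distance / total if total else 0.0,
        table=UniqueReadTable(table.reference_window, frame),
    )
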