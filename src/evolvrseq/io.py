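"""Domain types and plain-text readers/writers shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere inside the package; 1-based
inclusive positions appear only in written reports. Phred qualities use
offset 33 on disk and are capped at 40 on input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np
import pandas as pd

QUAL_OFFSET = 33
MAX_QUAL = 40

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PathLike = Union[str, Path]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record, naming the offending record."""


@dataclass
class Read:
    """A sequencing read: sequence over {A,C,G,T,N} plus per-base phred scores."""

    id: str
    seq: str
    qual: np.ndarray  # int array, values in [0, MAX_QUAL]

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise FastqParseError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AmpliconReference:
    """Single amplicon reference with the targeted mutagenesis window.

    ``window`` is a half-open 0-based interval on the reference marking the
    stretch flanked by the guide sites in which diversity is quantified.
    """

    name: str
    seq: str
    window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(f"reference {self.name!r} contains non-ACGT bases: {bad}")
        start, end = self.window
        if self.window == (0, 0):
            object.__setattr__(self, "window", (0, len(seq)))
        elif not (0 <= start < end <= len(seq)):
            raise ValueError(f"window {self.window} invalid for length {len(seq)}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def window_seq(self) -> str:
        return self.seq[self.window[0] : self.window[1]]


@dataclass(frozen=True)
class SampleMeta:
    """Sample-sheet row: who was sequenced and which parental control applies."""

    sample_id: str
    role: str  # "treated" or "parental"
    genotype: str  # free tag, e.g. "WT" or "msh6d"
    replicate: int = 1
    guides: tuple[str, ...] = ()
    fastq_r1: str = ""
    fastq_r2: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("treated", "parental"):
            raise ValueError(f"sample {self.sample_id!r}: role must be treated|parental")


@dataclass(frozen=True)
class CfuRecord:
    """Colony counts for one reversion-assay plate pair.

    Dilution factors scale each raw plate count back to the common culture
    volume; the selectable count can never exceed the corrected total.
    """

    sample_id: str
    selective_cfu: float
    total_cfu: float
    selective_dilution: float = 1.0
    total_dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.selective_cfu < 0:
            raise ValueError("selective_cfu must be nonnegative")
        if self.total_cfu <= 0:
            raise ValueError("total_cfu must be positive")
        if self.corrected_selective > self.corrected_total:
            raise ValueError(
                f"sample {self.sample_id!r}: corrected selective count exceeds total"
            )

    @property
    def corrected_selective(self) -> float:
        return self.selective_cfu * self.selective_dilution

    @property
    def corrected_total(self) -> float:
        return self.total_cfu * self.total_dilution


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def decode_quals(qual_line: str, offset: int = QUAL_OFFSET, max_qual: int = MAX_QUAL) -> np.ndarray:
    """Decode an ASCII quality string, clamping scores above ``max_qual``."""
    q = np.frombuffer(qual_line.encode("ascii"), dtype=np.uint8).astype(np.int16) - offset
    if (q < 0).any():
        raise FastqParseError(f"quality character below offset {offset} in {qual_line!r}")
    return np.minimum(q, max_qual)


def encode_quals(quals: Sequence[int], offset: int = QUAL_OFFSET) -> str:
    return "".join(chr(int(q) + offset) for q in quals)


def read_fastq(path: PathLike) -> Iterator[Read]:
    """Stream reads from a 4-line-per-record phred+33 FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqParseError(f"malformed FASTQ record at {header!r}")
            rid = header[1:].split()[0]
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"read {rid!r}: sequence and quality lines differ in length"
                )
            yield Read(rid, seq.upper(), decode_quals(qual))


def write_fastq(reads: Iterable[Read], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{encode_quals(r.qual)}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike, window: tuple[int, int] | None = None) -> AmpliconReference:
    """Load the single-amplicon reference; multi-record files are rejected."""
    names, seqs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                names.append(line[1:].split()[0])
                seqs.append([])
            elif line:
                if not names:
                    raise ValueError(f"{path}: sequence before FASTA header")
                seqs[-1].append(line)
    if len(names) != 1:
        raise ValueError(
            f"{path}: expected exactly one reference record, found {len(names)}"
        )
    seq = "".join(seqs[0]).upper()
    return AmpliconReference(names[0], seq, window or (0, 0))


def write_fasta(reference: AmpliconReference, path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{reference.name}\n")
        for i in range(0, len(reference.seq), width):
            fh.write(reference.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: PathLike, sort_by: str | list[str] | None = None,
                float_digits: int = 6) -> None:
    """Write a TSV with a deterministic row order and fixed float rendering.

    ``sort_by`` defaults to the first column (the table's primary key).
    """
    df = rows.copy()
    if sort_by is None and len(df.columns):
        sort_by = df.columns[0]
    if sort_by is not None and len(df):
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sample_sheet(path: PathLike) -> list[SampleMeta]:
    """Parse the TSV sample sheet and check parental coverage per genotype.

    Every treated sample must have at least one parental sample of the same
    genotype available for background subtraction.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    samples = []
    for _, row in df.iterrows():
        guides = tuple(g for g in str(row.get("guides", "")).split(",") if g)
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"],
                role=row["role"],
                genotype=row["genotype"],
                replicate=int(row.get("replicate", 1) or 1),
                guides=guides,
                fastq_r1=row.get("fastq_r1", ""),
                fastq_r2=row.get("fastq_r2", ""),
            )
        )
    parental_genotypes = {s.genotype for s in samples if s.role == "parental"}
    for s in samples:
        if s.role == "treated" and s.genotype not in parental_genotypes:
            raise ValueError(
                f"treated sample {s.sample_id!r} (genotype {s.genotype!r}) has no "
                "parental control of matching genotype"
            )
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: PathLike) -> None:
    rows = []
    for s in samples:
        d = dataclasses.asdict(s)
        d["guides"] = ",".join(s.guides)
        rows.append(d)
    write_table(pd.DataFrame(rows), path, sort_by="sample_id")


def read_cfu_table(path: PathLike) -> list[CfuRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            CfuRecord(
                sample_id=str(row["sample_id"]),
                selective_cfu=float(row["selective_cfu"]),
                total_cfu=float(row["total_cfu"]),
                selective_dilution=float(row.get("selective_dilution", 1.0)),
                total_dilution=float(row.get("total_dilution", 1.0)),
            )
        )
    return records


def to_report_positions(positions: np.ndarray | Sequence[int]) -> np.ndarray:
    """Convert internal 0-based positions to 1-based report positions."""
    return np.asarray(positions) + 1


def from_report_positions(positions: np.ndarray | Sequence[int]) -> np.ndarray:
    """Inverse of :func:`to_report_positions`."""
    return np.asarray(positions) - 1
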