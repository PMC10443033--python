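"""Forward simulator for nickase-guided error-prone polymerase mutagenesis.

The model: a Cas9 nickase variant (D10A or H840A) nicks one strand at a
guide-determined site; an error-prone polymerase extends from the nick 5'->3'
along the nicked strand, leaving templated mismatches that become substitutions
when they escape mismatch repair. Substitution probability peaks at the base
adjacent to the nick in the direction of synthesis and decays exponentially
over a ~40 bp forward window; a weaker mirrored footprint covers a ~15 bp
window in the opposite direction. Multiple guides combine as independent
events, with an optional synergy factor for opposite-strand nick pairs that
emulates double-strand-break formation. A uniform per-base background rate
stands in for untargeted mutation plus library noise.

Simulated molecules are sequenced as 2 x ``read_len`` paired-end reads that
fully span the amplicon, so downstream merging can reconstruct each molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import MAX_QUAL, AmpliconReference, Read, revcomp

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
# ASCII code -> 0..3 index (A=0 C=1 G=2 T=3)
_CODE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_INDEX[_b] = _i
_COMPLEMENT_CODE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_CODE[_a] = _b


class GuideValidationError(ValueError):
    """Guide does not match the reference (spacer mismatch or non-NGG PAM)."""


@dataclass(frozen=True)
class GuideSpec:
    """A 20-nt spacer with its protospacer strand and PAM location.

    ``pam_start`` is the 0-based reference coordinate of the first PAM base
    *on the protospacer strand*: for a ``+`` guide the PAM occupies reference
    ``[pam_start, pam_start+3)``; for a ``-`` guide it occupies reference
    ``[pam_start-2, pam_start+1)`` read on the minus strand.
    """

    name: str
    spacer: str
    strand: str  # '+' or '-'
    pam_start: int

    def protospacer_interval(self) -> tuple[int, int]:
        """Reference interval [start, end) occupied by the protospacer."""
        if self.strand == "+":
            return self.pam_start - 20, self.pam_start
        return self.pam_start + 1, self.pam_start + 21

    def validate(self, reference: AmpliconReference) -> None:
        if self.strand not in "+-":
            raise GuideValidationError(f"guide {self.name!r}: strand must be + or -")
        if len(self.spacer) != 20:
            raise GuideValidationError(f"guide {self.name!r}: spacer must be 20 nt")
        start, end = self.protospacer_interval()
        ref = reference.seq
        if self.strand == "+":
            if not (0 <= start and self.pam_start + 3 <= len(ref)):
                raise GuideValidationError(f"guide {self.name!r}: out of reference bounds")
            observed = ref[start:end]
            pam = ref[self.pam_start : self.pam_start + 3]
        else:
            if not (self.pam_start - 2 >= 0 and end <= len(ref)):
                raise GuideValidationError(f"guide {self.name!r}: out of reference bounds")
            observed = revcomp(ref[start:end])
            pam = revcomp(ref[self.pam_start - 2 : self.pam_start + 1])
        if observed != self.spacer.upper():
            raise GuideValidationError(
                f"guide {self.name!r}: spacer does not match reference on {self.strand} strand"
            )
        if pam[1:] != "GG":
            raise GuideValidationError(f"guide {self.name!r}: PAM {pam!r} is not NGG")


@dataclass(frozen=True)
class NickSpec:
    """A single-strand nick: between-base position, strand, synthesis direction.

    The nick lies between reference positions ``nick_pos - 1`` and
    ``nick_pos``; ``direction`` is the polymerase synthesis direction
    (5'->3' along the nicked strand) expressed on the reference axis.
    """

    nick_pos: int
    nicked_strand: str  # '+' or '-'
    direction: int  # +1 or -1

    def first_base(self) -> int:
        """Reference position of the first base adjacent to the nick in the
        direction of polymerase activity (the most mutable base)."""
        return self.nick_pos if self.direction == 1 else self.nick_pos - 1


#: Canonical SpCas9 blunt-cut geometry: the nick falls between protospacer
#: bases 17 and 18, i.e. 3 nt 5' of the PAM. Configurable for other effectors.
CUT_OFFSET_FROM_PAM = 3


def find_nick(reference: AmpliconReference, guide: GuideSpec, variant: str,
              cut_offset: int = CUT_OFFSET_FROM_PAM) -> NickSpec:
    """Locate the nick produced by a nickase variant acting at a guide site.

    D10A (RuvC-dead) nicks the strand complementary to the gRNA, i.e. the
    strand opposite the protospacer; H840A (HNH-dead) nicks the protospacer
    strand itself. Synthesis proceeds 5'->3' along the nicked strand.
    """
    guide.validate(reference)
    if variant not in ("D10A", "H840A"):
        raise ValueError(f"unknown nickase variant {variant!r}")
    if guide.strand == "+":
        nick_pos = guide.pam_start - cut_offset
    else:
        nick_pos = guide.pam_start + cut_offset + 1
    if variant == "H840A":
        nicked = guide.strand
    else:
        nicked = "-" if guide.strand == "+" else "+"
    direction = 1 if nicked == "+" else -1
    if not (0 < nick_pos < len(reference)):
        raise GuideValidationError(
            f"guide {guide.name!r}: nick position {nick_pos} outside reference"
        )
    return NickSpec(nick_pos=nick_pos, nicked_strand=nicked, direction=direction)


def uniform_subst_matrix() -> np.ndarray:
    """Row-stochastic 4x4 substitution-identity matrix, uniform over the
    three non-reference bases (zero diagonal)."""
    m = np.full((4, 4), 1 / 3)
    np.fill_diagonal(m, 0.0)
    return m


def biased_subst_matrix(ref_base: str, alt_base: str, weight: float) -> np.ndarray:
    """Uniform matrix with the ``ref_base`` row reweighted so that
    ``ref->alt`` receives probability ``weight`` (rest split evenly)."""
    m = uniform_subst_matrix()
    i, j = BASES.index(ref_base), BASES.index(alt_base)
    row = np.full(4, (1 - weight) / 2)
    row[i] = 0.0
    row[j] = weight
    m[i] = row
    return m


@dataclass
class MutagenesisProfile:
    """Shape of the per-nick mutational footprint.

    peak_rate
        Per-molecule substitution probability at the base adjacent to the
        nick in the direction of activity.
    fwd_window, rev_window
        Footprint lengths (bp) in the synthesis direction and opposite it.
    decay
        Exponential fall-off rate per bp within each window.
    rev_fraction
        Peak of the opposite-direction footprint relative to ``peak_rate``;
        the opposite-direction increase is reported as smaller but is not
        quantified, so this is a model knob.
    subst_matrix
        Row-stochastic 4x4 matrix of substitution identities (zero diagonal).
    """

    peak_rate: float = 0.02
    fwd_window: int = 40
    rev_window: int = 15
    decay: float = 0.1
    rev_fraction: float = 0.25
    subst_matrix: np.ndarray = field(default_factory=uniform_subst_matrix)

    def __post_init__(self) -> None:
        self.subst_matrix = np.asarray(self.subst_matrix, dtype=float)
        if not (0.0 <= self.peak_rate <= 1.0):
            raise ValueError("peak_rate must be in [0, 1]")
        if self.fwd_window < 0 or self.rev_window < 0:
            raise ValueError("window lengths must be nonnegative")
        if self.subst_matrix.shape != (4, 4):
            raise ValueError("subst_matrix must be 4x4")
        if not np.allclose(np.diag(self.subst_matrix), 0.0):
            raise ValueError("subst_matrix diagonal must be zero")
        if not np.allclose(self.subst_matrix.sum(axis=1), 1.0):
            raise ValueError("subst_matrix rows must sum to 1")


@dataclass
class RepairModel:
    """Mismatch-repair escape model plus uniform background.

    ``escape_prob`` is the probability a templated mismatch survives repair;
    ``msh6_multiplier`` scales it (and the background) in MMR-deficient
    (msh6 deletion) genotypes; ``background_rate`` is the per-base
    per-molecule probability of an untargeted mutation.
    """

    escape_prob: float = 0.5
    msh6_multiplier: float = 1.5
    background_rate: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("escape_prob", "background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.msh6_multiplier < 1.0:
            raise ValueError("msh6_multiplier must be >= 1")


def is_mmr_deficient(genotype: str) -> bool:
    """MMR-deficient genotypes are tagged with 'msh6' (e.g. 'msh6d')."""
    return "msh6" in genotype.lower()


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth substitutions carried by one simulated molecule."""

    molecule_id: str
    substitutions: tuple[tuple[int, str, str], ...]  # (position, ref, alt)


def _nick_profile(nick: NickSpec, model: MutagenesisProfile, length: int) -> np.ndarray:
    """Per-position substitution probability contributed by a single nick."""
    p = np.zeros(length)
    d = np.arange(max(model.fwd_window, model.rev_window))
    fwd = model.peak_rate * np.exp(-model.decay * d[: model.fwd_window])
    rev = model.peak_rate * model.rev_fraction * np.exp(-model.decay * d[: model.rev_window])
    if nick.direction == 1:
        fwd_pos = nick.nick_pos + d[: model.fwd_window]
        rev_pos = nick.nick_pos - 1 - d[: model.rev_window]
    else:
        fwd_pos = nick.nick_pos - 1 - d[: model.fwd_window]
        rev_pos = nick.nick_pos + d[: model.rev_window]
    for pos, val in ((fwd_pos, fwd), (rev_pos, rev)):
        ok = (pos >= 0) & (pos < length)
        p[pos[ok]] = val[ok]
    return p


def build_position_profile(reference: AmpliconReference, nicks: Sequence[NickSpec],
                           model: MutagenesisProfile, repair: RepairModel,
                           genotype: str = "WT", dsb_synergy: float = 1.0,
                           dsb_distance: int = 100) -> np.ndarray:
    """Combine per-nick footprints into a per-position substitution probability.

    Nicks act as independent events (probability union); when ``dsb_synergy``
    exceeds 1 and two nicks on opposite strands lie within ``dsb_distance``
    bp, the combined nick-derived probability is multiplied by it, emulating
    the elevated mutagenicity of double-strand-break repair. The result is
    scaled by the repair-escape probability and the background is added;
    MMR-deficient genotypes scale both by ``msh6_multiplier``.
    """
    length = len(reference)
    no_hit = np.ones(length)
    for nick in nicks:
        no_hit *= 1.0 - _nick_profile(nick, model, length)
    combined = 1.0 - no_hit
    if dsb_synergy != 1.0 and _has_opposite_strand_pair(nicks, dsb_distance):
        combined = np.minimum(combined * dsb_synergy, 1.0)
    mult = repair.msh6_multiplier if is_mmr_deficient(genotype) else 1.0
    escape = min(repair.escape_prob * mult, 1.0)
    p = combined * escape + repair.background_rate * mult
    return np.clip(p, 0.0, 1.0)


def _has_opposite_strand_pair(nicks: Sequence[NickSpec], max_dist: int) -> bool:
    for i, a in enumerate(nicks):
        for b in nicks[i + 1 :]:
            if a.nicked_strand != b.nicked_strand and abs(a.nick_pos - b.nick_pos) <= max_dist:
                return True
    return False


def simulate_molecules(reference: AmpliconReference, profile_vector: np.ndarray,
                       subst_matrix: np.ndarray, n: int,
                       rng: np.random.Generator | int) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw ``n`` amplicon molecules mutated per the position profile.

    Each position of each molecule independently substitutes with the
    profile's probability; the alternative base is drawn from the
    substitution-matrix row of the reference base. Substitutions only.

    Returns ``(molecules, truth)``: an ``(n, L)`` uint8 array of ASCII base
    codes and a tidy truth table with columns ``molecule_id`` (integer row
    index), ``position``, ``ref``, ``alt``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    ref_codes = np.frombuffer(reference.seq.encode(), dtype=np.uint8)
    length = len(reference)
    profile_vector = np.asarray(profile_vector, dtype=float)
    if profile_vector.shape != (length,):
        raise ValueError("profile_vector length must match reference")
    molecules = np.tile(ref_codes, (n, 1))
    mol_ids, positions, alts = [], [], []
    for x in np.nonzero(profile_vector > 0)[0]:
        k = rng.binomial(n, profile_vector[x])
        if k == 0:
            continue
        hit = rng.choice(n, size=k, replace=False)
        row = subst_matrix[_CODE_INDEX[ref_codes[x]]]
        alt_codes = _BASE_CODES[rng.choice(4, size=k, p=row)]
        molecules[hit, x] = alt_codes
        mol_ids.append(hit)
        positions.append(np.full(k, x))
        alts.append(alt_codes)
    if mol_ids:
        mid = np.concatenate(mol_ids)
        pos = np.concatenate(positions)
        alt = np.concatenate(alts)
        order = np.lexsort((pos, mid))
        truth = pd.DataFrame(
            {
                "molecule_id": mid[order],
                "position": pos[order],
                "ref": [chr(ref_codes[x]) for x in pos[order]],
                "alt": [chr(c) for c in alt[order]],
            }
        )
    else:
        truth = pd.DataFrame(columns=["molecule_id", "position", "ref", "alt"])
    return molecules, truth


def truth_records(truth: pd.DataFrame, prefix: str = "mol") -> Iterator[TruthRecord]:
    """View the tidy truth table as per-molecule :class:`TruthRecord` objects."""
    for mid, grp in truth.groupby("molecule_id"):
        subs = tuple(
            (int(r.position), str(r.ref), str(r.alt)) for r in grp.itertuples()
        )
        yield TruthRecord(f"{prefix}{int(mid)}", subs)


def truth_frequencies(truth: pd.DataFrame, n: int, length: int) -> np.ndarray:
    """Per-position substitution frequency implied by a truth table."""
    freq = np.zeros(length)
    if len(truth):
        counts = truth.groupby("position").size()
        freq[counts.index.to_numpy()] = counts.to_numpy() / n
    return freq


@dataclass
class QualModel:
    """Gaussian per-base quality model, truncated to [min_qual, max_qual]."""

    mean: float = 36.0
    sd: float = 3.0
    min_qual: int = 2
    max_qual: int = MAX_QUAL

    def draw(self, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        q = np.rint(rng.normal(self.mean, self.sd, size=shape))
        return np.clip(q, self.min_qual, self.max_qual).astype(np.uint8)


@dataclass
class ReadBatch:
    """Dense batch of equal-length reads (sequences + qualities as arrays)."""

    prefix: str
    seqs: np.ndarray  # (n, L) uint8 ASCII
    quals: np.ndarray  # (n, L) uint8 phred

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def read(self, i: int) -> Read:
        return Read(
            f"{self.prefix}:{i}",
            self.seqs[i].tobytes().decode(),
            self.quals[i].astype(np.int16),
        )

    def __iter__(self) -> Iterator[Read]:
        return (self.read(i) for i in range(len(self)))

    def write_fastq(self, path) -> None:
        qual_ascii = self.quals + 33
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(
                    f"@{self.prefix}:{i}\n{self.seqs[i].tobytes().decode()}\n+\n"
                    f"{qual_ascii[i].tobytes().decode()}\n"
                )


def sequence_reads(molecules: np.ndarray, read_len: int = 150, error_rate: float = 0.0,
                   qual_model: QualModel | None = None,
                   rng: np.random.Generator | int = 0, prefix: str = "mol",
                   min_overlap: int = 20) -> tuple[ReadBatch, ReadBatch]:
    """Sequence molecules as fully-spanning paired-end reads.

    R1 covers the first ``read_len`` bases of each molecule, R2 the reverse
    complement of the last ``read_len``; the amplicon must therefore be no
    longer than ``2 * read_len``. Per-base sequencing errors are independent
    at ``error_rate``; qualities come from ``qual_model`` (capped at 40).
    """
    rng = np.random.default_rng(rng)
    qual_model = qual_model or QualModel()
    n, length = molecules.shape
    if length > 2 * read_len:
        raise ValueError(
            f"amplicon length {length} exceeds 2 x read_len = {2 * read_len}: "
            "paired reads cannot fully span the molecule"
        )
    import warnings

    if 2 * read_len - length < min_overlap:
        warnings.warn(
            f"paired-read overlap {2 * read_len - length} bp is below "
            f"min_overlap={min_overlap}; downstream merging may fail",
            stacklevel=2,
        )
    eff_len = min(read_len, length)
    r1 = molecules[:, :eff_len].copy()
    r2 = _COMPLEMENT_CODE[molecules[:, length - eff_len :]][:, ::-1].copy()
    for arr in (r1, r2):
        if error_rate > 0:
            _inject_errors(arr, error_rate, rng)
    return (
        ReadBatch(prefix, r1, qual_model.draw(r1.shape, rng)),
        ReadBatch(prefix, r2, qual_model.draw(r2.shape, rng)),
    )


def _inject_errors(seqs: np.ndarray, error_rate: float, rng: np.random.Generator,
                   block: int = 50_000) -> None:
    """Flip each base to one of the three others with ``error_rate``, in place."""
    n, length = seqs.shape
    for start in range(0, n, block):
        sub = seqs[start : start + block]
        mask = rng.random(sub.shape) < error_rate
        idx = np.nonzero(mask)
        if not len(idx[0]):
            continue
        old = _CODE_INDEX[sub[idx]]
        shift = rng.integers(1, 4, size=len(idx[0]))
        sub[idx] = _BASE_CODES[(old + shift) % 4]


# ---------------------------------------------------------------------------
# Default synthetic amplicon: a 280 bp stretch with four embedded guide sites
# (alternating strands) flanking a central 100 bp targeted window, emulating
# the four-guide multiplex layout around a premature stop codon.
# ---------------------------------------------------------------------------

_AMPLICON_LENGTH = 280
_WINDOW = (90, 190)
# (name, strand, pam_start); strands alternate so multiplexing nicks both
# strands and, under H840A, the two central footprints point toward each other
_GUIDE_LAYOUT = [
    ("g1", "+", 110),
    ("g2", "-", 126),
    ("g3", "+", 170),
    ("g4", "-", 166),
]
_REFERENCE_SEED = 11  # fixed: the default amplicon is part of the package


def make_default_amplicon() -> tuple[AmpliconReference, dict[str, GuideSpec]]:
    """Deterministically construct the default synthetic amplicon and guides."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=_AMPLICON_LENGTH))
    for _, strand, pam in _GUIDE_LAYOUT:
        if strand == "+":
            seq[pam + 1] = "G"
            seq[pam + 2] = "G"
        else:
            seq[pam - 2] = "C"
            seq[pam - 1] = "C"
    ref_seq = "".join(seq)
    reference = AmpliconReference("synthetic_amplicon", ref_seq, _WINDOW)
    guides = {}
    for name, strand, pam in _GUIDE_LAYOUT:
        if strand == "+":
            spacer = ref_seq[pam - 20 : pam]
        else:
            spacer = revcomp(ref_seq[pam + 1 : pam + 21])
        guide = GuideSpec(name, spacer, strand, pam)
        guide.validate(reference)
        guides[name] = guide
    return reference, guides
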