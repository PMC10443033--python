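"""End-to-end orchestration: simulate fixtures, run every stage, write reports.

Stages run in a fixed order per sample (merge -> align -> pileup), then fan
out into the position-level profile (depth filter, end trim, background
subtraction) and the read-level diversity analysis (window trim, unique-read
tally, indel removal, occurrence and parental filters, spectra). Reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import align as _align
from . import io as _io
from . import merge as _merge
from . import profile as _profile
from . import readlevel as _readlevel
from .io import AmpliconReference, Read, SampleMeta
from .simulate import (
    GuideSpec,
    MutagenesisProfile,
    NickSpec,
    QualModel,
    RepairModel,
    build_position_profile,
    find_nick,
    make_default_amplicon,
    sequence_reads,
    simulate_molecules,
    truth_frequencies,
)


@dataclass
class RunConfig:
    """Every stage parameter in one serializable block."""

    reference_fasta: str = ""
    sample_sheet: str = ""
    output_dir: str = "results"
    window: tuple[int, int] | None = None
    min_overlap: int = 20
    max_mismatch: int = 0
    max_depth: int = _align.MAX_PILEUP_DEPTH
    min_depth: int = _profile.MIN_DEPTH
    floor: float = _profile.FLOOR
    left_trim: int = 10
    right_trim: int = 10
    min_count: int = _readlevel.MIN_OCCURRENCE
    depth_agg: str = "mean"
    background_agg: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_agg not in ("mean", "median"):
            raise ValueError("depth_agg must be mean|median")
        if self.background_agg not in ("mean", "median"):
            raise ValueError("background_agg must be mean|median")
        if self.min_overlap < 1 or self.max_mismatch < 0 or self.min_count < 0:
            raise ValueError("parameter out of documented range")
        if self.window is not None:
            self.window = tuple(self.window)  # type: ignore[assignment]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window) if self.window else None
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("window"):
            d["window"] = tuple(d["window"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSample:
    sample_id: str
    role: str  # treated | parental
    genotype: str
    guide_names: tuple[str, ...]


@dataclass(frozen=True)
class Scenario:
    """A named sample layout mirroring the study's cohort structure."""

    name: str
    samples: tuple[ScenarioSample, ...]
    description: str


def _scenario(name: str, desc: str, *samples: ScenarioSample) -> Scenario:
    return Scenario(name, samples, desc)


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        _scenario(
            "parental",
            "untransformed control: background mutations only",
            ScenarioSample("parental_WT_1", "parental", "WT", ()),
        ),
        _scenario(
            "parental-msh6d",
            "untransformed MMR-deficient control",
            ScenarioSample("parental_msh6d_1", "parental", "msh6d", ()),
        ),
        _scenario(
            "off-target-control",
            "guide targeting another locus: no nick in the amplicon",
            ScenarioSample("offtarget_WT_1", "treated", "WT", ()),
            ScenarioSample("parental_WT_1", "parental", "WT", ()),
        ),
        _scenario(
            "single-guide",
            "one guide (g2) plus matched parental control",
            ScenarioSample("g2_WT_1", "treated", "WT", ("g2",)),
            ScenarioSample("parental_WT_1", "parental", "WT", ()),
        ),
        _scenario(
            "single-guide-g1",
            "one guide (g1) plus matched parental control",
            ScenarioSample("g1_WT_1", "treated", "WT", ("g1",)),
            ScenarioSample("parental_WT_1", "parental", "WT", ()),
        ),
        _scenario(
            "single-guide-g3",
            "one guide (g3) plus matched parental control",
            ScenarioSample("g3_WT_1", "treated", "WT", ("g3",)),
            ScenarioSample("parental_WT_1", "parental", "WT", ()),
        ),
        _scenario(
            "single-guide-g4",
            "one guide (g4) plus matched parental control",
            ScenarioSample("g4_WT_1", "treated", "WT", ("g4",)),
            ScenarioSample("parental_WT_1", "parental", "WT", ()),
        ),
        _scenario(
            "multiplexed-4",
            "all four guides multiplexed plus matched parental control",
            ScenarioSample("g1234_WT_1", "treated", "WT", ("g1", "g2", "g3", "g4")),
            ScenarioSample("parental_WT_1", "parental", "WT", ()),
        ),
        _scenario(
            "msh6d",
            "all four guides in the MMR-deficient background",
            ScenarioSample("g1234_msh6d_1", "treated", "msh6d", ("g1", "g2", "g3", "g4")),
            ScenarioSample("parental_msh6d_1", "parental", "msh6d", ()),
        ),
    ]
}


@dataclass
class FixtureSample:
    meta: SampleMeta
    nicks: tuple[NickSpec, ...]
    truth_profile: np.ndarray  # simulated per-position substitution probability
    truth: pd.DataFrame
    r1: "object"  # ReadBatch
    r2: "object"


@dataclass
class Fixture:
    scenario: str
    seed: int
    reference: AmpliconReference
    guides: dict[str, GuideSpec]
    samples: dict[str, FixtureSample]

    def sample_sheet(self) -> list[SampleMeta]:
        return [self.samples[s].meta for s in sorted(self.samples)]


def make_fixture(seed: int, scenario: str, n_molecules: int = 100_000,
                 variant: str = "H840A", model: MutagenesisProfile | None = None,
                 repair: RepairModel | None = None, dsb_synergy: float = 1.0,
                 error_rate: float = 0.0, qual_model: QualModel | None = None,
                 read_len: int = 150, outdir=None) -> Fixture:
    """Simulate a named scenario: paired reads, truth tables, sample sheet.

    The default of 100000 molecules per sample matches the depth scale of a
    deep amplicon run. ``outdir`` additionally writes FASTQ pairs, truth and
    truth-profile TSVs, the reference FASTA and the sample sheet.
    """
    if scenario not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
        )
    spec = SCENARIOS[scenario]
    model = model or MutagenesisProfile()
    repair = repair or RepairModel()
    reference, guides = make_default_amplicon()
    seeds = np.random.SeedSequence(seed).spawn(2 * len(spec.samples))
    samples: dict[str, FixtureSample] = {}
    for i, samp in enumerate(spec.samples):
        nicks = tuple(
            find_nick(reference, guides[g], variant) for g in samp.guide_names
        )
        profile = build_position_profile(
            reference, nicks, model, repair, genotype=samp.genotype,
            dsb_synergy=dsb_synergy,
        )
        molecules, truth = simulate_molecules(
            reference, profile, model.subst_matrix, n_molecules,
            np.random.default_rng(seeds[2 * i]),
        )
        r1, r2 = sequence_reads(
            molecules, read_len=read_len, error_rate=error_rate,
            qual_model=qual_model, rng=np.random.default_rng(seeds[2 * i + 1]),
            prefix=samp.sample_id,
        )
        meta = SampleMeta(
            sample_id=samp.sample_id, role=samp.role, genotype=samp.genotype,
            replicate=1, guides=samp.guide_names,
            fastq_r1=f"{samp.sample_id}_R1.fastq", fastq_r2=f"{samp.sample_id}_R2.fastq",
        )
        samples[samp.sample_id] = FixtureSample(meta, nicks, profile, truth, r1, r2)
    fixture = Fixture(scenario, seed, reference, guides, samples)
    if outdir is not None:
        _write_fixture(fixture, Path(outdir))
    return fixture


def _write_fixture(fixture: Fixture, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(fixture.reference, outdir / "reference.fasta")
    _io.write_sample_sheet(fixture.sample_sheet(), outdir / "sample_sheet.tsv")
    for sid in sorted(fixture.samples):
        fs = fixture.samples[sid]
        fs.r1.write_fastq(outdir / fs.meta.fastq_r1)
        fs.r2.write_fastq(outdir / fs.meta.fastq_r2)
        _io.write_table(fs.truth, outdir / f"{sid}_truth.tsv", sort_by=["molecule_id", "position"])
        prof = pd.DataFrame(
            {
                "position": np.arange(1, len(fixture.reference) + 1),
                "truth_probability": fs.truth_profile,
            }
        )
        _io.write_table(prof, outdir / f"{sid}_truth_profile.tsv", sort_by="position")


# ---------------------------------------------------------------------------
# Per-sample processing and cohort analysis
# ---------------------------------------------------------------------------

@dataclass
class SampleAnalysis:
    sample_id: str
    merge_stats: _merge.MergeStats
    pileup: _align.PileupTable
    profile: _profile.MutationProfile | None = None
    mean_depth: float = 0.0
    unique_all: _readlevel.UniqueReadTable | None = None
    unique_novel: _readlevel.UniqueReadTable | None = None
    diversity: _readlevel.SpectrumSummary | None = None
    diversity_novel: _readlevel.SpectrumSummary | None = None
    reads_dropped_window: int = 0
    reads_dropped_indel: int = 0
    seq_counts: Counter = field(default_factory=Counter)
    window_counts: Counter = field(default_factory=Counter)


def process_sample(pairs: Iterable[tuple[Read, Read]], reference: AmpliconReference,
                   config: RunConfig, sample_id: str) -> SampleAnalysis:
    """Merge, deduplicate, align and pile up one sample's read pairs."""
    stats = _merge.MergeStats()
    seq_counts: Counter = Counter()
    for merged in _merge.merge_pairs(
        pairs, min_overlap=config.min_overlap, max_mismatch=config.max_mismatch,
        stats=stats,
    ):
        seq_counts[merged.seq] += 1
    table, alignments = _align.pileup_deduplicated(
        seq_counts, reference, max_depth=config.max_depth, sample_id=sample_id,
    )
    window = config.window or reference.window
    window_counts: Counter = Counter()
    dropped = 0
    for seq, count in seq_counts.items():
        projected = _readlevel.trim_to_window(alignments[seq], reference, window)
        if projected is None:
            dropped += count
        else:
            window_counts[projected] += count
    analysis = SampleAnalysis(sample_id, stats, table)
    analysis.seq_counts = seq_counts
    analysis.window_counts = window_counts
    analysis.reads_dropped_window = dropped
    return analysis


def analyze_cohort(analyses: dict[str, SampleAnalysis],
                   samples: dict[str, SampleMeta], reference: AmpliconReference,
                   config: RunConfig) -> tuple[dict[str, SampleAnalysis], dict]:
    """Position-level and read-level analysis across a cohort.

    Applies the depth filter, builds trimmed raw profiles, subtracts the
    matched-genotype parental background from treated samples, and runs the
    unique-read diversity analysis with parental haplotype removal.
    """
    log: dict = {"discarded_samples": [], "per_sample": {}}
    window = config.window or reference.window
    pileups = {sid: a.pileup for sid, a in analyses.items()}
    kept, discarded = _profile.depth_filter(pileups, config.min_depth, window)
    log["discarded_samples"] = discarded
    kept_ids = sorted(kept)

    raw_profiles: dict[str, _profile.MutationProfile] = {}
    for sid in kept_ids:
        prof = _profile.mutation_frequency(kept[sid], sample_id=sid)
        prof = _profile.trim_ends(prof, config.left_trim, config.right_trim)
        raw_profiles[sid] = prof
        a = analyses[sid]
        window_mask = np.zeros(len(reference), dtype=bool)
        window_mask[window[0] : window[1]] = True
        sel = window_mask & prof.retained
        depths = a.pileup.depth[sel]
        a.mean_depth = float(
            np.mean(depths) if config.depth_agg == "mean" else np.median(depths)
        )

    parental_by_genotype: dict[str, list[str]] = {}
    for sid in kept_ids:
        meta = samples[sid]
        if meta.role == "parental":
            parental_by_genotype.setdefault(meta.genotype, []).append(sid)

    # read-level parental tables: replicates pooled per genotype
    parental_tables: dict[str, _readlevel.UniqueReadTable] = {}
    for genotype, sids in parental_by_genotype.items():
        pooled: Counter = Counter()
        for sid in sids:
            pooled.update(analyses[sid].window_counts)
        parental_tables[genotype] = _readlevel.UniqueReadTable.from_counts(
            pooled, reference.window_seq if window == reference.window
            else reference.seq[window[0] : window[1]],
        )

    for sid in kept_ids:
        a = analyses[sid]
        meta = samples[sid]
        a.profile = raw_profiles[sid]
        if meta.role == "treated":
            parents = parental_by_genotype.get(meta.genotype, [])
            if not parents:
                raise RuntimeError(
                    f"stage posprofile, sample {sid!r}: no parental control of "
                    f"genotype {meta.genotype!r} passed the depth filter"
                )
            a.profile = _profile.subtract_background(
                raw_profiles[sid], [raw_profiles[p] for p in parents],
                floor=config.floor, agg=config.background_agg,
            )

        ref_window = reference.seq[window[0] : window[1]]
        table = _readlevel.UniqueReadTable.from_counts(a.window_counts, ref_window)
        table = _readlevel.flag_indels(table)
        table, removed = _readlevel.remove_indel_reads(table)
        a.reads_dropped_indel = removed
        table = _readlevel.filter_occurrence(table, config.min_count)
        a.unique_all = table
        a.diversity = _readlevel.normalize_and_spectrum(table, a.mean_depth)
        if meta.role == "treated":
            parental_table = parental_tables.get(meta.genotype)
            novel = (
                _readlevel.subtract_parental_reads(table, parental_table, config.min_count)
                if parental_table is not None
                else table
            )
            a.unique_novel = novel
            a.diversity_novel = _readlevel.normalize_and_spectrum(novel, a.mean_depth)
        log["per_sample"][sid] = {
            "pairs_total": a.merge_stats.total,
            "pairs_merged": a.merge_stats.merged,
            "reads_dropped_window": a.reads_dropped_window,
            "reads_dropped_indel": a.reads_dropped_indel,
            "unique_reads": len(table),
            "mean_depth": a.mean_depth,
        }
    return {sid: analyses[sid] for sid in kept_ids}, log


def run_all(config: RunConfig, stages: tuple[str, ...] | None = None) -> Path:
    """Execute the pipeline from files per the config; returns the output dir.

    Every output is accompanied by a snapshot of the exact config used, and
    reruns with the same config and seed are byte-identical.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = _io.read_fasta(config.reference_fasta, window=config.window)
    sheet = _io.read_sample_sheet(config.sample_sheet)
    samples = {s.sample_id: s for s in sheet}
    base = Path(config.sample_sheet).parent

    analyses: dict[str, SampleAnalysis] = {}
    for sid in sorted(samples):
        meta = samples[sid]
        r1 = _io.read_fastq(base / meta.fastq_r1)
        r2 = _io.read_fastq(base / meta.fastq_r2)
        analyses[sid] = process_sample(zip(r1, r2, strict=True), reference, config, sid)
        _io.write_table(
            analyses[sid].merge_stats.to_frame(), outdir / f"{sid}_merge_stats.tsv",
            sort_by=None,
        )
        _io.write_table(
            analyses[sid].pileup.to_frame(), outdir / f"{sid}_pileup.tsv",
            sort_by="position",
        )
    if stages is not None and not ({"profile", "reads"} & set(stages)):
        config.to_yaml(outdir / "config_used.yaml")
        return outdir

    analyses, log = analyze_cohort(analyses, samples, reference, config)
    for sid, a in sorted(analyses.items()):
        if a.profile is not None:
            _io.write_table(a.profile.to_frame(), outdir / f"{sid}_profile.tsv",
                            sort_by="position")
        final_table = a.unique_novel if a.unique_novel is not None else a.unique_all
        if final_table is not None:
            _io.write_table(final_table.frame, outdir / f"{sid}_unique_reads.tsv",
                            sort_by=None)
        if a.diversity is not None:
            _io.write_table(a.diversity.hamming_frame(),
                            outdir / f"{sid}_hamming_spectrum.tsv", sort_by="hamming")
            _io.write_table(a.diversity.substitution_spectrum.to_frame(),
                            outdir / f"{sid}_substitution_spectrum.tsv", sort_by=None)
            summary = pd.DataFrame(
                [
                    {
                        "sample_id": sid,
                        "fraction_mutated_reads": a.diversity.fraction_mutated,
                        "mean_hamming": a.diversity.mean_hamming,
                        "mean_depth": a.mean_depth,
                    }
                ]
            )
            _io.write_table(summary, outdir / f"{sid}_summary.tsv", sort_by=None)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "config_used.yaml")
    return outdir


def fixture_pairs(fs: FixtureSample) -> Iterable[tuple[Read, Read]]:
    """Iterate a fixture sample's in-memory read pairs."""
    return zip(iter(fs.r1), iter(fs.r2))


def simulate_and_analyze(scenario: str, seed: int, config: RunConfig | None = None,
                         **fixture_kwargs) -> tuple[Fixture, dict[str, SampleAnalysis], dict]:
    """Convenience: simulate a scenario and run the full in-memory analysis."""
    fixture = make_fixture(seed, scenario, **fixture_kwargs)
    config = config or RunConfig()
    analyses = {
        sid: process_sample(fixture_pairs(fs), fixture.reference, config, sid)
        for sid, fs in sorted(fixture.samples.items())
    }
    samples = {s.sample_id: s for s in fixture.sample_sheet()}
    analyses, log = analyze_cohort(analyses, samples, fixture.reference, config)
    return fixture, analyses, log
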