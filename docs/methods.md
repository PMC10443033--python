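# Methods

## The mutagenesis model

The simulator emulates a Cas9-nickase-guided error-prone DNA polymerase
acting on a short amplicon. Its components, in the order they compose:

**Nick geometry.** A guide is a 20-nt spacer with a protospacer strand and an
NGG PAM. The nick is placed at the canonical SpCas9 blunt-cut position,
between protospacer bases 17 and 18 (3 nt 5' of the PAM); the cut offset is
configurable for other effectors. The D10A variant nicks the strand
complementary to the gRNA, H840A the protospacer strand itself; polymerase
synthesis proceeds 5'→3' along the nicked strand, so a minus-strand nick has
direction −1 on the reference axis.

**Per-nick footprint.** The substitution probability contributed by one nick
at offset *d* from the nick in the direction of synthesis is
`peak_rate · exp(−decay · d)` for `d < fwd_window` (default 40 bp), and
`peak_rate · rev_fraction · exp(−decay · d)` in the opposite direction for
`d < rev_window` (default 15 bp). Defaults: `peak_rate = 0.02` per molecule
(the scale of observed per-bp frequencies at nick-adjacent bases),
`decay = 0.1 /bp` (a ~10 bp length constant, putting most of the mass in the
first half of the forward window while leaving it measurably elevated
throughout), `rev_fraction = 0.25` (the opposite-direction increase is
reported as clearly smaller but is not quantified; this is a model knob).

**Multiplex combination.** Nicks combine as independent events:
`p(x) = 1 − Π_i (1 − p_i(x))`. When two nicks on opposite strands lie within
`dsb_distance` (default 100 bp) and `dsb_synergy > 1`, the combined
probability is multiplied by the synergy factor (clipped at 1). This encodes
the hypothesis that simultaneous nicking of both strands creates a
double-strand break whose repair is more mutagenic, without asserting a
specific value; the default is 1 (no synergy).

**Repair and background.** The nick-derived probability is scaled by
`escape_prob` (default 0.5), the chance a templated mismatch survives
mismatch repair. Genotypes tagged `msh6` multiply both the escape probability
and the uniform background rate by `msh6_multiplier` (default 1.5, the scale
of the observed on-target increase in MMR-deficient cells); scaling the
background too reflects that untargeted mismatches are subject to the same
repair deficit, though a single multiplier cannot simultaneously reproduce a
much larger off-target increase — a known limitation. The background
(default 10⁻⁴ per base per molecule, the scale of the analysis' own flooring
threshold) is added after escape scaling.

**Sequencing.** Molecules are drawn position-independently (binomial counts
per position, alternative bases from a row-stochastic 4×4 substitution
matrix with zero diagonal, uniform by default). Reads are 2×150 bp fully
spanning the amplicon: R1 the first 150 bases, R2 the reverse complement of
the last 150, with independent per-base errors at `error_rate` and truncated
Gaussian qualities capped at 40. One root seed drives every draw through
spawned substreams, so fixtures are bit-reproducible.

**What the simulator does not model:** PCR amplification bias and chimeras,
per-cycle quality decay, indels (an `indel_rate` exists only to exercise the
indel filter; the analysis removes indel reads), and any correlation between
substitutions within a molecule beyond the shared footprint. Passing tests
therefore demonstrate correctness of the analysis chain under an idealized
error model, not robustness to library-preparation artifacts.

## The analysis chain

**Merging.** All relative placements of R1 against the reverse complement of
R2 are scanned exhaustively (the amplicon is short; correctness over speed).
A placement is valid when its overlap is at least `min_overlap` (default
20 bp) and contains at most `max_mismatch` mismatches (default 0; N matches
nothing). The largest valid overlap wins; two distinct placements of equal
maximal overlap are rejected as ambiguous, since under a zero-mismatch
policy a tie signals repetitive sequence and silent resolution would bias
pileups. Overlap qualities are the per-base maximum, capped at 40 — a
declared simplification of read-merger quality recombination. Dovetailed
placements are trimmed to the fragment span.

**Alignment.** One short reference makes index-based mapping unnecessary:
alignment is glocal (global in the read, free reference flanks) with affine
gaps, scoring match +1, mismatch −4, gap open −6, gap extend −1 (a length-g
gap costs 6 + g). The best ungapped placement is used directly whenever its
mismatch penalty cannot exceed the cheapest possible gap — provably optimal,
and the overwhelmingly common case for substitution-only amplicon reads —
otherwise the full affine DP runs (Biopython's PairwiseAligner with the same
scoring). Equal-scoring optima resolve leftmost-on-reference, then
indel-last. Reads scoring below 0.4 × length are flagged unaligned and
excluded. Identical read sequences are aligned once and piled up with their
multiplicity; the per-position depth cap (600000) applies in deterministic
input order (descending count, then lexicographic) rather than by random
subsampling.

**Pileup conventions.** Depth = A+C+G+T+deletion; N calls and insertion
starts are tallied but excluded from depth. Insertions anchor at the
reference position following their anchor base and do not enter the
position-level nonreference proportion (the read-level analysis removes
indel reads explicitly); deletions do.

**Position profiles.** Samples whose window-median depth is below
`min_depth` (default 40000) are discarded and named in the run log; the
depth rule is applied per sample with a per-position retained mask, covering
both a region-level and a sample-level reading of the rule. End trims
default to 10/10 bp (amplicon-specific; configurable). The raw proportion at
retained positions is (depth − ref_count)/depth; zero-depth positions are
dropped with a warning. Background subtraction uses the mean across parental
replicates (variance-minimizing; median selectable), clips negatives to
zero, then floors values below 10⁻⁴ — in that order, since proportions
cannot be negative and the floor presumes a nonnegative scale.

**Read-level diversity.** Reads are projected through their alignment onto
the targeted window (the ~100 bp stretch flanked by the guide sites, from
the reference's window annotation; the two clip offsets are configurable
because published per-amplicon trim values do not transfer across
amplicons). Reads not fully spanning the window are dropped and counted.
A read contains an indel iff its projected length differs from the window
length or its edit distance to the window reference is strictly below its
Hamming distance (compensating indels). After indel removal, unique reads
with occurrence ≥ 5 survive; strings with raw occurrence ≥ 5 in the pooled
parental replicates are removed from treated samples (the threshold is
stated as an occurrence count, so raw rather than depth-normalized parental
counts are used, and replicates are pooled). Normalized abundance divides
counts by the sample's mean depth over retained window positions (mean
matches the plotted quantity's definition; median selectable). The
fraction-of-mutated-reads and mean Hamming distance are computed on the
indel-removed, occurrence-filtered table *before* parental-haplotype
removal — the parental step removes the reference-identical read itself, so
a fraction computed after it would be meaningless — while the final
unique-read table written per sample is the parental-subtracted one.
Substitutions of each surviving read come from positionwise comparison to
the window reference (valid precisely because indel reads were removed) and
accumulate, weighted by read count, into the 12 ordered ref→alt categories
(transitions: A→G, G→A, C→T, T→C).

**Reversion assay.** Frequency = dilution-corrected selective CFU / total
CFU; reversion and stop-codon suppression are not distinguished (the assay
cannot). Groups of biological replicates are summarized by median, min, max
and n, with fold change over a designated control group; no hypothesis test
is attached by default (an optional percentile-bootstrap CI on the median is
provided).

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based inclusive only in
  written reports, with a tested convert/invert pair.
- Qualities above 40 are clamped on input, not rejected. N is allowed in
  reads (excluded from depth) but forbidden in the reference.
- The default synthetic amplicon is 280 bp with four embedded guide sites on
  alternating strands flanking a central 100 bp window — constructed
  deterministically in code from a fixed internal seed, so the package
  ships no sequence data. 280 bp leaves exactly the 20 bp minimum overlap
  for 2×150 bp reads; the simulator warns when the overlap falls below the
  merge threshold.
- The scenario registry mirrors the study layout: parental controls,
  single-guide runs, an off-target control (no nick in the amplicon), the
  four-guide multiplex, and its MMR-deficient counterpart. The default of
  100000 molecules per sample matches the depth scale of a deep amplicon
  run (mean depths near 10⁵) while keeping desk-scale runtimes; the
  parameter-recovery analyses use 200000 for tighter binomial error.
- Truth tables are tidy DataFrames (molecule_id, position, ref, alt) with a
  per-molecule record view; truth profiles convert counts to per-position
  frequencies for direct comparison with estimated profiles.

## Known limitations

- The merge quality model (max-and-cap) understates the information gain of
  agreeing overlap bases; it does not affect any downstream statistic here,
  since base qualities are not filtered by default.
- With `max_mismatch > 0`, overlap disagreements resolve to the
  higher-quality base; the zero-mismatch default sidesteps this entirely.
- The depth cap truncates per position in input order rather than
  subsampling; at desk-scale depths the cap never binds.
- Off-target activity of guides at other loci is out of the simulator's
  scope: the off-target-control scenario simply produces no nick in the
  amplicon.
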