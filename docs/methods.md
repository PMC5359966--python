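# Methods

This note records the model behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference model

The alignment reference is built from mature and hairpin FASTA in the
miRBase dialect (RNA alphabet, mixed case, `>id description` headers);
parsing converts U→T and upper-cases, optionally restricting to a
species id prefix.

**Deduplication.** Paralogous loci frequently carry byte-identical
mature sequences. Identical sequences are collapsed into groups; the
representative is the lexicographically smallest member id (the rule
had to be fixed somewhere; smallest-id is deterministic and
reconstructible), and all member ids are carried through to the
annotation table for traceability.

**Mapping and clustering.** Every exact sense-strand occurrence of
every unique mature on every unique hairpin is recorded — a mature may
occur in several precursors, several times in one precursor, or not at
all. Matures with no occurrence ("orphans") are excluded with a logged
warning rather than an error, because registry releases do contain
them. Matures whose occurrences overlap on a shared hairpin are
clustered by connected components of the overlap graph: reads from
such matures are nearly indistinguishable once end-variation is
allowed, so they must be grouped (or at least their residual ambiguity
counted — see *multi-entry reads* below).

**Extension and delimiters.** Each occurrence is extended by `E`
nucleotides of precursor flank on each side (clipped at hairpin
boundaries), flanks lower-case, mature upper-case. `E` defaults to 4:
it must cover the largest end offsets worth capturing, and observed
5' variation spans about ±1 nt while 3' variation spans about ±3 nt, so
4 covers both with a margin; it is configurable. Segments of one
mature are concatenated with a single `N`; in per-cluster mode,
boundaries between different matures of a cluster use `NN`. `N` never
matches any base and no reported alignment may span a delimiter, so
delimiters partition each entry into independent alignment targets
while keeping one sequence record per biological unit. Default
reference mode is per-mature (one entry per deduplicated mature);
per-cluster mode is available where cluster-level counting is wanted.
A mature occurring at several non-overlapping positions of one hairpin
contributes one segment per position.

Coordinates are 0-based half-open internally and 1-based inclusive in
emitted TSV (stated in the file header).

## Trimming and collapsing

Adapter removal is 3'-anchored prefix matching under a Hamming budget:
the leftmost read position at which the adapter prefix matches the
remainder of the read with at most `max_error_rate × overlap`
mismatches (default rate 0.1, minimum overlap 3, N never matches) is
the cut point; a full internal adapter occurrence removes everything
from its start. No indel support — small-RNA adapters sit at a fixed
ligation boundary and substitution errors dominate; the stage stays
dependency-free and exactly testable against a brute-force scan of all
cut points. Reads with no adapter found are kept by default
(`discard_untrimmed` reverses this); reads shorter than 16 nt after
trimming are discarded; no maximum-length cap is applied because the
extended-reference geometry rejects over-long reads naturally.
Quality strings are parsed and ignored — no stage is quality-aware.

Identical raw reads trim identically, so raw reads are collapsed
before trimming and each distinct sequence is trimmed once (a pure
optimization; semantics are per-read). Trimmed reads are collapsed
within each sample and then joined across samples into one unique-read
× sample count matrix whose column sums equal each sample's surviving
read count. With the cross-sample noise filter disabled, joint and
per-sample processing give identical results — joint collapsing is an
efficiency device, and the equivalence is asserted in the acceptance
suite.

## Alignment

Alignment is bounded-Hamming (no indels), sense-strand only by
default. Sense-only matters: hairpin arms can be exact reverse
complements of each other, in which case a strand-unaware aligner
assigns each arm's reads to both arms. `sense_only=False` exists to
reproduce that failure mode, not for production use.

The index stores all k-mers (default k = 8, minimum 8) of each entry.
Candidates for a read come from the pigeonhole principle: a placement
with ≤ `max_mm` mismatches over `max_mm + 1` disjoint blocks leaves at
least one block error-free, so the leading k-mer of each block is
looked up exactly. This is complete for reads of length ≥
`(max_mm + 1) × k`; shorter reads (possible only for `max_mm = 2` at
the 16 nt minimum) fall back to a full placement scan. The contract is
the *hit set*, not the algorithm: on random instances the
minimum-mismatch stratum must equal an independent position-by-position
Hamming scan exactly, and the test suite enforces this for
`max_mm ∈ {0, 1, 2}` on plain and delimiter-bearing references.

Per read, only the minimum-mismatch stratum is kept, ordered by entry
then position. `max_mm` defaults to 1 per stage (configurable per
stage): one substitution absorbs the dominant error mode without
opening the door to chance matches that bounded-mismatch short-read
alignment is known for.

**Cascade.** Each unique read is assigned the first stage with a hit
in the fixed order miRNA → hairpin → smallRNA → mRNA (the miRNA
reference is mandatory, the others optional and skipped with a log
note), else `unaligned`; categories are mutually exclusive and
exhaustive, so per-sample category totals sum to surviving reads.

**Multi-entry reads.** A read whose minimum-mismatch hits span several
reference entries is counted once, attributed to the lexicographically
smallest entry id, and tallied in a `multi_entry_reads` counter.
Reference grouping eliminates most such reads; the residue must not be
double counted, and the counter keeps the choice auditable. Reads
hitting several segments of one entry (identical extended contexts)
are counted once with offsets from the first segment.

**Remap invalidation.** Optional, enabled by supplying a genome. Only
reads whose retained hits carry ≥ 1 mismatch are candidates; a
candidate with an exact occurrence anywhere in the genome, either
strand (the origin locus of a spurious read is strand-unknown), has
its miRNA hits invalidated. Exact means exact — no tolerance for known
variants, which also means a mismatch read matching a polymorphic
locus is invalidated; the rule is deliberately unconditional. The
miRNA loci themselves are not excluded from the genome: a read exactly
matching its own locus is a perfect-match read and never a candidate.
Invalidation rates are reported over unique mismatch reads and over
their total counts; the two diverge when invalidated reads are
low-copy.

## Noise filter and counting

The filter operates on the unique-read count matrix (restricted to
valid miRNA-attributed reads) before table construction. A read is
noisy when zero in more than 60% of samples (strict), or its mean
count across samples is below 2 (strict). The two predicates combine
with OR by default; AND is available because both conventions are in
circulation — the combination mode is logged at runtime and the
difference only matters for reads that are rare but ubiquitous or
abundant but sample-specific.

miRNA counts sum the kept, valid unique-read counts per entry; isomiR
counts group by `(entry, offset5, offset3)` with
`offset5 = read_start − mature_start` and
`offset3 = read_end − mature_end` (negative offset5 = longer 5' end;
positive offset3 = longer 3' end; (0, 0) canonical). IsomiR identity
is offset-based only: internal substitutions do not split species —
they surface through the companion mismatch-only tables instead, which
count only mismatch-carrying reads and satisfy
`0 ≤ companion ≤ standard` elementwise, so `standard − companion` is
the perfect-match-only table. Per entry and sample, isomiR rows sum
exactly to the miRNA cell.

RPM divides each count by a per-sample denominator × 10⁻⁶. The default
denominator is the sample's miRNA-mapped total (each RPM column then
sums to 10⁶); `all_reads` (surviving reads) is available. Zero
denominators produce missing values with a warning.

"Detected miRNA" means count ≥ 1 in that sample (configurable
`min_detect_count`); the mismatch-read fraction is computed over
miRNA-category read counts.

## Synthetic data

The generator emulates the structures that make real references and
libraries awkward, with full ground truth. Defaults describe the study
conditions used throughout the tests: 24 hairpins (60–90 nt), 22 nt
matures planted with ≥ 4 nt flank margins, 8 samples × 50,000 reads of
length 50, lognormal entry expression (σ = 1.25), planted offset
distributions with 5' support {−1, 0, +1} (0.1/0.8/0.1) and 3' support
{−3…+3} (0.045/0.08/0.2/0.35/0.2/0.08/0.045) — 3' more variable than
5', qualitatively as in real libraries, not fitted to any dataset —
error-free reads, no background noise, 25 planted decoy reads and 3
rare species. Reads are hairpin substrings at the planted offsets plus
a 3' adapter and a fixed downstream filler, cut to the read length;
substitution errors are i.i.d. per base at rate ε. FASTQ qualities are
a constant 'I' since no stage reads them. All randomness flows from
one seed; outputs are byte-identical for identical parameters and
seed (gzip timestamps are zeroed). Read ids encode provenance
(`entry|o5|o3|sample|serial`, `noise|contig|pos|…`, `decoy|…`) for
read-by-read audit; the pipeline never consults them.

Planted structures: an identical mature on two hairpins with diverged
flanks; one hairpin with three mutually overlapping matures; one
hairpin whose arms are exact reverse complements; a decoy-donor
mature; rare matures receiving exactly one read in one sample (the
filter's textbook target). The genome is the hairpin loci plus decoy
contigs, one of which embeds a one-substitution variant of the donor
mature: planted decoy reads equal that variant, align to the donor
with one mismatch, match the genome exactly, and must be invalidated.
Decoy reads are emitted error-free so invalidation recall on them is
exactly 100% rather than approximately.

Three planted groups are *unexpressed* by default, each for a reason
the tests rely on. Overlapping-cluster matures: their reads are
genuinely indistinguishable at per-mature resolution (the reason
clustering exists), so exact truth recovery is undefined with them
expressed; `express_cluster=True` re-enables them for per-cluster
runs, where entry-level conservation is the meaningful check.
Reverse-complement arms: an error in a flank base of one arm's read
can turn it into an exact antisense genome match at the sister arm's
locus, which the unconditional remap rule then invalidates — correct
behaviour, but it would contaminate the "no true read invalidated"
oracle; the arms stay in the reference and strand handling is tested
with reads constructed directly from them (`express_rc_pair=True`
overrides). The decoy donor: its expression would let true reads
collide with the decoy variant sequence.

What the generator does **not** model, and what passing tests
therefore do not show about real data: ligation and sequence bias,
quality-score structure, indels, non-templated 3' additions as
sequence events (offsets only), adapter dimers, and *recurrent*
sequencing artifacts — errors here are i.i.d., so each error read is
essentially unique. Two consequences are worth naming. First, with
ε > 0 the noise filter removes error singletons carrying a noticeable
share of counts, so the "detection drops, counts barely move" property
of cross-sample filtering is evaluated in the error-free regime, where
it is purely background-driven, as at real depth where recurrent reads
dominate mismatch counts. Second, the generator's planted decoy is one
high-copy species, so the invalidation rate over unique mismatch reads
comes out *below* the rate over totals — the opposite of real
libraries, where invalidated reads are low-abundance; the statistics
themselves are computed identically either way.

## Numerical and procedural choices

- Determinism throughout: sorted iteration orders, fixed tie-breaks
  (lexicographically smallest id; leftmost placement first), zeroed
  gzip timestamps, fixed float formats in emitted files.
- Degenerate inputs: empty FASTA parses to an empty list; an empty
  reference is an error at index construction; zero reads per sample
  produce empty FASTQ and empty truth; samples with zero
  miRNA-mapped reads get missing RPM columns and missing redundancy
  values rather than division errors.
- The filter thresholds (0.60, 2) are strict inequalities on zero
  fraction and mean respectively; boundary rows (exactly 60% zeros or
  mean exactly 2) are kept.
- Problem sizes in the test and acceptance runs — 8 × 50,000-read
  samples for study-scale checks, 4 × 2,000–4,000 for unit fixtures,
  ~100 random instances for the aligner oracle — were chosen to make
  every statistical check decisive at desk scale while the whole suite
  runs in well under a minute.

## Known limitations

Single-end reads only; no quality trimming or UMI handling; no indel
alignment; no novel-miRNA discovery or differential expression (count
tables are the hand-off point); per-mature mode leaves residual
ambiguity for overlapping matures (counted once, audited via
`multi_entry_reads`, eliminated by per-cluster mode); remap
invalidation is exact-match only and will discard mismatch reads from
polymorphic miRNA loci.
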