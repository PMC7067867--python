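# Methods

## Pipeline model

srnakit treats small RNA-seq quantification as five independent stages with a
fixed composition order: quality control → alignment → annotation → microbial
screening → sample-level statistics. Each stage is a library module with a
file-level entry point, so any stage can run alone given its inputs; the
`pipeline` runner chains them and records a manifest (parameters, input
hashes, per-stage read counts).

### Quality control

A raw read passes through, in order: 3' adapter trimming, removal of the
randomized ligation bases, stripping of low-quality end runs, a mean-PHRED
filter, and length selection. The order matters and is pinned by a
regression test: the randomized bases sit at the ligation junctions *inside*
the adapter, so the adapter must come off first.

Adapter matching is a cutadapt-style 3'-anchored prefix search: at each read
position the adapter prefix (length ≥ `min_adapter_overlap`, default 3) is
compared to the remainder of the read and the leftmost position with
mismatch fraction ≤ 0.1 wins. This is deterministic and handles both a full
adapter mid-read and a short adapter prefix running off the 3' end.

Thresholds use the inclusive convention: a read with mean PHRED exactly
equal to `min_mean_phred` (default 20, i.e. ≥ 1% mean error) is removed, and
an end base with PHRED exactly at the head/tail threshold (defaults 20/20)
is stripped. End-trimming strips maximal runs, not single bases, and is
idempotent. Mean quality is evaluated on the sequence remaining after
trimming; a read trimmed to length 0 (legal — a pure-adapter read) is
discarded at the quality filter. Input is assumed PHRED+33 (configurable
offset); RNA-alphabet input (U) is normalized to DNA (T) on parsing since
alignment targets are DNA genomes.

Defaults: 4 randomized bases per end (NEXTflex-style kits), qualified length
interval [15, 45] nt closed — wide enough for miRNA (~22 nt), piRNA
(26–31 nt) and the 42 nt trimming maximum of a 50 nt read, while dropping
degradation fragments too short to map uniquely.

### Alignment

Two interchangeable routes fill one representation (0-based half-open
genomic coordinates everywhere internally; SAM's 1-based positions and
BED's half-open intervals are translated at the file boundary):

* **SAM/BAM ingestion** (pysam) for production aligners: CIGAR-derived
  reference span and soft-clip-aware read span, NM-tag mismatches, secondary
  records grouped into the read's multimap group, unmapped-flag records
  collected as reads.
* **Built-in micro-aligner** for self-contained runs: exhaustive end-to-end
  Hamming placement of each read on both strands (reverse complement for the
  minus strand) within a mismatch budget (default 1). It reports *every*
  placement, so multimap groups are complete by construction. It does not
  soft-clip or handle indels — local, clipped alignments are the province of
  the external-aligner route — and it is validated against a brute-force
  scan of every offset and strand in the test suite.

Reads with no placement form the unmapped set, written as FASTA for the
microbe stage.

### Annotation and counting

The degree of read support for a feature is `r_olp = L_olp / L_read`.
`L_read` is the *aligned* span on the read (soft clips excluded) by default:
with local alignment, an isomiR carrying non-templated end bases would
otherwise never reach ratio 1 and the default full-containment stringency
would discard exactly the reads the local alignment was chosen to rescue. A
`full_read_length` switch divides by the complete read length instead.

Annotation requires matching strand by default (`strand_mode="same"`) —
small RNA database entries are strand-specific — with an ignore option.
Molecules are identified by (RNA type, name): one molecule may own many
genomic intervals and entries in several databases; entries sharing (type,
name) merge into one row listing every supporting database. Counting then
follows two rules, applied per read over its whole multimap group:

1. the set of supported features is deduplicated at the molecule level, so
   a read mapping to any number of loci of one molecule adds exactly 1;
2. no RNA type outranks another, so a read supporting molecules of several
   types adds 1 to each — column sums may legitimately exceed the number of
   annotated reads.

The per-read, per-molecule contribution is therefore always 0 or 1; this
conservation law is property-tested on every fixture. Dedup is per molecule,
not per type: a read multimapped into two *different* molecules of the same
type counts once for each.

Feature databases are BED6-like text (chrom, start, end, name, id, strand),
interval-indexed per chromosome (intervaltree, verified against a linear
scan on ≥ 1000 random queries). Genome-build harmonization between the
genome and the databases is the caller's responsibility.

### Microbial screening

Unmapped reads are matched to microbial references — BLAST tabular
(outfmt 6) input in production, or the built-in exhaustive `micro_match`
(BLAST-shaped output, deterministic synthesized e-values) at test scale.
Default hit filters are conventional BLAST screening values, e-value ≤ 1e-3
and identity ≥ 90%, both configurable; the tool itself prescribes none, and
unfiltered nt output is too noisy to count directly.

All taxa of all passing hits are retained per read — homologous species are
reported without bias; a `--best-hit-only` convenience flag exists but is
off by default. Counts are rolled up the taxonomy tree: a taxon's count is
the number of reads hitting it or any descendant, each read counting at most
once per taxon (per-read ancestor-set union). Rollup is reported at every
rank, not species only, and grouped into archaea, bacteria, fungi and
viruses. Fractional (1/n) counting was rejected to keep integer,
count-once-compatible semantics throughout the pipeline. Taxonomy input is a
5-column TSV or NCBI-style nodes/names dumps with a subtree→group map.

### Sample-level statistics

Per-sample four-column tables (DB, Name, ID, Count) merge by molecule key
into a molecule × sample matrix, absent cells 0. CpM rescales each column to
1e6 using the column sum of the matrix being normalized as the library size
(an external-library-size override would be a thin extension; the
self-contained default is documented behaviour). Detection is raw count ≥ 5.

Differential expression is a per-molecule two-sided Mann-Whitney U. The
exact null distribution is used when min(n) ≤ 8 and the pooled values are
tie-free; otherwise the normal approximation with tie and continuity
corrections (scipy). The pipeline default tests CpM values (normalization is
presented as the default preprocessing step); raw-count testing is a flag.
An all-constant row is flagged and given p = 1. Benjamini–Hochberg
adjustment is available but off by default, matching the raw-p reporting
convention.

## Synthetic data generator

`fixtures` emulates a NEXTflex-style library: 50 nt reads structured as
4 randomized bases + genomic insert + 4 randomized bases + adapter, padded
with random sequence, on a 20 kb single-chromosome random genome with
planted features. Two scenarios are planted by construction: a 22-mer copied
to 11 loci annotated to one miRNA molecule, and the let-7a-5p sequence
(UGAGGUAGUAGGUUGUAUAGUU) forming the 5' 22 nt of a 30 nt piRNA
(piR_008113) interval. Planting is verified (exact occurrence counts on both
strands) and the background redrawn from a derived seed on the vanishingly
rare collision. Insert lengths are 18–32 nt; read counts per molecule are
drawn uniformly from [2, 8]; "good" reads have per-base PHRED in [25, 40]
and planted failures in [8, 18], so QC verdicts are deterministic and the
truth table is exact. All randomness derives from a single integer seed
through independent child streams; identical specs give byte-identical
files.

What the generator does **not** emulate: sequencing indels and
position-dependent quality decay, isomiR end-variation, expression-level
skew, multi-chromosome genomes, adapter dimers. Passing the end-to-end
truth-recovery test therefore shows the counting logic is exact under clean
multi-mapping and nesting structure — not that the pipeline is robust to
every artifact of real libraries, which is what the SAM-ingestion route and
configurable filters are for.

The differential-expression fixture generates continuous normalized-scale
values: null rows iid log-normal (median ≈ 100, σ = 1) across both groups
of 6, shifted rows completely separated (controls U(10, 20), cases
U(100, 200)), so every shifted row has exact two-sided p = 2/924 and the
null rejection rate at 0.05 sits at the exact test's conservative level
(≈ 0.041 for 6 vs 6).

## Numerical and design choices

* Ties in Mann-Whitney: average ranks with tie-corrected variance via the
  asymptotic path; the exact path is reserved for tie-free data.
* Interval arithmetic is closed-open throughout; containment ⇔ r_olp = 1 is
  an exact integer identity, no float tolerance needed.
* Duplicate feature lines are deduplicated on load and logged; degenerate
  intervals (start ≥ end) are errors with line numbers, not warnings.
* Fixture sizes (20 kb genome, ~170 reads, 1000-row DE matrices) keep the
  full suite in seconds while still exercising every rule; the micro-aligner
  is additionally cross-checked on a 100 kb genome against brute force.
* The unit over which count-once operates is the multimap group (all
  alignments sharing a read id); SAM ingestion accepts however many
  alignments the upstream aligner chose to report and imposes no cap.
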