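# Methods

This note documents what `asmqc` computes, the conventions it adopts where
several reasonable choices exist, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Evaluation model

The evaluator treats the supplied reference replicons as ground truth: a
mock community is, by construction, a sample whose true composition is
known, so any disagreement between a contig and its reference is charged
to the assembler (sequencing error reaching the consensus included).
The pipeline is:

1. read references and assemblies (multi-FASTA; one record per linear
   replicon);
2. global statistics on the original contig set;
3. length filter — the **filtered set (FS)** keeps contigs with length
   ≥ `min_contig_len` (default 1,000 bp). The comparison is inclusive
   (≥, BBTools `minlength` semantics); a strict `>` would differ only for
   contigs of exactly the threshold length;
4. map FS contigs to the references (built-in mapper, or user-supplied
   PAF), keeping primary alignments only;
5. per-replicon metrics, misassembly classification, gap detection;
6. consolidation of misassembled-contig and gap totals back into the
   FS global statistics;
7. optionally, read mapping (against the original, unfiltered assembly,
   since reads were assembled before any filtering) and cross-run
   comparisons when one assembler label carries several runs.

All internal coordinates are 0-based half-open (PAF native). Human-facing
event tables report 1-based inclusive coordinates and say so in a header
line; BED output stays 0-based half-open.

An empty assembly, or a replicon to which nothing aligns, produces a
flagged row rather than an error, so one failed assembler never aborts a
comparison.

## Per-replicon scores

* **Breadth of coverage** = |union of aligned target intervals| /
  replicon length. Unions never double-count overlap.
* **LSA** = longest single alignment block / replicon length. One block,
  not one contig: a contig broken into blocks contributes each block
  separately.
* **Identity and Pls.** Per contig and per replicon, identity is
  Σ matched columns / Σ alignment columns over that contig's blocks on
  that replicon (weighted, in effect, by alignment columns), and
  Pls = −10·log₁₀(E) with E = 1 − identity, or exactly 60 when E = 0.
  The logarithm is base 10, the Phred convention. The 60 branch applies
  only at E = 0; the closed form is used verbatim elsewhere, so
  identities above 0.9999 can in principle score above 60 — with the
  smallest representable nonzero error on a 10 kb contig (1 mismatch,
  E = 10⁻⁴) the score is 40, so the cap in practice binds only for
  perfect contigs. A chimera receives one Pls per replicon it touches.
* **SNPs** count substitution columns only (X columns of an extended
  CIGAR; for M-only CIGARs, NM minus indel bases). Indel bases are never
  mixed into the SNP count; they surface in the misassembly/event table.
  When neither an extended CIGAR nor NM is available the count is
  reported as missing, never silently zero.
* **Uncalled bases** per replicon are counted over aligned contig
  regions (not whole contigs), matching the per-replicon scope of the
  table they appear in. Everything outside {A,C,G,T} counts as uncalled.
* **COMPASS ratios.** coverage = covered reference bases / replicon
  length; validity = Σ aligned query bases / total FS bases of contigs
  whose best primary alignment is on this replicon; multiplicity =
  Σ aligned query bases / covered reference bases; parsimony =
  multiplicity / validity. Overlapping blocks double-count aligned query
  bases in multiplicity (redundancy is what multiplicity measures) but
  never in coverage. The validity denominator is a declared convention:
  assigning each contig to the replicon of its best primary alignment is
  what makes the ratios well defined in a multi-replicon community.
* **GC content** of a reference excludes uncalled bases from the
  denominator.

## Misassembly classification

Primary alignment records of one contig are split into blocks wherever
the *net* indel between reliable anchors reaches `block_split_indel`
(default 50 bp). An anchor is an exact-match run ≥ 20 bp; between two
anchors the query-consumed minus target-consumed difference is summed.
This matters because an edit-distance aligner spreads a large inserted or
deleted stretch over many small indel runs interleaved with 1–3 bp
coincidental matches; the net consumption recovers the event regardless
of that fragmentation, while dense substitution stretches (net 0) are
never split. The 20 bp anchor length is safe because a chance 20-mer
match occurs about once per 10¹² random columns.

Blocks are sorted along the forward contig and classified:

* blocks on ≥ 2 replicons → **chimera**, exclusively — no further rules
  run, the contig is one chimera event;
* otherwise, for each adjacent pair (gaps measured in the direction of
  travel along the contig, so the rules are invariant under
  reverse-complementing the whole contig):
  * opposite strands → **inversion**;
  * contig gap ≥ 50 bp with target gap < 50 bp → **insertion**;
  * 50 bp ≤ target gap < 1 kb with contig gap < 50 bp → **deletion**;
  * target gap ≥ 1 kb → **translocation**;
  * target intervals overlapping by ≥ 50 bp → **duplication**;
  * target order contradicting contig order on the same strand →
    **rearrangement**;
* a multi-block contig firing no rule is **inconsistent**.

Non-chimera categories can combine, one event per (pair, category); a
k-block contig fires at most k−1 pair events. The magnitude thresholds
are this tool's conventions (the 1 kb translocation bound follows the
relocation convention familiar from QUAST) and are all configurable;
the category taxonomy itself fixes no magnitudes. Distinguishing true
biological structural variation from assembler error is out of scope —
the reference is axiomatically the truth.

Consolidation counts a chimera once even though it appears in two
replicons' reports (distinct-contig union; events deduplicated by
contig, category, and junction coordinates).

## Built-in mapper

A deliberately small seed–chain–extend mapper exists so the pipeline runs
with no external binary; any PAF with extended CIGARs can replace it.

* every reference k-mer (default k = 15) is 2-bit packed into a sorted
  array; query k-mers are sampled every `seed_stride` (default 3) bases
  and looked up on both strands (the reverse strand by encoding the
  reverse-complemented query, PAF-style);
* anchors are chained greedily: an anchor joins the live chain with the
  closest diagonal among those within `max_seed_gap` (default 100 bp) in
  query, target, and diagonal shift; chains need ≥ 3 anchors. Structural
  breakpoints (inversions, distal joins, large indels beyond the gap
  bound) therefore split chains, which is exactly what the misassembly
  classifier consumes;
* chain ends are extended by ungapped X-drop extension (match +1,
  mismatch −2, drop 12) and the spanned region is aligned end-to-end
  with edlib (exact unit-cost edit distance, extended CIGAR). Unit-cost
  gap closing replaces an affine-gap DP: it is exact, orders of
  magnitude faster than a Python DP, and at the substitution-dominated
  error rates of this problem the two produce the same block structure;
  the match/mismatch scores apply to end extension only;
* alignments spanning < 100 query bases are suppressed; the
  best-scoring record per query region is primary, records overlapping
  a better one by more than half their span are secondary. Only primary
  records feed the metrics, which prevents double-counted coverage.

Consequences worth knowing: a substitution in the last 1–2 bases of a
contig is left unaligned (extension stops where the score peaks, as in
any local aligner), so error totals on noisy simulations recover the
planted rate to binomial precision, not exactly; and mapping quality is
not modelled (the mapq column is a constant placeholder).

## Synthetic communities

The generator emulates the structure of a defined mock community and an
assembler's output, with every planted deviation ledgered in a
`TruthSet`:

* **replicons**: i.i.d. bases, per-replicon GC drawn from `gc_range`,
  lengths uniform in `length_range`;
* **assembly**: each replicon is tiled into contiguous contigs (lengths
  normal, default mean 20 kb, floored at 1 kb so the default filter
  keeps every tile and planted gaps remain the only uncovered bases);
  planted gaps are left untiled; substitutions (to a different base) and
  uncalled bases are planted i.i.d. at the configured rates; each
  planted misassembly is built from its generative template (chimera:
  segments of two replicons joined; insertion: random filler between
  flanks; deletion/translocation: an internal skip below/above 1 kb;
  inversion: an internal segment reverse-complemented; duplication: a
  segment repeated; rearrangement: two adjacent segments swapped), with
  source segments drawn clear of planted gaps so the gap ledger stays
  exact;
* **reads**: fixed-length paired reads from uniformly placed fragments,
  replicon chosen per pair by the abundance profile — `even` (equal
  weights) or `log` (each next replicon 10× less abundant, spanning the
  orders-of-magnitude range a logarithmically distributed community is
  designed to probe) — with i.i.d. substitution errors.

All randomness flows from one mandatory seed through named substreams;
identical configs give byte-identical FASTA/FASTQ/JSON.

What the generator does **not** emulate — and what passing tests on it
therefore cannot show about real data: coverage-dependent contig breaks,
indel and position-dependent sequencing error profiles (no
Illumina-error-model realism), repeat-induced fragmentation and the
rRNA/tRNA/mobile-element gaps real genomes produce, inter-replicon
homology, and assembler-specific artifacts. The generator validates the
*measurement machinery* against planted truth; conclusions about real
assemblers require real mock-community data.

## Numerical and reporting choices

* N50: smallest length L with cumulative descending length sum ≥ half
  the total; an empty contig set reports 0 at the report layer (the
  failed-assembler row) while the core function raises.
* Cross-run contig matching is by exact length only (coarse by design:
  two different contigs of equal length are indistinguishable to it).
  `in_all`/`in_two`/`in_one` count matched contig entities; the
  inconsistency fraction divides by total copies across runs.
* Gap consistency across runs matches intervals whose endpoints both lie
  within `tolerance` bases (default 0, the strictest reading;
  configurable).
* Report determinism: tables are written with a fixed float format
  (`%.10g`), JSON with sorted keys, no timestamps; identical bundles are
  byte-identical. The HTML report is a static rendering of the same
  tables — every number also lives in a TSV/JSON file, nothing is
  HTML-only.
* Test problem sizes: the suite exercises the full pipeline on seeded
  communities from ~50 kb (unit scale) up to ~2 Mb across 5 replicons
  (end-to-end determinism), and rate-recovery checks use ~1 M aligned
  columns so binomial concentration places the mean Pls well inside one
  unit of the nominal score. These sizes are the package's validation
  conditions, chosen to make the statistical tolerances sharp at desk
  scale.

## Known limitations

* The built-in mapper targets desk-scale communities (a few Mb); it is
  not a minimap2 replacement in speed or sensitivity, and spliced or
  long-read alignment is out of scope. For large communities, map
  externally and pass `--paf`.
* Misassembly calls are only as good as the block structure: events
  smaller than `block_split_indel` are reported as indel columns inside
  a block, not as events.
* Matching contigs across runs by size cannot see content changes that
  preserve length.
* Uncalled-base and SNP counts on `-` strand blocks assume the CIGAR
  convention of PAF (alignment of the reverse-complemented query);
  PAF from tools using other conventions would need normalisation.
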