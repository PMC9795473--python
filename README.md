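# asmqc

Reference-based quality assessment of de novo assemblies of **defined mock
communities**. Given the complete reference replicons (chromosomes and
plasmids) of a community of known composition and one or more assemblies of
reads from that community, `asmqc` measures how faithfully each assembler
reconstructed the truth: global contig statistics, per-replicon coverage
and identity scores, misassembly classification, uncovered-region (gap)
analysis, and run-to-run reproducibility. A seeded synthetic-community
simulator with a planted-error ledger makes every metric testable without
any external data.

It is aimed at microbiologists and bioinformaticians choosing a short-read
prokaryotic assembler for a particular kind of sample: sequence (or
simulate) a mock community resembling your samples, assemble it with the
candidate assemblers, and let `asmqc` score the results against the known
references.

## Metrics

**Global** (per assembly, for the original contig set and the filtered set
of contigs ≥ 1,000 bp by default): number of contigs, total bp, largest
contig, N50, uncalled (non-ACGT) bases, fraction of reads mapping back to
the contigs, plus two consolidations of the per-replicon results — the
number of misassembled contigs and the total size of reference regions
covered by no contig.

**Per replicon** (filtered set only): breadth of coverage, aligned contigs
and bases, mismatches (SNPs), uncalled bases in aligned regions, the
COMPASS ratios (coverage, validity, multiplicity, parsimony), and two
contig-level scores:

* **LSA** — the fraction of the longest single contig-to-reference
  alignment relative to the replicon length;
* **Pls**, a Phred-like score of contig identity:

  $$\mathrm{Pls}(E) = \begin{cases} -10\,\log_{10} E & 0 < E \le 1 \\ 60 & E = 0 \end{cases}
  \qquad E = 1 - \mathrm{Identity}$$

  Like a Phred base quality, Pls 20 means one error per 100 aligned
  columns; a contig identical to its reference scores the cap of 60.

**Misassemblies**: each contig's alignments are split into blocks and
adjacent block pairs are classified as chimera (joins two replicons;
exclusive — ends classification), insertion, deletion, inversion,
rearrangement, translocation, or duplication; multi-block contigs where no
rule fires are reported as inconsistent.

**Reproducibility**: contigs are matched across repeated runs of the same
assembler by size (multiset semantics), reporting how many contigs appear
in all, two, or one of the runs; gap sets are likewise compared across runs.

## Worked example

Simulate a 3-replicon community whose "assembly" carries a 0.2 % per-base
substitution rate, then evaluate it:

```sh
asmqc simulate --n-replicons 3 --min-len 80000 --max-len 120000 \
      --substitution-rate 0.002 --read-pairs 500 --seed 7 -o sim
asmqc evaluate -r sim/references.fasta -a demo=sim/assembly.fasta \
      --reads sim/reads_R1.fastq --reads sim/reads_R2.fastq -o out
```

`out/reference_metrics.tsv` then contains (columns abridged):

```
replicon     replicon_len  n_contigs_aligned  breadth  lsa           snps
replicon_00  117797        7                  1        0.1948266934  222
replicon_01  105004        6                  1        0.2254866481  219
replicon_02  107411        5                  1        0.2396309503  219
```

Every replicon is fully covered (breadth 1), the longest single alignment
spans 19–24 % of its replicon, and the mismatch counts sit at the planted
0.2 % of replicon length. `out/contig_pls.tsv` holds one row per aligned
contig:

```
replicon     contig        contig_len  identity      pls
replicon_00  contig_00000  21736       0.9982977549  27.68977901
replicon_00  contig_00001  15443       0.9980573723  27.11610417
```

Pls ≈ 27 matches the planted error rate (−10·log₁₀ 0.002 = 27.0).
`out/global_metrics.tsv` reports a mapped-read fraction of 1 and zero
misassembled contigs, and `out/report.html` renders the same tables as a
static two-panel summary. Planted gaps appear in `out/gaps.bed`, and
`sim/truth.json` is the machine-readable ledger of every planted edit.

Repeated runs of one assembler are compared by tagging runs:

```sh
asmqc evaluate -r refs.fasta -a spades:1=run1.fasta -a spades:2=run2.fasta \
      -a spades:3=run3.fasta -o out3
```

which fills `out3/run_consistency.tsv` and `out3/gap_consistency.tsv`.

## Layout

* `src/asmqc/io.py` — FASTA/FASTQ via Biopython, PAF + CIGAR parsing
* `src/asmqc/mapper.py` — built-in k-mer seed / chain / extend mapper
* `src/asmqc/metrics.py` — global contig statistics and the length filter
* `src/asmqc/reference.py` — per-replicon metrics (breadth, LSA, Pls, COMPASS)
* `src/asmqc/misassembly.py` — alignment blocks and the misassembly classifier
* `src/asmqc/gaps.py` — uncovered-region detection and cross-run gap consistency
* `src/asmqc/reproducibility.py` — cross-run contig matching by size
* `src/asmqc/simulate.py` — synthetic communities with a planted-error ledger
* `src/asmqc/report.py`, `src/asmqc/cli.py` — pipeline orchestration, tables,
  static HTML report, command-line interface

See `docs/methods.md` for the models, conventions, and numerical choices.
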