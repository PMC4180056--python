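# nsit

A seed-based aligner for identifying **novel sequences** — regions of a de
novo whole-genome assembly absent from the reference genome (operationally:
≥ 100 bp, < 90% identity to the reference, not a known repeat).

The pipeline runs in three alignment phases, followed by candidate
post-processing and a comparison viewer:

1. **k-mer indexing** (`nsit.kmer_index`) — one hash table per reference
   chromosome mapping every N-free k-mer (base-4 encoded: A=0, C=1, G=2,
   T=3) to its sorted occurrence positions; persisted one chromosome at a
   time.
2. **Chromosome assignment** (`nsit.assignment`) — each query is scanned in
   both orientations with *gapped seeds*: only reference positions on a
   fixed stride `delta = (k + gap) / n_sets` are loaded, giving `n_sets`
   staggered seed subsets with period `k + gap`. Chains of seed matches are
   narrowed by position-list intersection until a unique reference location
   survives (maximal unique aligned regions), pruned around the longest
   region (anchor distance ≤ 10⁶ by default), and summed into one score per
   (chromosome, orientation) slot — 48 slots for a 24-chromosome reference.
   A slot is assigned when its score is a one-sided Gaussian outlier
   (z ≥ 2.326, i.e. p ≤ 0.01) over all slots.
3. **Query alignment** (`nsit.full_alignment`) — four query groups
   (assigned / unassigned / misassigned / large-unaligned-run excisions)
   are re-scanned at full seed density, blocks are extended by exact base
   comparison, overlaps resolved longest-first (seeded random tie-breaks),
   and the highest-scoring target wins per query.

Unaligned remainders become novel-sequence candidates
(`nsit.novel_candidates`), which can be whittled down with parsed BLAST
tabular (outfmt 6) and RepeatMasker `.out` evidence — homology subtraction
gated by a 90% identity ceiling, repeat subtraction, and a per-source
contamination screen. `nsit.viewer` renders candidates sorted by
originating-sequence length with per-set coverage tracks, making
contaminated candidate blocks visible as empty columns.
`nsit.synthetic_fixtures` generates seeded reference/assembly pairs with
known ground truth (SNPs, indels, N gaps, chimeras, repeat families,
contaminant contigs, and novel insertions that provably share no k-mer with
the reference).

## CLI

```sh
nsit simulate --out fixtures/ --seed 5            # synthetic fixture + truth
nsit stats --asm asm.fa --out stats.tsv           # N50 etc.
nsit split --asm asm.fa --target-len 500000 --out split.fa
nsit index --ref ref.fa --k 12 --out index_dir/
nsit assign --asm asm.fa --index index_dir/ --k 12 --gap 84 --sets 6 \
            --min-mum 200 --out assign.tsv
nsit align --asm asm.fa --ref ref.fa --assign assign.tsv --seed 17 --out aln
nsit extract --asm asm.fa --blocks aln.blocks.tsv --out-prefix novel
nsit filter --candidates novel.candidates.tsv --blast hits.tsv \
            --rm masks.out --contaminants ebv.tsv --out-prefix filtered
nsit view --candidates novel.candidates.tsv --track "YH:yh_hits.tsv" \
          --track "EBV:ebv.tsv" --out fig.png
nsit run-all --ref ref.fa --asm asm.fa --config run.yaml --out run/
```

`run-all` executes index → assign → align → extract and writes
`run_log.json` with the per-phase base tallies (assigned, unassigned,
misassigned, false-positive excisions, candidate bases) and an exact
conservation check. Defaults mirror the recommended large-assembly
settings: k=12, gap=84, 6 seed sets, minimum MUM length 200, pruning
radius 10⁶, false-positive cutoff 2.5 kb, minimum novel length 100 bp.
Exit codes: 0 ok, 1 user error, 2 internal error.

### Index directory layout

`nsit index` writes one binary file per chromosome plus a manifest:

```
index_dir/
  index.tsv          # chrom_id <TAB> file <TAB> k
  chrom000.nsidx     # magic "NSIDX1\n", version/k/chrom-id header,
  chrom001.nsidx     # then code, count, and position arrays (int64 LE)
  ...
```

Loading an index with a seed configuration materializes only the gapped
seed subset (positions divisible by `delta`); loading without one is a
byte-exact round-trip.

### Conventions

All coordinates are 0-based half-open internally and in BED/TSV outputs;
FASTA headers and human-readable reports use 1-based inclusive intervals.
Reverse-strand matching always reverse-complements the *query*, never the
reference. Lowercase and non-N IUPAC ambiguity codes are normalized to N
on ingest; N never matches anything.

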