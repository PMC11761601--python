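# ragvar

**On-the-fly personalized genomes and indel-realigned coverage tracks for
deep-learning sequence models.**

Training sequence models on *personalized* genomes — each individual's own
haplotypes paired with their functional data — normally means materializing
two consensus FASTA files per genome. At biobank scale that is ruinous: one
million diploid genomes stored as compressed FASTA occupy

```
1,000,000 genomes × 2 files × 0.987 GB  =  1,974,000 GB  ≈  1.97 PB
                                        →  $51,324 / month at $0.026 per GB-month
```

and reading FASTA during training throttles the GPU. The genotypes behind
those FASTAs are tiny: almost every base is the reference. `ragvar` stores
only the differences and rebuilds everything else on demand.

## What it does

A phased VCF, a BED file of fixed-length regions of interest, and one
read-depth track per sample (BigWig or bedGraph) are converted **once** into
a compact on-disk dataset:

* **Sparse sample-major genotypes** — for every `(region, sample,
  haplotype)`, just the sorted indices of the variants carried on that
  haplotype, as a memory-mapped *ragged array* (one flat file + an offsets
  file; any row is an O(1) slice, no decompression, no index search).
* **Run-length coverage intervals** — per `(region, sample)`, the per-base
  read depth collapsed into maximal constant `(start, end, value)` runs,
  again a ragged array. Decoding is lossless.

At training/inference time the engine reconstructs, per haplotype:

* a **fixed-length personalized sequence**, by splicing the haplotype's
  alleles into the reference window with a left-to-right cursor;
* the **re-aligned track**, applying the same edits to the per-base values —
  values over deleted bases are skipped, each inserted base duplicates the
  value at its anchor, substitutions keep their value.

Deletions shorten a haplotype, so the store records per region how much
extra reference (`max_extension`) must be fetched past the region end for
every output to still reach the region length — computed to a fixed point,
since widening the window can admit further deletions. Reference coordinates
can be projected into haplotype coordinates (`project_coordinate`), and
every output base carries its source reference position (`source_map`).

## Worked example

Generate a synthetic cohort (4 diploid samples, 10 regions of 1,024 bp on a
60 kb contig, SNPs at 1/100 bp and indels at 1/500 bp), build the store, and
pull one sample's haplotypes:

```console
$ rgv simulate --out inputs --contig-length 60000 --n-samples 4 \
      --n-regions 10 --region-length 1024 --seed 13
$ rgv write --vcf inputs/variants.vcf --bed inputs/regions.bed \
      --tracks inputs/tracks.tsv --reference inputs/reference.fa --out store
wrote store: 10 regions x 4 samples x ploidy 2, 352 variants
$ rgv inspect store
format_version: 1.0
regions:        10 (length 1024 bp)
samples:        4 (ploidy 2)
variants:       352
max extension:  32 bp
store size:     17006 bytes across 11 arrays
$ rgv get store --reference inputs/reference.fa --region 0 --sample 1
sample1_chr1_139_1163_hap0: ATCCGACGCGCTAACGTGTGAGGGCCCCTATCGAGTTCCTTTGTGACCGC... track mean 12.328
sample1_chr1_139_1163_hap1: ATCCGACGCGCTAACGTGTGAGGGCCCCTATCGAGTTCCTTTGTGACCGC... track mean 12.328
```

The entire personalized dataset — every variant, every haplotype's sparse
row, and all 40 run-length coverage rows — occupies 17 kB; `max extension:
32 bp` says the deepest net deletion in any single haplotype window is 32 bp,
so windows are fetched 32 bp long and trimmed to exactly 1,024. The same
data are available from Python:

```python
import ragvar
ds = ragvar.open_dataset("store", "inputs/reference.fa")
seqs, tracks = ds.get(0, 1)            # (2, 1024) bytes, (2, 1024) float32
for batch in ds.iter_batches(8, shuffle=True, seed=0):
    x = ragvar.one_hot(batch.sequences)  # (8, 2, 1024, 4)
```

`iter_batches` visits every `(region, sample)` pair exactly once per epoch;
equal seeds give identical orders across machines and processes. The
storage-cost model above is `rgv estimate-cost --n-genomes 1000000`:

```
total storage:  1,974,000.000 GB
monthly cost:   $51,324.00
```

## Layout

| Module | Contents |
| --- | --- |
| `ragvar.core` | `RaggedArray`, `Region`, `VariantRecord`, manifest, index arithmetic |
| `ragvar.ingest` | VCF/BED/track readers, sparsification, extension fixed point, RLE, cost model |
| `ragvar.reconstruct` | cursor engine: sequences, track re-alignment, coordinate projection, strand |
| `ragvar.dataset` | store writer/reader, `get`, `subset`, `iter_batches`, one-hot |
| `ragvar.simulate` | synthetic cohort generators and the splice oracles |
| `ragvar.cli` | `rgv simulate / write / inspect / get / estimate-cost` |

See `docs/methods.md` for the model, its assumptions, and numerical choices.
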