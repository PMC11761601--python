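# Methods

## The problem

A cohort's personalized genomic data is almost entirely redundant: each
haplotype differs from the reference at a few thousand positions per
megabase, yet consensus-FASTA workflows store and re-read every base.
`ragvar` keeps the reference once, stores per-haplotype *differences* and
per-sample coverage in memory-mappable form, and reconstructs fixed-length
model inputs on demand. This note documents the data model, the
reconstruction semantics, the synthetic cohort the test suite runs on, and
the numerical/design choices that were genuinely open.

## Data model

**Ragged arrays.** Every variable-length collection is a flat data vector
plus an `offsets` vector (`n_rows + 1`, `offsets[0] = 0`, non-decreasing,
`offsets[-1] = len(data)`). Row `i` is `data[offsets[i]:offsets[i+1]]`.
Stored as headerless little-endian files, rows are O(1) slices of a memory
map: no decompression, no search, no per-row system call. All shape and
dtype metadata lives in `manifest.json`; opening a dataset does a size
check (`file bytes == length × itemsize`) and maps the files lazily.

**Row order** is region-major, then sample, then haplotype
(`flat_index(r, s, h) = (r·S + s)·P + h`), so one sample's haplotypes for
one region are contiguous — the access pattern of random (region, sample)
sampling during training.

**Sparse genotypes.** Per `(region, sample, haplotype)` row: the int32
indices of the variants carried on that haplotype whose REF span intersects
the extended region, sorted by position. Variants are decomposed to
biallelic records with `size_delta = len(alt) − len(ref)`; internally all
coordinates are 0-based half-open (VCF positions decremented once on read,
BED used as-is).

**Coverage intervals.** Per `(region, sample)` row: maximal constant
`(start, end, value)` runs tiling `[region.start, region.end +
max_extension)` contiguously. Values are float32 — read-depth does not
merit 64 bits and halving the store matters. Encoding/decoding is exactly
lossless (`decode(encode(v)) == v` elementwise); a gap or short tiling at
decode time is reported as store corruption, never silently zero-filled.

## Reconstruction semantics

Given the reference window `[start, end + max_extension)` and one
haplotype's pos-sorted, non-overlapping variants, the cursor algorithm
emits reference bases up to each variant, then the variant's alt allele,
then jumps the cursor past the variant's REF span. Output is truncated to
the region length at the downstream end only — the region start anchors the
output, matching consensus-tool behavior. Edge rules:

* a variant starting before the cursor was swallowed by an applied
  deletion and is skipped;
* a deletion spanning the window start loses its in-window REF bases and
  contributes no alt bases (its anchor lies outside the window);
* insertions at the window end are included up to truncation;
* if the window itself is exhausted (deletions at a contig end), the
  sequence is padded with `N` and the track with 0.0 — an explicit
  sentinel, never wraparound.

Both outputs are driven by a single *edit plan*: for each output base, the
window offset it derives from. The sequence path additionally overlays the
alt letters; the track path reads the per-base values through the plan.
Alt base `j` of a variant at `p` derives from `p + min(j, len(ref) − 1)`,
which makes substitutions map positionally and every inserted base
duplicate the value at its anchor — the literal reading of
"duplicate values across insertions" adopted here (the alternative,
interpolating across an insertion, has no basis in read-depth semantics).
Because one routine produces the plan, the invariant
`track[i] == input[source_map[i]]` is structural, not merely tested.

`project_coordinate(ref_pos)` returns `(ref_pos − start) + Σ size_delta`
over variants wholly left of `ref_pos`; a position inside a deleted span
maps to the deletion's anchor offset. It is monotone non-decreasing and
inverts `source_map` wherever the reference base survives.

**Extension fixed point.** A row's deletion excess is
`max(0, −Σ effective_delta)` where `effective_delta` counts a variant's
in-window REF bases against its alt contribution (zero alt for
spanning-start deletions) — exactly mirroring the cursor. The per-region
extension is iterated: extend → re-assign variants → recompute excess.
The update is monotone non-decreasing across iterations, because a widened
window can admit an *insertion* that shrinks the recomputed excess; if the
window were allowed to contract again the iteration oscillates (observed
in randomized cohorts). Overshooting the minimal extension costs a few
extra fetched bases and nothing else. Extensions are capped at 2× the
region length with a warning; a haplotype needing more (deletions tiling
the whole window repeatedly) is pathological and ends N-padded.

## Input policy

* Unphased input is rejected, not silently phased: haplotype reconstruction
  is undefined without phase. Any non-missing call with the `/` separator
  raises an error naming the record and sample. Fully or partially missing
  calls (`./.`, `.|1`) are accepted and count as reference — the
  conservative consensus-tool convention.
* Multiallelic sites are decomposed; symbolic alleles (`<DEL>`, breakends,
  `*`) are skipped with a logged count; REF alleles are validated against
  the reference genome and a mismatch is a hard error.
* If two kept variants on one haplotype have overlapping REF spans, the
  earlier-position one wins and the later is dropped with a warning (ties:
  file order). Phased callers should not emit such rows; a deterministic
  rule keeps reconstruction well-defined when they do.
* All regions in one dataset must share a single length: the store serves
  fixed-length model inputs, and ragged batching is out of scope.
* bedGraph is accepted wherever BigWig is (selected by file extension), so
  text fixtures can stand in for binary tracks; both paths are tested
  against each other.

## Synthetic cohort

The generator emulates the statistical *shape* of a WGS + ATAC-seq cohort:
uniform-random reference, SNPs at 1/100 bp, indels at 1/500 bp with sizes
1–16 bp (deletion and insertion equally likely), per-site alt-allele
frequency uniform(0.05, 0.5), haplotypes drawn independently and written
phased. Coverage is background zero with rectangular peaks (height 1–50,
width 100–500 bp) centered on the regions of interest. Default scale: a
200 kb contig, 8 diploid samples, 64 regions of 2,048 bp — 1,024 haplotype
draws, sized so the oracle-equivalence suite is exhaustive yet runs in
seconds on one CPU.

What it deliberately does **not** model: linkage disequilibrium, realistic
mutation spectra, phasing errors, overlapping variant calls (the overlap
rule is exercised by hand-built pathological fixtures instead, keeping the
oracle's no-overlap precondition clean), soft-masking, multi-contig
genomes, and read-level noise. Passing tests therefore demonstrate
correctness of storage and reconstruction mechanics, not robustness to
caller artifacts in real VCFs beyond the cases handled explicitly above.

Generated variant positions avoid base 0 and stop `max_indel_len + 1` bases
short of the contig end, and regions are placed so that even the maximal
2× extension stays on the contig — so N-padding never triggers in the
standard cohort and is tested separately.

## Verification strategy

The engine is checked against two independent *splice oracles* that share
no code with it: apply each variant left-to-right by literal string/list
splicing with a cumulative offset. Over every haplotype of the default
cohort, engine sequence and track must equal the truncation of the oracle
outputs exactly — bytes and float values, no tolerance. Complementary
property suites cover ragged round trips, RLE round trips,
sparsify/densify identity, fixed output length, source-map consistency and
monotonicity, exactly-once epoch coverage, and byte-identical store
rewrites. Shuffling uses numpy's PCG64 with an explicit seed (logged), so
epoch order is reproducible across machines and processes.

## Storage-cost model

`estimate_fasta_storage(n, ref_size_gb, price)` = `n × 2 × ref_size_gb` GB
and that times the price per GB-month: one compressed FASTA per haplotype,
each approximated by the compressed reference size (0.987 GB, GRCh37), at
the All-of-Us object-storage price of $0.026 per GB-month. It is an
analytic model of the *alternative* workflow's cost, used to motivate the
sparse store; it involves no simulation.

## Known limitations

* Ploidy is taken from the VCF (tested at 2); polyploid stores are laid
  out correctly but untested beyond construction.
* One track per sample; multi-assay stores need one dataset per assay.
* The store is uncompressed by design (random access without
  decompression); disk footprint is traded for locality, which is the
  point — the sparse representation is already orders of magnitude smaller
  than consensus FASTA.
* No PGEN/BGEN input, no pangenome/graph coordinates, no read-level
  re-alignment (only per-base summary tracks).
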