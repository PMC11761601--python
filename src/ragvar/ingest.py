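"""Input ingestion: VCF/BED/coverage tracks -> sample-major sparse store contents.

A phased VCF is a dense, variant-major genotype matrix; most entries are
reference. This module flips that layout: per ``(region, sample, haplotype)``
it keeps only the indices of variants actually carried on that haplotype
(:class:`SparseGenotypes`), and per ``(region, sample)`` it run-length
encodes the coverage track into ``(start, end, value)`` runs
(:class:`IntervalStore`). Both are ragged arrays, ready to be written as
flat memory-mappable files.

Deletions shorten a haplotype, so producing a fixed-length output window
requires fetching reference sequence *past* the region end. The required
per-region ``max_extension`` is computed to a fixed point here, because
widening the fetch window can itself admit further deletions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from cyvcf2 import VCF
from pyfaidx import Fasta

from .core import RaggedArray, Region, VariantRecord, flat_index, ragged_from_lengths
from .errors import (
    InvalidInputError,
    PhasedInputRequiredError,
    ReferenceMismatchError,
)

logger = logging.getLogger(__name__)

# A region of length L can never need more than 2L extra bases: the fixed
# point is capped there (with a warning) to bound pathological inputs.
EXTENSION_CAP_FACTOR = 2

__all__ = [
    "VariantTable",
    "SparseGenotypes",
    "IntervalStore",
    "read_bed",
    "read_track_table",
    "load_variant_table",
    "assign_variants_to_regions",
    "sparsify_genotypes",
    "compute_extensions",
    "bigwig_to_intervals",
    "run_length_encode",
    "estimate_fasta_storage",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantTable:
    """Decomposed biallelic variants plus their phased genotype matrix.

    ``records`` is sorted by ``(contig, pos)``; ``genotypes`` has shape
    ``(n_variants, n_samples, ploidy)`` with entries in {0, 1} (1 = the alt
    allele of that record is on that haplotype).
    """

    records: list[VariantRecord]
    genotypes: np.ndarray
    sample_names: list[str]

    @property
    def n_variants(self) -> int:
        return len(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    @property
    def ploidy(self) -> int:
        return int(self.genotypes.shape[2]) if self.genotypes.ndim == 3 else 2

    def positions(self) -> np.ndarray:
        return np.fromiter((r.pos for r in self.records), dtype=np.int64, count=self.n_variants)

    def ref_ends(self) -> np.ndarray:
        return np.fromiter((r.ref_end for r in self.records), dtype=np.int64, count=self.n_variants)

    def size_deltas(self) -> np.ndarray:
        return np.fromiter((r.size_delta for r in self.records), dtype=np.int64, count=self.n_variants)


@dataclass
class SparseGenotypes:
    """Per ``(region, sample, haplotype)`` sorted variant-index lists.

    Rows are laid out region-major via :func:`ragvar.core.flat_index`; each
    row lists the int32 indices (into the companion :class:`VariantTable`)
    of the variants carried on that haplotype whose REF span intersects the
    extended region, sorted by position, with overlapping REF spans resolved
    in favour of the earlier variant.
    """

    ragged: RaggedArray
    n_regions: int
    n_samples: int
    ploidy: int

    def row(self, region_idx: int, sample_idx: int, hap_idx: int) -> np.ndarray:
        i = flat_index(region_idx, sample_idx, hap_idx, self.n_samples, self.ploidy)
        return self.ragged.row(i)


@dataclass
class IntervalStore:
    """Per ``(region, sample)`` run-length encoded coverage.

    Rows (region-major, then sample) hold contiguous, non-overlapping
    ``(start, end, value)`` runs tiling ``[region.start, region.end +
    max_extension)`` exactly; decoding back to per-base values is lossless.
    """

    starts: np.ndarray   # int64
    ends: np.ndarray     # int64
    values: np.ndarray   # float32
    offsets: np.ndarray  # int64, len n_rows + 1
    n_regions: int
    n_samples: int

    def row(self, region_idx: int, sample_idx: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = region_idx * self.n_samples + sample_idx
        if not 0 <= i < self.offsets.size - 1:
            raise IndexError(f"interval row ({region_idx}, {sample_idx}) out of range")
        lo, hi = int(self.offsets[i]), int(self.offsets[i + 1])
        return self.starts[lo:hi], self.ends[lo:hi], self.values[lo:hi]


# ---------------------------------------------------------------------------
# small input readers


def read_bed(path: Path | str) -> list[Region]:
    """Read BED3/BED6 regions (0-based half-open; strand from column 6)."""
    regions: list[Region] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InvalidInputError(f"{path}:{line_no}: BED line has fewer than 3 columns")
        strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
        regions.append(Region(parts[0], int(parts[1]), int(parts[2]), strand))
    if not regions:
        raise InvalidInputError(f"{path}: no regions found")
    return regions


def read_track_table(path: Path | str) -> dict[str, Path]:
    """Read the 2-column headerless TSV mapping sample name -> track path.

    Relative track paths are resolved against the TSV's own directory.
    """
    base = Path(path).parent
    table: dict[str, Path] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise InvalidInputError(f"{path}:{line_no}: expected 2 tab-separated columns")
        name, p = parts
        track = Path(p)
        if not track.is_absolute():
            track = base / track
        table[name] = track
    if not table:
        raise InvalidInputError(f"{path}: no samples found")
    return table


# ---------------------------------------------------------------------------
# VCF loading


def _padded_spans_by_contig(regions: list[Region]) -> dict[str, np.ndarray]:
    """Merged [start, end) spans per contig, each region padded on the right
    by its maximum possible extension (the fixed-point cap)."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        pad = EXTENSION_CAP_FACTOR * r.length
        raw.setdefault(r.contig, []).append((r.start, r.end + pad))
    merged: dict[str, np.ndarray] = {}
    for contig, spans in raw.items():
        spans.sort()
        out: list[list[int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = np.asarray(out, dtype=np.int64)
    return merged


def _is_symbolic(alt: str) -> bool:
    return alt == "*" or any(c in alt for c in "<>[].")


def load_variant_table(
    vcf_path: Path | str,
    regions: list[Region],
    reference_path: Path | str | None = None,
) -> VariantTable:
    """Read a phased VCF into a decomposed, sorted :class:`VariantTable`.

    Only variants whose REF span can intersect some region (padded by that
    region's maximum possible extension) are kept. Multiallelic sites are
    decomposed into one record per alt allele. Missing and half genotype
    calls count as reference; symbolic alleles are skipped with a logged
    count; any non-missing unphased call aborts with
    :class:`PhasedInputRequiredError`.

    When ``reference_path`` is given, every kept REF allele is validated
    against the reference genome (:class:`ReferenceMismatchError` on
    disagreement).
    """
    spans = _padded_spans_by_contig(regions)
    fasta = Fasta(str(reference_path), as_raw=True, rebuild=False) if reference_path else None

    vcf = VCF(str(vcf_path))
    sample_names = list(vcf.samples)
    if not sample_names:
        raise InvalidInputError(f"{vcf_path}: VCF contains no samples")

    records: list[VariantRecord] = []
    geno_rows: list[np.ndarray] = []
    n_symbolic = 0
    ploidy: int | None = None

    for v in vcf:
        contig_spans = spans.get(v.CHROM)
        if contig_spans is None:
            continue
        pos0 = v.POS - 1  # VCF is 1-based; everything internal is 0-based
        ref = v.REF.upper()
        ref_end = pos0 + len(ref)
        # REF span must intersect some padded region span; spans are merged
        # and sorted, so only the last span starting before ref_end matters.
        j = int(np.searchsorted(contig_spans[:, 0], ref_end, side="left"))
        if j == 0 or contig_spans[j - 1, 1] <= pos0:
            continue

        calls = v.genotypes  # per sample: [allele0, ..., phased_flag]
        if ploidy is None:
            ploidy = len(calls[0]) - 1
        gt = np.zeros((len(calls), ploidy), dtype=np.int16)
        for s, call in enumerate(calls):
            alleles = call[:-1]
            phased = bool(call[-1])
            non_missing = [a for a in alleles if a >= 0]
            if non_missing and not phased and len(alleles) > 1:
                raise PhasedInputRequiredError(
                    f"unphased genotype at {v.CHROM}:{v.POS} for sample "
                    f"{sample_names[s]}: phased input ('|' separator) is required"
                )
            for h, a in enumerate(alleles[:ploidy]):
                gt[s, h] = a if a >= 0 else 0  # missing/half-call -> reference

        for k, alt in enumerate(v.ALT):
            alt = alt.upper()
            if _is_symbolic(alt):
                n_symbolic += 1
                continue
            rec = VariantRecord(v.CHROM, pos0, ref, alt)
            if fasta is not None:
                seen = str(fasta[v.CHROM][pos0:ref_end]).upper()
                if seen != ref:
                    raise ReferenceMismatchError(
                        f"REF mismatch at {v.CHROM}:{v.POS}: VCF says {ref!r}, "
                        f"reference genome has {seen!r}"
                    )
            records.append(rec)
            geno_rows.append((gt == k + 1).astype(np.uint8))

    if n_symbolic:
        logger.warning("skipped %d symbolic alt allele(s)", n_symbolic)

    if ploidy is None:
        ploidy = 2
    if records:
        genotypes = np.stack(geno_rows)  # (n_variants, n_samples, ploidy)
        order = sorted(range(len(records)), key=lambda i: (records[i].contig, records[i].pos))
        records = [records[i] for i in order]
        genotypes = genotypes[order]
    else:
        genotypes = np.zeros((0, len(sample_names), ploidy), dtype=np.uint8)
    return VariantTable(records=records, genotypes=genotypes, sample_names=sample_names)


# ---------------------------------------------------------------------------
# sparsification and extensions


def assign_variants_to_regions(
    table: VariantTable,
    regions: list[Region],
    max_extension: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-region sorted variant index lists.

    Variant ``v`` belongs to region ``r`` iff its REF span
    ``[pos, pos + len(ref))`` intersects ``[r.start, r.end + ext_r)``. A
    deletion starting left of ``r.start`` but spanning into the region is
    assigned.
    """
    if max_extension is None:
        max_extension = np.zeros(len(regions), dtype=np.int64)
    pos = table.positions()
    ref_end = table.ref_ends()
    contigs = np.array([r.contig for r in table.records])
    out: list[np.ndarray] = []
    for r, ext in zip(regions, max_extension):
        win_end = r.end + int(ext)
        mask = (contigs == r.contig) & (pos < win_end) & (ref_end > r.start)
        out.append(np.flatnonzero(mask).astype(np.int32))
    return out


def sparsify_genotypes(
    table: VariantTable,
    assignment: list[np.ndarray],
) -> SparseGenotypes:
    """Flip the dense variant-major genotype matrix into per-haplotype rows.

    Row ``(r, s, h)`` lists exactly the region-``r`` variants with genotype 1
    on haplotype ``(s, h)``, position-sorted. If two such variants have
    overlapping REF spans (which phased callers should not emit but real
    files sometimes do), the earlier one is kept and the later dropped with
    a warning; ties keep the first in file order.
    """
    n_samples, ploidy = table.n_samples, table.ploidy
    ref_end = table.ref_ends()
    pos = table.positions()
    rows: list[np.ndarray] = []
    n_dropped = 0
    for region_variants in assignment:
        # genotype submatrix for this region: (n_assigned, n_samples, ploidy)
        sub = table.genotypes[region_variants] if region_variants.size else None
        for s in range(n_samples):
            for h in range(ploidy):
                if sub is None:
                    rows.append(np.empty(0, dtype=np.int32))
                    continue
                carried = region_variants[sub[:, s, h] == 1]
                if carried.size > 1:
                    keep = []
                    last_end = -1
                    for vi in carried:  # already pos-sorted (table is sorted)
                        if pos[vi] < last_end:
                            n_dropped += 1
                            continue
                        keep.append(vi)
                        last_end = int(ref_end[vi])
                    carried = np.asarray(keep, dtype=np.int32)
                rows.append(carried.astype(np.int32))
    if n_dropped:
        logger.warning(
            "dropped %d variant call(s) whose REF span overlaps an earlier "
            "variant on the same haplotype", n_dropped,
        )
    return SparseGenotypes(
        ragged=RaggedArray.from_rows(rows, dtype=np.int32),
        n_regions=len(assignment),
        n_samples=n_samples,
        ploidy=ploidy,
    )


def _effective_delta(pos: int, ref_end: int, alt_len: int, win_start: int, win_end: int) -> int:
    """Length change a variant causes within a window, mirroring the cursor
    reconstruction: in-window REF bases are consumed; the alt contributes
    only when the variant's anchor lies inside the window."""
    ref_in_window = min(ref_end, win_end) - max(pos, win_start)
    alt_contrib = alt_len if pos >= win_start else 0
    return alt_contrib - ref_in_window


def compute_extensions(
    table: VariantTable,
    regions: list[Region],
) -> tuple[SparseGenotypes, np.ndarray, np.ndarray]:
    """Fixed-point computation of per-region reference extensions.

    A haplotype carrying net deletions inside ``[start, end)`` needs extra
    reference past ``end`` to reach the region length; but variants inside
    that extra stretch may delete further. Iterate (assign -> sparsify ->
    per-row deletion excess -> new extension) until stable, capping each
    extension at ``EXTENSION_CAP_FACTOR`` x region length with a warning.

    Extensions only ever grow across iterations: a variant admitted by a
    wider window may be an insertion, which *reduces* the computed shortfall,
    and shrinking the window again would oscillate. The monotone update can
    overshoot the minimal extension slightly; the cost is a few extra
    reference bases fetched, never a wrong output.

    Returns ``(sparse, per_row_excess, max_extension)`` where ``sparse`` is
    built against the final extended windows.
    """
    n_regions = len(regions)
    ext = np.zeros(n_regions, dtype=np.int64)
    caps = np.array([EXTENSION_CAP_FACTOR * r.length for r in regions], dtype=np.int64)
    pos = table.positions()
    ref_end = table.ref_ends()
    alt_len = np.fromiter((len(r.alt) for r in table.records), dtype=np.int64,
                          count=table.n_variants)

    while True:
        assignment = assign_variants_to_regions(table, regions, ext)
        sparse = sparsify_genotypes(table, assignment)
        excess = np.zeros(sparse.ragged.n_rows, dtype=np.int64)
        new_ext = np.zeros(n_regions, dtype=np.int64)
        for ri, region in enumerate(regions):
            win_end = region.end + int(ext[ri])
            for s in range(sparse.n_samples):
                for h in range(sparse.ploidy):
                    row_i = flat_index(ri, s, h, sparse.n_samples, sparse.ploidy)
                    vis = sparse.ragged.row(row_i)
                    if vis.size:
                        total = sum(
                            _effective_delta(int(pos[v]), int(ref_end[v]), int(alt_len[v]),
                                             region.start, win_end)
                            for v in vis
                        )
                        excess[row_i] = max(0, -total)
            region_rows = excess[
                flat_index(ri, 0, 0, sparse.n_samples, sparse.ploidy):
                flat_index(ri, sparse.n_samples - 1, sparse.ploidy - 1,
                           sparse.n_samples, sparse.ploidy) + 1
            ]
            new_ext[ri] = region_rows.max() if region_rows.size else 0
        over = new_ext > caps
        if over.any():
            logger.warning(
                "capping extension at %dx region length for %d region(s)",
                EXTENSION_CAP_FACTOR, int(over.sum()),
            )
            new_ext = np.minimum(new_ext, caps)
        new_ext = np.maximum(new_ext, ext)  # monotone: never shrink
        if np.array_equal(new_ext, ext):
            return sparse, excess, ext
        ext = new_ext


# ---------------------------------------------------------------------------
# coverage tracks


def run_length_encode(values: np.ndarray, window_start: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode per-base values into maximal constant ``(start, end, value)`` runs."""
    values = np.asarray(values, dtype=np.float32)
    if values.size == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), np.empty(0, dtype=np.float32)
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change)).astype(np.int64) + window_start
    ends = np.concatenate((change, [values.size])).astype(np.int64) + window_start
    return starts, ends, values[starts - window_start]


class _BedGraphTrack:
    """Per-contig sorted (start, end, value) arrays parsed from a bedGraph file."""

    def __init__(self, path: Path):
        data: dict[str, list[tuple[int, int, float]]] = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split("\t")[:4]
            data.setdefault(c, []).append((int(s), int(e), float(v)))
        self.by_contig = {
            c: tuple(np.asarray(col) for col in zip(*sorted(rows)))
            for c, rows in data.items()
        }

    def contigs(self) -> set[str]:
        return set(self.by_contig)

    def window_values(self, contig: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=np.float32)
        entry = self.by_contig.get(contig)
        if entry is None:
            return out
        starts, ends, vals = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
            out[max(s, start) - start : max(min(e, end) - start, 0)] = v
        return out


class _BigWigTrack:
    def __init__(self, path: Path):
        import pyBigWig

        self.bw = pyBigWig.open(str(path))
        self.chrom_sizes = self.bw.chroms()

    def contigs(self) -> set[str]:
        return set(self.chrom_sizes)

    def window_values(self, contig: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=np.float32)
        size = self.chrom_sizes.get(contig)
        if size is None:
            return out
        hi = min(end, size)
        if hi > start:
            vals = np.asarray(self.bw.values(contig, start, hi, numpy=True), dtype=np.float32)
            np.nan_to_num(vals, copy=False)
            out[: hi - start] = vals
        return out


def _open_track(path: Path):
    suffix = path.suffix.lower()
    try:
        if suffix in (".bw", ".bigwig"):
            return _BigWigTrack(path)
        return _BedGraphTrack(path)
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read track file {path}: {exc}") from exc


def bigwig_to_intervals(
    track_paths: dict[str, Path | str],
    regions: list[Region],
    max_extension: np.ndarray,
) -> IntervalStore:
    """Run-length encode per-sample coverage over every extended region.

    One track file (BigWig or bedGraph, chosen by extension) per sample.
    Absent data — a region past the track's end, or a contig the track does
    not know — encodes as value 0.0 (with a warning for missing contigs).
    Decoding the runs back to per-base values is lossless.
    """
    starts_rows: list[np.ndarray] = []
    ends_rows: list[np.ndarray] = []
    value_rows: list[np.ndarray] = []
    lengths: list[int] = []
    missing_contigs: set[tuple[str, str]] = set()

    sample_tracks = []
    for sample, p in track_paths.items():
        p = Path(p)
        if not p.exists():
            raise IOError(f"track file for sample {sample} not found: {p}")
        sample_tracks.append((sample, _open_track(p)))

    for ri, region in enumerate(regions):
        win_end = region.end + int(max_extension[ri])
        for sample, track in sample_tracks:
            if region.contig not in track.contigs():
                missing_contigs.add((sample, region.contig))
            vals = track.window_values(region.contig, region.start, win_end)
            s, e, v = run_length_encode(vals, region.start)
            starts_rows.append(s)
            ends_rows.append(e)
            value_rows.append(v)
            lengths.append(s.size)

    for sample, contig in sorted(missing_contigs):
        logger.warning("track for sample %s lacks contig %s; zero-filled", sample, contig)

    offsets = ragged_from_lengths(lengths)
    cat = lambda rows, dtype: (
        np.concatenate(rows).astype(dtype) if rows else np.empty(0, dtype=dtype)
    )
    return IntervalStore(
        starts=cat(starts_rows, np.int64),
        ends=cat(ends_rows, np.int64),
        values=cat(value_rows, np.float32),
        offsets=offsets,
        n_regions=len(regions),
        n_samples=len(sample_tracks),
    )


# ---------------------------------------------------------------------------
# storage-cost model


def estimate_fasta_storage(
    n_genomes: int | float,
    ref_size_gb: float = 0.987,
    price_per_gb_month: float = 0.026,
) -> tuple[float, float]:
    """Storage for personalized diploid genomes kept as compressed FASTA.

    Each genome needs one compressed FASTA per haplotype, each roughly the
    size of the compressed reference genome (default 0.987 GB, GRCh37), so

        total_gb     = n_genomes x 2 x ref_size_gb
        monthly_cost = total_gb x price_per_gb_month   (default $0.026/GB-mo)

    Returns ``(total_gb, monthly_cost_usd)``.
    """
    if n_genomes < 0 or ref_size_gb < 0 or price_per_gb_month < 0:
        raise InvalidInputError("storage-cost inputs must be non-negative")
    total_gb = n_genomes * 2 * ref_size_gb
    return total_gb, total_gb * price_per_gb_month
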