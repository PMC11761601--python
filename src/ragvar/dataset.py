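"""The on-disk dataset: write once, memory-map forever.

``write_dataset`` runs the full ingest pipeline (load variants -> assign to
regions -> sparsify -> deletion-extension fixed point -> interval-encode
tracks) and lays the results down as headerless little-endian flat files
described by ``manifest.json``. ``open_dataset`` validates file sizes
against the manifest, fail-fast checks the reference, and memory-maps the
arrays, so serving a haplotype touches only the bytes of its own rows.

Store layout (all paths relative to the dataset directory)::

    manifest.json                   metadata, dtypes, array lengths
    regions.bed                     verbatim copy of the input regions
    variants.pos.bin        <i8     0-based REF start per variant
    variants.size_delta.bin <i4     len(alt) - len(ref)
    variants.contig.bin     <i4     index into manifest's contig list
    variants.alleles.bin    u1      ragged bytes, rows 2v (ref) / 2v+1 (alt)
    variants.alleles.offsets.bin <i8
    genotypes.idx.bin       <i4     ragged variant indices per (region,
    genotypes.offsets.bin   <i8       sample, haplotype), region-major
    intervals.start.bin     <i8     ragged coverage runs per (region,
    intervals.end.bin       <i8       sample), tiling the extended region
    intervals.value.bin     <f4
    intervals.offsets.bin   <i8
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from pyfaidx import Fasta

from . import ingest
from .core import FORMAT_VERSION, DatasetManifest, Region, VariantRecord, flat_index
from .errors import CorruptStoreError, InvalidInputError, UnsupportedVersionError
from .reconstruct import intervals_to_values, orient, realign_track, reconstruct_haplotype

logger = logging.getLogger(__name__)

__all__ = ["Batch", "Dataset", "write_dataset", "open_dataset", "one_hot"]

_ARRAY_SPECS = {
    "variants.pos": ("variants.pos.bin", "<i8"),
    "variants.size_delta": ("variants.size_delta.bin", "<i4"),
    "variants.contig": ("variants.contig.bin", "<i4"),
    "variants.alleles": ("variants.alleles.bin", "u1"),
    "variants.alleles.offsets": ("variants.alleles.offsets.bin", "<i8"),
    "genotypes.idx": ("genotypes.idx.bin", "<i4"),
    "genotypes.offsets": ("genotypes.offsets.bin", "<i8"),
    "intervals.start": ("intervals.start.bin", "<i8"),
    "intervals.end": ("intervals.end.bin", "<i8"),
    "intervals.value": ("intervals.value.bin", "<f4"),
    "intervals.offsets": ("intervals.offsets.bin", "<i8"),
}


@dataclass(frozen=True)
class Batch:
    """One minibatch of personalized haplotypes and re-aligned tracks.

    ``sequences`` is ``(batch, ploidy, length)`` of single bytes (dtype S1),
    ``tracks`` is ``(batch, ploidy, length)`` float32; ``region_indices`` /
    ``sample_indices`` locate each entry within the (possibly subset)
    dataset it came from.
    """

    sequences: np.ndarray
    tracks: np.ndarray
    region_indices: np.ndarray
    sample_indices: np.ndarray

    def __len__(self) -> int:
        return self.sequences.shape[0]


def _write_array(out: Path, name: str, arr: np.ndarray, arrays: dict) -> None:
    fname, dtype = _ARRAY_SPECS[name]
    data = np.ascontiguousarray(arr).astype(dtype)
    (out / fname).write_bytes(data.tobytes())
    arrays[name] = {"path": fname, "dtype": dtype, "length": int(data.size)}


def write_dataset(
    vcf_path: Path | str,
    bed_path: Path | str,
    track_table_path: Path | str,
    reference_path: Path | str,
    out_dir: Path | str,
    overwrite: bool = False,
) -> DatasetManifest:
    """Convert VCF + BED + coverage tracks into the memory-mapped store.

    All regions must share one length (fixed-length model inputs). Samples
    are ordered as in the VCF; the track table must provide a file for each.
    Re-running with identical inputs writes byte-identical files.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise InvalidInputError(
                f"output directory {out} is not empty (pass overwrite=True to replace)"
            )
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    regions = ingest.read_bed(bed_path)
    lengths = {r.length for r in regions}
    if len(lengths) > 1:
        offenders = sorted(lengths)
        raise InvalidInputError(
            f"all regions must share one length; found lengths {offenders}"
        )

    table = ingest.load_variant_table(vcf_path, regions, reference_path)
    sparse, _excess, max_ext = ingest.compute_extensions(table, regions)

    tracks = ingest.read_track_table(track_table_path)
    missing = [s for s in table.sample_names if s not in tracks]
    if missing:
        raise InvalidInputError(f"track table lacks sample(s): {', '.join(missing)}")
    ordered_tracks = {s: tracks[s] for s in table.sample_names}
    intervals = ingest.bigwig_to_intervals(ordered_tracks, regions, max_ext)

    contigs = sorted({r.contig for r in table.records} | {r.contig for r in regions})
    contig_idx = {c: i for i, c in enumerate(contigs)}

    arrays: dict = {}
    _write_array(out, "variants.pos", table.positions(), arrays)
    _write_array(out, "variants.size_delta", table.size_deltas(), arrays)
    _write_array(
        out, "variants.contig",
        np.fromiter((contig_idx[r.contig] for r in table.records), dtype=np.int32,
                    count=table.n_variants),
        arrays,
    )
    allele_bytes = bytearray()
    allele_offsets = [0]
    for rec in table.records:
        for allele in (rec.ref, rec.alt):
            allele_bytes.extend(allele.encode("ascii"))
            allele_offsets.append(len(allele_bytes))
    _write_array(out, "variants.alleles", np.frombuffer(bytes(allele_bytes), dtype=np.uint8), arrays)
    _write_array(out, "variants.alleles.offsets", np.asarray(allele_offsets), arrays)
    _write_array(out, "genotypes.idx", sparse.ragged.data, arrays)
    _write_array(out, "genotypes.offsets", sparse.ragged.offsets, arrays)
    _write_array(out, "intervals.start", intervals.starts, arrays)
    _write_array(out, "intervals.end", intervals.ends, arrays)
    _write_array(out, "intervals.value", intervals.values, arrays)
    _write_array(out, "intervals.offsets", intervals.offsets, arrays)

    shutil.copyfile(bed_path, out / "regions.bed")

    manifest = DatasetManifest(
        format_version=FORMAT_VERSION,
        n_regions=len(regions),
        n_samples=table.n_samples,
        ploidy=table.ploidy,
        sample_names=list(table.sample_names),
        contigs=contigs,
        regions=[
            {"contig": r.contig, "start": r.start, "end": r.end, "strand": r.strand}
            for r in regions
        ],
        max_extension=[int(e) for e in max_ext],
        n_variants=table.n_variants,
        arrays=arrays,
    )
    manifest.save(out / "manifest.json")
    logger.info(
        "wrote dataset: %d regions x %d samples x ploidy %d, %d variants",
        manifest.n_regions, manifest.n_samples, manifest.ploidy, manifest.n_variants,
    )
    return manifest


def _open_memmap(path: Path, dtype: str, length: int) -> np.ndarray:
    if length == 0:
        return np.empty(0, dtype=dtype)
    return np.memmap(path, dtype=dtype, mode="r", shape=(length,))


@dataclass
class Dataset:
    """Read-only handle over a written store.

    Arrays are memory-mapped: opening performs no full-file reads, and
    ``subset`` produces index-remapped views without copying store data.
    """

    root: Path
    manifest: DatasetManifest
    reference_path: Path
    region_ids: np.ndarray  # active subset -> parent region indices
    sample_ids: np.ndarray
    _arrays: dict = field(default_factory=dict, repr=False)
    _fasta: Fasta | None = field(default=None, repr=False)
    _regions: list[Region] | None = field(default=None, repr=False)

    # -- lazy handles -------------------------------------------------------

    def _array(self, name: str) -> np.ndarray:
        if name not in self._arrays:
            meta = self.manifest.arrays[name]
            self._arrays[name] = _open_memmap(
                self.root / meta["path"], meta["dtype"], meta["length"]
            )
        return self._arrays[name]

    @property
    def fasta(self) -> Fasta:
        if self._fasta is None:
            self._fasta = Fasta(str(self.reference_path), as_raw=True, rebuild=False)
        return self._fasta

    @property
    def regions(self) -> list[Region]:
        if self._regions is None:
            self._regions = self.manifest.region_objects()
        return self._regions

    # -- shape --------------------------------------------------------------

    @property
    def n_regions(self) -> int:
        return self.region_ids.size

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def ploidy(self) -> int:
        return self.manifest.ploidy

    @property
    def region_length(self) -> int:
        r = self.regions[0]
        return r.length

    @property
    def sample_names(self) -> list[str]:
        return [self.manifest.sample_names[i] for i in self.sample_ids]

    def __len__(self) -> int:
        return self.n_regions * self.n_samples

    # -- variant decoding ---------------------------------------------------

    def _variant(self, vi: int) -> VariantRecord:
        pos = int(self._array("variants.pos")[vi])
        contig = self.manifest.contigs[int(self._array("variants.contig")[vi])]
        offs = self._array("variants.alleles.offsets")
        blob = self._array("variants.alleles")
        ref = blob[int(offs[2 * vi]) : int(offs[2 * vi + 1])].tobytes().decode("ascii")
        alt = blob[int(offs[2 * vi + 1]) : int(offs[2 * vi + 2])].tobytes().decode("ascii")
        return VariantRecord(contig, pos, ref, alt)

    def _variant_row(self, region_id: int, sample_id: int, hap: int) -> list[VariantRecord]:
        row = flat_index(region_id, sample_id, hap,
                         self.manifest.n_samples, self.manifest.ploidy)
        offs = self._array("genotypes.offsets")
        idx = self._array("genotypes.idx")[int(offs[row]) : int(offs[row + 1])]
        return [self._variant(int(v)) for v in idx]

    def _interval_row(self, region_id: int, sample_id: int):
        row = region_id * self.manifest.n_samples + sample_id
        offs = self._array("intervals.offsets")
        lo, hi = int(offs[row]), int(offs[row + 1])
        return (
            self._array("intervals.start")[lo:hi],
            self._array("intervals.end")[lo:hi],
            self._array("intervals.value")[lo:hi],
        )

    # -- core access --------------------------------------------------------

    def get(self, region_idx: int, sample_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """Personalized ``(sequences, tracks)`` for one (region, sample).

        Returns ``(ploidy, L)`` byte and float32 arrays, ``L`` the common
        region length, strand-oriented per the region's BED strand. A pure
        function of (store, reference, indices).
        """
        if not 0 <= region_idx < self.n_regions:
            raise IndexError(f"region index {region_idx} out of range [0, {self.n_regions})")
        if not 0 <= sample_idx < self.n_samples:
            raise IndexError(f"sample index {sample_idx} out of range [0, {self.n_samples})")
        rid = int(self.region_ids[region_idx])
        sid = int(self.sample_ids[sample_idx])
        region = self.regions[rid]
        ext = self.manifest.max_extension[rid]
        L = region.length
        win_len = L + ext

        raw = str(self.fasta[region.contig][region.start : region.start + win_len])
        window = raw.upper().ljust(win_len, "N")  # contig end -> N padding
        starts, ends, values = self._interval_row(rid, sid)
        base_values = intervals_to_values(starts, ends, values, region.start, win_len)

        seqs = np.empty((self.ploidy, L), dtype="S1")
        tracks = np.empty((self.ploidy, L), dtype=np.float32)
        for h in range(self.ploidy):
            variants = self._variant_row(rid, sid, h)
            result = reconstruct_haplotype(window, variants, L, window_start=region.start)
            track = realign_track(base_values, variants, L, window_start=region.start)
            seqs[h] = orient(result, region.strand).sequence
            tracks[h] = orient(track, region.strand)
        return seqs, tracks

    # -- subsetting ---------------------------------------------------------

    def subset(
        self,
        region_indices: np.ndarray | list[int] | None = None,
        sample_indices: np.ndarray | list[int] | None = None,
    ) -> "Dataset":
        """View-only subset; composing subsets composes the index maps."""
        def _resolve(sel, current: np.ndarray, what: str) -> np.ndarray:
            if sel is None:
                return current
            sel = np.asarray(sel, dtype=np.int64)
            if sel.size != np.unique(sel).size:
                raise InvalidInputError(f"duplicate {what} indices in subset")
            if sel.size and (sel.min() < 0 or sel.max() >= current.size):
                raise InvalidInputError(
                    f"{what} indices out of range [0, {current.size})"
                )
            return current[sel]

        return replace(
            self,
            region_ids=_resolve(region_indices, self.region_ids, "region"),
            sample_ids=_resolve(sample_indices, self.sample_ids, "sample"),
        )

    # -- iteration ----------------------------------------------------------

    def iter_batches(
        self, batch_size: int, shuffle: bool = False, seed: int | None = None
    ) -> Iterator[Batch]:
        """Yield every (region, sample) pair exactly once per epoch.

        Unshuffled order is row-major (region-major, then sample). With
        ``shuffle=True``, the order is a permutation drawn from numpy's
        PCG64 generator seeded with ``seed``, hence identical across runs
        and processes for equal seeds. The final partial batch is yielded.
        """
        if batch_size < 1:
            raise InvalidInputError("batch_size must be >= 1")
        n = len(self)
        order = np.arange(n)
        if shuffle:
            logger.info("shuffling epoch with PCG64 seed %r", seed)
            order = np.random.default_rng(seed).permutation(n)
        for lo in range(0, n, batch_size):
            chunk = order[lo : lo + batch_size]
            r_idx = chunk // self.n_samples
            s_idx = chunk % self.n_samples
            seqs = []
            tracks = []
            for r, s in zip(r_idx, s_idx):
                sq, tr = self.get(int(r), int(s))
                seqs.append(sq)
                tracks.append(tr)
            yield Batch(
                sequences=np.stack(seqs),
                tracks=np.stack(tracks),
                region_indices=r_idx.astype(np.int64),
                sample_indices=s_idx.astype(np.int64),
            )


def open_dataset(out_dir: Path | str, reference_path: Path | str) -> Dataset:
    """Open a written store for reading.

    Validates the manifest version, the byte length of every store file,
    and — fail-fast — that the reference genome knows every region's
    contig. No array data is read until first access.
    """
    root = Path(out_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise CorruptStoreError(f"no manifest.json in {root}")
    manifest = DatasetManifest.load(manifest_path)
    if manifest.format_version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"store format {manifest.format_version!r} is not supported "
            f"(this build reads {FORMAT_VERSION!r})"
        )
    for name, meta in manifest.arrays.items():
        path = root / meta["path"]
        if not path.exists():
            raise CorruptStoreError(f"store file missing: {meta['path']}")
        expected = meta["length"] * np.dtype(meta["dtype"]).itemsize
        actual = path.stat().st_size
        if actual != expected:
            raise CorruptStoreError(
                f"store file {meta['path']} is {actual} bytes, expected {expected}"
            )

    fasta = Fasta(str(reference_path), as_raw=True, rebuild=False)
    for r in manifest.regions:
        if r["contig"] not in fasta:
            raise CorruptStoreError(
                f"reference genome lacks contig {r['contig']} used by a region"
            )

    ds = Dataset(
        root=root,
        manifest=manifest,
        reference_path=Path(reference_path),
        region_ids=np.arange(manifest.n_regions, dtype=np.int64),
        sample_ids=np.arange(manifest.n_samples, dtype=np.int64),
    )
    ds._fasta = fasta
    return ds


_ONE_HOT_LUT = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate(b"ACGT"):
    _ONE_HOT_LUT[_b, _i] = 1.0
    _ONE_HOT_LUT[ord(chr(_b).lower()), _i] = 1.0


def one_hot(sequences: np.ndarray) -> np.ndarray:
    """One-hot encode byte sequences to ``(..., 4)`` float32 (A,C,G,T); any
    other byte (N) maps to an all-zero column."""
    codes = sequences.view(np.uint8)
    return _ONE_HOT_LUT[codes]
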