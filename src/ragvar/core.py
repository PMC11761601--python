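"""Shared domain types and the ragged-array container.

The store keeps every variable-length collection — variant index lists per
haplotype, allele strings, coverage runs per region/sample — as a
*ragged array*: one flat data vector plus an ``offsets`` vector of length
``n_rows + 1``, where row ``i`` occupies ``data[offsets[i]:offsets[i+1]]``.
Flat little-endian files of this shape can be memory-mapped directly, so a
single row is an O(1) slice with no decompression or search.

Coordinates are 0-based half-open everywhere inside the package: BED
intervals are used as-is and VCF positions are decremented once on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError

FORMAT_VERSION = "1.0"

__all__ = [
    "FORMAT_VERSION",
    "RaggedArray",
    "Region",
    "VariantRecord",
    "DatasetManifest",
    "ragged_from_lengths",
    "flat_index",
]


def ragged_from_lengths(lengths: Sequence[int] | np.ndarray) -> np.ndarray:
    """Build an offsets vector from per-row lengths.

    Parameters
    ----------
    lengths
        Non-negative row lengths. May be empty.

    Returns
    -------
    numpy.ndarray
        int64 vector of length ``len(lengths) + 1`` with ``offsets[0] == 0``
        and ``offsets[i+1] - offsets[i] == lengths[i]``.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.ndim != 1:
        raise InvalidInputError("lengths must be one-dimensional")
    if arr.size and arr.min() < 0:
        raise InvalidInputError("row lengths must be non-negative")
    offsets = np.zeros(arr.size + 1, dtype=np.int64)
    np.cumsum(arr, out=offsets[1:])
    return offsets


def flat_index(
    region_idx: int, sample_idx: int, hap_idx: int, n_samples: int, ploidy: int
) -> int:
    """Row index of ``(region, sample, haplotype)`` in the sample-major layout.

    Rows are ordered region-major, then sample, then haplotype, so one
    sample's haplotypes for one region are adjacent on disk.
    """
    if not 0 <= sample_idx < n_samples:
        raise IndexError(f"sample index {sample_idx} out of range [0, {n_samples})")
    if not 0 <= hap_idx < ploidy:
        raise IndexError(f"haplotype index {hap_idx} out of range [0, {ploidy})")
    if region_idx < 0:
        raise IndexError(f"region index {region_idx} is negative")
    return (region_idx * n_samples + sample_idx) * ploidy + hap_idx


@dataclass(frozen=True)
class RaggedArray:
    """Variable-length rows over one flat data vector.

    ``data`` may be any 1-D numpy array (including memory-mapped); ``offsets``
    is int64 with ``offsets[0] == 0``, non-decreasing, and
    ``offsets[-1] == len(data)``. Empty rows are allowed.
    """

    data: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets)
        if offsets.ndim != 1 or offsets.size < 1:
            raise InvalidInputError("offsets must be a 1-D vector of length >= 1")
        if offsets[0] != 0:
            raise InvalidInputError("offsets[0] must be 0")
        if offsets.size > 1 and np.any(np.diff(offsets) < 0):
            raise InvalidInputError("offsets must be non-decreasing")
        if int(offsets[-1]) != len(self.data):
            raise InvalidInputError(
                f"offsets[-1] ({int(offsets[-1])}) != len(data) ({len(self.data)})"
            )

    @classmethod
    def from_rows(cls, rows: Iterable[np.ndarray | Sequence], dtype=None) -> "RaggedArray":
        rows = [np.asarray(r, dtype=dtype) for r in rows]
        offsets = ragged_from_lengths([len(r) for r in rows])
        if rows:
            data = np.concatenate(rows) if offsets[-1] else np.empty(0, dtype=rows[0].dtype)
        else:
            data = np.empty(0, dtype=dtype if dtype is not None else np.int64)
        return cls(data=data, offsets=offsets)

    @property
    def n_rows(self) -> int:
        return self.offsets.size - 1

    def __len__(self) -> int:
        return self.n_rows

    def row(self, i: int) -> np.ndarray:
        """Return row ``i`` as a zero-copy slice of the flat data."""
        if not 0 <= i < self.n_rows:
            raise IndexError(f"row index {i} out of range [0, {self.n_rows})")
        return self.data[int(self.offsets[i]) : int(self.offsets[i + 1])]

    def lengths(self) -> np.ndarray:
        return np.diff(self.offsets)

    def rows(self) -> list[np.ndarray]:
        return [self.row(i) for i in range(self.n_rows)]


@dataclass(frozen=True)
class Region:
    """A genomic window, 0-based half-open, with an optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InvalidInputError(
                f"region {self.contig}:{self.start}-{self.end} must satisfy 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


_ALLELE_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class VariantRecord:
    """One decomposed biallelic variant.

    ``pos`` is the 0-based position of the first REF base. ``size_delta``
    (``len(alt) - len(ref)``) is negative for deletions and positive for
    insertions; indel-aware reconstruction and track re-alignment are driven
    entirely by this quantity and the REF span ``[pos, pos + len(ref))``.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise InvalidInputError(
                    f"{name} allele {allele!r} at {self.contig}:{self.pos} "
                    "must be a non-empty string over A/C/G/T/N"
                )
        if self.pos < 0:
            raise InvalidInputError(f"variant position {self.pos} is negative")

    @property
    def size_delta(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def ref_end(self) -> int:
        """End (exclusive) of the REF span."""
        return self.pos + len(self.ref)


@dataclass
class DatasetManifest:
    """Versioned metadata binding the store files together.

    Arrays are headerless flat files of little-endian fixed-width elements;
    every shape and dtype lives here, so the files themselves need no parsing
    — only a size check at open followed by memory-mapping.
    """

    format_version: str
    n_regions: int
    n_samples: int
    ploidy: int
    sample_names: list[str]
    contigs: list[str]
    regions: list[dict]          # contig/start/end/strand per region
    max_extension: list[int]     # bp past region end fetched for deletions
    n_variants: int
    arrays: dict = field(default_factory=dict)  # name -> {path, dtype, length}

    def to_json(self) -> str:
        payload = {
            "format_version": self.format_version,
            "n_regions": self.n_regions,
            "n_samples": self.n_samples,
            "ploidy": self.ploidy,
            "sample_names": self.sample_names,
            "contigs": self.contigs,
            "regions": self.regions,
            "max_extension": self.max_extension,
            "n_variants": self.n_variants,
            "arrays": self.arrays,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(
            format_version=d["format_version"],
            n_regions=d["n_regions"],
            n_samples=d["n_samples"],
            ploidy=d["ploidy"],
            sample_names=list(d["sample_names"]),
            contigs=list(d["contigs"]),
            regions=list(d["regions"]),
            max_extension=list(d["max_extension"]),
            n_variants=d["n_variants"],
            arrays=dict(d["arrays"]),
        )

    def save(self, path: Path | str) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Path | str) -> "DatasetManifest":
        return cls.from_json(Path(path).read_text())

    def region_objects(self) -> list[Region]:
        return [
            Region(r["contig"], r["start"], r["end"], r.get("strand", "+"))
            for r in self.regions
        ]
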