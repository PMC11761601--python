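"""Synthetic inputs (reference, phased VCF, regions, coverage tracks) and
naive splice oracles.

The generator emulates the statistical shape of a WGS + ATAC-seq cohort:
a uniform-random reference contig, phased biallelic SNPs and indels at
realistic per-bp rates with per-site allele frequencies, and per-sample
piecewise-constant read-depth tracks with rectangular peaks, with regions of
interest centered on the peaks. Every generator is a pure function of
``(config, seed)``.

The oracles (:func:`oracle_consensus`, :func:`oracle_realign`) apply
variants by literal left-to-right string/list splicing with an explicit
cumulative offset — deliberately naive, so they verify the cursor engine
without sharing any code with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Region, VariantRecord
from .errors import InvalidInputError

__all__ = [
    "SimulationConfig",
    "make_reference",
    "make_phased_vcf",
    "make_tracks",
    "write_fixture",
    "oracle_consensus",
    "oracle_realign",
]

_BASES = np.array(list("ACGT"))
CONTIG = "chr1"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults model a dense variant landscape over a 200 kb contig: one SNP
    per 100 bp, one indel per 500 bp (sizes 1-16 bp), 8 diploid samples, and
    64 non-overlapping 2,048 bp regions — enough haplotype draws (64 x 8 x 2
    = 1,024) for exhaustive oracle comparison while staying desk-sized.
    """

    contig_length: int = 200_000
    n_samples: int = 8
    snp_rate: float = 0.01
    indel_rate: float = 0.002
    max_indel_len: int = 16
    region_length: int = 2_048
    n_regions: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contig_length <= 0:
            raise InvalidInputError("contig_length must be positive")
        if not (0 <= self.snp_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise InvalidInputError("rates must lie in [0, 1]")
        if self.max_indel_len < 1:
            raise InvalidInputError("max_indel_len must be >= 1")
        if self.n_samples < 1 or self.n_regions < 1 or self.region_length < 1:
            raise InvalidInputError("n_samples, n_regions, region_length must be >= 1")
        # each region needs room for its maximum possible extension (2x its
        # length) before the contig end
        usable = self.contig_length - 2 * self.region_length
        if usable < self.n_regions * self.region_length:
            raise InvalidInputError(
                f"{self.n_regions} regions of {self.region_length} bp do not fit "
                f"in a {self.contig_length} bp contig with room for extensions"
            )

    @property
    def sample_names(self) -> list[str]:
        return [f"sample{i}" for i in range(self.n_samples)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so adding one never perturbs another
    return np.random.default_rng([config.seed, stream])


def make_reference(config: SimulationConfig) -> str:
    """Uniform-random A/C/G/T sequence of ``contig_length``."""
    rng = _rng(config, 0)
    return "".join(_BASES[rng.integers(0, 4, size=config.contig_length)])


def make_phased_vcf(config: SimulationConfig, reference: str) -> str:
    """VCF 4.2 text with phased biallelic SNPs and indels.

    A left-to-right sweep draws at most one site per position (SNP with
    probability ``snp_rate``, else indel with probability ``indel_rate``)
    and then jumps past the site's REF span, so no two REF spans overlap.
    Deletions remove 1..max_indel_len bases (REF length 2..max_indel_len+1,
    ALT = anchor base); insertions add 1..max_indel_len bases after a 1-base
    REF. Per site the alt-allele frequency is uniform(0.05, 0.5) and each
    haplotype draws its allele independently, written phased.
    """
    rng = _rng(config, 1)
    n_hap = 2 * config.n_samples
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CONTIG},length={config.contig_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(config.sample_names),
    ]

    pos = 1  # leave base 0 untouched so indel anchors always exist
    limit = config.contig_length - config.max_indel_len - 1
    while pos < limit:
        u = rng.random()
        if u < config.snp_rate:
            ref = reference[pos]
            alt = str(rng.choice(_BASES[_BASES != ref]))
            span = 1
        elif u < config.snp_rate + config.indel_rate:
            if rng.random() < 0.5:  # deletion
                n_del = int(rng.integers(1, config.max_indel_len + 1))
                ref = reference[pos : pos + n_del + 1]
                alt = ref[0]
                span = n_del + 1
            else:  # insertion
                ref = reference[pos]
                n_ins = int(rng.integers(1, config.max_indel_len + 1))
                alt = ref + "".join(_BASES[rng.integers(0, 4, size=n_ins)])
                span = 1
        else:
            pos += 1
            continue
        af = rng.uniform(0.05, 0.5)
        haps = (rng.random(n_hap) < af).astype(int)
        gts = "\t".join(f"{haps[2 * s]}|{haps[2 * s + 1]}" for s in range(config.n_samples))
        lines.append(f"{CONTIG}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}")
        pos += span  # REF spans never overlap

    return "\n".join(lines) + "\n"


def make_tracks(
    config: SimulationConfig, n_peaks: int | None = None
) -> tuple[dict[str, list[tuple[int, int, float]]], list[Region]]:
    """Per-sample piecewise-constant depth tracks and peak-centered regions.

    Regions (all of ``region_length``) are placed in non-overlapping slots
    across the contig; the first ``n_peaks`` regions (default: all) get a
    rectangular peak per sample — height uniform 1..50, width uniform
    100..500 bp — centered on the region. Returns ``(runs_per_sample,
    regions)`` where runs are nonzero ``(start, end, value)`` triples.
    """
    if n_peaks is None:
        n_peaks = config.n_regions
    rng = _rng(config, 2)
    usable = config.contig_length - 2 * config.region_length
    slot = usable // config.n_regions

    regions: list[Region] = []
    for i in range(config.n_regions):
        jitter = int(rng.integers(0, max(slot - config.region_length, 0) + 1))
        start = i * slot + jitter
        regions.append(Region(CONTIG, start, start + config.region_length, "+"))

    runs: dict[str, list[tuple[int, int, float]]] = {s: [] for s in config.sample_names}
    for i, region in enumerate(regions[: min(n_peaks, config.n_regions)]):
        center = (region.start + region.end) // 2
        for sample in config.sample_names:
            height = float(rng.integers(1, 51))
            width = int(rng.integers(100, 501))
            s = max(center - width // 2, 0)
            e = min(s + width, config.contig_length)
            runs[sample].append((s, e, height))
    for sample in runs:
        runs[sample].sort()
    return runs, regions


def write_fixture(
    config: SimulationConfig, out_dir: Path | str, n_peaks: int | None = None
) -> dict[str, Path]:
    """Write the complete input fixture to ``out_dir``.

    Emits ``reference.fa`` (+ ``.fai``), ``variants.vcf``, ``regions.bed``
    (BED6), ``tracks/<sample>.bedgraph`` and the 2-column ``tracks.tsv``
    mapping. Returns the paths keyed by role.
    """
    from pyfaidx import Faidx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)

    reference = make_reference(config)
    ref_path = out / "reference.fa"
    with ref_path.open("w") as fh:
        fh.write(f">{CONTIG}\n")
        for i in range(0, len(reference), 60):
            fh.write(reference[i : i + 60] + "\n")
    Faidx(str(ref_path), rebuild=True)

    vcf_path = out / "variants.vcf"
    vcf_path.write_text(make_phased_vcf(config, reference))

    runs, regions = make_tracks(config, n_peaks)
    bed_path = out / "regions.bed"
    with bed_path.open("w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tregion{i}\t0\t{r.strand}\n")

    tsv_lines = []
    for sample in config.sample_names:
        track_path = out / "tracks" / f"{sample}.bedgraph"
        with track_path.open("w") as fh:
            for s, e, v in runs[sample]:
                fh.write(f"{CONTIG}\t{s}\t{e}\t{v:g}\n")
        tsv_lines.append(f"{sample}\ttracks/{sample}.bedgraph")
    tsv_path = out / "tracks.tsv"
    tsv_path.write_text("\n".join(tsv_lines) + "\n")

    return {
        "reference": ref_path,
        "vcf": vcf_path,
        "bed": bed_path,
        "tracks": tsv_path,
    }


# ---------------------------------------------------------------------------
# oracles


def _check_oracle_preconditions(variants: Sequence[VariantRecord]) -> None:
    last_end = None
    last_pos = None
    for v in variants:
        if last_pos is not None and v.pos < last_pos:
            raise InvalidInputError("oracle requires pos-sorted variants")
        if last_end is not None and v.pos < last_end:
            raise InvalidInputError(
                f"oracle requires non-overlapping variants (REF span ending at "
                f"{last_end} overlaps variant at {v.pos})"
            )
        last_pos, last_end = v.pos, v.ref_end


def oracle_consensus(
    ref_window: str, variants: Sequence[VariantRecord], window_start: int = 0
) -> str:
    """Full (untruncated) personalized string by literal splicing.

    Applies each variant left to right as ``s[i:i+len(ref)] = alt`` at the
    offset-corrected index. A variant whose REF span begins before the
    window keeps no alt bases and loses only its in-window REF portion.
    Output length = window length + sum of in-window size deltas.
    """
    _check_oracle_preconditions(variants)
    s = list(ref_window.upper())
    offset = 0
    for v in variants:
        rel = v.pos - window_start
        if rel < 0:
            # only the first variant can span the window start, so offset == 0
            cut = rel + len(v.ref)  # in-window REF bases to remove
            if cut > 0:
                del s[0:cut]
                offset -= cut
            continue
        i = rel + offset
        s[i : i + len(v.ref)] = list(v.alt)
        offset += v.size_delta
    return "".join(s)


def oracle_realign(
    values: Sequence[float] | np.ndarray,
    variants: Sequence[VariantRecord],
    window_start: int = 0,
) -> np.ndarray:
    """Full (untruncated) re-aligned value vector by literal splicing.

    The splice drops the values of deleted REF bases (keeping the anchor's)
    and repeats the anchor's value for every inserted base.
    """
    _check_oracle_preconditions(variants)
    vals = [float(x) for x in np.asarray(values)]
    offset = 0
    for v in variants:
        rel = v.pos - window_start
        if rel < 0:
            cut = rel + len(v.ref)
            if cut > 0:
                del vals[0:cut]
                offset -= cut
            continue
        i = rel + offset
        n_ref = len(v.ref)
        replacement = [
            vals[min(i + min(j, n_ref - 1), len(vals) - 1)] for j in range(len(v.alt))
        ]
        vals[i : i + n_ref] = replacement
        offset += v.size_delta
    return np.asarray(vals, dtype=np.float32)
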