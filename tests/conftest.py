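"""Shared fixtures: a small synthetic cohort written once per session.

The standard fixture is 10 regions x 4 diploid samples over a 60 kb contig
with 1,024 bp regions — large enough to contain SNPs and indels in most
regions, small enough that every test that needs a written store can share
one. Hand-built VCF/reference helpers serve the tests that need precise
pathological inputs (overlaps, unphased calls, REF mismatches).
"""

from pathlib import Path

import numpy as np
import pytest
from pyfaidx import Faidx

import ragvar
from ragvar.simulate import CONTIG


@pytest.fixture(scope="session")
def small_config() -> ragvar.SimulationConfig:
    return ragvar.SimulationConfig(
        contig_length=60_000,
        n_samples=4,
        n_regions=10,
        region_length=1_024,
        seed=13,
    )


@pytest.fixture(scope="session")
def fixture_paths(small_config, tmp_path_factory) -> dict[str, Path]:
    out = tmp_path_factory.mktemp("inputs")
    return ragvar.write_fixture(small_config, out)


@pytest.fixture(scope="session")
def store_dir(fixture_paths, tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("store") / "ds"
    ragvar.write_dataset(
        fixture_paths["vcf"],
        fixture_paths["bed"],
        fixture_paths["tracks"],
        fixture_paths["reference"],
        out,
    )
    return out


@pytest.fixture(scope="session")
def dataset(store_dir, fixture_paths) -> ragvar.Dataset:
    return ragvar.open_dataset(store_dir, fixture_paths["reference"])


def write_reference(path: Path, sequence: str, contig: str = CONTIG) -> Path:
    """Write a single-contig FASTA plus .fai index."""
    with path.open("w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")
    Faidx(str(path), rebuild=True)
    return path


def write_vcf(path: Path, body_lines: list[str], samples: list[str],
              contig: str = CONTIG, contig_length: int = 1000) -> Path:
    """Write a minimal VCF 4.2 with the given pre-formatted body lines."""
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header + body_lines) + "\n")
    return path


@pytest.fixture()
def tiny_reference(tmp_path) -> tuple[Path, str]:
    """A fixed 120 bp reference for hand-built VCF tests."""
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
    return write_reference(tmp_path / "ref.fa", seq), seq
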