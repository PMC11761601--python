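"""VCF loading, sparsification, extension fixed point, interval encoding,
and the FASTA storage-cost model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ragvar
from ragvar.core import Region, VariantRecord
from ragvar.errors import InvalidInputError, PhasedInputRequiredError, ReferenceMismatchError
from ragvar.ingest import (
    VariantTable,
    assign_variants_to_regions,
    bigwig_to_intervals,
    compute_extensions,
    estimate_fasta_storage,
    load_variant_table,
    read_track_table,
    run_length_encode,
    sparsify_genotypes,
)
from ragvar.reconstruct import intervals_to_values
from ragvar.simulate import CONTIG, oracle_consensus

from conftest import write_vcf


def _regions(*spans):
    return [Region(CONTIG, s, e) for s, e in spans]


def _table(records, genotypes):
    """VariantTable from records plus a (n_var, n_samples, ploidy) matrix."""
    return VariantTable(
        records=records,
        genotypes=np.asarray(genotypes, dtype=np.uint8),
        sample_names=[f"sample{i}" for i in range(np.asarray(genotypes).shape[1])],
    )


# ---------------------------------------------------------------------------
# VCF loading


class TestLoadVariantTable:
    def test_snp_parse_converts_to_zero_based(self, tmp_path, tiny_reference):
        ref_path, seq = tiny_reference
        vcf = write_vcf(
            tmp_path / "a.vcf", [f"{CONTIG}\t5\t.\t{seq[4]}\t{'G' if seq[4] != 'G' else 'T'}\t.\t.\t.\tGT\t0|1"],
            ["s0"], contig_length=len(seq),
        )
        table = load_variant_table(vcf, _regions((0, 100)), ref_path)
        assert table.n_variants == 1
        rec = table.records[0]
        assert (rec.pos, rec.ref) == (4, seq[4])
        assert table.genotypes[0, 0].tolist() == [0, 1]

    def test_multiallelic_site_is_decomposed(self, tmp_path, tiny_reference):
        ref_path, seq = tiny_reference
        alts = [b for b in "ACGT" if b != seq[4]][:2]
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [f"{CONTIG}\t5\t.\t{seq[4]}\t{alts[0]},{alts[1]}\t.\t.\t.\tGT\t1|2"],
            ["s0"], contig_length=len(seq),
        )
        table = load_variant_table(vcf, _regions((0, 100)), ref_path)
        assert table.n_variants == 2
        assert [r.alt for r in table.records] == alts
        # allele 1 on hap0, allele 2 on hap1
        assert table.genotypes[0, 0].tolist() == [1, 0]
        assert table.genotypes[1, 0].tolist() == [0, 1]

    def test_unphased_call_is_rejected(self, tmp_path, tiny_reference):
        ref_path, seq = tiny_reference
        vcf = write_vcf(
            tmp_path / "a.vcf", [f"{CONTIG}\t5\t.\t{seq[4]}\tN\t.\t.\t.\tGT\t0/1"],
            ["s0"], contig_length=len(seq),
        )
        with pytest.raises(PhasedInputRequiredError, match="s0"):
            load_variant_table(vcf, _regions((0, 100)), ref_path)

    def test_missing_genotype_counts_as_reference(self, tmp_path, tiny_reference):
        ref_path, seq = tiny_reference
        alt = "G" if seq[4] != "G" else "T"
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [f"{CONTIG}\t5\t.\t{seq[4]}\t{alt}\t.\t.\t.\tGT\t.|.\t.|1"],
            ["s0", "s1"], contig_length=len(seq),
        )
        table = load_variant_table(vcf, _regions((0, 100)), ref_path)
        assert table.genotypes[0, 0].tolist() == [0, 0]  # missing -> ref
        assert table.genotypes[0, 1].tolist() == [0, 1]  # half-call -> ref

    def test_symbolic_alleles_are_skipped(self, tmp_path, tiny_reference):
        ref_path, seq = tiny_reference
        vcf = write_vcf(
            tmp_path / "a.vcf", [f"{CONTIG}\t5\t.\t{seq[4]}\t<DEL>\t.\t.\t.\tGT\t0|1"],
            ["s0"], contig_length=len(seq),
        )
        table = load_variant_table(vcf, _regions((0, 100)), ref_path)
        assert table.n_variants == 0

    def test_ref_mismatch_is_a_validation_error(self, tmp_path, tiny_reference):
        ref_path, seq = tiny_reference
        wrong = "A" if seq[4] != "A" else "C"
        vcf = write_vcf(
            tmp_path / "a.vcf", [f"{CONTIG}\t5\t.\t{wrong}\tT\t.\t.\t.\tGT\t0|1"],
            ["s0"], contig_length=len(seq),
        )
        with pytest.raises(ReferenceMismatchError):
            load_variant_table(vcf, _regions((0, 100)), ref_path)

    def test_loading_is_idempotent(self, fixture_paths, small_config):
        from ragvar.ingest import read_bed

        regions = read_bed(fixture_paths["bed"])
        t1 = load_variant_table(fixture_paths["vcf"], regions, fixture_paths["reference"])
        t2 = load_variant_table(fixture_paths["vcf"], regions, fixture_paths["reference"])
        assert t1.records == t2.records
        assert np.array_equal(t1.genotypes, t2.genotypes)
        assert t1.sample_names == t2.sample_names


# ---------------------------------------------------------------------------
# assignment and sparsification


def test_assignment_uses_ref_span_intersection():
    records = [
        VariantRecord(CONTIG, 9, "A", "C"),       # span [9,10): outside
        VariantRecord(CONTIG, 8, "AAAA", "A"),    # span [8,12): spans into region
        VariantRecord(CONTIG, 19, "A", "ATT"),    # span [19,20): inside
    ]
    table = _table(records, np.ones((3, 1, 2)))
    (assigned,) = assign_variants_to_regions(table, [Region(CONTIG, 10, 20)])
    assert assigned.tolist() == [1, 2]


def test_sparsify_matches_hand_worked_example():
    records = [VariantRecord(CONTIG, 3, "A", "C"), VariantRecord(CONTIG, 7, "A", "G")]
    # s0: 0|1 then 1|1 ; s1: 0|0 then 0|1
    genotypes = [
        [[0, 1], [0, 0]],
        [[1, 1], [0, 1]],
    ]
    table = _table(records, genotypes)
    assignment = assign_variants_to_regions(table, [Region(CONTIG, 0, 10)])
    sparse = sparsify_genotypes(table, assignment)
    assert sparse.row(0, 0, 0).tolist() == [1]
    assert sparse.row(0, 0, 1).tolist() == [0, 1]
    assert sparse.row(0, 1, 0).tolist() == []
    assert sparse.row(0, 1, 1).tolist() == [1]


def test_all_reference_genotypes_give_empty_rows():
    records = [VariantRecord(CONTIG, 3, "A", "C")]
    table = _table(records, np.zeros((1, 2, 2)))
    sparse = sparsify_genotypes(
        table, assign_variants_to_regions(table, [Region(CONTIG, 0, 10)])
    )
    assert sparse.ragged.data.size == 0
    assert sparse.ragged.n_rows == 4


def test_overlapping_same_haplotype_variants_keep_earlier():
    records = [
        VariantRecord(CONTIG, 3, "AAAA", "A"),  # deletes [3,7)
        VariantRecord(CONTIG, 5, "A", "T"),     # inside the deletion's span
    ]
    table = _table(records, np.ones((2, 1, 2)))
    sparse = sparsify_genotypes(
        table, assign_variants_to_regions(table, [Region(CONTIG, 0, 10)])
    )
    assert sparse.row(0, 0, 0).tolist() == [0]


def _densify(sparse, n_variants, assignment):
    """Naive dense reconstruction: independent oracle for the round trip."""
    dense = np.zeros((n_variants, sparse.n_samples, sparse.ploidy), dtype=np.uint8)
    assigned = set(assignment[0].tolist())
    for s in range(sparse.n_samples):
        for h in range(sparse.ploidy):
            for vi in sparse.row(0, s, h):
                dense[vi, s, h] = 1
    return dense, assigned


def test_sparsify_densify_round_trip():
    """Sparse rows carry exactly the dense genotype matrix, restricted to
    assigned variants (here: all non-overlapping, all assigned)."""
    rng = np.random.default_rng(5)
    positions = np.sort(rng.choice(np.arange(0, 400, 2), size=20, replace=False))
    records = [VariantRecord(CONTIG, int(p), "A", "C") for p in positions]
    genotypes = rng.integers(0, 2, size=(20, 5, 2)).astype(np.uint8)
    table = _table(records, genotypes)
    assignment = assign_variants_to_regions(table, [Region(CONTIG, 0, 400)])
    sparse = sparsify_genotypes(table, assignment)
    dense, assigned = _densify(sparse, 20, assignment)
    assert assigned == set(range(20))
    # SNP REF spans never overlap, so nothing is dropped
    assert np.array_equal(dense, genotypes)


# ---------------------------------------------------------------------------
# extensions


def test_deletion_excess_is_net_shortfall():
    records = [
        VariantRecord(CONTIG, 5, "AAAA", "A"),   # -3
        VariantRecord(CONTIG, 20, "A", "ATTTTT"),  # +5
    ]
    # sample0 carries only the deletion on hap0; sample1 carries both on hap0
    genotypes = [
        [[1, 0], [1, 0]],
        [[0, 0], [1, 0]],
    ]
    table = _table(records, genotypes)
    sparse, excess, max_ext = compute_extensions(table, [Region(CONTIG, 0, 30)])
    assert excess[0] == 3       # deletion only
    assert excess[2] == 0       # -3 + 5 clips at zero
    assert max_ext[0] == 3


def test_extension_fixed_point_admits_cascading_deletions():
    """A deletion just past the region end only matters once the first
    deletion extends the window; the fixed point must find both. The oracle
    is the personalized string length from a full splice."""
    region = Region(CONTIG, 0, 20)
    records = [
        VariantRecord(CONTIG, 10, "AAAAAA", "A"),  # -5, inside region
        VariantRecord(CONTIG, 22, "AAAA", "A"),    # -3, only in extended window
    ]
    table = _table(records, np.ones((2, 1, 1)))
    sparse, excess, max_ext = compute_extensions(table, [region])
    assert max_ext[0] == 8

    # oracle: splice the full extended window; output must reach 20 bases
    window = "A" * (region.length + int(max_ext[0]))
    personalized = oracle_consensus(window, [records[0], records[1]], window_start=0)
    assert len(personalized) >= region.length


def test_extension_fixed_point_terminates_when_extension_admits_insertion():
    """An insertion that only enters the window once a deletion extends it
    reduces the shortfall; the fixed point must settle, not oscillate."""
    records = [
        VariantRecord(CONTIG, 10, "AAAAAA", "A"),    # -5 inside the region
        VariantRecord(CONTIG, 22, "A", "AAAAAA"),    # +5, visible only extended
    ]
    table = _table(records, np.ones((2, 1, 1)))
    _, _, max_ext = compute_extensions(table, [Region(CONTIG, 0, 20)])
    assert max_ext[0] >= 5  # enough window to absorb the deletion
    assert max_ext[0] <= 40  # and still bounded by the cap


def test_extension_capped_at_twice_region_length():
    region = Region(CONTIG, 0, 10)
    # pathological: deletions tile the whole window and beyond
    records = [VariantRecord(CONTIG, p, "A" * 10, "A") for p in range(0, 60, 10)]
    table = _table(records, np.ones((len(records), 1, 1)))
    _, _, max_ext = compute_extensions(table, [region])
    assert max_ext[0] == 20


# ---------------------------------------------------------------------------
# intervals


def test_run_length_encoding_example():
    starts, ends, values = run_length_encode(np.array([5, 5, 5, 2, 2], dtype=np.float32), 100)
    assert starts.tolist() == [100, 103]
    assert ends.tolist() == [103, 105]
    assert values.tolist() == [5.0, 2.0]


def test_all_zero_window_is_one_run():
    starts, ends, values = run_length_encode(np.zeros(50, dtype=np.float32), 7)
    assert (starts.tolist(), ends.tolist(), values.tolist()) == ([7], [57], [0.0])


@given(
    st.lists(st.sampled_from([0.0, 1.0, 2.5, 7.0]), min_size=1, max_size=60),
    st.integers(0, 1000),
)
@settings(deadline=None, max_examples=100)
def test_run_length_round_trip(vals, start):
    v = np.asarray(vals, dtype=np.float32)
    s, e, r = run_length_encode(v, start)
    assert np.array_equal(intervals_to_values(s, e, r, start, v.size), v)
    # maximal runs: adjacent runs never share a value
    assert all(r[i] != r[i + 1] for i in range(r.size - 1))


def _bedgraph(path, rows):
    path.write_text("".join(f"{CONTIG}\t{s}\t{e}\t{v}\n" for s, e, v in rows))
    return path


def test_bedgraph_ingest_tiles_extended_region(tmp_path):
    track = _bedgraph(tmp_path / "a.bedgraph", [(100, 103, 5.0), (103, 105, 2.0)])
    regions = [Region(CONTIG, 100, 105)]
    store = bigwig_to_intervals({"s0": track}, regions, np.array([3]))
    starts, ends, values = store.row(0, 0)
    # contiguous tiling of [100, 108) with zero fill past the data
    assert starts[0] == 100 and ends[-1] == 108
    assert np.array_equal(starts[1:], ends[:-1])
    decoded = intervals_to_values(starts, ends, values, 100, 8)
    assert decoded.tolist() == [5, 5, 5, 2, 2, 0, 0, 0]


def test_missing_contig_zero_fills(tmp_path):
    track = (tmp_path / "empty.bedgraph")
    track.write_text("otherchr\t0\t5\t1.0\n")
    store = bigwig_to_intervals({"s0": track}, [Region(CONTIG, 0, 10)], np.array([0]))
    starts, ends, values = store.row(0, 0)
    assert values.tolist() == [0.0]
    assert (starts[0], ends[-1]) == (0, 10)


def test_unreadable_track_names_sample(tmp_path):
    with pytest.raises(IOError, match="s0"):
        bigwig_to_intervals(
            {"s0": tmp_path / "missing.bedgraph"}, [Region(CONTIG, 0, 10)], np.array([0])
        )


def test_bigwig_input_matches_bedgraph(tmp_path):
    pyBigWig = pytest.importorskip("pyBigWig")
    rows = [(10, 40, 3.0), (40, 60, 1.0)]
    bw_path = tmp_path / "a.bw"
    bw = pyBigWig.open(str(bw_path), "w")
    bw.addHeader([(CONTIG, 1000)])
    bw.addEntries(
        [CONTIG] * len(rows),
        [r[0] for r in rows],
        ends=[r[1] for r in rows],
        values=[r[2] for r in rows],
    )
    bw.close()
    bg_path = _bedgraph(tmp_path / "a.bedgraph", rows)
    regions = [Region(CONTIG, 0, 80)]
    from_bw = bigwig_to_intervals({"s0": bw_path}, regions, np.array([0]))
    from_bg = bigwig_to_intervals({"s0": bg_path}, regions, np.array([0]))
    assert np.array_equal(from_bw.starts, from_bg.starts)
    assert np.array_equal(from_bw.ends, from_bg.ends)
    assert np.array_equal(from_bw.values, from_bg.values)


def test_track_table_resolves_relative_paths(tmp_path):
    (tmp_path / "t.bedgraph").write_text("")
    tsv = tmp_path / "tracks.tsv"
    tsv.write_text("s0\tt.bedgraph\n")
    table = read_track_table(tsv)
    assert table["s0"] == tmp_path / "t.bedgraph"


# ---------------------------------------------------------------------------
# storage-cost model


def test_storage_cost_model():
    total_gb, monthly = estimate_fasta_storage(1_000_000, 0.987, 0.026)
    assert total_gb == pytest.approx(1_974_000)
    assert monthly == pytest.approx(51_324)

    total_gb, _ = estimate_fasta_storage(3_202, 0.987, 0.026)
    assert total_gb == pytest.approx(6_320.748)

    assert estimate_fasta_storage(0, 0.987, 0.026) == (0, 0)
    with pytest.raises(InvalidInputError):
        estimate_fasta_storage(-1, 0.987, 0.026)
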