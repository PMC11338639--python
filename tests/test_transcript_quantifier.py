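"""Pseudo-mapping, RPKM/TPM arithmetic, detection and aggregation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codhscan.io_formats import reverse_complement
from codhscan.transcript_quantifier import (
    GeneMeta,
    assign_read,
    assign_reads,
    build_kmer_index,
    compute_rpkm,
    compute_tpm,
    detect_and_aggregate,
    quant_from_counts,
    read_fastq,
)


def _random_gene(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestKmerIndex:
    def test_minimal_gene_indexes_one_forward_kmer(self):
        rng = random.Random(0)
        seq = _random_gene(rng, 31)
        index = build_kmer_index([("g", seq)])
        assert seq in index
        assert reverse_complement(seq) in index
        forward = {k for k, v in index.items() if "g" in v}
        assert len(forward) <= 2  # the k-mer and its reverse complement

    def test_identical_genes_share_all_kmers(self):
        rng = random.Random(1)
        seq = _random_gene(rng, 60)
        index = build_kmer_index([("a", seq), ("b", seq)])
        for genes in index.values():
            assert genes == {"a", "b"}

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_kmer_index([("a", "A" * 40), ("a", "C" * 40)])

    def test_determinism(self):
        rng = random.Random(2)
        genes = [("g%d" % i, _random_gene(rng, 100)) for i in range(3)]
        assert build_kmer_index(genes) == build_kmer_index(genes)


class TestAssignReads:
    def test_unique_read_assigned_to_source(self):
        rng = random.Random(3)
        genes = [("a", _random_gene(rng, 300)), ("b", _random_gene(rng, 300))]
        index = build_kmer_index(genes)
        read = genes[0][1][50:150]
        assert assign_read(read, index) == "a"
        assert assign_read(reverse_complement(read), index) == "a"

    def test_shared_region_read_discarded_as_tie(self):
        rng = random.Random(4)
        shared = _random_gene(rng, 120)
        genes = [("a", shared + _random_gene(rng, 100)),
                 ("b", shared + _random_gene(rng, 100))]
        index = build_kmer_index(genes)
        assert assign_read(shared[:100], index) == ""  # ambiguous

    def test_foreign_read_unassigned(self):
        rng = random.Random(5)
        genes = [("a", _random_gene(rng, 200))]
        index = build_kmer_index(genes)
        assert assign_read(_random_gene(rng, 100), index) is None

    def test_read_count_conservation(self):
        rng = random.Random(6)
        genes = [("g%d" % i, _random_gene(rng, 400)) for i in range(5)]
        reads = []
        for i in range(200):
            gid, seq = genes[rng.randrange(5)]
            start = rng.randrange(len(seq) - 80)
            reads.append((f"r{i}", seq[start : start + 80]))
        reads.append(("alien", _random_gene(rng, 80)))
        quant = assign_reads(reads, genes)
        assert (
            quant.mapped_reads + quant.ambiguous_reads + quant.unassigned_reads
            == quant.total_reads
            == 201
        )
        assert sum(quant.counts.values()) == quant.mapped_reads

    def test_covered_positions_bounded_by_length(self):
        rng = random.Random(7)
        genes = [("a", _random_gene(rng, 500))]
        reads = [("r%d" % i, genes[0][1][i * 40 : i * 40 + 90]) for i in range(10)]
        quant = assign_reads(reads, genes)
        assert 0 < quant.covered_positions["a"] <= 500


class TestAbundanceFormulas:
    def test_rpkm_worked_example(self):
        rpkm = compute_rpkm({"g": 10}, {"g": 2000}, mapped_reads=1_000_000)
        assert rpkm["g"] == pytest.approx(5.0)

    def test_rpkm_scale_invariance_and_zero(self):
        r1 = compute_rpkm({"a": 4, "b": 0}, {"a": 1000, "b": 500}, 100)
        r2 = compute_rpkm({"a": 8, "b": 0}, {"a": 1000, "b": 500}, 200)
        assert r1 == pytest.approx(r2)
        assert r1["b"] == 0.0
        assert compute_rpkm({"a": 0}, {"a": 100}, 0) == {"a": 0.0}

    def test_rpkm_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm({"a": 1}, {"a": 0}, 10)

    def test_tpm_symmetry_and_zero_vector(self):
        assert compute_tpm({"a": 5.0, "b": 5.0}) == pytest.approx(
            {"a": 5e5, "b": 5e5}
        )
        assert compute_tpm({"a": 0.0, "b": 0.0}) == {"a": 0.0, "b": 0.0}

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=30)
    )
    def test_tpm_normalization_property(self, values):
        rpkm = {f"g{i}": v for i, v in enumerate(values)}
        tpm = compute_tpm(rpkm)
        total = sum(tpm.values())
        if sum(values) > 0:
            assert total == pytest.approx(1e6, rel=1e-9)
        else:
            assert total == 0.0


class TestDetectAndAggregate:
    META = {
        "w1": GeneMeta("w1", genus="Blautia", context_type="WLP"),
        "p1": GeneMeta("p1", genus="Veillonella", context_type="PEPCK"),
    }

    def _quant(self, counts):
        return quant_from_counts(counts, {"w1": 1000, "p1": 1000}, "d1")

    def test_zero_reads_not_detected(self):
        s = detect_and_aggregate(self._quant({"w1": 0, "p1": 0}), self.META)
        assert not s.pcodh_detected and s.pcodh_reads == 0

    def test_single_context_gets_full_fraction(self):
        s = detect_and_aggregate(self._quant({"w1": 10, "p1": 0}), self.META)
        assert s.pcodh_detected
        assert s.read_fraction_by_context["WLP"] == pytest.approx(1.0)

    def test_missing_metadata_raises_with_gene_name(self):
        quant = quant_from_counts({"x": 5}, {"x": 500}, "d1")
        with pytest.raises(ValueError, match="x"):
            detect_and_aggregate(quant, self.META)

    def test_taxon_fractions_sum_to_one(self):
        s = detect_and_aggregate(self._quant({"w1": 30, "p1": 10}), self.META)
        assert sum(s.read_fraction_by_taxon["genus"].values()) == pytest.approx(1.0)
        assert s.read_fraction_by_taxon["genus"]["Blautia"] == pytest.approx(0.75)


def test_fastq_roundtrip(tmp_path):
    from codhscan.synthetic_data import write_fastq

    reads = [("r1 src", "ACGTACGT"), ("r2", "TTTTAAAA")]
    p = tmp_path / "r.fastq"
    write_fastq(p, reads)
    assert read_fastq(p) == reads
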