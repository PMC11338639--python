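"""Homology search: alignment statistics, thresholds, clade assignment."""

from __future__ import annotations

import random

import pytest

from codhscan.homolog_search import (
    SearchParams,
    align_local,
    assign_clade,
    candidate_gene_ids,
    find_candidates,
    find_mo_codh,
    passes_thresholds,
)
from codhscan.io_formats import GeneRecord, GenomeBundle, TabularHit
from codhscan.synthetic_data import (
    AMINO_ACIDS,
    PlantSpec,
    PlantedGene,
    make_coxl_reference,
    mutate_to_identity,
    plant_genome,
)

from oracle_sw import sw_score


def _random_protein(rng, n):
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


class TestAlignLocal:
    def test_identical_sequences_full_identity(self, reference_set):
        (_, seq), *_ = reference_set[0]
        hit = align_local(seq[:300], seq[:300])
        assert hit.pct_identity == 100.0
        assert hit.aln_length == 300
        assert hit.q_start == 1 and hit.q_end == 300

    def test_half_mutated_copy_near_fifty_pct(self, reference_set):
        (_, seq), *_ = reference_set[0]
        mutant = mutate_to_identity(seq, 0.5, seed=3)
        hit = align_local(seq, mutant)
        assert abs(hit.pct_identity - 50.0) <= 2.0

    def test_random_pairs_fail_evalue_cutoff(self):
        rng = random.Random(0)
        params = SearchParams()
        for _ in range(25):
            a, b = _random_protein(rng, 300), _random_protein(rng, 300)
            assert align_local(a, b, params).evalue > params.evalue_max

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            align_local("MKV*", "MKVL")
        with pytest.raises(ValueError, match="empty"):
            align_local("", "MKVL")

    def test_score_matches_dp_oracle_on_short_pairs(self):
        rng = random.Random(1)
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-12,
            extend_gap_score=-1,
        )
        for _ in range(20):
            a = _random_protein(rng, rng.randint(8, 30))
            b = _random_protein(rng, rng.randint(8, 30))
            assert aligner.score(a, b) == pytest.approx(sw_score(a, b))


@pytest.fixture(scope="module")
def planted(reference_set):
    records, clade_map = reference_set
    spec = PlantSpec(
        genome_id="gsearch",
        planted_genes=[PlantedGene("synCooS_cladeE", 0.6)],
        seed=21,
        n_background_genes=20,
    )
    bundle, truth = plant_genome(spec, records, clade_map)
    planted_id = next(r.gene_id for r in truth if r.fact_type == "planted_codh")
    return bundle, planted_id


class TestFindCandidates:
    def test_planted_gene_recovered_background_clean(self, planted, reference_set):
        bundle, planted_id = planted
        records, _ = reference_set
        hits = find_candidates(bundle, records)
        assert candidate_gene_ids(hits) == [planted_id]

    def test_empty_reference_set_rejected(self, planted):
        bundle, _ = planted
        with pytest.raises(ValueError, match="empty reference set"):
            find_candidates(bundle, [])

    def test_threshold_monotonicity(self, planted, reference_set):
        bundle, _ = planted
        records, _ = reference_set
        rng = random.Random(5)
        loose = SearchParams(evalue_max=1e-3, identity_min_pct=15, alnlen_min_aa=50)
        base = set(candidate_gene_ids(find_candidates(bundle, records, loose)))
        prev = base
        for _ in range(4):
            stricter = SearchParams(
                evalue_max=loose.evalue_max * 10 ** -rng.randint(1, 8),
                identity_min_pct=loose.identity_min_pct + rng.randint(5, 30),
                alnlen_min_aa=loose.alnlen_min_aa + rng.randint(50, 200),
            )
            cur = set(candidate_gene_ids(find_candidates(bundle, records, stricter)))
            assert cur <= base
            prev = cur


class TestAssignClade:
    CLADES = {"refB": "B", "refE": "E"}

    def _hit(self, ref, ident, bits=100.0):
        return TabularHit(ref, "g1", ident, 300, 10, 0, 1, 300, 1, 300, 1e-50, bits)

    def test_argmax_identity(self):
        call = assign_clade(
            "g1", [self._hit("refE", 75.0), self._hit("refB", 40.0)], self.CLADES
        )
        assert call.clade == "E"
        assert call.best_identity_pct == 75.0

    def test_tie_breaks_bitscore_then_label(self):
        call = assign_clade(
            "g1",
            [self._hit("refE", 60.0, bits=90.0), self._hit("refB", 60.0, bits=95.0)],
            self.CLADES,
        )
        assert call.clade == "B"
        call = assign_clade(
            "g1",
            [self._hit("refE", 60.0, bits=90.0), self._hit("refB", 60.0, bits=90.0)],
            self.CLADES,
        )
        assert call.clade == "B"  # lexicographic

    def test_no_hit_raises(self):
        with pytest.raises(ValueError):
            assign_clade("gX", [], self.CLADES)


class TestMoCodh:
    def _bundle_with(self, protein, gene_id="mo1"):
        gene = GeneRecord(gene_id, "G", "c1", 0, 3 * len(protein) + 3, "+", protein=protein)
        return GenomeBundle(genome_id="G", contigs={}, genes=[gene])

    def test_motif_bearing_homolog_reported(self):
        ref = make_coxl_reference()
        protein = mutate_to_identity(ref[1], 0.7, protected_positions=range(380, 387), seed=1)
        assert "AYRCSFR" in protein
        assert find_mo_codh(self._bundle_with(protein), ref) == ["mo1"]

    def test_single_substitution_breaks_motif(self):
        ref = make_coxl_reference()
        protein = mutate_to_identity(ref[1], 0.7, protected_positions=range(380, 387), seed=1)
        broken = protein.replace("AYRCSFR", "AYRCSFS")
        assert find_mo_codh(self._bundle_with(broken), ref) == []


def test_passes_thresholds_is_conjunction():
    params = SearchParams()
    good = TabularHit("q", "s", 45.0, 250, 10, 0, 1, 250, 1, 250, 1e-20, 200.0)
    assert passes_thresholds(good, params)
    for field, value in [
        ("pct_identity", 25.0),
        ("aln_length", 150),
        ("evalue", 1e-5),
    ]:
        bad = TabularHit(
            "q", "s",
            25.0 if field == "pct_identity" else 45.0,
            150 if field == "aln_length" else 250,
            10, 0, 1, 250, 1, 250,
            1e-5 if field == "evalue" else 1e-20,
            200.0,
        )
        assert not passes_thresholds(bad, params)
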