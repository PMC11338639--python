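"""Generator contracts: determinism, identity control, planted truth."""

from __future__ import annotations

import itertools

import pytest

from codhscan.homolog_search import align_local
from codhscan.synthetic_data import (
    CONTEXT_TYPES,
    PlantSpec,
    PlantedGene,
    REFERENCE_CLADES,
    make_coxl_reference,
    make_reference_set,
    motif_window_positions,
    mutate_to_identity,
    plant_genome,
    simulate_reads,
    write_fastq,
)


class TestReferenceSet:
    def test_clade_labels_and_template_lengths(self, reference_set):
        records, clade_map = reference_set
        assert sorted(clade_map.values()) == sorted(REFERENCE_CLADES)
        assert all(len(seq) >= 600 for _, seq in records)

    def test_templates_mutually_divergent(self, reference_set):
        records, _ = reference_set
        for (_, a), (_, b) in itertools.combinations(records, 2):
            assert align_local(a, b).pct_identity < 60.0

    def test_same_seed_reproduces_byte_identical_set(self):
        assert make_reference_set(3) == make_reference_set(3)

    def test_templates_carry_motif_residues(self, reference_set, motif_config):
        records, _ = reference_set
        for _, seq in records:
            for site in motif_config.sites:
                for pos, allowed in zip(site.positions, site.required):
                    assert seq[pos - 1] in allowed


class TestMutateToIdentity:
    @pytest.mark.parametrize("target", [1.0, 0.9, 0.5, 0.3])
    def test_realized_identity_within_two_points(self, reference_set, target):
        (_, template), *_ = reference_set[0]
        mutant = mutate_to_identity(template, target, seed=5)
        matches = sum(a == b for a, b in zip(template, mutant))
        assert abs(matches / len(template) - target) <= 0.02

    def test_protected_positions_untouched(self, reference_set):
        (_, template), *_ = reference_set[0]
        protected = motif_window_positions()
        mutant = mutate_to_identity(template, 0.4, protected, seed=1)
        for p in protected:
            assert mutant[p - 1] == template[p - 1]

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError):
            mutate_to_identity("MKVL" * 10, 0.0, protected_positions=range(1, 30))


class TestPlantGenome:
    def _spec(self, **kw):
        defaults = dict(
            genome_id="g1",
            planted_genes=[PlantedGene("synCooS_cladeB", 0.6)],
            seed=3,
        )
        defaults.update(kw)
        return PlantSpec(**defaults)

    def test_wlp_context_places_acsb_within_window(self, reference_set):
        records, clade_map = reference_set
        bundle, truth = plant_genome(
            self._spec(context_type="WLP"), records, clade_map
        )
        focal = next(r.gene_id for r in truth if r.fact_type == "context_type")
        focal_rank = bundle.gene(focal).rank
        acsb = [g for g in bundle.genes if "K14138" in g.ko_ids]
        assert acsb and all(abs(g.rank - focal_rank) <= 15 for g in acsb)

    def test_no_context_means_no_marker_in_window(self, reference_set):
        records, clade_map = reference_set
        bundle, truth = plant_genome(self._spec(context_type=None), records, clade_map)
        focal = next(r.gene_id for r in truth if r.fact_type == "context_type")
        focal_rank = bundle.gene(focal).rank
        markers = {"K14138", "K01610", "COG1251", "COG4624", "K01738"}
        for g in bundle.genes:
            if abs(g.rank - focal_rank) <= 15 and g.gene_id != focal:
                assert not (g.annotations & markers)

    def test_motif_state_recorded_in_truth(self, reference_set):
        records, clade_map = reference_set
        spec = self._spec(
            planted_genes=[PlantedGene("synCooS_cladeC", 0.7, motif_state="substituted")]
        )
        _, truth = plant_genome(spec, records, clade_map)
        states = [r.value for r in truth if r.key == "motif_state"]
        assert states == ["substituted"]

    def test_determinism(self, reference_set):
        records, clade_map = reference_set
        spec = self._spec(context_type="FNOR", wlp_profile="fdh_lacking_pfl")
        b1, t1 = plant_genome(spec, records, clade_map)
        b2, t2 = plant_genome(spec, records, clade_map)
        assert b1.contigs == b2.contigs and t1 == t2

    def test_every_context_type_plants_cleanly(self, reference_set):
        records, clade_map = reference_set
        for ctx in CONTEXT_TYPES:
            bundle, _ = plant_genome(self._spec(context_type=ctx), records, clade_map)
            assert len(bundle.genes) == 40

    def test_window_overflow_raises(self, reference_set):
        records, clade_map = reference_set
        spec = self._spec(
            planted_genes=[PlantedGene("synCooS_cladeB", 0.6, rank_slot=39)],
            context_type="WLP",
        )
        with pytest.raises(ValueError, match="contig too small"):
            plant_genome(spec, records, clade_map)


class TestSimulateReads:
    def test_single_gene_reads_are_substrings(self, planted_bundle):
        bundle, _ = planted_bundle
        gid = bundle.genes[0].gene_id
        reads, counts = simulate_reads([bundle], {gid: 1.0}, 100, 100, seed=4)
        assert counts[gid] == 100
        seq = bundle.gene_nucleotide(gid)
        from codhscan.io_formats import reverse_complement

        for _, r in reads:
            assert r in seq or reverse_complement(r) in seq

    def test_weight_ratio_recovered(self, planted_bundle):
        bundle, _ = planted_bundle
        g1, g2 = bundle.genes[0].gene_id, bundle.genes[1].gene_id
        l1 = bundle.genes[0].length_nt
        l2 = bundle.genes[1].length_nt
        n = 10_000
        _, counts = simulate_reads([bundle], {g1: 1.0, g2: 3.0}, 80, n, seed=9)
        expected = 3 * l2 / (1 * l1 + 3 * l2)
        p_hat = counts[g2] / n
        # binomial 99.7 % interval
        sd = (expected * (1 - expected) / n) ** 0.5
        assert abs(p_hat - expected) < 3.5 * sd

    def test_deterministic_fastq(self, planted_bundle, tmp_path):
        bundle, _ = planted_bundle
        gid = bundle.genes[0].gene_id
        out = []
        for _ in range(2):
            reads, _c = simulate_reads([bundle], {gid: 1.0}, 60, 50, seed=2)
            p = tmp_path / "r.fastq"
            write_fastq(p, reads)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_zero_weights_rejected(self, planted_bundle):
        bundle, _ = planted_bundle
        gid = bundle.genes[0].gene_id
        with pytest.raises(ValueError, match="zero"):
            simulate_reads([bundle], {gid: 0.0}, 60, 10, seed=1)


def test_coxl_reference_carries_motif():
    _, seq = make_coxl_reference()
    assert "AYRCSFR" in seq
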