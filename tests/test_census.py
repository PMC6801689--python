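from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_match
from ringcensus import (
    GeneModel,
    TandemParams,
    build_census,
    count_intronless,
    find_tandem_clusters,
    pairwise_identity,
    protein_stats,
    scan_proteome,
)
from ringcensus.census import isoelectric_point, _net_charge


def gm(gene_id, protein_id, chrom, start, end, exons=1, strand="+"):
    return GeneModel(gene_id, protein_id, chrom, start, end, strand, exons)


class TestGeneModel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            gm("g", "p", "chr1", 100, 50)
        with pytest.raises(ValueError):
            gm("g", "p", "chr1", 1, 10, exons=0)


class TestBuildCensus:
    def test_empty(self):
        table = build_census([])
        assert table.n_complete_domains == 0
        assert table.n_ring_proteins == 0
        assert table.per_chromosome == {}

    def test_conservation_identities(self, small_proteome):
        records, gene_models, _ = small_proteome
        matches = scan_proteome(records)
        table = build_census(matches, gene_models)
        assert sum(table.per_chromosome.values()) == table.n_complete_domains
        assert sum(table.per_type.values()) == table.n_complete_domains
        n_complete_proteins = len({m.protein_id for m in matches if m.is_complete})
        assert table.n_ring_proteins == n_complete_proteins

    def test_per_chromosome_matches_planted_design(self, small_proteome):
        records, gene_models, truth = small_proteome
        matches = scan_proteome(records)
        table = build_census(matches, gene_models)
        chrom_of = {g.protein_id: g.chromosome for g in gene_models}
        expected = Counter(chrom_of[d.protein_id] for d in truth.domains)
        assert table.per_chromosome == dict(expected)

    def test_multi_domain_protein(self):
        matches = [
            make_match((2, 14, 1, 2, 2, 10, 2), protein_id="p1"),
            make_match((2, 14, 1, 2, 2, 10, 2), protein_id="p1", start=200),
            make_match((2, 14, 1, 2, 2, 10, 2), protein_id="p2"),
        ]
        table = build_census(matches)
        assert table.n_multi_domain == 1
        assert table.n_single_domain == 1

    def test_unplaced_and_chr0_flagged(self):
        matches = [
            make_match((2, 14, 1, 2, 2, 10, 2), protein_id="p1"),
            make_match((2, 14, 1, 2, 2, 10, 2), protein_id="p2"),
        ]
        models = [gm("g1", "p1", "0", 1, 1000)]
        table = build_census(matches, models)
        flags = {r.protein_id: r.excluded for r in table.rows}
        assert flags == {"p1": True, "p2": True}  # chr0 and unplaced
        assert sum(table.per_chromosome.values()) == 2


class TestCountIntronless:
    def test_examples(self):
        models = [
            gm("g1", "p1", "chr1", 1, 10, exons=1),
            gm("g2", "p2", "chr1", 20, 40, exons=2),
            gm("g3", "p3", "chr1", 50, 60, exons=1),
            gm("g4", "p4", "chr1", 70, 99, exons=5),
        ]
        assert count_intronless(models, ["g1", "g2", "g3", "g4"]) == 2
        assert count_intronless(models, []) == 0

    def test_planted_intronless(self, small_proteome):
        _, gene_models, _ = small_proteome
        all_ids = [g.gene_id for g in gene_models]
        expected = sum(1 for g in gene_models if g.exon_count == 1)
        assert count_intronless(gene_models, all_ids) == expected


class TestProteinStats:
    def test_glycine(self):
        stats = protein_stats("G")
        assert stats.length == 1
        assert stats.molecular_weight == pytest.approx(75.07, abs=0.005)

    def test_diglycine(self):
        assert protein_stats("GG").molecular_weight == pytest.approx(132.12, abs=0.005)

    def test_length(self):
        assert protein_stats("ACDEFG").length == 6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            protein_stats("")

    def test_nonstandard_letter_warns(self):
        with pytest.warns(UserWarning):
            protein_stats("GXG")

    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_additivity(self, a, b):
        mw = lambda s: protein_stats(s).molecular_weight
        assert mw(a + b) == pytest.approx(mw(a) + mw(b) - 18.0153, abs=1e-6)


class TestIsoelectricPoint:
    def test_basic_protein_high_pi(self):
        assert isoelectric_point("KKKKKKKK") > 9.5

    def test_acidic_protein_low_pi(self):
        assert isoelectric_point("DDDDDDDD") < 4.5

    def test_charge_at_pi_is_zero(self):
        for seq in ("MKLVHDE", "ACDEFGHIKLMNPQRSTVWY", "GGGG"):
            pi = isoelectric_point(seq)
            assert abs(_net_charge(Counter(seq), pi)) < 1e-4

    def test_charge_monotone_decreasing(self):
        counts = Counter("MKDEHRC")
        charges = [_net_charge(counts, ph) for ph in (0, 2, 4, 6, 8, 10, 12, 14)]
        assert all(a > b for a, b in zip(charges, charges[1:]))


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKLV", "MKLV") == 1.0

    def test_disjoint(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AATA") == 0.75

    def test_symmetric(self, rng):
        import numpy as np

        letters = np.array(list("ACDEFG"))
        for _ in range(10):
            a = "".join(rng.choice(letters, size=int(rng.integers(5, 20))))
            b = "".join(rng.choice(letters, size=int(rng.integers(5, 20))))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AAA")


class TestTandemClusters:
    def test_adjacent_duplicates(self):
        seqs = {"p1": "MKLVAD" * 10, "p2": "MKLVAD" * 10}
        ring = [gm("g1", "p1", "chr1", 1000, 2000), gm("g2", "p2", "chr1", 3000, 4000)]
        (cluster,) = find_tandem_clusters(ring, ring, seqs)
        assert cluster.gene_ids == ("g1", "g2")

    def test_far_apart_no_cluster(self):
        seqs = {"p1": "MKLVAD" * 10, "p2": "MKLVAD" * 10}
        ring = [gm("g1", "p1", "chr1", 1000, 2000), gm("g2", "p2", "chr1", 3_000_000, 3_001_000)]
        fillers = [
            gm(f"f{i}", f"fp{i}", "chr1", 10_000 + 1_000 * i, 10_500 + 1_000 * i)
            for i in range(5)
        ]
        assert find_tandem_clusters(ring, ring + fillers, seqs) == []

    def test_dissimilar_neighbours_not_clustered(self):
        seqs = {"p1": "MKLVAD" * 10, "p2": "WWYYFF" * 10}
        ring = [gm("g1", "p1", "chr1", 1000, 2000), gm("g2", "p2", "chr1", 3000, 4000)]
        assert find_tandem_clusters(ring, ring, seqs) == []

    def test_planted_triple(self, small_proteome):
        records, gene_models, truth = small_proteome
        (planted_group,) = truth.tandem
        sequences = {r.id: r.sequence for r in records}
        ring_proteins = {d.protein_id for d in truth.domains}
        ring = [g for g in gene_models if g.protein_id in ring_proteins]
        clusters = find_tandem_clusters(ring, gene_models, sequences)
        assert any(set(planted_group) <= set(c.gene_ids) for c in clusters)

    def test_row_order_invariance(self, small_proteome, rng):
        records, gene_models, truth = small_proteome
        sequences = {r.id: r.sequence for r in records}
        ring_proteins = {d.protein_id for d in truth.domains}
        ring = [g for g in gene_models if g.protein_id in ring_proteins]
        baseline = find_tandem_clusters(ring, gene_models, sequences)
        shuffled_ring = [ring[i] for i in rng.permutation(len(ring))]
        shuffled_all = [gene_models[i] for i in rng.permutation(len(gene_models))]
        assert find_tandem_clusters(shuffled_ring, shuffled_all, sequences) == baseline

    def test_params_respected(self):
        seqs = {"p1": "MKLVAD" * 10, "p2": "MKLVAD" * 10}
        ring = [gm("g1", "p1", "chr1", 1000, 2000), gm("g2", "p2", "chr1", 150_000, 151_000)]
        filler = [gm(f"f{i}", f"fp{i}", "chr1", 10_000 + i * 10_000, 11_000 + i * 10_000) for i in range(4)]
        params = TandemParams(max_intervening=1, max_distance=100_000)
        assert find_tandem_clusters(ring, ring + filler, seqs, params) == []
        params = TandemParams(max_intervening=10, max_distance=100_000)
        (cluster,) = find_tandem_clusters(ring, ring + filler, seqs, params)
        assert cluster.gene_ids == ("g1", "g2")
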