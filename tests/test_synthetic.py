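from __future__ import annotations

import numpy as np
import pytest

from ringcensus import (
    OctetCandidate,
    ProteomeConfig,
    TYPE_NAMES,
    classify_octet,
    generate_proteome,
    instantiate_consensus,
    mutate_cds,
    pairwise_identity,
    random_cds,
    scan_protein,
    scan_proteome,
)
from ringcensus.evolution import codons_of, _FORWARD
from ringcensus.scanner import ProteinRecord, enumerate_octets
from ringcensus.synthetic import InfeasibleConfigError, SAFE_FILLER


class TestInstantiateConsensus:
    def test_ring_g_fixed_length(self):
        s = instantiate_consensus("RING-G", (2, 16, 1, 2, 2, 13, 2), "A")
        assert len(s) == 46

    def test_round_trip_classification(self, rng):
        for type_name in TYPE_NAMES:
            for _ in range(5):
                s = instantiate_consensus(type_name, "random", None, rng)
                hits = enumerate_octets(s)
                assert len(hits) == 1
                assert hits[0].type_name == type_name

    def test_h2_explicit_gaps_classifies(self):
        s = instantiate_consensus("RING-H2", (2, 14, 1, 2, 2, 10, 2), "A")
        assert len(s) == 41
        (hit,) = enumerate_octets(s)
        assert classify_octet(hit.candidate) == "RING-H2"

    def test_gap_outside_spec_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            instantiate_consensus("RING-H2", (2, 40, 1, 2, 2, 10, 2))

    def test_bad_gap_shape_rejected(self):
        with pytest.raises(ValueError):
            instantiate_consensus("RING-H2", (2, 14, 1))

    def test_default_filler_is_safe(self, rng):
        s = instantiate_consensus("RING-H2", "random", None, rng)
        non_ligand = [c for i, c in enumerate(s) if c not in "CHSG"]
        assert set(non_ligand) <= set(SAFE_FILLER)

    def test_st_always_carries_serine(self, rng):
        for _ in range(20):
            s = instantiate_consensus("RING-S/T", "random", None, rng)
            (hit,) = enumerate_octets(s)
            assert hit.type_name == "RING-S/T"
            assert "S" in (hit.candidate.residues[1], hit.candidate.residues[5])


class TestGenerateProteome:
    def test_determinism(self):
        config = ProteomeConfig(n_proteins=10, n_domains=10, n_decoys=2, tandem_clusters=(2,))
        r1, g1, t1 = generate_proteome(config, 7)
        r2, g2, t2 = generate_proteome(config, 7)
        assert r1 == r2
        assert g1 == g2
        assert t1 == t2

    def test_different_seeds_differ(self):
        config = ProteomeConfig(n_proteins=10, n_domains=10)
        r1, _, _ = generate_proteome(config, 1)
        r2, _, _ = generate_proteome(config, 2)
        assert [r.sequence for r in r1] != [r.sequence for r in r2]

    def test_one_domain_each(self):
        config = ProteomeConfig(n_proteins=10, n_domains=10)
        records, _, truth = generate_proteome(config, 7)
        assert len(truth.domains) == 10
        assert len(records) == 10

    def test_truth_rows_verified_by_scanner(self):
        config = ProteomeConfig(n_proteins=30, n_domains=40)
        records, _, truth = generate_proteome(config, 3)
        by_id = {r.id: r for r in records}
        for d in truth.domains:
            seq = by_id[d.protein_id].sequence
            window = seq[d.ml1_index : d.ml1_index + d.length]
            (m,) = scan_protein(ProteinRecord("w", window))
            assert m.type_name == d.type_name
            assert m.gaps == d.gaps

    def test_flanked_by_filler(self):
        config = ProteomeConfig(n_proteins=20, n_domains=25, flank=5)
        records, _, truth = generate_proteome(config, 5)
        by_id = {r.id: r for r in records}
        for d in truth.domains:
            seq = by_id[d.protein_id].sequence
            left = seq[max(0, d.ml1_index - 5) : d.ml1_index]
            right = seq[d.ml1_index + d.length : d.ml1_index + d.length + 5]
            assert len(left) == 5 and len(right) == 5
            assert set(left + right) <= set(SAFE_FILLER)

    def test_type_coverage_when_budget_allows(self):
        config = ProteomeConfig(n_proteins=20, n_domains=12)
        _, _, truth = generate_proteome(config, 9)
        assert set(d.type_name for d in truth.domains) == set(TYPE_NAMES)

    def test_decoys_reported_iff_single_knockout(self):
        config = ProteomeConfig(n_proteins=20, n_domains=5, n_decoys=6, decoy_knockouts=2)
        records, _, truth = generate_proteome(config, 13)
        matches = scan_proteome(records)  # default max_violations=1
        assert sum(1 for m in matches if not m.is_complete) == 0
        matches2 = scan_proteome(records, max_violations=2)
        incomplete = [m for m in matches2 if not m.is_complete]
        assert {(m.protein_id, m.ml_positions[0]) for m in incomplete} == {
            (d.protein_id, d.ml1_index) for d in truth.decoys
        }
        assert all(len(m.violations) == 2 for m in incomplete)

    def test_gene_models_cover_all_proteins(self, small_proteome):
        records, gene_models, _ = small_proteome
        assert {g.protein_id for g in gene_models} == {r.id for r in records}
        assert all(g.cds is not None for g in gene_models)
        for g in gene_models:
            protein = next(r for r in records if r.id == g.protein_id)
            assert len(g.cds) == 3 * len(protein.sequence)

    def test_tandem_members_similar(self, small_proteome):
        records, gene_models, truth = small_proteome
        (group,) = truth.tandem
        seqs = {r.id: r.sequence for r in records}
        prot_of = {g.gene_id: g.protein_id for g in gene_models}
        members = [seqs[prot_of[gid]] for gid in group]
        for other in members[1:]:
            assert pairwise_identity(members[0], other) >= 0.9

    def test_infeasible_domain_budget(self):
        with pytest.raises(InfeasibleConfigError):
            generate_proteome(ProteomeConfig(n_proteins=2, n_domains=5), 0)

    def test_domain_longer_than_max_protein(self):
        config = ProteomeConfig(n_proteins=1, n_domains=2, length_range=(60, 100))
        with pytest.raises(InfeasibleConfigError):
            generate_proteome(config, 0)

    def test_length_range_respected(self):
        config = ProteomeConfig(n_proteins=50, n_domains=0)
        records, _, _ = generate_proteome(config, 21)
        assert all(60 <= len(r.sequence) <= 1888 for r in records)


class TestMutateCds:
    def test_noop(self, rng):
        cds = random_cds(20, rng)
        mutated, record = mutate_cds(cds, 0, 0, rng)
        assert mutated == cds
        assert record.changes == ()

    def test_one_synonymous_on_lysine_runs(self, rng):
        mutated, record = mutate_cds("AAA" * 10, 1, 0, rng)
        diffs = [i for i, (a, b) in enumerate(zip("AAA" * 10, mutated)) if a != b]
        assert len(diffs) == 1
        assert mutated[diffs[0]] == "G"  # AAA -> AAG is the only synonymous change
        assert record.n_synonymous == 1

    def test_methionine_admits_no_synonymous_change(self, rng):
        with pytest.raises(InfeasibleConfigError):
            mutate_cds("ATG" * 5, 1, 0, rng)

    def test_changes_verified_against_code(self, rng):
        base = random_cds(40, rng)
        mutated, record = mutate_cds(base, 3, 4, rng)
        base_codons, mut_codons = codons_of(base), codons_of(mutated)
        changed = [i for i, (a, b) in enumerate(zip(base_codons, mut_codons)) if a != b]
        assert len(changed) == 7  # no two changes in the same codon
        syn = sum(1 for i in changed if _FORWARD[base_codons[i]] == _FORWARD[mut_codons[i]])
        assert syn == 3

    def test_no_stop_codons_introduced(self, rng):
        base = random_cds(30, rng)
        mutated, _ = mutate_cds(base, 2, 5, rng)
        codons_of(mutated)  # raises on stops
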