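"""Generators: determinism, design-target recovery, validity of outputs."""

import numpy as np
import pytest

from mitochar.codon_usage import VERTEBRATE_MITO, extract_codons
from mitochar.composition import base_composition
from mitochar.io_formats import extract_gene_sequence
from mitochar.selection import count_differences
from mitochar.synthetic_data import (SimulationConfig, TrnaSpec,
                                     evolve_codon_alignment,
                                     generate_mitogenome, generate_trna,
                                     random_sense_codons, random_tree,
                                     tree_distance_matrix)


class TestMitogenomeGenerator:
    def test_feature_census(self, synthetic_genome):
        t = synthetic_genome.table
        assert len(t) == 39
        assert len(t.pcgs) == 13
        assert len(t.by_class("tRNA")) == 22
        assert len(t.by_class("rRNA")) == 2

    def test_skew_targets_recovered(self, synthetic_genome):
        cfg = synthetic_genome.config
        rep = base_composition(synthetic_genome.record.sequence)
        assert abs(rep.at_skew - cfg.target_at_skew) <= 0.01
        assert abs(rep.gc_skew - cfg.target_gc_skew) <= 0.01

    def test_pcgs_validate_cleanly(self, synthetic_genome):
        """Every simulated CDS passes frame/stop validation with the planted
        start and stop codons."""
        rec, table = synthetic_genome.record, synthetic_genome.table
        for f in table.pcgs:
            cds = extract_gene_sequence(rec, f)
            codons, cls = extract_codons(cds, gene=f.name)
            assert cls.start_codon == f.start_codon
            assert cls.stop_codon == f.stop_codon
            if f.name == "cox1":
                assert cls.start_codon == "GTG"
            if f.name in ("cox2", "nad4", "cytb"):
                assert not cls.stop_complete

    def test_planted_cr_motifs_present(self, synthetic_genome):
        from mitochar.control_region import scan_motifs
        rec, table = synthetic_genome.record, synthetic_genome.table
        cr = extract_gene_sequence(rec, table.get("CR"))
        for motif, offsets in synthetic_genome.planted_motifs.items():
            hits = {h.position for h in scan_motifs(cr, [motif])
                    if h.strand == "H" and h.mismatches == 0}
            assert set(offsets) <= hits

    def test_bit_reproducible_under_seed(self):
        a = generate_mitogenome(SimulationConfig(seed=77))
        b = generate_mitogenome(SimulationConfig(seed=77))
        assert a.record.sequence == b.record.sequence
        assert [(f.name, f.start, f.end) for f in a.table] == \
               [(f.name, f.start, f.end) for f in b.table]
        c = generate_mitogenome(SimulationConfig(seed=78))
        assert c.record.sequence != a.record.sequence

    def test_explicit_genome_length_pads_cr(self):
        sim = generate_mitogenome(SimulationConfig(seed=5,
                                                   genome_length=17000))
        assert len(sim.record) == 17000
        assert sim.table.features[-1].end == 17000

    def test_infeasible_length_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_mitogenome(SimulationConfig(seed=5, genome_length=1000))

    def test_invalid_skew_target_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(target_at_skew=1.5)


class TestTrnaGenerator:
    def test_reproducible(self):
        s1, m1 = generate_trna(TrnaSpec(), seed=4)
        s2, m2 = generate_trna(TrnaSpec(), seed=4)
        assert s1 == s2 and m1 == m2

    def test_designed_length(self):
        spec = TrnaSpec(acceptor=8, variable=6)
        seq, _ = generate_trna(spec, seed=0)
        assert len(seq) == spec.length

    def test_spec_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_trna(TrnaSpec(dhu_stem=5), seed=0)


class TestCodonEvolution:
    def test_omega_zero_only_synonymous_changes(self):
        rng = np.random.default_rng(2)
        anc = random_sense_codons(300, rng)
        aln = evolve_codon_alignment(anc, "(a:0.5,b:0.5);", omega=0.0,
                                     kappa=2.0, seed=2)
        for taxon in ("a", "b"):
            derived = [aln[taxon][i:i + 3] for i in range(0, 900, 3)]
            for ca, cb in zip(anc, derived):
                # every substitution was synonymous, so the protein is frozen
                assert VERTEBRATE_MITO.forward[ca] == VERTEBRATE_MITO.forward[cb]
                if sum(x != y for x, y in zip(ca, cb)) == 1:
                    assert count_differences(ca, cb) == (1.0, 0.0)

    def test_zero_branch_identical_descendant(self):
        rng = np.random.default_rng(3)
        anc = random_sense_codons(100, rng)
        aln = evolve_codon_alignment(anc, "(a:0.0,b:0.3);", omega=0.5,
                                     kappa=2.0, seed=3)
        assert aln["a"] == "".join(anc)

    def test_no_stop_codons_ever_emitted(self):
        rng = np.random.default_rng(4)
        anc = random_sense_codons(200, rng)
        aln = evolve_codon_alignment(anc, "(a:1.0,b:1.0);", omega=1.0,
                                     kappa=2.0, seed=4)
        for seq in aln.values():
            for i in range(0, len(seq), 3):
                assert not VERTEBRATE_MITO.is_stop(seq[i:i + 3])

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            evolve_codon_alignment(["ATG"], "(a:1,b:1);", omega=-0.1)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        anc = random_sense_codons(50, rng)
        a = evolve_codon_alignment(anc, "(x:0.2,y:0.2);", omega=0.3, seed=9)
        b = evolve_codon_alignment(anc, "(x:0.2,y:0.2);", omega=0.3, seed=9)
        assert a == b


class TestRandomTrees:
    def test_reproducible_and_additive(self):
        assert random_tree(6, seed=3) == random_tree(6, seed=3)
        labels, D = tree_distance_matrix(random_tree(6, seed=3))
        assert len(labels) == 6
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
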