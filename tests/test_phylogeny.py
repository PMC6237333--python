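"""Supermatrix, distances, NJ (vs dendropy's independent NJ), bootstrap,
monophyly."""

import math

import dendropy
import numpy as np
import pytest

from mitochar.phylogeny import (Supermatrix, bipartitions, bootstrap,
                                concatenate, distance_matrix,
                                is_monophyletic, neighbor_joining,
                                robinson_foulds)
from mitochar.synthetic_data import random_tree, tree_distance_matrix


class TestConcatenate:
    g1 = {"t1": "ACGTAC", "t2": "ACGTAC", "t3": "ACGTTT"}
    g2 = {"t1": "AAACCCGGG", "t2": "AAACCCGGA", "t3": "AAACCCGGC"}

    def test_toy_widths_and_partitions(self):
        sm = concatenate({"g1": self.g1, "g2": self.g2},
                         gene_order=("g1", "g2"))
        assert sm.n_columns == 15
        assert sm.partitions == {"g1": (1, 6), "g2": (7, 15)}

    def test_gene_order_permutation_same_columns(self):
        a = concatenate({"g1": self.g1, "g2": self.g2},
                        gene_order=("g1", "g2"))
        b = concatenate({"g1": self.g1, "g2": self.g2},
                        gene_order=("g2", "g1"))
        for t in a.taxa:
            assert sorted(a.sequences[t]) == sorted(b.sequences[t])
        assert a.partitions != b.partitions

    def test_missing_taxon_lists_holes(self):
        bad = {"g1": self.g1, "g2": {k: v for k, v in self.g2.items()
                                     if k != "t2"}}
        with pytest.raises(ValueError, match=r"g2.*t2"):
            concatenate(bad)

    def test_unaligned_gene_rejected(self):
        bad = {"g1": {"t1": "ACG", "t2": "ACGT", "t3": "ACG"}}
        with pytest.raises(ValueError, match="unaligned"):
            concatenate(bad)

    def test_synthetic_width_bookkeeping(self):
        rng = np.random.default_rng(0)
        genes = {}
        widths = []
        taxa = [f"t{i}" for i in range(6)]
        for g in range(4):
            w = int(rng.integers(30, 90)) * 3
            widths.append(w)
            genes[f"gene{g}"] = {
                t: "".join(rng.choice(list("ACGT"), size=w)) for t in taxa}
        sm = concatenate(genes)
        assert sm.n_columns == sum(widths)


class TestDistances:
    def test_identical_rows_zero_for_all_models(self):
        sm = Supermatrix(["a", "b"], {"a": "ACGT" * 5, "b": "ACGT" * 5},
                         {"g": (1, 20)})
        for model in ("p", "jc69", "k2p"):
            assert distance_matrix(sm, model)[0, 1] == 0.0

    def test_k2p_closed_form_transitions_only(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        sm = Supermatrix(["a", "b"], {"a": a, "b": b}, {"g": (1, 100)})
        d = distance_matrix(sm, "k2p")[0, 1]
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-10)

    def test_jc_dominates_p_and_agrees_at_small_p(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=2000))
        mutated = list(base)
        for i in rng.choice(2000, size=40, replace=False):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        sm = Supermatrix(["a", "b"], {"a": base, "b": "".join(mutated)},
                         {"g": (1, 2000)})
        p = distance_matrix(sm, "p")[0, 1]
        jc = distance_matrix(sm, "jc69")[0, 1]
        k2p = distance_matrix(sm, "k2p")[0, 1]
        assert jc >= p
        assert abs(jc - p) < 0.01 and abs(k2p - p) < 0.01

    def test_saturated_pair_flagged_nan(self):
        sm = Supermatrix(["a", "b"], {"a": "A" * 50, "b": "C" * 50},
                         {"g": (1, 50)})
        assert math.isnan(distance_matrix(sm, "jc69")[0, 1])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        phy = neighbor_joining(D, ["a", "b", "c"])
        tree = phy.tree()
        bl = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert bl == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovers_topology(self, seed):
        nwk = random_tree(4 + seed % 7, seed=seed)
        labels, D = tree_distance_matrix(nwk)
        phy = neighbor_joining(D, labels)
        assert robinson_foulds(phy, nwk) == 0

    def test_agrees_with_dendropy_nj_topology(self):
        """Independent cross-check: dendropy's own NJ on the same matrix."""
        nwk = random_tree(8, seed=99)
        labels, D = tree_distance_matrix(nwk)
        phy = neighbor_joining(D, labels)
        csv_rows = ["," + ",".join(labels)]
        for i, a in enumerate(labels):
            csv_rows.append(a + "," + ",".join(str(D[i, j])
                                               for j in range(len(labels))))
        import io as _io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO("\n".join(csv_rows) + "\n"), delimiter=",")
        dtree = pdm.nj_tree()
        assert robinson_foulds(phy, dtree.as_string(schema="newick")) == 0

    def test_perturbed_four_point_still_returns_tree(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        labels, D = tree_distance_matrix(nwk)
        D[0, 1] += 0.05  # minimal four-point violation
        D[1, 0] += 0.05
        phy = neighbor_joining(D, labels)
        assert robinson_foulds(phy, nwk) in (0, 2)


class TestBootstrap:
    def test_zero_variation_all_supports_100(self):
        seqs = {t: "ACGT" * 10 for t in "abcd"}
        sm = Supermatrix(list("abcd"), seqs, {"g": (1, 40)})
        phy = bootstrap(sm, "p", replicates=10, seed=1)
        assert all(v == 100.0 for v in phy.supports.values())

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        base = rng.choice(list("ACGT"), size=60)
        seqs = {}
        for i in range(5):  # related rows: ~10% divergence, no saturation
            row = base.copy()
            idx = rng.choice(60, size=6, replace=False)
            row[idx] = rng.choice(list("ACGT"), size=6)
            seqs[f"t{i}"] = "".join(row)
        sm = Supermatrix(sorted(seqs), seqs, {"g": (1, 60)})
        a = bootstrap(sm, "jc69", replicates=25, seed=7)
        b = bootstrap(sm, "jc69", replicates=25, seed=7)
        assert a.supports == b.supports and a.newick == b.newick

    def test_long_branch_separated_clades_supported(self):
        """Data simulated on a well-separated 8-taxon tree: every true
        bipartition gets >= 95% support at 100 replicates."""
        from mitochar.synthetic_data import (evolve_codon_alignment,
                                             random_sense_codons)
        inner = "(((a:0.02,b:0.02):0.3,(c:0.02,d:0.02):0.3):0.3," \
                "((e:0.02,f:0.02):0.3,(g:0.02,h:0.02):0.3):0.3);"
        rng = np.random.default_rng(6)
        anc = random_sense_codons(400, rng)
        aln = evolve_codon_alignment(anc, inner, omega=1.0, kappa=2.0, seed=6)
        sm = concatenate({"g": aln})
        phy = bootstrap(sm, "jc69", replicates=100, seed=3)
        true_bips = bipartitions(inner)
        for b in true_bips:
            assert phy.supports.get(b, 0.0) >= 95.0


class TestMonophyly:
    def test_clean_clade(self):
        ok, intruders = is_monophyletic("((A,B),(C,D));", {"A", "B"}, "D")
        assert ok and intruders == set()

    def test_intruder_identified(self):
        ok, intruders = is_monophyletic("((A,(B,X)),out);", {"A", "B"}, "out")
        assert not ok and intruders == {"X"}

    def test_unknown_taxon_raises(self):
        with pytest.raises(ValueError):
            is_monophyletic("((A,B),C);", {"A", "Z"}, "C")

    def test_family_paraphyly_topology(self):
        """One halfbeak sister to the flyingfish clade: the family alone is
        paraphyletic, family+flyingfishes together are monophyletic."""
        nwk = ("(((Hquoyi:1,(Pbrachypterus:1,Cdoederleinii:1):1):1,"
               "(Hintermedius:1,Hsajori:1):1):1,Ccuning:2);")
        hemi = {"Hquoyi", "Hintermedius", "Hsajori"}
        exo = {"Pbrachypterus", "Cdoederleinii"}
        ok, intruders = is_monophyletic(nwk, hemi, "Ccuning")
        assert not ok and intruders == exo
        ok2, intr2 = is_monophyletic(nwk, hemi | exo, "Ccuning")
        assert ok2 and intr2 == set()


def test_rf_identity_and_symmetry():
    a = random_tree(7, seed=1)
    b = random_tree(7, seed=2)
    assert robinson_foulds(a, a) == 0
    assert robinson_foulds(a, b) == robinson_foulds(b, a)
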