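"""Nei-Gojobori counting against exhaustive enumeration oracles.

The oracles below use Biopython's table-2 translator and explicit
enumeration, independent of the package's GeneticCode tables and pathway
code.
"""

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Seq import Seq

from mitochar.selection import (count_differences, count_sites, jukes_cantor,
                                kaks_pair)
from mitochar.synthetic_data import evolve_codon_alignment, random_sense_codons

BASES = "ACGT"
STOPS = {"TAA", "TAG", "AGA", "AGG"}
SENSE = [c for c in ("".join(p) for p in product(BASES, repeat=3))
         if c not in STOPS]


def aa2(codon: str) -> str:
    return str(Seq(codon).translate(table=2))


def oracle_sites(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        nbs = [codon[:pos] + b + codon[pos + 1:]
               for b in BASES if b != codon[pos]]
        nbs = [n for n in nbs if n not in STOPS]
        if nbs:
            s += sum(aa2(n) == aa2(codon) for n in nbs) / len(nbs)
    return s, 3.0 - s


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur, sd, nd = a, 0, 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS:
                blocked = True
                break
            sd += aa2(cur) == aa2(nxt)
            nd += aa2(cur) != aa2(nxt)
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:
        return math.nan, math.nan  # fallback case, checked separately
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


class TestSiteCounting:
    def test_atg_and_ttt_hand_values(self):
        assert count_sites("ATG")[0] == pytest.approx(1 / 3)
        assert count_sites("TTT")[0] == pytest.approx(1 / 3)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("AGA")

    def test_all_sense_codons_match_oracle_and_partition(self):
        for codon in SENSE:
            s, n = count_sites(codon)
            os_, on_ = oracle_sites(codon)
            assert s == pytest.approx(os_), codon
            assert s + n == pytest.approx(3.0)


class TestDifferenceCounting:
    def test_single_step_synonymous(self):
        assert count_differences("ATG", "ATA") == (1.0, 0.0)

    def test_identity(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_all_sense_pairs_match_exhaustive_oracle(self):
        """Pathway-averaged sd/nd equals brute-force enumeration for every
        sense-codon pair (the fallback-only pairs are compared for their
        total instead)."""
        for a in SENSE:
            for b in SENSE:
                sd, nd = count_differences(a, b)
                osd, ond = oracle_differences(a, b)
                ndiff = sum(x != y for x, y in zip(a, b))
                assert sd + nd == pytest.approx(ndiff)
                if not math.isnan(osd):
                    assert sd == pytest.approx(osd), (a, b)
                    assert nd == pytest.approx(ond), (a, b)


class TestKaKsPair:
    def test_identical_sequences(self):
        r = kaks_pair("ATGAAACCC", "ATGAAACCC")
        assert r.Ka == 0.0 and r.Ks == 0.0 and r.ratio is None

    def test_three_codon_manual_arithmetic(self):
        """ATG AAA CCC vs ATG AAG CCA: one synonymous change at each of two
        codons; S, N from per-codon site sums."""
        a, b = "ATGAAACCC", "ATGAAGCCA"
        r = kaks_pair(a, b)
        exp_S = sum(count_sites(c)[0] for c in ("ATG", "AAA", "CCC"))
        exp_S2 = sum(count_sites(c)[0] for c in ("ATG", "AAG", "CCA"))
        assert r.S == pytest.approx((exp_S + exp_S2) / 2)
        assert r.N == pytest.approx(9 - r.S)
        assert r.Sd == pytest.approx(2.0)
        assert r.Nd == pytest.approx(0.0)
        assert r.Ks == pytest.approx(jukes_cantor(2.0 / r.S))
        assert r.Ka == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = "".join(random_sense_codons(60, rng))
        b = "".join(random_sense_codons(60, rng))
        r1, r2 = kaks_pair(a, b), kaks_pair(b, a)
        assert r1.Sd == pytest.approx(r2.Sd)
        assert r1.S == pytest.approx(r2.S)
        assert (r1.ratio is None) == (r2.ratio is None)
        if r1.ratio is not None:
            assert r1.ratio == pytest.approx(r2.ratio)

    def test_gap_and_ambiguity_codons_dropped_pairwise(self):
        r = kaks_pair("ATGGGGAAAC", "ATGCC-AATC")
        assert r.n_codons == 2  # gap codon column dropped, trailing nt trimmed

    def test_omega_recovery_from_simulation(self):
        """omega=0.1 on 500 codons, branch 0.2+0.2, fixed seed: estimated
        Ka/Ks falls in [0.05, 0.2]."""
        rng = np.random.default_rng(7)
        anc = random_sense_codons(500, rng)
        aln = evolve_codon_alignment(anc, "(a:0.2,b:0.2);", omega=0.1,
                                     kappa=2.0, seed=7)
        r = kaks_pair(aln["a"], aln["b"])
        assert 0.05 <= r.ratio <= 0.2

    def test_purifying_selection_across_simulated_genes(self):
        """Every simulated gene under omega<1 estimates Ka/Ks < 1."""
        rng = np.random.default_rng(13)
        for k in range(13):
            anc = random_sense_codons(120, rng)
            aln = evolve_codon_alignment(anc, "(a:0.3,b:0.3);", omega=0.2,
                                         kappa=2.0, seed=100 + k)
            r = kaks_pair(aln["a"], aln["b"])
            assert r.ratio is not None and r.ratio < 1.0

    def test_saturation_reported_not_clamped(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.0) == 0.0
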