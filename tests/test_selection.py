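"""NG86 dN/dS against hand values and an exhaustive pathway oracle,
plus p-distance / neighbor-joining plumbing."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from mitocensus.codon_usage import SENSE_CODONS, STOP_CODONS, translate_codon
from mitocensus.selection import (FrameError, codon_differences, codon_sites,
                                  gene_dnds_average, jukes_cantor, ng86_pairwise,
                                  nj_tree, p_distance_matrix)
from mitocensus.synthetic import evolve_sequences


# --- independent oracle: exhaustive enumeration over substitution orderings

def _oracle_diffs(c1, c2, exclude_stop_paths=True):
    """Brute-force pathway enumeration, written independently of the
    implementation: walk every permutation of the differing positions and
    classify each single-base step by translation."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, steps, blocked = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            steps.append((translate_codon(cur), translate_codon(nxt)))
            cur = nxt
        results.append((blocked, steps))
    usable = [s for blocked, s in results if not blocked] if exclude_stop_paths else None
    if not usable:
        usable = [s for _, s in results]
    sd = nd = 0.0
    for steps in usable:
        for aa_from, aa_to in steps:
            if aa_from is not None and aa_from == aa_to:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


class TestCodonMachinery:
    @pytest.mark.parametrize("codon,s", [("TTT", 1 / 3), ("CTA", 4 / 3), ("ATG", 1 / 3)])
    def test_site_counts_hand_cases(self, codon, s):
        syn, non = codon_sites(codon)
        assert syn == pytest.approx(s)
        assert syn + non == pytest.approx(3.0)

    def test_sites_partition_for_every_sense_codon(self):
        for c in SENSE_CODONS:
            s, n = codon_sites(c)
            assert 0 <= s <= 3 and s + n == pytest.approx(3.0)

    @pytest.mark.parametrize("exclude", [True, False])
    def test_differences_match_exhaustive_oracle(self, exclude):
        """Every sense-codon pair agrees with independent pathway
        enumeration (the full 60x60 space)."""
        for c1, c2 in itertools.product(SENSE_CODONS, SENSE_CODONS):
            got = codon_differences(c1, c2, exclude_stop_paths=exclude)
            want = _oracle_diffs(c1, c2, exclude_stop_paths=exclude) \
                if c1 != c2 else (0.0, 0.0)
            assert got == pytest.approx(want), (c1, c2)

    def test_total_differences_equal_hamming(self):
        for c1, c2 in [("AAA", "CCC"), ("ATG", "ATA"), ("TTT", "GGA")]:
            sd, nd = codon_differences(c1, c2)
            assert sd + nd == pytest.approx(sum(a != b for a, b in zip(c1, c2)))


class TestNG86Pairwise:
    def test_identical_sequences(self):
        r = ng86_pairwise("ATGAAA", "ATGAAA")
        assert r.sd == r.nd == 0.0 and r.dS == r.dN == 0.0
        assert r.omega is None

    def test_single_synonymous_change_worked_example(self):
        # 10 Phe codons, one third-position TTT->TTC change
        r = ng86_pairwise("TTT" * 10, "TTT" * 9 + "TTC")
        assert r.S == pytest.approx(10 / 3)
        assert (r.sd, r.nd) == (1.0, 0.0)
        assert r.pS == pytest.approx(0.3)
        assert r.dS == pytest.approx(0.3831, abs=5e-5)
        assert r.dN == 0.0 and r.omega == 0.0

    def test_nonsynonymous_only_pair_has_missing_omega(self):
        r = ng86_pairwise("ATGAAA", "ATGGAA")  # Lys -> Glu
        assert r.dS == 0.0 and r.dN > 0
        assert r.omega is None  # dS = 0 denominator

    def test_site_partition_invariant(self):
        r = ng86_pairwise("ATGAAACCC", "ATGAAGCCA")
        assert r.S + r.N == pytest.approx(3 * r.codons)

    def test_symmetry(self):
        tips, _ = evolve_sequences(120, "(A:0.5,B:0.5);", syn_rate=0.3,
                                   nonsyn_rate=0.15, seed=3)
        r1 = ng86_pairwise(tips["A"], tips["B"])
        r2 = ng86_pairwise(tips["B"], tips["A"])
        assert (r1.S, r1.N, r1.sd, r1.nd) == (r2.S, r2.N, r2.sd, r2.nd)

    def test_ambiguous_codons_dropped_pairwise(self):
        r = ng86_pairwise(["ATG", "ANA", "AAA"], ["ATG", "AAA", "AAA"])
        assert r.codons == 2

    def test_internal_stop_aborts(self):
        with pytest.raises(FrameError):
            ng86_pairwise("ATGTAAAAA", "ATGTAAAAA", allow_terminal_stop=False)

    def test_shared_terminal_stop_trimmed(self):
        r = ng86_pairwise("ATGAAATAA", "ATGAAATAA")
        assert r.codons == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ng86_pairwise("ATGAAA", "ATGAAACCC")

    def test_saturated_proportion_undefined(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.0) == 0.0

    def test_matches_independent_ng86_implementation(self):
        """Exact agreement with Biopython's NG86 (all-pathway convention)
        on simulated diverged CDS pairs."""
        warnings.filterwarnings("ignore")
        from Bio.Data import CodonTable
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        table2 = CodonTable.unambiguous_dna_by_id[2]
        for seed in (5, 6, 7):
            tips, _ = evolve_sequences(200, "(A:0.3,B:0.3);", syn_rate=0.2,
                                       nonsyn_rate=0.1, seed=seed)
            mine = ng86_pairwise(tips["A"], tips["B"], exclude_stop_paths=False)
            dn, ds = cal_dn_ds(CodonSeq(tips["A"]), CodonSeq(tips["B"]),
                               codon_table=table2, method="NG86")
            assert mine.dN == pytest.approx(dn, abs=1e-10)
            assert mine.dS == pytest.approx(ds, abs=1e-10)


class TestSimulatedSelectionRegimes:
    def test_synonymous_only_evolution_gives_zero_dn(self):
        tips, _ = evolve_sequences(150, "(A:1.0,B:1.0,C:1.0);", syn_rate=0.5,
                                   nonsyn_rate=0.0, seed=9, single_hit=True)
        res = gene_dnds_average(tips, gene="synon")
        assert res.mean_dN == 0.0
        assert res.mean_dS > 0.0

    def test_nonsynonymous_only_evolution_gives_zero_ds(self):
        tips, _ = evolve_sequences(150, "(A:0.6,B:0.6);", syn_rate=0.0,
                                   nonsyn_rate=0.3, seed=10, single_hit=True)
        r = ng86_pairwise(tips["A"], tips["B"])
        assert r.dS == 0.0 and r.dN > 0.0


class TestGeneAverages:
    def test_two_species_mean_equals_pairwise(self):
        tips, _ = evolve_sequences(100, "(A:0.4,B:0.4);", syn_rate=0.3,
                                   nonsyn_rate=0.1, seed=21)
        res = gene_dnds_average(tips)
        single = ng86_pairwise(tips["A"], tips["B"])
        assert res.mean_dN == pytest.approx(single.dN)
        assert res.mean_dS == pytest.approx(single.dS)
        assert res.n_pairs == 1

    def test_undefined_omega_pairs_are_counted_not_zeroed(self):
        seqs = {"a": "ATGAAA", "b": "ATGGAA", "c": "ATGAAA"}  # no syn changes
        res = gene_dnds_average(seqs)
        assert res.mean_omega is None
        assert res.n_omega_pairs == 0 and res.n_excluded == 3

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            gene_dnds_average({"only": "ATGAAA"})


class TestDistanceAndTree:
    def test_p_distance_extremes_and_hand_count(self):
        m = p_distance_matrix({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        assert m.loc["a", "b"] == 0.0
        m = p_distance_matrix({"a": "AAAA", "b": "CCCC"})
        assert m.loc["a", "b"] == 1.0
        m = p_distance_matrix({"a": "AAAAAAAAAA", "b": "AAACCCAAAA"})
        assert m.loc["a", "b"] == pytest.approx(0.3)

    def test_matrix_symmetric_zero_diagonal(self):
        tips, _ = evolve_sequences(80, "(A:0.3,(B:0.2,C:0.2):0.3);",
                                   syn_rate=0.4, nonsyn_rate=0.2, seed=4)
        m = p_distance_matrix(tips)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_nj_needs_three_taxa(self):
        m = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_nj_recovers_additive_four_taxon_tree(self):
        # distances constructed from ((A,B),(C,D)) with all branches 1
        m = pd.DataFrame(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        nwk = nj_tree(m)
        assert _has_split(nwk, {"A", "B"}) or _has_split(nwk, {"C", "D"})

    def test_nj_deterministic(self):
        m = pd.DataFrame(
            [[0, .1, .3, .35], [.1, 0, .32, .31], [.3, .32, 0, .12], [.35, .31, .12, 0]],
            index=list("ABCD"), columns=list("ABCD"))
        assert nj_tree(m) == nj_tree(m)


def _has_split(newick, tips):
    from io import StringIO

    from Bio import Phylo
    tree = Phylo.read(StringIO(newick), "newick")
    for clade in tree.find_clades():
        if not clade.is_terminal():
            if {t.name for t in clade.get_terminals()} == tips:
                return True
    return False
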