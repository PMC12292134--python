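"""Codon extraction, RSCU and amino-acid usage under translation table 2."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocensus.codon_usage import (SENSE_CODONS, CodonList, CodonUsageTable,
                                    amino_acid_composition, extract_cds, rscu,
                                    start_stop_census, synonymous_family,
                                    translate_codon)
from mitocensus.io import GeneFeature, MitogenomeRecord


def _toy_record(seq, strand="+"):
    feat = GeneFeature(name="toy", category="PCG", start=1, stop=len(seq),
                       strand=strand)
    return MitogenomeRecord(id="toy", features=[feat], sequence=seq), feat


class TestGeneticCode:
    def test_table2_specials(self):
        # the three deviations from the standard code that matter here
        assert translate_codon("ATA") == "M"
        assert translate_codon("TGA") == "W"
        assert translate_codon("AGA") is None and translate_codon("AGG") is None

    def test_family_sizes_cover_sense_codons(self):
        assert sum(len(set(synonymous_family(c))) == len(synonymous_family(c))
                   for c in SENSE_CODONS) == len(SENSE_CODONS)


class TestExtractCds:
    def test_plus_strand_toy(self):
        rec, feat = _toy_record("ATGAAATAA")
        cl = extract_cds(rec, feat)
        assert cl.codons == ["ATG", "AAA", "TAA"]
        assert cl.start_codon == "ATG" and cl.terminal_triplet == "TAA"
        assert not cl.incomplete

    def test_incomplete_stop_flagged(self, synth):
        rec, _ = synth
        cl = extract_cds(rec, rec.get("nad4"))  # length 1381 = 3*460 + 1
        assert len(cl.codons) == 460
        assert cl.trailing_bases != "" and len(cl.trailing_bases) == 1

    def test_complete_orf_not_flagged(self, synth):
        rec, _ = synth
        cl = extract_cds(rec, rec.get("cox1"))  # length 1596 = 3*532
        assert len(cl.codons) == 532 and not cl.incomplete

    def test_strand_equivariance(self):
        import mitocensus.synthetic as syn
        seq = "ATGAAACCCGGGTAA"
        plus, pf = _toy_record(seq, strand="+")
        minus, mf = _toy_record(syn._revcomp(seq), strand="-")
        assert extract_cds(plus, pf).codons == extract_cds(minus, mf).codons

    def test_short_cds_rejected(self):
        rec, feat = _toy_record("ATGAA")
        with pytest.raises(ValueError, match="shorter"):
            extract_cds(rec, feat)

    def test_non_pcg_rejected(self, synth):
        rec, _ = synth
        with pytest.raises(ValueError):
            extract_cds(rec, rec.get("trnP"))


class TestRscu:
    def test_two_codon_family_equal_counts(self):
        vals = rscu({"GAA": 5, "GAG": 5})  # Glu family
        assert vals["GAA"] == vals["GAG"] == 1.0

    def test_four_fold_family_hand_values(self):
        # Gly family GGA/GGC/GGG/GGT with counts (3,1,0,0)
        vals = rscu({"GGA": 3, "GGC": 1})
        assert [vals[c] for c in ("GGA", "GGC", "GGG", "GGT")] == [3.0, 1.0, 0.0, 0.0]

    def test_unobserved_family_is_missing(self):
        vals = rscu({"GGA": 3})
        assert vals["GAA"] is None  # Glu never seen

    def test_uniform_usage_gives_all_ones(self):
        vals = rscu({c: 7 for c in SENSE_CODONS})
        assert all(v == pytest.approx(1.0) for v in vals.values())

    @given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                           st.integers(min_value=0, max_value=50), max_size=40))
    @settings(max_examples=150, deadline=None)
    def test_family_sum_equals_family_size(self, counts):
        vals = rscu(counts)
        seen = set()
        for codon in SENSE_CODONS:
            fam = synonymous_family(codon)
            if fam in seen:
                continue
            seen.add(fam)
            total = sum(counts.get(c, 0) for c in fam)
            if total == 0:
                assert all(vals[c] is None for c in fam)
            else:
                assert sum(vals[c] for c in fam) == pytest.approx(len(fam))

    def test_rscu_nonnegative_on_table(self, synth):
        rec, _ = synth
        cds = [extract_cds(rec, f) for f in rec.features if f.category == "PCG"]
        table = CodonUsageTable.from_codon_lists(cds)
        assert table.total > 3000
        assert all(v is None or v >= 0 for v in table.rscu().values())


class TestStartStopCensus:
    def test_published_start_codons(self, reference):
        starts, _, _ = start_stop_census(reference)
        assert starts == Counter({"ATG": 12, "GTG": 1})

    def test_published_taa_share(self, reference):
        _, terminals, taa = start_stop_census(reference)
        assert terminals["TAA"] == 7
        assert taa == 53.8  # 7 of 13

    def test_invalid_terminal_triplets_kept_verbatim(self, reference):
        _, terminals, _ = start_stop_census(reference)
        # incomplete/abutted stops are reported as printed, never "fixed"
        assert terminals["ACT"] == 1 and terminals["TCT"] == 1 and terminals["CCT"] == 1

    def test_all_taa_toy(self):
        feats = [GeneFeature(name=f"g{i}", category="PCG", start=10 * i + 1,
                             stop=10 * i + 9, strand="+", start_codon="ATG",
                             stop_codon="TAA") for i in range(4)]
        rec = MitogenomeRecord(id="toy", features=feats)
        _, _, taa = start_stop_census(rec)
        assert taa == 100.0

    def test_missing_annotation_and_sequence_rejected(self):
        feats = [GeneFeature(name="g", category="PCG", start=1, stop=9, strand="+")]
        rec = MitogenomeRecord(id="toy", features=feats)
        with pytest.raises(ValueError):
            start_stop_census(rec)


class TestAminoAcidComposition:
    @staticmethod
    def _table(codons):
        cl = CodonList(gene="g", codons=codons, start_codon=codons[0],
                       terminal_triplet=codons[-1])
        return CodonUsageTable.from_codon_lists([cl])

    def test_toy_gene_counts(self):
        # ATG AAA AAA TAA -> Met 1, Lys 2 (terminal excluded)
        t = self._table(["ATG", "AAA", "AAA", "TAA"])
        df = amino_acid_composition({"sp": t}, as_frequency=False)
        assert df.loc["sp", "M"] == 1 and df.loc["sp", "K"] == 2
        assert "*" not in df.columns

    def test_identical_species_identical_rows(self):
        t = self._table(["ATG", "CTA", "CTA", "AAA", "TAA"])
        df = amino_acid_composition({"a": t, "b": t})
        assert (df.loc["a"] == df.loc["b"]).all()

    def test_leucine_biased_generator_recovered(self, rng):
        # codon bias concentrated on the Leu family must make Leu modal
        from mitocensus.codon_usage import extract_cds
        from mitocensus.synthetic import GeneratorConfig, generate_genome
        bias = {c: (50.0 if translate_codon(c) == "L" else 1.0) for c in SENSE_CODONS}
        rec, _ = generate_genome(GeneratorConfig(seed=77, codon_bias=bias))
        cds = [extract_cds(rec, f) for f in rec.features if f.category == "PCG"]
        table = CodonUsageTable.from_codon_lists(cds)
        df = amino_acid_composition({"synthetic": table})
        assert df.loc["synthetic"].idxmax() == "L"

    def test_needs_at_least_one_species(self):
        with pytest.raises(ValueError):
            amino_acid_composition({})
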