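"""Variant effect annotation and mutation nomenclature."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsakit.errors import InvalidInputError, RefMismatchError
from bsakit.genome import (
    GeneModel,
    Genome,
    Variant,
    annotate_variant,
    cds_coordinate,
    format_nomenclature,
    parse_nt_name,
    translate_codon,
)
from tests.conftest import (
    cds_with_codon,
    frameshift_deletion_cds,
    frameshift_insertion_cds,
    genomic_pos,
    place_gene,
    random_seq,
    revcomp,
)


class TestTranslateCodon:
    @pytest.mark.parametrize("codon,aa", [("GAA", "E"), ("TAA", "*"), ("AGT", "S"), ("ATG", "M"), ("TGA", "*")])
    def test_standard_code(self, codon, aa):
        assert translate_codon(codon) == aa

    @pytest.mark.parametrize("bad", ["GA", "GAAA", "GAN", ""])
    def test_invalid_codons_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            translate_codon(bad)


class TestCdsCoordinate:
    def test_first_coding_base_plus_strand(self):
        gene = GeneModel("G", "chr01", "+", 1000, 1299)
        assert cds_coordinate(gene, 1000) == 1
        assert cds_coordinate(gene, 1299) == 300

    def test_promoter_offset_is_negative_with_no_zero(self):
        gene = GeneModel("G", "chr01", "+", 1000, 1299)
        assert cds_coordinate(gene, 999) == -1
        assert cds_coordinate(gene, 1000 - 379) == -379
        assert cds_coordinate(gene, 500) == -500

    def test_outside_promoter_window_is_none(self):
        gene = GeneModel("G", "chr01", "+", 1000, 1299)
        assert cds_coordinate(gene, 499) is None  # 501 bp upstream
        assert cds_coordinate(gene, 1300) is None

    def test_minus_strand_counts_from_cds_end(self):
        gene = GeneModel("G", "chr01", "-", 1000, 1299)
        assert cds_coordinate(gene, 1299) == 1
        assert cds_coordinate(gene, 1000) == 300
        assert cds_coordinate(gene, 1300) == -1
        assert cds_coordinate(gene, 1299 + 500) == -500
        assert cds_coordinate(gene, 1299 + 501) is None


class TestAnnotateSubstitutions:
    def test_nonsense_at_codon_235(self):
        # GAA (Glu) at CDS 703-705; G->T at its first base creates TAA
        genome, gene = place_gene(cds_with_codon("GAA", 235, 240))
        v = Variant("chr01", genomic_pos(gene, 703), "G", "T")
        eff = annotate_variant(genome, [gene], v)
        assert eff.effect_class == "nonsense"
        assert (eff.nt_name, eff.aa_name) == ("703 G->T", "E235*")

    def test_missense_at_codon_2996(self):
        # ACT (Thr) at CDS 8986-8988; C->G at the middle base gives AGT (Ser)
        genome, gene = place_gene(cds_with_codon("ACT", 2996, 2996))
        v = Variant("chr01", genomic_pos(gene, 8987), "C", "G")
        eff = annotate_variant(genome, [gene], v)
        assert eff.effect_class == "missense"
        assert (eff.nt_name, eff.aa_name) == ("8987 C->G", "T2996S")

    def test_synonymous_third_position(self):
        # GCT -> GCC is still Ala
        genome, gene = place_gene(cds_with_codon("GCT", 5, 10, fill="AAA"))
        v = Variant("chr01", genomic_pos(gene, 15), "T", "C")
        eff = annotate_variant(genome, [gene], v)
        assert eff.effect_class == "synonymous"
        assert eff.aa_ref == eff.aa_alt == "A"

    def test_promoter_substitution(self):
        genome, gene = place_gene(cds_with_codon("GAA", 2, 10))
        pos = genomic_pos(gene, -379)
        ref = genome.fetch("chr01", pos, pos)
        alt = "A" if ref != "A" else "G"
        eff = annotate_variant(genome, [gene], Variant("chr01", pos, ref, alt))
        assert eff.effect_class == "promoter"
        assert eff.cds_position == -379
        assert eff.aa_name == "Promoter"
        assert eff.nt_name == f"-379 {ref}->{alt}"

    def test_intergenic_far_from_any_gene(self):
        genome, gene = place_gene(cds_with_codon("GAA", 2, 10), flank=800)
        eff = annotate_variant(genome, [gene], Variant("chr01", 10, genome.fetch("chr01", 10, 10), "A" if genome.fetch("chr01", 10, 10) != "A" else "C"))
        assert eff.effect_class == "intergenic"
        assert eff.gene is None

    def test_ref_mismatch_raises(self):
        genome, gene = place_gene(cds_with_codon("GAA", 235, 240))
        pos = genomic_pos(gene, 703)
        wrong = "C" if genome.fetch("chr01", pos, pos) != "C" else "T"
        with pytest.raises(RefMismatchError):
            annotate_variant(genome, [gene], Variant("chr01", pos, wrong, "A"))


class TestAnnotateFrameshifts:
    def test_deletion_with_delayed_amino_acid_change(self):
        genome, gene = place_gene(frameshift_deletion_cds())
        pos = genomic_pos(gene, 675)
        v = Variant("chr01", pos, "G", "")
        eff = annotate_variant(genome, [gene], v)
        assert eff.effect_class == "frameshift"
        assert (eff.nt_name, eff.aa_name) == ("675_675delG", "G227Vfs249")

    def test_insertion_frameshift(self):
        genome, gene = place_gene(frameshift_insertion_cds())
        pos = genomic_pos(gene, 2494)
        v = Variant("chr01", pos, "", "T")
        eff = annotate_variant(genome, [gene], v)
        assert eff.effect_class == "frameshift"
        assert (eff.nt_name, eff.aa_name) == ("2494_2495insT", "L832Ffs834")

    def test_inframe_deletion_is_not_frameshift(self):
        genome, gene = place_gene(cds_with_codon("GAA", 5, 20))
        pos = genomic_pos(gene, 13)  # whole codon 5
        v = Variant("chr01", pos, genome.fetch("chr01", pos, pos + 2), "")
        eff = annotate_variant(genome, [gene], v)
        assert eff.effect_class == "inframe_indel"

    def test_no_stop_in_scan_reports_unknown_terminus(self):
        # CTG repeats shift to TGC/GCT frames with no stop anywhere downstream
        genome, gene = place_gene("CTG" * 40, flank=600, seed=7)
        # overwrite downstream flank so the scan finds no stop: extend CTG
        chrom = genome.chromosomes["chr01"]
        start = gene.cds_end
        genome.chromosomes["chr01"] = chrom[:start] + "CTG" * 120 + chrom[start + 360 :]
        pos = genomic_pos(gene, 6)
        v = Variant("chr01", pos, genome.fetch("chr01", pos, pos), "")
        eff = annotate_variant(genome, [gene], v)
        assert eff.effect_class == "frameshift"
        assert eff.aa_name.endswith("fs?")


class TestMinusStrand:
    def _mirror(self, cds, cds_pos, ref_c, alt_c, kind):
        """Annotate the same mutation on a plus- and a minus-strand embedding."""
        g_plus, gene_plus = place_gene(cds, "+", seed=11)
        g_minus, gene_minus = place_gene(cds, "-", seed=11)
        if kind == "substitution":
            vp = Variant("chr01", genomic_pos(gene_plus, cds_pos), ref_c, alt_c)
            vm = Variant("chr01", genomic_pos(gene_minus, cds_pos), revcomp(ref_c), revcomp(alt_c))
        elif kind == "deletion":
            lo = genomic_pos(gene_minus, cds_pos + len(ref_c) - 1)
            vp = Variant("chr01", genomic_pos(gene_plus, cds_pos), ref_c, "")
            vm = Variant("chr01", lo, revcomp(ref_c), "")
        else:
            vp = Variant("chr01", genomic_pos(gene_plus, cds_pos), "", alt_c)
            vm = Variant("chr01", genomic_pos(gene_minus, cds_pos + 1), "", revcomp(alt_c))
        ep = annotate_variant(g_plus, [gene_plus], vp)
        em = annotate_variant(g_minus, [gene_minus], vm)
        return ep, em

    def test_substitution_equivalence(self):
        ep, em = self._mirror(cds_with_codon("GAA", 235, 240), 703, "G", "T", "substitution")
        assert (ep.nt_name, ep.aa_name) == (em.nt_name, em.aa_name) == ("703 G->T", "E235*")

    def test_frameshift_deletion_equivalence(self):
        ep, em = self._mirror(frameshift_deletion_cds(), 675, "G", "", "deletion")
        assert (ep.nt_name, ep.aa_name) == (em.nt_name, em.aa_name) == ("675_675delG", "G227Vfs249")

    def test_insertion_equivalence(self):
        ep, em = self._mirror(frameshift_insertion_cds(), 2494, "", "T", "insertion")
        assert (ep.nt_name, ep.aa_name) == (em.nt_name, em.aa_name) == ("2494_2495insT", "L832Ffs834")

    def test_random_substitutions_agree_with_mirrored_construct(self, rng):
        """Property: minus-strand annotation equals the reverse-complemented plus-strand oracle."""
        cds = random_seq(300, seed=3)
        cds = "ATG" + cds[3:]
        for _ in range(50):
            p = int(rng.integers(1, 301))
            g_plus, gene_plus = place_gene(cds, "+", seed=13)
            ref = cds[p - 1]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            ep, em = self._mirror(cds, p, ref, alt, "substitution")
            assert ep.effect_class == em.effect_class
            assert (ep.codon_index, ep.aa_ref, ep.aa_alt) == (em.codon_index, em.aa_ref, em.aa_alt)


class TestCodonIndexRule:
    def test_codon_index_is_ceiling_of_thirds(self, rng):
        """codon_index == ceil(p/3), checked against a per-base scan."""
        cds = random_seq(90, seed=5)
        genome, gene = place_gene(cds)
        brute = [i // 3 + 1 for i in range(90)]  # base i (0-based) lives in codon i//3+1
        for p in rng.integers(1, 91, size=30):
            p = int(p)
            ref = cds[p - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + 1) % 4]
            eff = annotate_variant(genome, [gene], Variant("chr01", genomic_pos(gene, p), ref, alt))
            assert eff.codon_index == math.ceil(p / 3) == brute[p - 1]


class TestNomenclature:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("703 G->T", (703, "G", "T", "substitution")),
            ("703G→T", (703, "G", "T", "substitution")),
            ("-379 G->A", (-379, "G", "A", "substitution")),
            ("100_100delT", (100, "T", "", "deletion")),
            ("2494_2495insT", (2494, "", "T", "insertion")),
        ],
    )
    def test_parse_known_names(self, name, expected):
        assert parse_nt_name(name) == expected

    def test_intergenic_has_no_name(self):
        genome, gene = place_gene(cds_with_codon("GAA", 2, 10), flank=800)
        v = Variant("chr01", 10, genome.fetch("chr01", 10, 10), "A" if genome.fetch("chr01", 10, 10) != "A" else "C")
        eff = annotate_variant(genome, [gene], v)
        with pytest.raises(InvalidInputError):
            format_nomenclature(eff, v)

    @given(
        pos=st.integers(min_value=-500, max_value=5000).filter(lambda p: p != 0),
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
        kind=st.sampled_from(["substitution", "deletion", "insertion"]),
        seq=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_format_parse_round_trip(self, pos, ref, alt, kind, seq):
        """Formatting then parsing recovers (position, ref, alt, kind) exactly."""
        from bsakit.genome import _nt_name

        if kind == "substitution":
            if ref == alt:
                return
            name = _nt_name(pos, ref, alt, kind)
            assert parse_nt_name(name) == (pos, ref, alt, kind)
        elif kind == "deletion":
            if pos < 0 and pos + len(seq) - 1 >= 0:
                return  # span would cross the promoter/CDS boundary
            name = _nt_name(pos, seq, "", kind)
            assert parse_nt_name(name) == (pos, seq, "", kind)
        else:
            name = _nt_name(pos, "", seq, kind)
            assert parse_nt_name(name) == (pos, "", seq, kind)


class TestGeneAssignment:
    def test_cds_hit_beats_promoter_of_neighbor(self):
        seq = random_seq(3000, seed=9)
        a = GeneModel("A", "chr01", "+", 1001, 1300)
        cds_a = seq[1000:1300]
        b = GeneModel("B", "chr01", "+", 1501, 1800)
        genome = Genome({"chr01": seq})
        p = 1290  # inside A's CDS and within 500 bp of B's start
        ref = seq[p - 1]
        alt = "A" if ref != "A" else "C"
        eff = annotate_variant(genome, [a, b], Variant("chr01", p, ref, alt))
        assert eff.gene == "A"
        assert eff.region == "coding"
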