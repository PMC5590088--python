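"""Codon mapping, translation and consequence calling."""

import pandas as pd
import pytest

from ramdecode import fixtures
from ramdecode.gene_models import (
    NON_CODING,
    AlleleMismatchError,
    CatalogMatch,
    GeneModel,
    GenomeSlice,
    InvalidCodonError,
    OutOfGeneRangeError,
    ProteinVariantCall,
    VariantSite,
    call_coding_variant,
    codon_spec,
    map_genomic_to_codon,
    match_known_catalog,
    read_gene_models,
    reverse_complement,
    translate_codon,
    write_gene_models,
)

# a toy plus-strand gene: 2 exons, no UTR, codes for a short peptide
TOY_SEQ = "atgaaacgcgtttgctaa"  # M K R V C *
TOY_PLUS = GeneModel("TOY", "chrT", "+", ((11, 19), (25, 33)), 0, 5)


def _toy_slice():
    # exon1 bases 11..19, intron 20..24, exon2 25..33
    seq = "n" * 0 + "gcagcagcag" + TOY_SEQ[:9] + "gtaag" + TOY_SEQ[9:] + "gcagca"
    return GenomeSlice("chrT", 1, seq)


class TestTranslateCodon:
    @pytest.mark.parametrize("codon,residue", [
        ("cgc", "R"), ("cac", "H"), ("taa", "*"), ("ATG", "M"), ("gAa", "E"),
    ])
    def test_standard_code(self, codon, residue):
        assert translate_codon(codon) == residue

    @pytest.mark.parametrize("bad", ["cg", "cgcg", "crc", "c-c", ""])
    def test_rejects_ambiguity_and_length(self, bad):
        with pytest.raises(InvalidCodonError):
            translate_codon(bad)


class TestMapGenomicToCodon:
    def test_published_site_positions(self, models, sites_df):
        # every printed variant position lands on the printed codon number
        for r in sites_df.itertuples(index=False):
            aa_pos, offset = map_genomic_to_codon(models[r.gene], r.pos_published)
            assert aa_pos == r.aa_pos, r.label
            assert offset in (1, 2, 3)

    def test_gdf9_r87h_middle_base(self, models):
        # chr5:41,843,258 is the middle base of codon 87
        assert map_genomic_to_codon(models["GDF9"], 41_843_258) == (87, 2)

    def test_first_coding_base_plus_strand(self):
        assert map_genomic_to_codon(TOY_PLUS, 11) == (1, 1)

    def test_non_coding_and_out_of_range(self, models):
        m = models["BMPR1B"]
        assert map_genomic_to_codon(m, 29_409_900) == NON_CODING  # UTR exon 1
        assert map_genomic_to_codon(m, 29_401_000) == NON_CODING  # intron
        with pytest.raises(OutOfGeneRangeError):
            map_genomic_to_codon(m, 29_000_000)

    def test_minus_strand_exhaustive_walk(self):
        """Every exonic position agrees with a brute-force walk that
        reverse-complements the concatenated exons and indexes codons."""
        exons = ((101, 109), (121, 132))
        model = GeneModel("TOYM", "chrT", "-", exons, 0, 6)
        # independent oracle: spell the coding sequence by brute force
        genome = {p: "acgt"[(p * 7) % 4] for p in range(95, 140)}
        plus = "".join(genome[p] for p in range(95, 140))
        sl = GenomeSlice("chrT", 95, plus)
        exon_positions = [p for s, e in exons for p in range(s, e + 1)]
        coding_order = sorted(exon_positions, reverse=True)  # minus strand
        for walk_idx, pos in enumerate(coding_order):
            expected = (walk_idx // 3 + 1, walk_idx % 3 + 1)
            assert map_genomic_to_codon(model, pos) == expected
            # codon spelled by the model matches the brute-force spelling
            aa_pos = expected[0]
            codon_positions = coding_order[3 * (aa_pos - 1): 3 * aa_pos]
            brute = "".join(reverse_complement(genome[p])
                            for p in codon_positions)
            assert codon_spec(model, sl, aa_pos).ref_codon == brute


class TestCallCodingVariant:
    def test_all_table1_labels(self, models, slices, sites_df):
        """The nine site/allele pairs reproduce the printed codon-variant
        labels exactly."""
        for site, r in zip(fixtures.variant_sites(),
                           sites_df.itertuples(index=False)):
            call = call_coding_variant(models[r.gene], slices[site.chrom],
                                       site, site.alt_alleles[0])
            assert call.label == r.label
            assert call.ref_residue == r.ref_res
            assert call.alt_residue == r.var_res

    def test_bmpr1b_m64i(self, models, slices):
        site = [s for s in fixtures.variant_sites()
                if s.site_id == "BMPR1B:M64I"][0]
        call = call_coding_variant(models["BMPR1B"], slices["chr6"], site, "t")
        assert (call.aa_pos, call.ref_residue, call.alt_residue,
                call.consequence) == (64, "M", "I", "missense")

    def test_reference_allele_is_silent(self, models, slices):
        site = [s for s in fixtures.variant_sites()
                if s.site_id == "GDF9:R87H"][0]
        call = call_coding_variant(models["GDF9"], slices["chr5"], site, "c")
        assert call.consequence == "silent"
        assert call.ref_residue == call.alt_residue == "R"

    def test_bmp15_leucine_deletion(self, models, slices):
        site = [s for s in fixtures.variant_sites()
                if s.site_id == "BMP15:L11ΔL"][0]
        call = call_coding_variant(models["BMP15"], slices["chrX"], site, "aag")
        assert call.consequence == "inframe_indel"
        assert call.label == "L11ΔL"
        assert call.hgvs == "p.(Leu10_11delinsLeu)"
        assert call.alt_residue == "ΔL"

    def test_allele_mismatch(self, models, slices):
        site = [s for s in fixtures.variant_sites()
                if s.site_id == "GDF9:R87H"][0]
        with pytest.raises(AlleleMismatchError):
            call_coding_variant(models["GDF9"], slices["chr5"], site, "g")

    def test_nonsense_and_frameshift_on_toy_gene(self):
        sl = _toy_slice()
        # cgc (R3) -> tgc would be missense; make a stop: aaa (K2) -> taa
        stop_site = VariantSite("chrT", 14, "a", ("t",))
        call = call_coding_variant(TOY_PLUS, sl, stop_site, "t")
        assert call.consequence == "nonsense" and call.alt_residue == "*"
        # single-base deletion -> frameshift
        fs_site = VariantSite("chrT", 13, "ga", ("g",))
        call = call_coding_variant(TOY_PLUS, sl, fs_site, "g")
        assert call.consequence == "frameshift"

    def test_splice_site_flank(self):
        sl = _toy_slice()
        site = VariantSite("chrT", 20, "g", ("a",))  # first intronic base
        call = call_coding_variant(TOY_PLUS, sl, site, "a")
        assert call.consequence == "splice_site"

    def test_strand_symmetry(self):
        """Calling on a minus-strand gene equals calling on the
        reverse-complemented plus-strand construction of the same gene."""
        sl = _toy_slice()
        n = len(sl.seq)
        rc = GenomeSlice("chrT", 1, reverse_complement(sl.seq))
        flip = lambda p: n - p + 1  # position map under reverse complement
        minus = GeneModel("TOYR", "chrT", "-",
                          tuple(sorted((flip(e), flip(s))
                                       for s, e in TOY_PLUS.exons)), 0, 5)
        for pos, alt in ((14, "t"), (12, "c"), (27, "a")):
            plus_site = VariantSite("chrT", pos, sl.base(pos), (alt,))
            minus_site = VariantSite(
                "chrT", flip(pos), rc.base(flip(pos)),
                (reverse_complement(alt),))
            a = call_coding_variant(TOY_PLUS, sl, plus_site, alt)
            b = call_coding_variant(minus, rc, minus_site,
                                    reverse_complement(alt))
            assert (a.aa_pos, a.ref_residue, a.alt_residue, a.consequence) \
                == (b.aa_pos, b.ref_residue, b.alt_residue, b.consequence)

    def test_call_is_idempotent(self, models, slices):
        """Re-deriving a call from the same site and allele is stable."""
        for site in fixtures.variant_sites():
            gene = site.site_id.split(":")[0]
            first = call_coding_variant(models[gene], slices[site.chrom],
                                        site, site.alt_alleles[0])
            second = call_coding_variant(models[gene], slices[site.chrom],
                                         site, site.alt_alleles[0])
            assert first == second


class TestCatalog:
    def test_v371m_known(self):
        call = ProteinVariantCall("GDF9", 371, "V", "M", "missense")
        m = match_known_catalog(call, fixtures.catalog())
        assert not m.novel
        assert m.phenotype == "Fecundity"
        assert "Finnish landrace" in m.breeds

    def test_r67q_novel(self):
        call = ProteinVariantCall("BMP15", 67, "R", "Q", "missense")
        assert match_known_catalog(call, fixtures.catalog()).novel

    def test_empty_catalog_is_novel(self):
        call = ProteinVariantCall("GDF9", 371, "V", "M", "missense")
        empty = pd.DataFrame(columns=["gene", "variant", "phenotype",
                                      "breeds", "source"])
        assert match_known_catalog(call, empty).novel

    def test_stop_and_deletion_tokens(self):
        stop = ProteinVariantCall("BMP15", 239, "Q", "*", "nonsense")
        assert not match_known_catalog(stop, fixtures.catalog()).novel
        dele = ProteinVariantCall("BMP15", 11, "L", "ΔL", "inframe_indel")
        assert not match_known_catalog(dele, fixtures.catalog()).novel


class TestModelIO:
    def test_bed_round_trip(self, models, tmp_path):
        bed, side = tmp_path / "genes.bed", tmp_path / "genes.tsv"
        write_gene_models(models, bed, side)
        back = read_gene_models(bed, side)
        assert back == models

    def test_invariants(self, models):
        for m in models.values():
            # CDS length minus stop is 3 x protein length
            assert m.cds_length - 3 == 3 * m.protein_length
            assert m.exon_length >= m.cds_offset + m.cds_length
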