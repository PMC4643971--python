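"""MAF/VCF readers, score joins, gene grouping and the min-variant filter."""

from __future__ import annotations

import pandas as pd
import pytest

from negsel.reference import Consequence, TranscriptModel
from negsel.variants import (CdsLocator, Cohort, CohortTable, Variant,
                             VariantClass, attach_scores, infer_variant_class,
                             min_variant_filter, read_maf, read_vcf,
                             resolve_consequences)


def make_variant(gene="G1", pos=4, ref="G", alt="A", cohort=Cohort.somatic,
                 vclass=VariantClass.snv, **kw):
    return Variant(cohort, gene, ref=ref, alt=alt, variant_class=vclass,
                   cds_pos=pos, **kw)


class TestVariantInvariants:
    def test_snv_requires_single_bases(self):
        with pytest.raises(ValueError):
            make_variant(ref="GG", alt="A")

    def test_indel_requires_length_difference(self):
        with pytest.raises(ValueError):
            make_variant(ref="G", alt="A", vclass=VariantClass.deletion)

    @pytest.mark.parametrize("ref,alt,expected", [
        ("G", "A", VariantClass.snv),
        ("G", "-", VariantClass.deletion),
        ("-", "GAT", VariantClass.insertion),
        ("GAT", "G", VariantClass.deletion),
        ("G", "GAT", VariantClass.insertion),
    ])
    def test_class_inference_from_alleles(self, ref, alt, expected):
        assert infer_variant_class(ref, alt) is expected


class TestReadMaf:
    def test_direct_mapping(self, six_gene_paths):
        table = read_maf(six_gene_paths["maf"])
        assert table.cohort is Cohort.somatic
        assert table.gene_count("GOOD") == 5
        v = table.by_gene["GOOD"][0]
        assert (v.variant_class, v.cds_pos) == (VariantClass.snv, 4)

    def test_allele_length_rule_for_deletions(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text("Hugo_Symbol\tReference_Allele\tTumor_Seq_Allele2\t"
                       "Start_Position\nG1\tG\t-\t3\n")
        table = read_maf(maf)
        assert table.by_gene["G1"][0].variant_class is VariantClass.deletion

    def test_missing_gene_column_names_the_role(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text("Reference_Allele\tTumor_Seq_Allele2\tStart_Position\nG\tA\t3\n")
        with pytest.raises(ValueError, match="gene"):
            read_maf(maf)

    def test_consequence_column_is_honored(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text("Hugo_Symbol\tVariant_Classification\tVariant_Type\t"
                       "Reference_Allele\tTumor_Seq_Allele2\tStart_Position\n"
                       "G1\tSplice_Site\tSNP\tG\tA\t3\n")
        v = read_maf(maf).by_gene["G1"][0]
        assert v.consequence is Consequence.splice_site


class TestReadVcf:
    def test_multiallelic_split_and_chrom_fallback(self, tmp_path):
        transcripts = {"G1": TranscriptModel("G1", "ATGGGGTAA")}
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=G1,length=9>\n"
            "##contig=<ID=chrUn,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "G1\t4\t.\tG\tA,C\t.\tPASS\t.\n"
            "chrUn\t5\t.\tG\tA\t.\tPASS\t.\n")
        table = read_vcf(vcf, transcripts)
        assert table.gene_count("G1") == 2
        assert {v.alt for v in table.by_gene["G1"]} == {"A", "C"}
        assert table.provenance["dropped"] == 1

    def test_two_exon_coordinate_arithmetic(self, tmp_path):
        # gene on chr1 with exons 101-106 and 201-203 (plus strand):
        # genomic 203 -> CDS position 6 + 3 = 9
        transcripts = {"G1": TranscriptModel("G1", "ATGGGGTAA")}
        locator = CdsLocator({"G1": [("chr1", 101, 106, "+"), ("chr1", 201, 203, "+")]})
        assert locator.locate("chr1", 101) == ("G1", 1)
        assert locator.locate("chr1", 106) == ("G1", 6)
        assert locator.locate("chr1", 201) == ("G1", 7)
        assert locator.locate("chr1", 203) == ("G1", 9)
        assert locator.locate("chr1", 150) is None
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=300>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t203\t.\tA\tG\t.\tPASS\t.\n")
        table = read_vcf(vcf, transcripts, locator=locator)
        v = table.by_gene["G1"][0]
        assert (v.gene_id, v.cds_pos) == ("G1", 9)

    def test_minus_strand_locator(self):
        locator = CdsLocator({"G1": [("chr2", 100, 105, "-")]})
        # transcription runs 105 -> 100, so genomic 105 is CDS position 1
        assert locator.locate("chr2", 105) == ("G1", 1)
        assert locator.locate("chr2", 100) == ("G1", 6)


class TestAttachScores:
    def test_match_and_nonmatch(self, tmp_path):
        table = CohortTable(Cohort.somatic, [
            make_variant(pos=4, consequence=Consequence.missense),
            make_variant(pos=6, alt="T", consequence=Consequence.missense),
        ])
        scores = tmp_path / "s.tsv"
        scores.write_text("gene_id\tcds_pos\tref\talt\tscore_a\tscore_b\n"
                          "G1\t4\tG\tA\t0.8\t0.7\n")
        attach_scores(table, scores)
        scored, unscored = table.by_gene["G1"]
        assert (scored.score_a, scored.score_b) == (0.8, 0.7)
        assert unscored.score_a is None
        assert table.provenance["unscored_nonsyn"] == 1

    def test_conflicting_duplicate_key_errors_in_strict_mode(self, tmp_path):
        table = CohortTable(Cohort.somatic, [make_variant(pos=4)])
        scores = tmp_path / "s.tsv"
        scores.write_text("gene_id\tcds_pos\tref\talt\tscore_a\tscore_b\n"
                          "G1\t4\tG\tA\t0.8\t0.7\nG1\t4\tG\tA\t0.9\t0.7\n")
        with pytest.raises(ValueError, match="conflicting"):
            attach_scores(table, scores, strict=True)
        # equal duplicates are accepted silently
        scores.write_text("gene_id\tcds_pos\tref\talt\tscore_a\tscore_b\n"
                          "G1\t4\tG\tA\t0.8\t0.7\nG1\t4\tG\tA\t0.8\t0.7\n")
        attach_scores(table, scores, strict=True)


class TestRoundTrip:
    def test_tsv_round_trip_preserves_variant_multiset(self, tmp_path):
        table = CohortTable(Cohort.somatic, [
            make_variant(pos=4, score_a=0.5, score_b=0.25,
                         consequence=Consequence.missense),
            make_variant(pos=4),  # duplicate record must survive
            make_variant(pos=6, ref="G", alt="GAT", vclass=VariantClass.insertion),
        ])
        path = tmp_path / "t.tsv"
        table.write_tsv(path)
        back = CohortTable.read_tsv(path)
        assert sorted(map(repr, back.variants())) == sorted(map(repr, table.variants()))


class TestMinVariantFilter:
    @staticmethod
    def _cohort(cohort, counts):
        table = CohortTable(cohort)
        for gene, n in counts.items():
            for i in range(n):
                table.add(make_variant(gene=gene, pos=4 + (i % 3), cohort=cohort))
        return table

    def test_boundary_and_either_cohort_rule(self):
        somatic = self._cohort(Cohort.somatic, {"A": 11, "B": 10, "C": 11})
        germline = self._cohort(Cohort.germline, {"A": 11, "B": 500, "C": 10})
        # A meets the boundary in both; B and C each fail one cohort
        assert min_variant_filter(somatic, germline, 11) == {"A"}

    def test_degenerate_threshold_keeps_everything_shared(self):
        somatic = self._cohort(Cohort.somatic, {"A": 1, "B": 2})
        germline = self._cohort(Cohort.germline, {"A": 3})
        assert min_variant_filter(somatic, germline, 1) == {"A"}


class TestResolveConsequences:
    def test_snv_classification_and_indel_arithmetic(self):
        transcripts = {"G1": TranscriptModel("G1", "ATGGGGTAA")}
        table = CohortTable(Cohort.somatic, [
            make_variant(pos=6),                                 # GGG->GGA synonymous
            make_variant(pos=6, ref="G", alt="GTTT", vclass=VariantClass.insertion),
            make_variant(pos=6, ref="G", alt="GT", vclass=VariantClass.insertion),
        ])
        resolve_consequences(table, transcripts)
        cons = [v.consequence for v in table.by_gene["G1"]]
        assert cons == [Consequence.synonymous, Consequence.inframe_indel,
                        Consequence.frameshift_indel]

    def test_preannotated_consequence_is_kept(self):
        transcripts = {"G1": TranscriptModel("G1", "ATGGGGTAA")}
        table = CohortTable(Cohort.somatic,
                            [make_variant(pos=6, consequence=Consequence.splice_site)])
        resolve_consequences(table, transcripts)
        assert table.by_gene["G1"][0].consequence is Consequence.splice_site
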