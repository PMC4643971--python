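"""Shared fixtures: toy transcripts and the printed 6-gene cascade fixture.

The 6-gene fixture is fully hand-checkable.  Every gene shares the CDS
ATG GGG GGG GGG TAA (5 codons), for which NG86 counting gives
n_sites = 34/3, s_sites = 11/3 and a missense-site exposure of 6.0
(first-codon changes are start-loss, stop-codon changes are stop-loss or
synonymous).  With min_variants = 4 the genes are designed to fail exactly
one filter each, except GOOD (passes all) and LOWCOUNT (too few somatic
variants):

gene       somatic variants                 germline          omega    f_som  f_germ
GOOD       1 missense(0.10) + 4 syn         2 mis(.90/.92)+2syn  0.1528   0.0    0.5
LOWCOUNT   3 syn (fails min=4)              4 syn                -        -      -
HIGHDNDS   4 missense(low) + 1 syn          4 syn                2.4444   0.0    0.0
NOEXPR     1 missense(0.12) + 4 syn         2 mis(.88/.91)+2syn  0.1528   0.0    0.5
NODEPLETE  1 missense(0.95) + 4 syn         4 syn                0.1528   0.2    0.0
UNDEF      4 missense(low), 0 syn           4 syn                undef    0.0    0.0

The 15 pooled missense scores sorted are 0.10..0.19 (ten values) then
0.88, 0.90, 0.91, 0.92, 0.95; the linear-interpolated 70th percentile is
0.19 + 0.8*(0.88-0.19) = 0.742, so exactly the five scores >= 0.88 are
high-impact.  Expression means 1/10/20/30/40/50 give strictly-smaller ranks
0/0.2/0.4/0.6/0.8/1.0; rank must exceed 0.20, so NOEXPR (and LOWCOUNT)
fail the expression filter.  The only essential gene is GOOD.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from negsel import PipelineConfig
from negsel.reference import TranscriptModel

FIXTURE_CDS = "ATGGGGGGGGGGTAA"

SIX_GENE_FASTA = "".join(
    f">{g}\n{FIXTURE_CDS}\n"
    for g in ["GOOD", "LOWCOUNT", "HIGHDNDS", "NOEXPR", "NODEPLETE", "UNDEF"]
)

_MAF_HEADER = ("Hugo_Symbol\tVariant_Classification\tVariant_Type\t"
               "Reference_Allele\tTumor_Seq_Allele2\tStart_Position\n")

_SOMATIC_ROWS = [
    ("GOOD", 4, "A"), ("GOOD", 6, "A"), ("GOOD", 9, "A"), ("GOOD", 12, "A"),
    ("GOOD", 6, "T"),
    ("LOWCOUNT", 6, "A"), ("LOWCOUNT", 9, "A"), ("LOWCOUNT", 12, "A"),
    ("HIGHDNDS", 4, "A"), ("HIGHDNDS", 4, "C"), ("HIGHDNDS", 5, "A"),
    ("HIGHDNDS", 7, "A"), ("HIGHDNDS", 9, "A"),
    ("NOEXPR", 4, "A"), ("NOEXPR", 6, "A"), ("NOEXPR", 9, "A"),
    ("NOEXPR", 12, "A"), ("NOEXPR", 12, "C"),
    ("NODEPLETE", 4, "T"), ("NODEPLETE", 6, "A"), ("NODEPLETE", 9, "A"),
    ("NODEPLETE", 12, "A"), ("NODEPLETE", 9, "T"),
    ("UNDEF", 4, "A"), ("UNDEF", 5, "T"), ("UNDEF", 7, "C"), ("UNDEF", 8, "C"),
]

SIX_GENE_MAF = _MAF_HEADER + "".join(
    f"{g}\t\tSNP\tG\t{alt}\t{pos}\n" for g, pos, alt in _SOMATIC_ROWS
)

_GERMLINE_ROWS = [
    ("GOOD", 5, "A"), ("GOOD", 5, "C"), ("GOOD", 6, "A"), ("GOOD", 9, "A"),
    ("LOWCOUNT", 6, "A"), ("LOWCOUNT", 9, "A"), ("LOWCOUNT", 12, "A"),
    ("LOWCOUNT", 6, "T"),
    ("HIGHDNDS", 6, "A"), ("HIGHDNDS", 9, "A"), ("HIGHDNDS", 12, "A"),
    ("HIGHDNDS", 6, "T"),
    ("NOEXPR", 5, "A"), ("NOEXPR", 5, "C"), ("NOEXPR", 6, "A"), ("NOEXPR", 9, "A"),
    ("NODEPLETE", 6, "A"), ("NODEPLETE", 9, "A"), ("NODEPLETE", 12, "A"),
    ("NODEPLETE", 6, "T"),
    ("UNDEF", 6, "A"), ("UNDEF", 9, "A"), ("UNDEF", 12, "A"), ("UNDEF", 6, "T"),
]

SIX_GENE_VCF = (
    "##fileformat=VCFv4.2\n"
    + "".join(f"##contig=<ID={g},length=15>\n"
              for g in ["GOOD", "LOWCOUNT", "HIGHDNDS", "NOEXPR", "NODEPLETE", "UNDEF"])
    + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    + "".join(f"{g}\t{pos}\t.\tG\t{alt}\t.\tPASS\t.\n" for g, pos, alt in _GERMLINE_ROWS)
)

SIX_GENE_SCORES = "gene_id\tcds_pos\tref\talt\tscore_a\tscore_b\n" + "".join(
    f"{g}\t{pos}\tG\t{alt}\t{s}\t{s}\n" for g, pos, alt, s in [
        ("GOOD", 4, "A", 0.10), ("GOOD", 5, "A", 0.90), ("GOOD", 5, "C", 0.92),
        ("HIGHDNDS", 4, "A", 0.15), ("HIGHDNDS", 4, "C", 0.16),
        ("HIGHDNDS", 5, "A", 0.17), ("HIGHDNDS", 7, "A", 0.18),
        ("NOEXPR", 4, "A", 0.12), ("NOEXPR", 5, "A", 0.88), ("NOEXPR", 5, "C", 0.91),
        ("NODEPLETE", 4, "T", 0.95),
        ("UNDEF", 4, "A", 0.11), ("UNDEF", 5, "T", 0.13),
        ("UNDEF", 7, "C", 0.14), ("UNDEF", 8, "C", 0.19),
    ]
)

SIX_GENE_EXPRESSION = "gene_id\tS1\tS2\n" + "".join(
    f"{g}\t{m}\t{m}\n" for g, m in [
        ("GOOD", 50.0), ("LOWCOUNT", 10.0), ("HIGHDNDS", 40.0),
        ("NOEXPR", 1.0), ("NODEPLETE", 20.0), ("UNDEF", 30.0),
    ]
)

#: hand-computed verdicts: (pass_min_variants, pass_dnds, pass_expression, pass_depletion)
SIX_GENE_EXPECTED = {
    "GOOD": (True, True, True, True),
    "LOWCOUNT": (False, False, False, False),
    "HIGHDNDS": (True, False, True, False),
    "NOEXPR": (True, True, False, True),
    "NODEPLETE": (True, True, True, False),
    "UNDEF": (True, False, True, False),
}


@pytest.fixture
def six_gene_paths(tmp_path: Path) -> dict[str, Path]:
    paths = {
        "cds": tmp_path / "cds.fasta",
        "maf": tmp_path / "somatic.maf",
        "vcf": tmp_path / "germline.vcf",
        "scores": tmp_path / "scores.tsv",
        "expression": tmp_path / "expression.tsv",
    }
    paths["cds"].write_text(SIX_GENE_FASTA)
    paths["maf"].write_text(SIX_GENE_MAF)
    paths["vcf"].write_text(SIX_GENE_VCF)
    paths["scores"].write_text(SIX_GENE_SCORES)
    paths["expression"].write_text(SIX_GENE_EXPRESSION)
    return paths


@pytest.fixture
def six_gene_config() -> PipelineConfig:
    return PipelineConfig(min_variants=4)


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    return TranscriptModel("toy", FIXTURE_CDS)
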