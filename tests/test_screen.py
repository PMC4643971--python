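"""Expression filter and the four-filter selection cascade."""

from __future__ import annotations

import math

import pandas as pd
import pytest

from conftest import SIX_GENE_EXPECTED
from negsel import EssentialGeneScreen, PipelineConfig
from negsel.screen import decisions_frame, expression_filter, run_selection


class TestExpressionFilter:
    def test_lowest_quantile_removed(self):
        matrix = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0, 5.0]},
                              index=[f"g{i}" for i in range(1, 6)])
        profiles, kept = expression_filter(matrix, quantile=0.20)
        assert kept == {"g2", "g3", "g4", "g5"}
        assert profiles["g1"].quantile_rank == 0.0
        assert profiles["g5"].quantile_rank == 1.0

    def test_quantile_zero_keeps_all_but_rank_zero(self):
        matrix = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        _, kept = expression_filter(matrix, quantile=0.0)
        assert kept == {"b", "c"}  # rank must be strictly greater than 0

    def test_single_sample_mean_is_that_column(self):
        matrix = pd.DataFrame({"s1": [7.0, 3.0]}, index=["a", "b"])
        profiles, _ = expression_filter(matrix)
        assert profiles["a"].mean_expression == 7.0

    def test_ties_share_rank(self):
        matrix = pd.DataFrame({"s1": [1.0, 1.0, 5.0]}, index=["a", "b", "c"])
        profiles, kept = expression_filter(matrix, quantile=0.20)
        assert profiles["a"].quantile_rank == profiles["b"].quantile_rank == 0.0
        assert kept == {"c"}

    def test_non_numeric_cells_error(self):
        matrix = pd.DataFrame({"s1": ["x", "y"]}, index=["a", "b"])
        with pytest.raises(ValueError):
            expression_filter(matrix)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            expression_filter(pd.DataFrame())


@pytest.fixture
def six_gene_results(six_gene_paths, six_gene_config):
    model = EssentialGeneScreen.from_files(
        six_gene_paths["cds"], six_gene_paths["maf"], six_gene_paths["vcf"],
        six_gene_paths["expression"], six_gene_paths["scores"],
        config=six_gene_config)
    return model.fit()


class TestSixGeneCascade:
    def test_exactly_one_essential_gene(self, six_gene_results):
        assert six_gene_results.essential_genes == ["GOOD"]

    def test_every_pass_flag_matches_hand_calculation(self, six_gene_results):
        by_gene = {d.gene_id: d for d in six_gene_results.decisions}
        assert set(by_gene) == set(SIX_GENE_EXPECTED)
        for gene, expected in SIX_GENE_EXPECTED.items():
            d = by_gene[gene]
            got = (d.pass_min_variants, d.pass_dnds, d.pass_expression,
                   d.pass_depletion)
            assert got == expected, f"{gene}: {got} != {expected}"

    def test_carried_values_match_hand_calculation(self, six_gene_results):
        by_gene = {d.gene_id: d for d in six_gene_results.decisions}
        assert by_gene["GOOD"].omega == pytest.approx((1 / 6) / (4 / (11 / 3)))
        assert by_gene["HIGHDNDS"].omega == pytest.approx((4 / 6) / (1 / (11 / 3)))
        assert math.isnan(by_gene["UNDEF"].omega)
        assert by_gene["GOOD"].f_germline == pytest.approx(0.5)
        assert by_gene["GOOD"].f_somatic == 0.0
        assert by_gene["NODEPLETE"].f_somatic == pytest.approx(0.2)
        th = six_gene_results.impact_thresholds["somatic"]
        assert th.cutoff_a == pytest.approx(0.742)

    def test_s1_style_columns_present(self, six_gene_results):
        frame = six_gene_results.frame
        for col in ["Gene", "skcm.dnds", "quantile.expression", "norm.neutral",
                    "norm.high", "skcm.neutral", "skcm.high"]:
            assert col in frame.columns
        row = frame.set_index("Gene").loc["GOOD"]
        assert (row["norm.high"], row["norm.neutral"]) == (2, 2)
        assert (row["skcm.high"], row["skcm.neutral"]) == (0, 5)


class TestCascadeEdgeCases:
    def test_zero_dnds_threshold_passes_nothing(self, six_gene_paths):
        cfg = PipelineConfig(min_variants=4, dnds_threshold=0.0)
        model = EssentialGeneScreen.from_files(
            six_gene_paths["cds"], six_gene_paths["maf"], six_gene_paths["vcf"],
            six_gene_paths["expression"], six_gene_paths["scores"], config=cfg)
        results = model.fit()
        assert not any(d.pass_dnds for d in results.decisions)
        assert results.essential_genes == []

    def test_gene_missing_from_expression_fails_that_filter(
            self, six_gene_paths, six_gene_config, tmp_path):
        expr = tmp_path / "expr.tsv"
        lines = six_gene_paths["expression"].read_text().splitlines()
        expr.write_text("\n".join(l for l in lines if not l.startswith("GOOD")) + "\n")
        model = EssentialGeneScreen.from_files(
            six_gene_paths["cds"], six_gene_paths["maf"], six_gene_paths["vcf"],
            expr, six_gene_paths["scores"], config=six_gene_config)
        results = model.fit()
        d = {x.gene_id: x for x in results.decisions}["GOOD"]
        assert not d.pass_expression and not d.essential

    def test_relaxing_thresholds_yields_supersets(self, six_gene_paths):
        def essential(**kw):
            cfg = PipelineConfig(**{"min_variants": 4, **kw})
            model = EssentialGeneScreen.from_files(
                six_gene_paths["cds"], six_gene_paths["maf"], six_gene_paths["vcf"],
                six_gene_paths["expression"], six_gene_paths["scores"], config=cfg)
            return set(model.fit().essential_genes)

        base = essential()
        assert base <= essential(dnds_threshold=5.0)
        assert base <= essential(min_variants=1)
        assert base <= essential(expression_quantile=0.0)

    def test_no_gene_overlap_errors(self, six_gene_paths, tmp_path):
        maf = tmp_path / "other.maf"
        maf.write_text("Hugo_Symbol\tVariant_Type\tReference_Allele\t"
                       "Tumor_Seq_Allele2\tStart_Position\nZZZ\tSNP\tG\tA\t4\n")
        model = EssentialGeneScreen.from_files(
            six_gene_paths["cds"], maf, six_gene_paths["vcf"],
            six_gene_paths["expression"], six_gene_paths["scores"])
        with pytest.raises(ValueError, match="overlap"):
            model.fit()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(expression_quantile=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(min_variants=0)
        with pytest.raises(ValueError):
            PipelineConfig(dnds_threshold=-1)


def test_decisions_frame_is_sorted_and_complete(six_gene_paths, six_gene_config):
    model = EssentialGeneScreen.from_files(
        six_gene_paths["cds"], six_gene_paths["maf"], six_gene_paths["vcf"],
        six_gene_paths["expression"], six_gene_paths["scores"],
        config=six_gene_config)
    frame = decisions_frame(model.fit().decisions)
    assert list(frame["Gene"]) == sorted(frame["Gene"])
    assert frame["essential"].sum() == 1
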