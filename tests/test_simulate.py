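"""Synthetic-study generator: determinism, validity and parameter recovery."""

from __future__ import annotations

import numpy as np
import pytest

from negsel.dnds import estimate_dnds, pooled_dnds
from negsel.reference import Consequence, count_sites, load_cds
from negsel.simulate import (SimulationConfig, SyntheticStudy, simulate_cds,
                             simulate_study)
from negsel.variants import (Cohort, VariantClass, attach_scores, read_maf,
                             read_vcf, resolve_consequences)


def small_cfg(**kw):
    defaults = dict(n_genes=12, cds_length_range=(50, 80), somatic_mean=20,
                    germline_mean=20, n_samples=8, n_gene_sets=4,
                    n_random_edges=60, random_seed=5)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateCds:
    def test_requested_shape(self):
        rng = np.random.default_rng(0)
        cfg = small_cfg(n_genes=3, cds_length_range=(100, 100))
        transcripts = simulate_cds(cfg, rng)
        assert len(transcripts) == 3
        assert all(len(t.cds_sequence) == 300 for t in transcripts.values())

    def test_start_stop_and_no_internal_stops(self):
        rng = np.random.default_rng(1)
        for t in simulate_cds(small_cfg(), rng).values():
            assert t.cds_sequence.startswith("ATG")
            assert t.cds_sequence[-3:] in ("TAA", "TAG", "TGA")
            # TranscriptModel construction already rejects internal stops

    def test_same_seed_identical(self):
        a = simulate_cds(small_cfg(), np.random.default_rng(9))
        b = simulate_cds(small_cfg(), np.random.default_rng(9))
        assert {g: t.cds_sequence for g, t in a.items()} == \
               {g: t.cds_sequence for g, t in b.items()}

    def test_degenerate_range_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            small_cfg(cds_length_range=(0, 0))


class TestStudyDeterminism:
    def test_full_study_reproducible_under_fixed_seed(self):
        a = simulate_study(small_cfg())
        b = simulate_study(small_cfg())
        assert a.somatic.to_frame().equals(b.somatic.to_frame())
        assert a.germline.to_frame().equals(b.germline.to_frame())
        assert a.expression.equals(b.expression)
        assert a.truth.equals(b.truth)
        assert a.scores.equals(b.scores)

    def test_different_seed_differs(self):
        a = simulate_study(small_cfg(random_seed=1))
        b = simulate_study(small_cfg(random_seed=2))
        assert not a.somatic.to_frame().equals(b.somatic.to_frame())


class TestCohortConstruction:
    def test_omega_zero_emits_no_missense(self):
        study = simulate_study(small_cfg(omega_background=0.0, essential_fraction=0.0,
                                         p_insertion=0, p_deletion=0, p_splice=0))
        resolve_consequences(study.somatic, study.transcripts)
        assert all(v.consequence is not Consequence.missense
                   for v in study.somatic.variants())

    def test_zero_count_gene_still_listed(self):
        study = simulate_study(small_cfg(somatic_mean=0.0))
        assert set(study.somatic.by_gene) == set(study.transcripts)
        assert study.somatic.n_variants == 0

    def test_variant_records_are_valid_against_cds(self):
        study = simulate_study(small_cfg())
        for v in study.somatic.variants():
            seq = study.transcripts[v.gene_id].cds_sequence
            if v.variant_class is VariantClass.snv:
                assert seq[v.cds_pos - 1] == v.ref

    def test_scores_shared_between_cohorts(self):
        # a site seen in both cohorts must carry identical scores
        study = simulate_study(small_cfg(somatic_mean=60, germline_mean=60))
        keys = {}
        for table in (study.somatic, study.germline):
            for v in table.variants():
                if v.score_a is None:
                    continue
                key = (v.gene_id, v.cds_pos, v.ref, v.alt)
                if key in keys:
                    assert keys[key] == (v.score_a, v.score_b)
                keys[key] = (v.score_a, v.score_b)


class TestParameterRecovery:
    @pytest.mark.parametrize("true_omega", [1.0, 0.3])
    def test_pooled_omega_recovers_truth(self, true_omega):
        cfg = SimulationConfig(n_genes=30, cds_length_range=(80, 150),
                               somatic_mean=120, germline_mean=5,
                               essential_fraction=0.0, omega_background=true_omega,
                               p_insertion=0, p_deletion=0, p_splice=0,
                               n_samples=4, n_gene_sets=2, n_random_edges=10,
                               random_seed=21)
        study = simulate_study(cfg)
        resolve_consequences(study.somatic, study.transcripts)
        ests = [estimate_dnds(study.somatic.by_gene[g],
                              count_sites(study.transcripts[g]))
                for g in study.transcripts]
        assert pooled_dnds(ests) == pytest.approx(true_omega, rel=0.08)

    def test_essential_genes_have_depleted_expected_f(self):
        study = simulate_study(small_cfg(essential_fraction=0.25))
        truth = study.truth.set_index("gene_id")
        essential = truth[truth.planted_class == "essential"]
        assert (essential.expected_f_germline > essential.expected_f_somatic).all()


class TestExpressionMatrix:
    def test_silent_fraction_falls_below_quantile(self):
        cfg = SimulationConfig(n_genes=300, cds_length_range=(30, 40),
                               somatic_mean=0, germline_mean=0,
                               essential_fraction=0.0, silent_fraction=0.2,
                               n_samples=10, n_gene_sets=2, n_random_edges=10,
                               random_seed=13)
        study = simulate_study(cfg)
        means = study.expression.mean(axis=1)
        cut = means.quantile(0.2)
        truth = study.truth.set_index("gene_id")
        silent = truth[~truth.expressed].index
        # the silent component is well separated, so nearly all silent genes
        # sit below the empirical 20th percentile of means
        assert (means.loc[silent] <= cut).mean() > 0.9

    def test_single_sample_matrix(self):
        study = simulate_study(small_cfg(n_samples=1))
        assert study.expression.shape[1] == 1


class TestEmittedFiles:
    def test_formats_round_trip_through_readers(self, tmp_path):
        study = simulate_study(small_cfg())
        paths = study.write(tmp_path)
        transcripts = load_cds(paths["cds"])
        assert set(transcripts) == set(study.transcripts)
        somatic = read_maf(paths["somatic"])
        assert somatic.n_variants == study.somatic.n_variants
        germline = read_vcf(paths["germline"], transcripts)
        assert germline.n_variants == study.germline.n_variants
        attach_scores(somatic, paths["scores"])
        # every scored in-memory somatic variant is scored after the file join
        n_mem = sum(v.score_a is not None for v in study.somatic.variants())
        n_file = sum(v.score_a is not None for v in somatic.variants())
        assert n_file == n_mem

    def test_written_files_byte_identical_across_runs(self, tmp_path):
        p1 = simulate_study(small_cfg()).write(tmp_path / "a")
        p2 = simulate_study(small_cfg()).write(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name
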