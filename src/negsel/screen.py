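"""The essential-gene filter cascade and its model/results interface.

A gene is called *essential* when it simultaneously (i) carries at least
``min_variants`` variants in both the somatic and the germline cohort,
(ii) has somatic dN/dS below the negative-selection threshold, (iii) is
expressed above the lowest ``expression_quantile`` of mean expression, and
(iv) is depleted of high-impact mutations somatically (f_germline >
f_somatic).  All four verdicts are retained per gene; the essential flag is
their conjunction.

:class:`EssentialGeneScreen` is the model object (built from the two cohorts,
the coding sequences, the expression matrix and an optional impact-score
table); :meth:`EssentialGeneScreen.fit` runs the cascade and returns a
:class:`ScreenResults` carrying estimates, decisions and a summary table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dnds import (DnDsEstimate, OmegaDistribution, estimate_dnds,
                   find_negative_selection_threshold, omega_histogram)
from .impact import (GeneCohortSummary, ImpactThresholds, PercentilePopulation,
                     compute_f, depletion_test, derive_thresholds)
from .reference import SiteCounts, TranscriptModel, count_sites, load_cds
from .variants import (CohortTable, attach_scores, min_variant_filter,
                       read_maf, read_vcf, resolve_consequences)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the cascade (defaults follow the study design)."""

    min_variants: int = 11
    dnds_threshold: float | str = 0.25          # or "auto"
    expression_quantile: float = 0.20
    impact_percentile: float = 0.70
    impact_population: str = "pooled_cohorts"   # or "per_cohort"
    interaction_score_min: float = 0.9
    histogram_bin_width: float = 0.05
    histogram_range: tuple[float, float] = (0.0, 2.0)
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expression_quantile", "impact_percentile"):
            q = getattr(self, name)
            if not 0.0 <= q < 1.0:
                raise ValueError(f"{name}={q} outside [0, 1)")
        if self.min_variants < 1:
            raise ValueError("min_variants must be >= 1")
        if self.dnds_threshold != "auto" and float(self.dnds_threshold) < 0:
            raise ValueError("dnds_threshold must be >= 0 or 'auto'")
        if not 0.0 <= self.interaction_score_min <= 1.0:
            raise ValueError("interaction_score_min outside [0, 1]")
        PercentilePopulation(self.impact_population)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "histogram_range" in data:
            data["histogram_range"] = tuple(data["histogram_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["histogram_range"] = list(self.histogram_range)
        return d


@dataclass(frozen=True)
class ExpressionProfile:
    """Mean expression of one gene and its empirical quantile rank.

    ``quantile_rank`` is the fraction of *other* genes with strictly smaller
    mean: #{strictly smaller} / (n_genes - 1), so the lowest gene ranks 0.0
    and the highest 1.0.
    """

    gene_id: str
    mean_expression: float
    quantile_rank: float


def expression_filter(matrix: pd.DataFrame, quantile: float = 0.20,
                      ) -> tuple[dict[str, ExpressionProfile], set[str]]:
    """Mean-expression profiles and the kept set (rank strictly above quantile).

    ``matrix`` is genes x samples (index = gene ids).  The kept set doubles as
    the enrichment reference universe.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    values = matrix.to_numpy(dtype=float)  # raises on non-numeric cells
    means = values.mean(axis=1)
    n = len(means)
    order = np.argsort(means, kind="stable")
    # count of strictly smaller means, tie-aware
    sorted_means = means[order]
    strictly_smaller = np.searchsorted(sorted_means, means, side="left")
    ranks = strictly_smaller / (n - 1) if n > 1 else np.ones(n)
    profiles = {
        str(g): ExpressionProfile(str(g), float(m), float(r))
        for g, m, r in zip(matrix.index, means, ranks)
    }
    kept = {g for g, p in profiles.items() if p.quantile_rank > quantile}
    return profiles, kept


@dataclass(frozen=True)
class SelectionDecision:
    """Per-gene verdicts of the four filters and the final essential call."""

    gene_id: str
    pass_min_variants: bool
    pass_dnds: bool
    pass_expression: bool
    pass_depletion: bool
    omega: float = float("nan")
    quantile_rank: float = float("nan")
    f_germline: float = float("nan")
    f_somatic: float = float("nan")
    n_somatic: int = 0
    n_germline: int = 0
    germline_high: int = 0
    somatic_high: int = 0

    @property
    def essential(self) -> bool:
        return (self.pass_min_variants and self.pass_dnds
                and self.pass_expression and self.pass_depletion)


@dataclass
class _ScreenComputation:
    decisions: list[SelectionDecision]
    estimates: dict[str, DnDsEstimate]
    site_counts: dict[str, SiteCounts]
    thresholds: dict  # impact thresholds per cohort key or 'pooled'
    dnds_threshold: float
    omega_distribution: OmegaDistribution | None
    expression_profiles: dict[str, ExpressionProfile]
    universe: set[str]
    stage_counts: dict[str, int]


def _run(somatic: CohortTable, germline: CohortTable,
         transcripts: Mapping[str, TranscriptModel],
         expression: pd.DataFrame,
         scores: "pd.DataFrame | str | Path | None",
         cfg: PipelineConfig) -> _ScreenComputation:
    if scores is not None:
        attach_scores(somatic, scores)
        attach_scores(germline, scores)
    resolve_consequences(somatic, transcripts)
    resolve_consequences(germline, transcripts)

    genes = sorted(set(somatic.by_gene) & set(germline.by_gene))
    if not genes:
        raise ValueError("no gene overlap between somatic and germline cohorts")
    passing_min = min_variant_filter(somatic, germline, cfg.min_variants)

    site_counts: dict[str, SiteCounts] = {}
    estimates: dict[str, DnDsEstimate] = {}
    for g in sorted(passing_min):
        t = transcripts.get(g)
        if t is None:
            log.warning("gene %s has no CDS; cannot estimate dN/dS", g)
            continue
        site_counts[g] = count_sites(t)
        estimates[g] = estimate_dnds(somatic.by_gene[g], site_counts[g])

    dist = None
    if cfg.dnds_threshold == "auto":
        dist = omega_histogram(list(estimates.values()), cfg.histogram_bin_width,
                               cfg.histogram_range)
        omega_cut = find_negative_selection_threshold(dist)
    else:
        omega_cut = float(cfg.dnds_threshold)

    profiles, universe = expression_filter(expression, cfg.expression_quantile)

    population = PercentilePopulation(cfg.impact_population)
    if population is PercentilePopulation.pooled_cohorts:
        pooled = list(somatic.variants()) + list(germline.variants())
        th = derive_thresholds(pooled, cfg.impact_percentile, population)
        thresholds = {"somatic": th, "germline": th}
    else:
        thresholds = {
            "somatic": derive_thresholds(list(somatic.variants()),
                                         cfg.impact_percentile, population),
            "germline": derive_thresholds(list(germline.variants()),
                                          cfg.impact_percentile, population),
        }

    decisions: list[SelectionDecision] = []
    for g in genes:
        if g not in passing_min or g not in estimates:
            decisions.append(SelectionDecision(
                g, pass_min_variants=False, pass_dnds=False,
                pass_expression=False, pass_depletion=False,
                n_somatic=somatic.gene_count(g), n_germline=germline.gene_count(g)))
            continue
        est = estimates[g]
        pass_dnds = est.defined and est.omega < omega_cut
        profile = profiles.get(g)
        if profile is None:
            log.warning("gene %s absent from expression matrix; fails expression filter", g)
        pass_expr = profile is not None and profile.quantile_rank > cfg.expression_quantile
        f_som = compute_f(somatic.by_gene[g], thresholds["somatic"])
        f_germ = compute_f(germline.by_gene[g], thresholds["germline"])
        decisions.append(SelectionDecision(
            g, pass_min_variants=True, pass_dnds=pass_dnds,
            pass_expression=pass_expr,
            pass_depletion=depletion_test(f_som, f_germ),
            omega=est.omega,
            quantile_rank=profile.quantile_rank if profile else float("nan"),
            f_germline=f_germ.f, f_somatic=f_som.f,
            n_somatic=f_som.n_total, n_germline=f_germ.n_total,
            germline_high=f_germ.n_high, somatic_high=f_som.n_high))

    stage_counts = {
        "genes_in_both_cohorts": len(genes),
        "pass_min_variants": sum(d.pass_min_variants for d in decisions),
        "pass_dnds": sum(d.pass_min_variants and d.pass_dnds for d in decisions),
        "pass_expression": sum(d.pass_min_variants and d.pass_dnds and d.pass_expression
                               for d in decisions),
        "essential": sum(d.essential for d in decisions),
    }
    return _ScreenComputation(decisions, estimates, site_counts, thresholds,
                              omega_cut, dist, profiles, universe, stage_counts)


def run_selection(somatic: CohortTable, germline: CohortTable,
                  transcripts: Mapping[str, TranscriptModel],
                  expression: pd.DataFrame,
                  scores: "pd.DataFrame | str | Path | None" = None,
                  cfg: PipelineConfig | None = None) -> list[SelectionDecision]:
    """Run the full filter cascade; returns one decision per overlapping gene."""
    return _run(somatic, germline, transcripts, expression, scores,
                cfg or PipelineConfig()).decisions


S1_COLUMNS = ["Gene", "skcm.dnds", "quantile.expression", "norm.neutral",
              "norm.high", "skcm.neutral", "skcm.high"]


def decisions_frame(decisions: Sequence[SelectionDecision]) -> pd.DataFrame:
    """Report table with S1-style columns plus the per-filter verdicts."""
    rows = []
    for d in sorted(decisions, key=lambda d: d.gene_id):
        rows.append({
            "Gene": d.gene_id,
            "skcm.dnds": round(d.omega, 6) if math.isfinite(d.omega) else float("nan"),
            "quantile.expression": (round(d.quantile_rank, 6)
                                    if math.isfinite(d.quantile_rank) else float("nan")),
            "norm.neutral": d.n_germline - d.germline_high,
            "norm.high": d.germline_high,
            "skcm.neutral": d.n_somatic - d.somatic_high,
            "skcm.high": d.somatic_high,
            "pass_min_variants": d.pass_min_variants,
            "pass_dnds": d.pass_dnds,
            "pass_expression": d.pass_expression,
            "pass_depletion": d.pass_depletion,
            "essential": d.essential,
        })
    return pd.DataFrame(rows, columns=S1_COLUMNS + [
        "pass_min_variants", "pass_dnds", "pass_expression", "pass_depletion", "essential"])


class EssentialGeneScreen:
    """Model object: two variant cohorts + CDS + expression (+ impact scores).

    Construct directly from in-memory objects or via :meth:`from_files`, then
    call :meth:`fit` to run the cascade.
    """

    def __init__(self, somatic: CohortTable, germline: CohortTable,
                 transcripts: Mapping[str, TranscriptModel],
                 expression: pd.DataFrame,
                 impact_scores: "pd.DataFrame | str | Path | None" = None,
                 config: PipelineConfig | None = None):
        self.somatic = somatic
        self.germline = germline
        self.transcripts = transcripts
        self.expression = expression
        self.impact_scores = impact_scores
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, cds_fasta: str | Path, somatic_maf: str | Path,
                   germline_vcf: str | Path, expression_tsv: str | Path,
                   scores_tsv: str | Path | None = None,
                   config: PipelineConfig | None = None,
                   maf_column_map: Mapping[str, str] | None = None,
                   ) -> "EssentialGeneScreen":
        transcripts = load_cds(cds_fasta)
        somatic = read_maf(somatic_maf, column_map=maf_column_map)
        germline = read_vcf(germline_vcf, transcripts)
        expression = pd.read_csv(expression_tsv, sep="\t", index_col=0)
        return cls(somatic, germline, transcripts, expression,
                   impact_scores=scores_tsv, config=config)

    def fit(self) -> "ScreenResults":
        comp = _run(self.somatic, self.germline, self.transcripts,
                    self.expression, self.impact_scores, self.config)
        return ScreenResults(self, comp)


class ScreenResults:
    """Results of the cascade: estimates, decisions, thresholds, summary."""

    def __init__(self, model: EssentialGeneScreen, comp: _ScreenComputation):
        self.model = model
        self.decisions = comp.decisions
        self.estimates = comp.estimates
        self.site_counts = comp.site_counts
        self.impact_thresholds = comp.thresholds
        self.dnds_threshold = comp.dnds_threshold
        self.omega_distribution = comp.omega_distribution
        self.expression_profiles = comp.expression_profiles
        self.universe = comp.universe
        self.stage_counts = comp.stage_counts

    @property
    def frame(self) -> pd.DataFrame:
        return decisions_frame(self.decisions)

    @property
    def essential_genes(self) -> list[str]:
        return sorted(d.gene_id for d in self.decisions if d.essential)

    def summary(self) -> str:
        c = self.stage_counts
        th = self.impact_thresholds["somatic"]
        lines = [
            "Essential-gene screen",
            "=" * 54,
            f"{'genes in both cohorts':40s}{c['genes_in_both_cohorts']:>8d}",
            f"{'pass min-variant filter (>= %d/%d)' % (self.model.config.min_variants, self.model.config.min_variants):40s}{c['pass_min_variants']:>8d}",
            f"{'... and dN/dS < %.3g' % self.dnds_threshold:40s}{c['pass_dnds']:>8d}",
            f"{'... and expressed (rank > %.2g)' % self.model.config.expression_quantile:40s}{c['pass_expression']:>8d}",
            f"{'essential (all four filters)':40s}{c['essential']:>8d}",
            "-" * 54,
            f"impact cutoffs (p{100 * th.percentile:.0f}): "
            f"score_a > {th.cutoff_a:.4g}, score_b > {th.cutoff_b:.4g}",
            f"expression universe size: {len(self.universe)}",
        ]
        if self.essential_genes:
            lines.append("essential genes: " + ", ".join(self.essential_genes))
        return "\n".join(lines)

    # --- downstream analyses ------------------------------------------------
    def enrich(self, collections, grouping: str = "within_collection"):
        """Over-representation of the essential set against gene-set collections."""
        from .enrich import enrich

        return enrich(set(self.essential_genes), self.universe, collections,
                      grouping=grouping)

    def summarize_network(self, edges, min_score: float | None = None):
        """Prey counts and common partners of essential genes in an edge list."""
        from .network import summarize_baits

        if min_score is None:
            min_score = self.model.config.interaction_score_min
        return summarize_baits(edges, set(self.essential_genes), min_score)

    def plot_omega(self, path: str | Path) -> None:
        """Export the genome-wide omega histogram with the threshold marked."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        dist = self.omega_distribution
        if dist is None:
            dist = omega_histogram(list(self.estimates.values()),
                                   self.model.config.histogram_bin_width,
                                   self.model.config.histogram_range)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(dist.centers(), dist.counts, width=dist.bin_width * 0.9, color="0.5")
        ax.axvline(self.dnds_threshold, color="red", ls="--",
                   label=f"threshold {self.dnds_threshold:.2f}")
        ax.set_xlabel("dN/dS")
        ax.set_ylabel("genes")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def write_tables(self, outdir: str | Path) -> None:
        from .dnds import write_estimates, write_histogram

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(outdir / "decisions.tsv", sep="\t", index=False)
        with open(outdir / "essential_genes.txt", "w") as fh:
            for g in self.essential_genes:
                fh.write(g + "\n")
        write_estimates(self.estimates.values(), outdir / "dnds_estimates.tsv")
        if self.estimates and any(e.defined for e in self.estimates.values()):
            dist = self.omega_distribution or omega_histogram(
                list(self.estimates.values()),
                self.model.config.histogram_bin_width,
                self.model.config.histogram_range)
            write_histogram(dist, outdir / "omega_histogram.tsv")
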