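"""High-functional-impact classification and the per-gene fraction f.

A variant is high-impact if it belongs to a categorical high-impact class
(insertion/deletion, stop loss, stop gain, splice site) or if either of its
two ensemble impact scores is strictly greater than the empirical 70th
percentile of that score's distribution.  Per gene and cohort,
f = #(high-impact mutations) / #(all mutations); the depletion signature of an
essential gene is f_germline > f_somatic (strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .reference import Consequence
from .variants import Variant, VariantClass

#: consequences that are high-impact by class, before any score is consulted
CATEGORICAL_HIGH_IMPACT = frozenset({
    Consequence.stop_gain,
    Consequence.stop_loss,
    Consequence.splice_site,
    Consequence.frameshift_indel,
    Consequence.inframe_indel,
})

#: SNV consequences whose impact is judged by score (start-loss is treated as
#: missense for impact purposes)
SCOREABLE = frozenset({Consequence.missense, Consequence.start_loss})


class PercentilePopulation(str, Enum):
    pooled_cohorts = "pooled_cohorts"
    per_cohort = "per_cohort"


@dataclass(frozen=True)
class ImpactThresholds:
    """Empirical percentile cutoffs for the two score channels."""

    percentile: float
    cutoff_a: float
    cutoff_b: float
    population: PercentilePopulation = PercentilePopulation.pooled_cohorts

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 1.0:
            raise ValueError(f"percentile {self.percentile} outside [0, 1]")


@dataclass(frozen=True)
class GeneCohortSummary:
    """Per gene per cohort: total variants, high-impact count, fraction f."""

    gene_id: str
    cohort: str
    n_total: int
    n_high: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_high <= self.n_total:
            raise ValueError(f"{self.gene_id}: n_high {self.n_high} outside [0, {self.n_total}]")

    @property
    def f(self) -> float:
        return self.n_high / self.n_total if self.n_total else float("nan")


def _scoreable(v: Variant) -> bool:
    return v.variant_class is VariantClass.snv and v.consequence in SCOREABLE


def derive_thresholds(variants: Iterable[Variant], percentile: float = 0.70,
                      population: PercentilePopulation = PercentilePopulation.pooled_cohorts,
                      ) -> ImpactThresholds:
    """Empirical percentile cutoffs over the scored non-synonymous SNVs given.

    Pass the pooled cohorts (default) or a single cohort's variants for
    per-cohort cutoffs; uses the linear-interpolation percentile definition.
    """
    scores_a: list[float] = []
    scores_b: list[float] = []
    for v in variants:
        if not _scoreable(v):
            continue
        if v.score_a is not None:
            scores_a.append(v.score_a)
        if v.score_b is not None:
            scores_b.append(v.score_b)
    if not scores_a or not scores_b:
        raise ValueError("no scored non-synonymous SNVs to derive thresholds from")
    cutoff_a = float(np.percentile(scores_a, 100.0 * percentile))
    cutoff_b = float(np.percentile(scores_b, 100.0 * percentile))
    return ImpactThresholds(percentile, cutoff_a, cutoff_b, PercentilePopulation(population))


def is_high_impact(v: Variant, th: ImpactThresholds) -> bool:
    """Categorical classes are always high-impact; missense by strict score cut.

    Synonymous SNVs are never high-impact; unscored missense SNVs are treated
    as not high-impact (conservative).
    """
    if v.variant_class in (VariantClass.insertion, VariantClass.deletion):
        return True
    if v.consequence in CATEGORICAL_HIGH_IMPACT:
        return True
    if not _scoreable(v):
        return False
    if v.score_a is not None and v.score_a > th.cutoff_a:
        return True
    if v.score_b is not None and v.score_b > th.cutoff_b:
        return True
    return False


def compute_f(variants: Sequence[Variant], th: ImpactThresholds) -> GeneCohortSummary:
    """Fraction of high-impact mutations among ALL mutations of one gene+cohort."""
    variants = list(variants)
    if not variants:
        raise ValueError("compute_f requires at least one variant")
    gene_ids = {v.gene_id for v in variants}
    cohorts = {v.cohort for v in variants}
    if len(gene_ids) != 1 or len(cohorts) != 1:
        raise ValueError(f"compute_f expects one gene and one cohort, got {gene_ids}, {cohorts}")
    n_high = sum(1 for v in variants if is_high_impact(v, th))
    return GeneCohortSummary(gene_ids.pop(), cohorts.pop().value, len(variants), n_high)


def depletion_test(somatic: GeneCohortSummary, germline: GeneCohortSummary) -> bool:
    """True iff f_germline > f_somatic (strict): somatic depletion of impact."""
    if somatic.gene_id != germline.gene_id:
        raise ValueError(f"gene mismatch: {somatic.gene_id} vs {germline.gene_id}")
    return germline.f > somatic.f
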