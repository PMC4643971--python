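"""Per-gene dN/dS (omega) estimation and negative-selection threshold detection.

Only missense and synonymous SNVs enter the counts: nonsense, start-loss,
splice and indel variants have no synonymous counterpart and are excluded from
both the numerator and the denominator.  For internal consistency the dN
exposure is therefore the missense-site count (NG86 fractional sites at which
a substitution yields a plain amino-acid replacement) rather than the full
non-synonymous site count — numerator and exposure count the same event class,
which makes the pooled estimator unbiased under neutral uniform substitution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference import Consequence, SiteCounts
from .variants import Variant, VariantClass

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DnDsEstimate:
    """Per-gene omega = (n_obs/n_sites) / (s_obs/s_sites).

    ``n_sites`` is the missense-site exposure matched to the missense-only
    numerator; ``s_sites`` the NG86 synonymous sites.  ``defined`` is False
    when ``s_obs == 0`` (no pseudocounts): undefined genes can never pass an
    omega threshold.
    """

    gene_id: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float

    @property
    def defined(self) -> bool:
        return self.s_obs > 0 and self.n_sites > 0 and self.s_sites > 0

    @property
    def omega(self) -> float:
        if not self.defined:
            return float("nan")
        return (self.n_obs / self.n_sites) / (self.s_obs / self.s_sites)


def estimate_dnds(variants: Iterable[Variant], sites: SiteCounts,
                  dedupe: bool = False) -> DnDsEstimate:
    """Estimate omega for one gene from its somatic SNVs.

    ``variants`` must have consequences resolved; each record counts as one
    observation unless ``dedupe`` collapses identical (pos, ref, alt) sites.
    """
    n_obs = s_obs = 0
    seen: set[tuple] = set()
    for v in variants:
        if v.gene_id != sites.gene_id:
            raise ValueError(f"variant gene {v.gene_id} does not match sites {sites.gene_id}")
        if v.variant_class is not VariantClass.snv:
            continue
        if v.consequence not in (Consequence.missense, Consequence.synonymous):
            continue
        if dedupe:
            key = (v.cds_pos, v.ref, v.alt)
            if key in seen:
                continue
            seen.add(key)
        if v.consequence is Consequence.missense:
            n_obs += 1
        else:
            s_obs += 1
    return DnDsEstimate(sites.gene_id, n_obs, s_obs,
                        n_sites=sites.missense_sites, s_sites=sites.s_sites)


def pooled_dnds(estimates: Iterable[DnDsEstimate]) -> float:
    """Count-weighted pooled omega across genes (sums counts and exposures)."""
    n = s = N = S = 0.0
    for e in estimates:
        n += e.n_obs
        s += e.s_obs
        N += e.n_sites
        S += e.s_sites
    if s == 0 or N == 0 or S == 0:
        return float("nan")
    return (n / N) / (s / S)


@dataclass(frozen=True)
class OmegaDistribution:
    """Histogram of defined per-gene omega values (left-closed bins)."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    bin_width: float
    range: tuple[float, float]

    def centers(self) -> np.ndarray:
        edges = np.asarray(self.bin_edges)
        return (edges[:-1] + edges[1:]) / 2.0


def omega_histogram(estimates: Sequence[DnDsEstimate], bin_width: float = 0.05,
                    range: tuple[float, float] = (0.0, 2.0)) -> OmegaDistribution:
    """Genome-wide omega histogram over defined estimates.

    Bins are left-closed ``[edge, edge + width)``; values outside ``range``
    (including the right edge itself) are not counted.
    """
    omegas = np.array([e.omega for e in estimates if e.defined], dtype=float)
    if omegas.size == 0:
        raise ValueError("no defined omega estimates to bin")
    lo, hi = range
    n_bins = int(round((hi - lo) / bin_width))
    if n_bins < 1 or not np.isclose(lo + n_bins * bin_width, hi):
        raise ValueError(f"range {range} is not a multiple of bin_width {bin_width}")
    idx = np.floor((omegas - lo) / bin_width + 1e-9).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins) & (omegas >= lo) & (omegas < hi)]
    counts = np.bincount(idx, minlength=n_bins)
    edges = tuple(lo + i * bin_width for i in np.arange(n_bins + 1))
    return OmegaDistribution(edges, tuple(int(c) for c in counts), bin_width, (lo, hi))


class ThresholdFallbackWarning(UserWarning):
    """No interior histogram minimum found; the configured fallback was used."""


def find_negative_selection_threshold(dist: OmegaDistribution,
                                      search_interval: tuple[float, float] = (0.05, 0.75),
                                      fallback: float = 0.25) -> float:
    """Data-driven omega threshold: center of the local-minimum histogram bin.

    Scans interior bins whose centers lie in ``search_interval`` for local
    minima (count no larger than either neighbor, strictly smaller than at
    least one); among minima returns the center of the lowest-count bin,
    breaking ties toward smaller omega.  If no interior minimum exists the
    ``fallback`` (default 0.25, the value at which genome-wide tumor omega
    histograms dip) is returned with a warning.
    """
    counts = dist.counts
    centers = dist.centers()
    lo, hi = search_interval
    overlapping = [i for i in range(len(counts))
                   if dist.bin_edges[i] < hi and dist.bin_edges[i + 1] > lo]
    if len(overlapping) < 3:
        raise ValueError(
            f"need at least 3 bins intersecting search interval {search_interval}")
    eligible = [i for i in range(1, len(counts) - 1) if lo <= centers[i] <= hi]
    candidates = [
        i for i in eligible
        if counts[i] <= counts[i - 1] and counts[i] <= counts[i + 1]
        and (counts[i] < counts[i - 1] or counts[i] < counts[i + 1])
    ]
    if not candidates:
        warnings.warn(
            f"no interior local minimum in {search_interval}; using fallback {fallback}",
            ThresholdFallbackWarning, stacklevel=2)
        return fallback
    best = min(candidates, key=lambda i: (counts[i], centers[i]))
    return float(centers[best])


def write_estimates(estimates: Iterable[DnDsEstimate], path: str | Path) -> None:
    """Per-gene estimates TSV (gene, skcm.dnds and the underlying counts)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tskcm.dnds\tn_obs\ts_obs\tn_sites\ts_sites\tdefined\n")
        for e in sorted(estimates, key=lambda e: e.gene_id):
            omega = f"{e.omega:.6f}" if e.defined else "NA"
            fh.write(f"{e.gene_id}\t{omega}\t{e.n_obs}\t{e.s_obs}\t"
                     f"{e.n_sites:.6f}\t{e.s_sites:.6f}\t{str(e.defined).lower()}\n")


def write_histogram(dist: OmegaDistribution, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for i, c in enumerate(dist.counts):
            fh.write(f"{dist.bin_edges[i]:.6f}\t{dist.bin_edges[i + 1]:.6f}\t{c}\n")
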