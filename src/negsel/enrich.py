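"""Hypergeometric over-representation analysis with BH correction.

The test asks whether a target list (here: the essential genes) contains more
members of a gene set than expected by chance when drawing ``n`` genes from a
universe of ``M`` containing ``K`` set members; the p-value is the exact
upper tail P[X >= k] of the hypergeometric distribution, summed as integer
binomial coefficients before a single division.  Benjamini–Hochberg step-up
adjustment is applied per collection source (or globally).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    category: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    category: str
    k: int   # hits: target genes in the set (within universe)
    K: int   # set members in universe
    n: int   # target size in universe
    M: int   # universe size
    p_value: float
    p_adjusted: float

    @property
    def fold_enrichment(self) -> float:
        expected = self.K * self.n / self.M if self.M else float("nan")
        return self.k / expected if expected else float("nan")


def read_gmt(path: str | Path, category: str | None = None) -> list[GeneSet]:
    """Read gene sets from GMT (name <TAB> description <TAB> genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets.append(GeneSet(name, frozenset(genes),
                                category=category or Path(path).stem,
                                description=desc))
    return sets


def hypergeometric_overrep(k: int, K: int, n: int, M: int) -> float:
    """Exact upper-tail P[X >= k], X ~ Hypergeometric(M, K, n).

    Summed with integer binomial coefficients (exact until the final
    division), so the result is correct to full float precision.
    """
    if not (0 <= k <= K <= M and 0 <= n <= M and k <= n):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, M={M}")
    total = comb(M, n)
    tail = sum(comb(K, i) * comb(M - K, n - i)
               for i in range(k, min(K, n) + 1))
    return tail / total


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down, cap at 1
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def enrich(target: set[str], universe: set[str],
           collections: Iterable[GeneSet],
           grouping: str = "within_collection",
           strict: bool = True) -> list[EnrichmentResult]:
    """Test each gene set for over-representation of ``target`` in ``universe``.

    Set members are intersected with the universe first (sets that vanish are
    skipped); BH adjustment runs within each category source by default
    (``grouping="global"`` adjusts across everything).
    """
    if grouping not in ("within_collection", "global"):
        raise ValueError(f"unknown grouping {grouping!r}")
    stray = target - universe
    if stray:
        if strict:
            raise ValueError(f"target genes outside universe: {sorted(stray)[:10]}")
        target = target & universe
    M = len(universe)
    n = len(target)
    partial: list[tuple[GeneSet, int, int, float]] = []
    for gs in collections:
        members = gs.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & target)
        partial.append((gs, k, K, hypergeometric_overrep(k, K, n, M)))
    results: list[EnrichmentResult] = []
    if grouping == "global":
        groups: dict[str, list] = {"": partial}
    else:
        groups = {}
        for item in partial:
            groups.setdefault(item[0].category, []).append(item)
    for items in groups.values():
        adj = bh_adjust([p for (_, _, _, p) in items])
        for (gs, k, K, p), q in zip(items, adj):
            results.append(EnrichmentResult(gs.name, gs.category, k, K, n, M,
                                            p, float(q)))
    results.sort(key=lambda r: (r.category, r.p_value, r.set_name))
    return results


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tset\tk\tK\tn\tM\tfold\tp_value\tp_adjusted\n")
        for r in results:
            fh.write(f"{r.category}\t{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.M}\t"
                     f"{r.fold_enrichment:.4g}\t{r.p_value:.6g}\t{r.p_adjusted:.6g}\n")
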