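"""High-confidence interaction-network summaries for the essential set.

Edges above a combined-score threshold (strictly greater than 0.9 by default,
STRING-style) form an undirected graph; each essential gene is a *bait* whose
neighbors are its *preys*.  The summary reports prey counts per bait, shared
partners for each bait pair, and direct bait-bait physical links when a
physical flag is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected scored edge; endpoints stored in canonical (sorted) order."""

    protein_a: str
    protein_b: str
    combined_score: float
    physical: bool | None = None

    def __post_init__(self) -> None:
        a, b = sorted((self.protein_a, self.protein_b))
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"score {self.combined_score} outside [0, 1]")


@dataclass
class BaitSummary:
    bait: str
    prey_count: int
    preys: frozenset[str]
    common_partners: dict[str, int] = field(default_factory=dict)
    physical_baits: frozenset[str] = frozenset()


def load_edges(path: str | Path, score_scale: str = "unit") -> list[InteractionEdge]:
    """Load a STRING-style TSV edge list (protein_a, protein_b, combined_score).

    ``score_scale="milli"`` divides scores by 1000 (STRING's integer scale).
    Duplicate edges (either orientation) keep the maximum score; an optional
    ``physical`` column (0/1 or true/false) is carried through.
    """
    if score_scale not in ("unit", "milli"):
        raise ValueError(f"unknown score scale {score_scale!r}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"edge table {path} needs at least 3 columns")
    cols = list(df.columns)
    has_physical = "physical" in cols
    best: dict[tuple[str, str], tuple[float, bool | None]] = {}
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        score = float(row[2])
        if score_scale == "milli":
            score /= 1000.0
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge ({a},{b}) score {score} outside [0,1] after scaling")
        physical = None
        if has_physical:
            raw = getattr(row, "physical")
            if not pd.isna(raw):
                physical = str(raw).lower() in ("1", "true", "yes") or raw is True or raw == 1
        key = tuple(sorted((a, b)))
        prev = best.get(key)
        if prev is None or score > prev[0]:
            best[key] = (score, physical if prev is None else (physical or prev[1]))
        elif physical and not prev[1]:
            best[key] = (prev[0], True)
    return [InteractionEdge(a, b, s, p) for (a, b), (s, p) in sorted(best.items())]


def summarize_baits(edges: Iterable[InteractionEdge], baits: set[str],
                    min_score: float = 0.9,
                    ) -> tuple[list[BaitSummary], list[str]]:
    """Per-bait prey counts and pairwise common partners above ``min_score``.

    Returns (summaries for baits with >= 1 prey, sidecar list of zero-prey
    baits).  Scores must be strictly greater than ``min_score``; self-loops
    are ignored; bait-bait edges count toward both baits' preys.
    """
    if not baits:
        raise ValueError("empty bait set")
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score {min_score} outside [0, 1]")
    g = nx.Graph()
    for e in edges:
        if e.protein_a == e.protein_b:
            continue
        if e.combined_score > min_score:
            g.add_edge(e.protein_a, e.protein_b,
                       score=e.combined_score, physical=bool(e.physical))
    summaries: list[BaitSummary] = []
    zero_prey: list[str] = []
    neighbor_sets = {b: (set(g.neighbors(b)) if b in g else set()) for b in baits}
    for bait in sorted(baits):
        preys = neighbor_sets[bait]
        if not preys:
            zero_prey.append(bait)
            continue
        common = {}
        for other in sorted(baits):
            if other == bait:
                continue
            shared = preys & neighbor_sets[other]
            if shared:
                common[other] = len(shared)
        physical = frozenset(
            other for other in baits
            if other != bait and g.has_edge(bait, other)
            and g.edges[bait, other].get("physical"))
        summaries.append(BaitSummary(bait, len(preys), frozenset(preys),
                                     common, physical))
    return summaries, zero_prey


def write_bait_table(summaries: Sequence[BaitSummary], path: str | Path,
                     sidecar: Sequence[str] = (), sidecar_path: str | Path | None = None,
                     ) -> None:
    """Table-2-style TSV (bait, prey count), preys sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("bait\tprey_count\tcommon_partner_pairs\n")
        for s in sorted(summaries, key=lambda s: (-s.prey_count, s.bait)):
            pairs = ";".join(f"{o}:{c}" for o, c in sorted(s.common_partners.items()))
            fh.write(f"{s.bait}\t{s.prey_count}\t{pairs}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            for b in sorted(sidecar):
                fh.write(b + "\n")


def write_edge_list(edges: Iterable[InteractionEdge], path: str | Path,
                    min_score: float = 0.0) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\tphysical\n")
        for e in sorted(edges, key=lambda e: (e.protein_a, e.protein_b)):
            if e.combined_score > min_score:
                phys = "" if e.physical is None else str(int(e.physical))
                fh.write(f"{e.protein_a}\t{e.protein_b}\t{e.combined_score:.3f}\t{phys}\n")
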