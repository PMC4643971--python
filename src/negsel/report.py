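"""Run manifests and the human-readable summary report bundle.

Report generation is pure: it serializes results that were already computed,
so re-running it on the same stage outputs is byte-identical.  Manifests
record only content (config snapshot, input basenames with SHA-256 digests,
per-stage gene counts, tool version, seed) — no timestamps or absolute paths,
so two runs with the same inputs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__

log = logging.getLogger(__name__)

#: cascade stages whose gene counts must be non-increasing
CASCADE_ORDER = ["genes_in_both_cohorts", "pass_min_variants", "pass_dnds",
                 "pass_expression", "essential"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    inputs: list[dict] = field(default_factory=list)   # {name, sha256, n_records}
    stage_counts: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def add_input(self, path: str | Path, n_records: int | None = None) -> None:
        entry = {"name": Path(path).name, "sha256": file_digest(path)}
        if n_records is not None:
            entry["n_records"] = n_records
        self.inputs.append(entry)

    def validate(self) -> None:
        counts = [self.stage_counts[k] for k in CASCADE_ORDER if k in self.stage_counts]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"inconsistent cascade counts: {self.stage_counts}")

    def to_json(self) -> str:
        self.validate()
        payload = {"config": self.config, "inputs": self.inputs,
                   "stage_counts": self.stage_counts, "seed": self.seed,
                   "version": self.version}
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def write_report(outdir: str | Path, decisions: Sequence, enrichments=None,
                 bait_summaries=None, zero_prey_baits: Sequence[str] = (),
                 manifest: RunManifest | None = None) -> Path:
    """Write the summary bundle: report.txt plus machine-readable TSVs.

    An empty essential list is a finding, not an error; sections whose stage
    was not run are marked as such.
    """
    from .enrich import write_enrichment
    from .network import write_bait_table
    from .screen import decisions_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = decisions_frame(decisions)
    frame.to_csv(outdir / "decisions.tsv", sep="\t", index=False)
    essential = sorted(d.gene_id for d in decisions if d.essential)

    lines = ["Essential-gene screen report", "=" * 60, ""]
    n_pass = {
        "genes with decisions": len(decisions),
        "pass_min_variants": sum(d.pass_min_variants for d in decisions),
        "pass_dnds": sum(d.pass_dnds for d in decisions),
        "pass_expression": sum(d.pass_expression for d in decisions),
        "pass_depletion": sum(d.pass_depletion for d in decisions),
        "essential (all filters)": len(essential),
    }
    lines += [f"{name:32s}{count:>8d}" for name, count in n_pass.items()]
    lines += ["", f"essential genes ({len(essential)}):"]
    lines += ["  " + g for g in essential] if essential else ["  (none)"]

    lines += ["", "Gene-set enrichment", "-" * 60]
    if enrichments is None:
        lines.append("  not run")
    elif not enrichments:
        lines.append("  no testable sets")
    else:
        write_enrichment(enrichments, outdir / "enrichment.tsv")
        for r in enrichments[:10]:
            lines.append(f"  {r.category}/{r.set_name}: k={r.k}/K={r.K} "
                         f"p={r.p_value:.3g} padj={r.p_adjusted:.3g}")

    lines += ["", "Interaction network (baits = essential genes)", "-" * 60]
    if bait_summaries is None:
        lines.append("  not run")
    else:
        write_bait_table(bait_summaries, outdir / "bait_preys.tsv",
                         sidecar=zero_prey_baits,
                         sidecar_path=outdir / "baits_without_preys.txt")
        lines.append(f"  baits with preys: {len(bait_summaries)}; "
                     f"without: {len(zero_prey_baits)}")
        for s in sorted(bait_summaries, key=lambda s: (-s.prey_count, s.bait))[:10]:
            lines.append(f"  {s.bait}: {s.prey_count} preys")

    if manifest is not None:
        manifest.validate()
        manifest.write(outdir / "manifest.json")
        lines += ["", f"version {manifest.version}, seed {manifest.seed}"]
    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
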