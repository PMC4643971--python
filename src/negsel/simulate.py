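"""Synthetic study generator: CDS, variant cohorts, scores, expression, sets, edges.

Every pipeline input can be produced here with known ground truth, so each
stage of the screen is testable without external snapshots.  Variant cohorts
are built by acceptance sampling against the same codon model the estimator
uses: propose a uniform CDS position and a uniform alternative base, classify
the change, accept synonymous changes always and non-synonymous changes with
probability equal to the gene's true omega (for omega > 1 the rejection flips
to the synonymous side).  Under NG86 counting this makes the expected
observed dN/dS equal to the true omega — a property the test suite verifies
rather than assumes.

High-impact depletion of planted essential genes is modelled by an extra
somatic retention factor < 1 applied to damaging missense, nonsense, splice
and indel proposals; damaging status and impact scores are fixed per site and
shared between cohorts (a variant's functional effect is a property of the
change, not of the cohort it is observed in).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference import (Consequence, TranscriptModel, codon_to_aa, count_sites)
from .variants import Cohort, CohortTable, Variant, VariantClass

log = logging.getLogger(__name__)

ESSENTIAL = "essential"
BACKGROUND = "background"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study (defaults emulate the melanoma screen setup:
    two cohorts of coding variants over a few hundred genes, 374 expression
    samples, a 5% planted-essential fraction under strong purifying selection).
    """

    n_genes: int = 500
    cds_length_range: tuple[int, int] = (100, 400)   # codons, inclusive
    essential_fraction: float = 0.05
    omega_background: float = 1.0
    omega_essential: float = 0.1
    somatic_mean: float = 60.0        # Poisson mean variants per gene
    germline_mean: float = 60.0
    # proposal class probabilities (the remainder are SNV proposals)
    p_insertion: float = 0.02
    p_deletion: float = 0.03
    p_splice: float = 0.01
    # impact-score model
    p_damaging_missense: float = 0.4
    benign_score_loc: float = 0.0
    damaging_score_loc: float = 1.5
    score_sd: float = 1.0
    impact_percentile: float = 0.70
    # extra somatic retention of high-impact changes in essential genes
    somatic_impact_retention: float = 0.3
    # expression model
    n_samples: int = 374
    expressed_log_mean: float = 3.0
    expressed_log_sd: float = 1.0
    silent_log_mean: float = -3.0
    silent_log_sd: float = 0.5
    silent_fraction: float = 0.25
    sample_log_sd: float = 0.3
    # gene sets and interaction edges
    n_gene_sets: int = 20
    gene_set_size: tuple[int, int] = (10, 40)
    n_random_edges: int = 1500
    essential_edge_prob: float = 0.3
    random_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"degenerate CDS length range {self.cds_length_range}")
        for name in ("essential_fraction", "p_insertion", "p_deletion", "p_splice",
                     "p_damaging_missense", "silent_fraction", "impact_percentile",
                     "somatic_impact_retention", "essential_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_insertion + self.p_deletion + self.p_splice > 1.0:
            raise ValueError("class proposal probabilities sum above 1")
        if self.omega_background < 0 or self.omega_essential < 0:
            raise ValueError("omegas must be >= 0")


def _sense_codons(table_id: int = 1) -> list[str]:
    aa = codon_to_aa(table_id)
    return sorted(c for c, a in aa.items() if a != "*")


def _stop_codons(table_id: int = 1) -> list[str]:
    aa = codon_to_aa(table_id)
    return sorted(c for c, a in aa.items() if a == "*")


def simulate_cds(cfg: SimulationConfig, rng: np.random.Generator,
                 ) -> dict[str, TranscriptModel]:
    """Random coding sequences: ATG start, sense body, terminal stop."""
    sense = _sense_codons()
    stops = _stop_codons()
    transcripts: dict[str, TranscriptModel] = {}
    lo, hi = cfg.cds_length_range
    width = max(len(str(cfg.n_genes)), 4)
    for i in range(cfg.n_genes):
        gene = f"G{i + 1:0{width}d}"
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(sense), size=n_codons - 2)
        seq = "ATG" + "".join(sense[j] for j in body) + stops[int(rng.integers(3))]
        transcripts[gene] = TranscriptModel(gene, seq)
    return transcripts


@dataclass
class _SiteCache:
    """Damaging status and scores per candidate change, shared across cohorts."""

    p_damaging: float
    benign_loc: float
    damaging_loc: float
    sd: float
    rng: np.random.Generator
    sites: dict[tuple, tuple[bool, float, float]] = field(default_factory=dict)

    def lookup(self, gene: str, pos: int, ref: str, alt: str,
               ) -> tuple[bool, float, float]:
        key = (gene, pos, ref, alt)
        hit = self.sites.get(key)
        if hit is None:
            damaging = bool(self.rng.random() < self.p_damaging)
            loc = self.damaging_loc if damaging else self.benign_loc
            hit = (damaging,
                   float(self.rng.normal(loc, self.sd)),
                   float(self.rng.normal(loc, self.sd)))
            self.sites[key] = hit
        return hit

    def score_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "cds_pos": p, "ref": r, "alt": a,
             "score_a": sa, "score_b": sb}
            for (g, p, r, a), (_, sa, sb) in sorted(self.sites.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "cds_pos", "ref", "alt",
                                           "score_a", "score_b"])


_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def simulate_cohort(transcripts: Mapping[str, TranscriptModel],
                    gene_classes: Mapping[str, str],
                    cfg: SimulationConfig, cohort: Cohort,
                    rng: np.random.Generator,
                    site_cache: _SiteCache) -> CohortTable:
    """One cohort of variants by acceptance sampling (see module docstring).

    Germline cohorts are neutral (omega 1, full retention); somatic cohorts
    use each gene's true omega and, for essential genes, the configured
    high-impact retention.
    """
    cohort = Cohort(cohort)
    table = CohortTable(cohort)
    mean = cfg.somatic_mean if cohort is Cohort.somatic else cfg.germline_mean
    p_cls = cfg.p_insertion + cfg.p_deletion + cfg.p_splice
    for gene, t in transcripts.items():
        if cohort is Cohort.somatic:
            omega = (cfg.omega_essential if gene_classes[gene] == ESSENTIAL
                     else cfg.omega_background)
            retention = (cfg.somatic_impact_retention
                         if gene_classes[gene] == ESSENTIAL else 1.0)
        else:
            omega, retention = 1.0, 1.0
        accept_nonsyn = min(1.0, omega)
        accept_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
        accept_high = min(1.0, omega * retention)
        n_target = int(rng.poisson(mean))
        seq = t.cds_sequence
        L = len(seq)
        n_emitted = 0
        guard = 0
        while n_emitted < n_target:
            guard += 1
            if guard > 2000 * max(n_target, 1):
                raise RuntimeError(
                    f"{gene}: acceptance sampling stalled (omega={omega})")
            u = rng.random()
            if u < p_cls:
                v = _propose_class_variant(u, t, cfg, cohort, gene, rng)
                if rng.random() < accept_high:
                    table.add(v)
                    n_emitted += 1
                continue
            pos = int(rng.integers(1, L + 1))
            ref = seq[pos - 1]
            alt = _OTHER_BASES[ref][int(rng.integers(3))]
            cons = _classify_fast(t, pos, ref, alt)
            if cons is Consequence.synonymous:
                accept = accept_syn
            elif cons is Consequence.missense:
                damaging, _, _ = site_cache.lookup(gene, pos, ref, alt)
                accept = accept_nonsyn * (retention if damaging else 1.0)
            else:  # nonsense-class: stop gain/loss, start loss
                accept = accept_high
            if rng.random() >= accept:
                continue
            v = Variant(cohort, gene, ref=ref, alt=alt,
                        variant_class=VariantClass.snv, cds_pos=pos)
            if cons in (Consequence.missense, Consequence.start_loss):
                _, sa, sb = site_cache.lookup(gene, pos, ref, alt)
                v.score_a, v.score_b = sa, sb
            table.add(v)
            n_emitted += 1
        if n_target == 0:
            table.by_gene.setdefault(gene, [])
    table.provenance = {"source": f"simulated:{cohort.value}",
                        "kept": table.n_variants, "dropped": 0}
    return table


def _classify_fast(t: TranscriptModel, pos: int, ref: str, alt: str) -> Consequence:
    # inline consequence call on a simulated CDS (no splice windows declared)
    codon, offset = t.codon_at(pos)
    aa = codon_to_aa(t.codon_table_id)
    ref_aa = aa[codon]
    alt_aa = aa[codon[:offset] + alt + codon[offset + 1:]]
    if ref_aa == alt_aa:
        return Consequence.synonymous
    if pos <= 3:
        return Consequence.start_loss
    if alt_aa == "*":
        return Consequence.stop_gain
    if ref_aa == "*":
        return Consequence.stop_loss
    return Consequence.missense


def _propose_class_variant(u: float, t: TranscriptModel, cfg: SimulationConfig,
                           cohort: Cohort, gene: str,
                           rng: np.random.Generator) -> Variant:
    seq = t.cds_sequence
    L = len(seq)
    if u < cfg.p_insertion:
        pos = int(rng.integers(1, L + 1))
        ref = seq[pos - 1]
        ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 4))))
        return Variant(cohort, gene, ref=ref, alt=ref + ins,
                       variant_class=VariantClass.insertion, cds_pos=pos)
    if u < cfg.p_insertion + cfg.p_deletion:
        dlen = int(rng.integers(1, 4))
        pos = int(rng.integers(1, max(2, L - dlen)))
        ref = seq[pos - 1: pos + dlen]
        return Variant(cohort, gene, ref=ref, alt=ref[0],
                       variant_class=VariantClass.deletion, cds_pos=pos)
    pos = int(rng.integers(1, L + 1))
    ref = seq[pos - 1]
    alt = _OTHER_BASES[ref][int(rng.integers(3))]
    return Variant(cohort, gene, ref=ref, alt=alt, variant_class=VariantClass.snv,
                   cds_pos=pos, consequence=Consequence.splice_site)


def simulate_expression(cfg: SimulationConfig, gene_classes: Mapping[str, str],
                        rng: np.random.Generator,
                        ) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Log-normal gene x sample matrix; a fraction of background genes near zero."""
    genes = list(gene_classes)
    expressed: dict[str, bool] = {}
    mus = []
    for g in genes:
        on = gene_classes[g] == ESSENTIAL or rng.random() >= cfg.silent_fraction
        expressed[g] = bool(on)
        if on:
            mus.append(rng.normal(cfg.expressed_log_mean, cfg.expressed_log_sd))
        else:
            mus.append(rng.normal(cfg.silent_log_mean, cfg.silent_log_sd))
    values = np.exp(np.asarray(mus)[:, None]
                    + rng.normal(0.0, cfg.sample_log_sd, size=(len(genes), cfg.n_samples)))
    df = pd.DataFrame(values, index=genes,
                      columns=[f"S{j + 1:03d}" for j in range(cfg.n_samples)])
    df.index.name = "gene_id"
    return df, expressed


def simulate_gene_sets(cfg: SimulationConfig, gene_classes: Mapping[str, str],
                       rng: np.random.Generator):
    """Random gene sets plus one set concentrated in the planted essential genes."""
    from .enrich import GeneSet

    genes = list(gene_classes)
    essential = [g for g in genes if gene_classes[g] == ESSENTIAL]
    lo, hi = cfg.gene_set_size
    sets = []
    if essential:
        n_ess = max(1, int(0.8 * len(essential)))
        chosen = [essential[i] for i in rng.choice(len(essential), n_ess, replace=False)]
        pad = [genes[i] for i in rng.choice(len(genes), max(0, lo - n_ess), replace=False)]
        sets.append(GeneSet("planted_essential_module",
                            frozenset(chosen) | frozenset(pad),
                            category="synthetic_go",
                            description="set enriched in planted essential genes"))
    for i in range(cfg.n_gene_sets):
        size = min(int(rng.integers(lo, hi + 1)), len(genes))
        members = frozenset(genes[j] for j in rng.choice(len(genes), size, replace=False))
        category = "synthetic_go" if i % 2 == 0 else "synthetic_pathways"
        sets.append(GeneSet(f"random_set_{i + 1:02d}", members, category=category,
                            description="uniform random gene set"))
    return sets


def simulate_edges(cfg: SimulationConfig, gene_classes: Mapping[str, str],
                   rng: np.random.Generator):
    """STRING-style scored edges with a high-confidence essential cluster."""
    from .network import InteractionEdge

    genes = list(gene_classes)
    essential = [g for g in genes if gene_classes[g] == ESSENTIAL]
    edges: dict[tuple[str, str], float] = {}
    for _ in range(cfg.n_random_edges):
        i, j = rng.choice(len(genes), 2, replace=False)
        key = tuple(sorted((genes[i], genes[j])))
        edges[key] = max(edges.get(key, 0.0), float(rng.uniform(0.15, 0.999)))
    for i in range(len(essential)):
        for j in range(i + 1, len(essential)):
            if rng.random() < cfg.essential_edge_prob:
                key = tuple(sorted((essential[i], essential[j])))
                edges[key] = max(edges.get(key, 0.0), float(rng.uniform(0.905, 0.999)))
    return [InteractionEdge(a, b, s) for (a, b), s in sorted(edges.items())]


def _nominal_score_cutoff(cfg: SimulationConfig, damaging_weight: float) -> float:
    """Percentile of the nominal benign/damaging score mixture (one channel)."""
    lo = min(cfg.benign_score_loc, cfg.damaging_score_loc) - 6 * cfg.score_sd
    hi = max(cfg.benign_score_loc, cfg.damaging_score_loc) + 6 * cfg.score_sd
    grid = np.linspace(lo, hi, 4001)
    cdf = ((1 - damaging_weight) * norm.cdf(grid, cfg.benign_score_loc, cfg.score_sd)
           + damaging_weight * norm.cdf(grid, cfg.damaging_score_loc, cfg.score_sd))
    return float(np.interp(cfg.impact_percentile, cdf, grid))


def _expected_f(cfg: SimulationConfig, t: TranscriptModel, omega: float,
                retention: float, cutoff: float) -> float:
    """Analytic approximation of the expected high-impact fraction for one gene."""
    sc = count_sites(t)
    L3 = 3.0 * t.n_codons
    m_frac = 3.0 * sc.missense_sites / L3
    s_frac = 3.0 * sc.s_sites / L3
    non_frac = max(0.0, 1.0 - m_frac - s_frac)
    p_cls = cfg.p_insertion + cfg.p_deletion + cfg.p_splice
    a_hi = min(1.0, omega * retention)
    a_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    a_non = min(1.0, omega)
    d = cfg.p_damaging_missense
    exc_d = 1.0 - norm.cdf(cutoff, cfg.damaging_score_loc, cfg.score_sd) ** 2
    exc_b = 1.0 - norm.cdf(cutoff, cfg.benign_score_loc, cfg.score_sd) ** 2
    w_cls = p_cls * a_hi
    w_mis_d = (1 - p_cls) * m_frac * d * a_non * retention
    w_mis_b = (1 - p_cls) * m_frac * (1 - d) * a_non
    w_syn = (1 - p_cls) * s_frac * a_syn
    w_non = (1 - p_cls) * non_frac * a_hi
    total = w_cls + w_mis_d + w_mis_b + w_syn + w_non
    high = w_cls + w_non + w_mis_d * exc_d + w_mis_b * exc_b
    return high / total if total else float("nan")


@dataclass
class SyntheticStudy:
    """A full simulated study: all pipeline inputs plus the ground-truth sidecar."""

    config: SimulationConfig
    transcripts: dict[str, TranscriptModel]
    gene_classes: dict[str, str]
    somatic: CohortTable
    germline: CohortTable
    scores: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: list
    edges: list
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit all inputs in the pipeline's on-disk formats (plus truth TSV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fname for name, fname in [
            ("cds", "cds.fasta"), ("somatic", "somatic.maf"),
            ("germline", "germline.vcf"), ("scores", "impact_scores.tsv"),
            ("expression", "expression.tsv"), ("gene_sets", "gene_sets.gmt"),
            ("edges", "interactions.tsv"), ("truth", "ground_truth.tsv"),
            ("config", "sim_config.json"),
        ]}
        write_fasta(self.transcripts, paths["cds"])
        write_maf(self.somatic, paths["somatic"])
        write_vcf(self.germline, self.transcripts, paths["germline"])
        self.scores.to_csv(paths["scores"], sep="\t", index=False,
                           float_format="%.6f")
        self.expression.to_csv(paths["expression"], sep="\t", float_format="%.6f")
        write_gmt(self.gene_sets, paths["gene_sets"])
        from .network import write_edge_list

        with open(paths["edges"], "w") as fh:
            fh.write("protein_a\tprotein_b\tcombined_score\n")
            for e in self.edges:
                fh.write(f"{e.protein_a}\t{e.protein_b}\t{int(round(e.combined_score * 1000))}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
        cfg = asdict(self.config)
        cfg["cds_length_range"] = list(self.config.cds_length_range)
        cfg["gene_set_size"] = list(self.config.gene_set_size)
        with open(paths["config"], "w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def simulate_study(cfg: SimulationConfig | None = None,
                   seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study (deterministic under fixed seed)."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.random_seed if seed is None else seed)
    transcripts = simulate_cds(cfg, rng)
    genes = list(transcripts)
    n_essential = int(round(cfg.essential_fraction * cfg.n_genes))
    essential_idx = set(map(int, rng.choice(cfg.n_genes, n_essential, replace=False)))
    gene_classes = {g: (ESSENTIAL if i in essential_idx else BACKGROUND)
                    for i, g in enumerate(genes)}
    site_cache = _SiteCache(cfg.p_damaging_missense, cfg.benign_score_loc,
                            cfg.damaging_score_loc, cfg.score_sd, rng)
    somatic = simulate_cohort(transcripts, gene_classes, cfg, Cohort.somatic,
                              rng, site_cache)
    germline = simulate_cohort(transcripts, gene_classes, cfg, Cohort.germline,
                               rng, site_cache)
    expression, expressed = simulate_expression(cfg, gene_classes, rng)
    gene_sets = simulate_gene_sets(cfg, gene_classes, rng)
    edges = simulate_edges(cfg, gene_classes, rng)
    cutoff = _nominal_score_cutoff(cfg, cfg.p_damaging_missense)
    rows = []
    for g in genes:
        is_ess = gene_classes[g] == ESSENTIAL
        omega_som = cfg.omega_essential if is_ess else cfg.omega_background
        retention = cfg.somatic_impact_retention if is_ess else 1.0
        rows.append({
            "gene_id": g,
            "planted_class": gene_classes[g],
            "true_omega_somatic": omega_som,
            "true_omega_germline": 1.0,
            "expected_f_somatic": _expected_f(cfg, transcripts[g], omega_som,
                                              retention, cutoff),
            "expected_f_germline": _expected_f(cfg, transcripts[g], 1.0, 1.0, cutoff),
            "expressed": expressed[g],
        })
    truth = pd.DataFrame(rows)
    return SyntheticStudy(cfg, transcripts, gene_classes, somatic, germline,
                          site_cache.score_frame(), expression, gene_sets,
                          edges, truth)


# ---------------------------------------------------------------------------
# writers for the pipeline's input formats

def write_fasta(transcripts: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, t in transcripts.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(t.cds_sequence), 60):
                fh.write(t.cds_sequence[i:i + 60] + "\n")


_MAF_CLASS_OUT = {VariantClass.snv: "SNP", VariantClass.insertion: "INS",
                  VariantClass.deletion: "DEL"}

_MAF_CONSEQUENCE_OUT = {
    Consequence.synonymous: "Silent",
    Consequence.missense: "Missense_Mutation",
    Consequence.stop_gain: "Nonsense_Mutation",
    Consequence.stop_loss: "Nonstop_Mutation",
    Consequence.start_loss: "Translation_Start_Site",
    Consequence.splice_site: "Splice_Site",
}


def write_maf(table: CohortTable, path: str | Path) -> None:
    """MAF-dialect TSV with TCGA default column names, CDS-relative positions."""
    with open(path, "w") as fh:
        fh.write("Hugo_Symbol\tVariant_Classification\tVariant_Type\t"
                 "Reference_Allele\tTumor_Seq_Allele2\tStart_Position\n")
        for v in sorted(table.variants(), key=Variant.sort_key):
            if v.variant_class is not VariantClass.snv:
                suffix = "Ins" if v.variant_class is VariantClass.insertion else "Del"
                inframe = (v.consequence is Consequence.inframe_indel
                           or (v.consequence is None
                               and abs(len(v.ref) - len(v.alt)) % 3 == 0))
                cons = f"{'In_Frame' if inframe else 'Frame_Shift'}_{suffix}"
            else:
                cons = _MAF_CONSEQUENCE_OUT.get(v.consequence, "")
            fh.write(f"{v.gene_id}\t{cons}\t{_MAF_CLASS_OUT[v.variant_class]}\t"
                     f"{v.ref}\t{v.alt}\t{v.cds_pos}\n")


def write_vcf(table: CohortTable, transcripts: Mapping[str, TranscriptModel],
              path: str | Path) -> None:
    """Plain VCF 4.2: one contig per gene, POS = CDS coordinate, GENE/CDSPOS INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=CDSPOS,Number=1,Type=Integer,Description="1-based CDS position">\n')
        fh.write('##INFO=<ID=CONS,Number=1,Type=String,Description="Pre-annotated consequence">\n')
        for gene, t in transcripts.items():
            fh.write(f"##contig=<ID={gene},length={len(t.cds_sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(table.variants(), key=Variant.sort_key):
            info = f"GENE={v.gene_id};CDSPOS={v.cds_pos}"
            if v.consequence is Consequence.splice_site:
                info += ";CONS=splice_site"
            fh.write(f"{v.gene_id}\t{v.cds_pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def write_gmt(gene_sets: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            genes = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description or gs.category}\t{genes}\n")
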