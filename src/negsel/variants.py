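"""Reading and normalizing somatic (MAF-dialect TSV) and germline (VCF) variants.

Both cohorts are reduced to a single :class:`Variant` record keyed by gene and
1-based CDS position, with optional pre-annotated consequence and ensemble
functional-impact scores (MetaSVM/MetaLR-style ``score_a``/``score_b``).
Indel left-alignment is NOT performed; variants are taken as keyed by the
producer.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import Consequence, TranscriptModel, classify_snv

log = logging.getLogger(__name__)


class Cohort(str, Enum):
    somatic = "somatic"
    germline = "germline"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class VariantClass(str, Enum):
    snv = "snv"
    insertion = "insertion"
    deletion = "deletion"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class Variant:
    """One normalized variant observation (one record = one occurrence)."""

    cohort: Cohort
    gene_id: str
    ref: str
    alt: str
    variant_class: VariantClass
    cds_pos: int | None = None
    consequence: Consequence | None = None
    score_a: float | None = None
    score_b: float | None = None

    def __post_init__(self) -> None:
        self.cohort = Cohort(self.cohort)
        self.variant_class = VariantClass(self.variant_class)
        if self.consequence is not None:
            self.consequence = Consequence(self.consequence)
        if self.variant_class is VariantClass.snv:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError(f"SNV alleles must be single bases: {self.ref}>{self.alt}")
        elif _allele_len(self.ref) == _allele_len(self.alt):
            raise ValueError(
                f"{self.variant_class.value} requires differing allele lengths: "
                f"{self.ref}>{self.alt}"
            )

    def sort_key(self) -> tuple:
        return (self.gene_id, self.cds_pos or 0, self.ref, self.alt, self.variant_class.value)


def _allele_len(allele: str) -> int:
    return 0 if allele in ("-", "", ".") else len(allele)


def infer_variant_class(ref: str, alt: str) -> VariantClass:
    lr, la = _allele_len(ref), _allele_len(alt)
    if lr == la == 1:
        return VariantClass.snv
    if la > lr:
        return VariantClass.insertion
    if la < lr:
        return VariantClass.deletion
    raise ValueError(f"cannot classify alleles {ref!r}>{alt!r} (equal multi-base lengths)")


class CohortTable:
    """Variants of one cohort grouped by gene, with provenance bookkeeping."""

    def __init__(self, cohort: Cohort, variants: Iterable[Variant] = (),
                 provenance: dict | None = None):
        self.cohort = Cohort(cohort)
        self.by_gene: dict[str, list[Variant]] = {}
        self.provenance: dict = provenance or {}
        for v in variants:
            self.add(v)

    def add(self, v: Variant) -> None:
        if v.cohort is not self.cohort:
            raise ValueError(f"variant cohort {v.cohort} does not match table {self.cohort}")
        self.by_gene.setdefault(v.gene_id, []).append(v)

    def genes(self) -> list[str]:
        return sorted(self.by_gene)

    @property
    def n_variants(self) -> int:
        return sum(len(vs) for vs in self.by_gene.values())

    def variants(self) -> Iterable[Variant]:
        for g in self.genes():
            yield from self.by_gene[g]

    def gene_count(self, gene_id: str) -> int:
        return len(self.by_gene.get(gene_id, ()))

    # -- canonical TSV round-trip ------------------------------------------
    _COLUMNS = ["cohort", "gene_id", "cds_pos", "ref", "alt", "variant_class",
                "consequence", "score_a", "score_b"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in sorted(self.variants(), key=Variant.sort_key):
            rows.append({
                "cohort": v.cohort.value, "gene_id": v.gene_id, "cds_pos": v.cds_pos,
                "ref": v.ref, "alt": v.alt, "variant_class": v.variant_class.value,
                "consequence": v.consequence.value if v.consequence else None,
                "score_a": v.score_a, "score_b": v.score_b,
            })
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValueError(f"empty cohort table {path}")
        table = cls(Cohort(df["cohort"].iloc[0]), provenance={"source": str(path)})
        for row in df.itertuples(index=False):
            table.add(Variant(
                cohort=Cohort(row.cohort), gene_id=row.gene_id,
                cds_pos=None if pd.isna(row.cds_pos) else int(row.cds_pos),
                ref=str(row.ref), alt=str(row.alt),
                variant_class=VariantClass(row.variant_class),
                consequence=None if pd.isna(row.consequence) else Consequence(row.consequence),
                score_a=None if pd.isna(row.score_a) else float(row.score_a),
                score_b=None if pd.isna(row.score_b) else float(row.score_b),
            ))
        return table


#: default MAF-dialect column roles (TCGA naming)
DEFAULT_MAF_COLUMNS: Mapping[str, str] = {
    "gene": "Hugo_Symbol",
    "variant_class": "Variant_Type",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "pos": "Start_Position",
    "consequence": "Variant_Classification",
}

_MAF_CLASS = {"SNP": VariantClass.snv, "SNV": VariantClass.snv,
              "INS": VariantClass.insertion, "DEL": VariantClass.deletion}

_MAF_CONSEQUENCE = {
    "Silent": Consequence.synonymous,
    "Missense_Mutation": Consequence.missense,
    "Nonsense_Mutation": Consequence.stop_gain,
    "Nonstop_Mutation": Consequence.stop_loss,
    "Translation_Start_Site": Consequence.start_loss,
    "Splice_Site": Consequence.splice_site,
    "Frame_Shift_Ins": Consequence.frameshift_indel,
    "Frame_Shift_Del": Consequence.frameshift_indel,
    "In_Frame_Ins": Consequence.inframe_indel,
    "In_Frame_Del": Consequence.inframe_indel,
}


def read_maf(path: str | Path, column_map: Mapping[str, str] | None = None,
             one_based: bool = True) -> CohortTable:
    """Read a MAF-dialect tab-delimited somatic mutation table.

    ``column_map`` maps roles (gene, variant_class, ref, alt, pos, consequence)
    to column names; positions are CDS-relative, 1-based unless ``one_based``
    is False.  Unparseable rows are counted and logged, not fatal.
    """
    cols = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"empty MAF table {path}")
    for role in ("gene", "ref", "alt", "pos"):
        if cols[role] not in df.columns:
            raise ValueError(f"MAF {path} is missing the {role!r} column ({cols[role]!r})")
    table = CohortTable(Cohort.somatic)
    n_bad = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        try:
            gene = d[cols["gene"]]
            ref, alt = d[cols["ref"]], d[cols["alt"]]
            pos_raw = d[cols["pos"]]
            pos = int(pos_raw) + (0 if one_based else 1)
            raw_class = d.get(cols.get("variant_class", ""), None)
            if raw_class and str(raw_class) in _MAF_CLASS:
                vclass = _MAF_CLASS[str(raw_class)]
            else:
                vclass = infer_variant_class(ref, alt)
            raw_cons = d.get(cols.get("consequence", ""), None)
            cons = _MAF_CONSEQUENCE.get(str(raw_cons)) if raw_cons else None
            table.add(Variant(Cohort.somatic, str(gene), ref=str(ref), alt=str(alt),
                              variant_class=vclass, cds_pos=pos, consequence=cons))
        except (ValueError, KeyError, TypeError) as exc:
            n_bad += 1
            log.debug("skipping MAF row: %s", exc)
    if n_bad:
        log.warning("read_maf(%s): skipped %d unparseable rows", path, n_bad)
    table.provenance = {"source": Path(path).name, "kept": table.n_variants, "dropped": n_bad}
    return table


class CdsLocator:
    """Map genomic (chrom, pos) to (gene, 1-based CDS position) via exon layouts.

    ``layout`` maps gene_id to an ordered list of exons ``(chrom, start, end,
    strand)`` in transcription order with 1-based inclusive genomic
    coordinates.  Minus-strand exons run 3'→5' in genome space.
    """

    def __init__(self, layout: Mapping[str, Sequence[tuple[str, int, int, str]]]):
        self._by_chrom: dict[str, list[tuple[int, int, str, int, str]]] = {}
        for gene, exons in layout.items():
            cds_offset = 0
            for chrom, start, end, strand in exons:
                if end < start:
                    raise ValueError(f"{gene}: exon end < start ({start}, {end})")
                self._by_chrom.setdefault(chrom, []).append(
                    (start, end, gene, cds_offset, strand))
                cds_offset += end - start + 1
        for ivs in self._by_chrom.values():
            ivs.sort()

    def locate(self, chrom: str, pos: int) -> tuple[str, int] | None:
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return None
        idx = bisect.bisect_right([iv[0] for iv in ivs], pos) - 1
        for i in range(max(0, idx - 1), min(len(ivs), idx + 2)):
            start, end, gene, offset, strand = ivs[i]
            if start <= pos <= end:
                if strand == "+":
                    return gene, offset + (pos - start) + 1
                return gene, offset + (end - pos) + 1
        return None


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def read_vcf(path: str | Path, transcripts: Mapping[str, TranscriptModel],
             locator: CdsLocator | None = None,
             gene_tag: str = "GENE", cds_pos_tag: str = "CDSPOS",
             consequence_tag: str = "CONS",
             cohort: Cohort = Cohort.germline) -> CohortTable:
    """Read germline variants from VCF 4.x, assigning records to CDS positions.

    Gene assignment tries, in order: ``gene_tag``/``cds_pos_tag`` INFO fields,
    the genomic ``locator``, and finally CHROM-as-gene with POS as the CDS
    coordinate (the layout the synthetic generator emits).  Multi-allelic
    records yield one variant per alt; records outside any CDS are dropped and
    counted.
    """
    from cyvcf2 import VCF

    table = CohortTable(cohort)
    n_dropped = n_total = 0
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            n_total += 1
            gene = rec.INFO.get(gene_tag)
            cds_pos = rec.INFO.get(cds_pos_tag)
            strand = "+"
            if gene is None and locator is not None:
                hit = locator.locate(rec.CHROM, rec.POS)
                if hit:
                    gene, cds_pos = hit
            if gene is None and rec.CHROM in transcripts:
                gene, cds_pos = rec.CHROM, rec.POS
            t = transcripts.get(gene) if gene else None
            if t is None or cds_pos is None:
                n_dropped += 1
                continue
            cds_pos = int(cds_pos)
            ref = rec.REF
            if not 1 <= cds_pos <= len(t.cds_sequence):
                n_dropped += 1
                continue
            cons_raw = rec.INFO.get(consequence_tag)
            try:
                cons = Consequence(cons_raw) if cons_raw else None
                vclass = infer_variant_class(ref, alt)
                table.add(Variant(cohort, gene, ref=ref, alt=alt,
                                  variant_class=vclass, cds_pos=cds_pos,
                                  consequence=cons))
            except ValueError:
                n_dropped += 1
    if n_total == 0:
        log.warning("read_vcf(%s): no records", path)
    if table.n_variants == 0 and n_total > 0:
        log.warning("read_vcf(%s): zero records overlapped a CDS", path)
    table.provenance = {"source": Path(path).name, "kept": table.n_variants,
                        "dropped": n_dropped}
    return table


SCORE_KEY = ["gene_id", "cds_pos", "ref", "alt"]


def attach_scores(table: CohortTable, score_table: str | Path | pd.DataFrame,
                  strict: bool = False) -> CohortTable:
    """Attach ensemble impact scores to matching variants (in place).

    The score table is keyed by (gene_id, cds_pos, ref, alt) with ``score_a``
    and ``score_b`` columns.  Unmatched non-synonymous SNVs are counted as
    unscored (they will never be called high-impact).
    """
    if isinstance(score_table, pd.DataFrame):
        df = score_table
    else:
        df = pd.read_csv(score_table, sep="\t")
    missing = [c for c in SCORE_KEY + ["score_a", "score_b"] if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns {missing}")
    scores: dict[tuple, tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.gene_id), int(row.cds_pos), str(row.ref), str(row.alt))
        val = (float(row.score_a), float(row.score_b))
        if key in scores and scores[key] != val:
            if strict:
                raise ValueError(f"conflicting scores for {key}: {scores[key]} vs {val}")
            log.warning("conflicting scores for %s: keeping first", key)
            continue
        scores[key] = val
    n_unscored_nonsyn = 0
    for v in table.variants():
        if v.cds_pos is None:
            continue
        hit = scores.get((v.gene_id, v.cds_pos, v.ref, v.alt))
        if hit:
            v.score_a, v.score_b = hit
        elif (v.variant_class is VariantClass.snv
              and v.consequence not in (None, Consequence.synonymous)):
            n_unscored_nonsyn += 1
    table.provenance["unscored_nonsyn"] = n_unscored_nonsyn
    return table


def resolve_consequences(table: CohortTable, transcripts: Mapping[str, TranscriptModel],
                         overwrite: bool = False) -> CohortTable:
    """Fill in consequences for SNVs via :func:`classify_snv` (in place).

    Pre-annotated consequences are kept unless ``overwrite``.  Indels with no
    annotation are labelled frameshift/in-frame by allele-length arithmetic.
    """
    n_bad = 0
    for v in table.variants():
        if v.consequence is not None and not overwrite:
            continue
        if v.variant_class is VariantClass.snv:
            t = transcripts.get(v.gene_id)
            if t is None or v.cds_pos is None:
                continue
            try:
                v.consequence = classify_snv(t, v.cds_pos, v.ref, v.alt)
            except ValueError as exc:
                n_bad += 1
                log.debug("cannot classify %s:%s: %s", v.gene_id, v.cds_pos, exc)
        else:
            delta = abs(_allele_len(v.alt) - _allele_len(v.ref))
            v.consequence = (Consequence.inframe_indel if delta % 3 == 0
                             else Consequence.frameshift_indel)
    if n_bad:
        log.warning("resolve_consequences: %d SNVs could not be classified", n_bad)
    return table


def min_variant_filter(somatic: CohortTable, germline: CohortTable,
                       min_n: int = 11) -> set[str]:
    """Genes with at least ``min_n`` variants in BOTH cohorts.

    The count includes all variant classes (SNVs and indels), matching the
    all-mutations denominator of the impact fraction f.
    """
    return {g for g in set(somatic.by_gene) & set(germline.by_gene)
            if somatic.gene_count(g) >= min_n and germline.gene_count(g) >= min_n}
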