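"""Coding-sequence model, NG86 site counting and SNV consequence classification.

The dN/dS machinery in this package follows the Nei–Gojobori (1986) counting
scheme: every codon position contributes fractional "synonymous sites" equal to
the fraction of its three possible single-nucleotide changes that preserve the
encoded amino acid, and the remainder as "non-synonymous sites".  Changes that
create or destroy a stop codon, and changes that destroy the initiator ATG, are
non-synonymous in the NG86 sense but are tracked separately (they have no
synonymous counterpart and are excluded from the missense exposure used by the
dN/dS estimator; see :mod:`negsel.dnds`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: half-width (nt) of the splice window around a declared exon boundary
SPLICE_WINDOW = 2


class Consequence(str, Enum):
    """Codon-level consequence of a single variant."""

    synonymous = "synonymous"
    missense = "missense"
    stop_gain = "stop_gain"
    stop_loss = "stop_loss"
    start_loss = "start_loss"
    splice_site = "splice_site"
    inframe_indel = "inframe_indel"
    frameshift_indel = "frameshift_indel"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: consequences entering the dN/dS counts (everything else lacks a synonymous
#: counterpart or is an indel)
DNDS_CLASSES = frozenset({Consequence.synonymous, Consequence.missense})


@lru_cache(maxsize=8)
def codon_to_aa(table_id: int = 1) -> Mapping[str, str]:
    """Codon → amino-acid map for an NCBI translation table, stops as ``*``."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


class CdsValidationError(ValueError):
    """Raised when a coding sequence violates the transcript invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's coding sequence on the coding strand.

    ``exon_boundaries`` are CDS coordinates (1-based) at which an intron
    interrupts the CDS: positions within ``SPLICE_WINDOW`` nt of a boundary are
    treated as splice-site territory by :func:`classify_snv`.
    """

    gene_id: str
    cds_sequence: str
    exon_boundaries: tuple[int, ...] | None = None
    codon_table_id: int = 1

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        n = len(seq)
        if n == 0 or n % 3 != 0:
            raise CdsValidationError(
                f"{self.gene_id}: CDS length {n} is not a positive multiple of 3"
            )
        bad = set(seq) - VALID_BASES
        if bad:
            raise CdsValidationError(
                f"{self.gene_id}: invalid bases {sorted(bad)} in CDS"
            )
        aa = codon_to_aa(self.codon_table_id)
        for i in range(0, n - 3, 3):
            if aa[seq[i : i + 3]] == "*":
                raise CdsValidationError(
                    f"{self.gene_id}: internal stop codon at CDS position {i + 1}"
                )
        if self.exon_boundaries is not None:
            bounds = tuple(int(b) for b in self.exon_boundaries)
            if list(bounds) != sorted(set(bounds)):
                raise CdsValidationError(
                    f"{self.gene_id}: exon boundaries must be strictly increasing"
                )
            if bounds and (bounds[0] < 1 or bounds[-1] > n):
                raise CdsValidationError(
                    f"{self.gene_id}: exon boundary outside [1, {n}]"
                )
            object.__setattr__(self, "exon_boundaries", bounds)

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    def codon_at(self, cds_pos: int) -> tuple[str, int]:
        """Return (codon, 0-based offset within codon) for a 1-based CDS position."""
        i = cds_pos - 1
        start = (i // 3) * 3
        return self.cds_sequence[start : start + 3], i - start

    def in_splice_window(self, cds_pos: int) -> bool:
        if not self.exon_boundaries:
            return False
        return any(abs(cds_pos - b) <= SPLICE_WINDOW for b in self.exon_boundaries)


@dataclass(frozen=True)
class SiteCounts:
    """Expected NG86 site counts for one transcript.

    ``n_sites`` (non-synonymous) and ``s_sites`` (synonymous) partition the
    sequence exactly: ``n_sites + s_sites == 3 * n_codons``.  ``missense_sites``
    is the part of ``n_sites`` whose changes are plain amino-acid replacements
    (excludes nonsense, start-loss and splice-window positions); it is the
    exposure matched to a missense-only dN numerator.
    """

    gene_id: str
    n_sites: float
    s_sites: float
    missense_sites: float


@lru_cache(maxsize=None)
def _change_categories_cached(codon: str, offset: int, table_id: int) -> tuple[int, int, int]:
    return _change_categories(codon, offset, codon_to_aa(table_id))


def _change_categories(codon: str, offset: int, aa: Mapping[str, str]) -> tuple[int, int, int]:
    """(synonymous, missense, nonsense) counts over the 3 changes at one position."""
    syn = mis = non = 0
    ref_aa = aa[codon]
    for b in "ACGT":
        if b == codon[offset]:
            continue
        alt_aa = aa[codon[:offset] + b + codon[offset + 1 :]]
        if alt_aa == ref_aa:
            syn += 1
        elif alt_aa == "*" or ref_aa == "*":
            non += 1
        else:
            mis += 1
    return syn, mis, non


def count_sites(t: TranscriptModel) -> SiteCounts:
    """NG86 expected synonymous/non-synonymous site counts for one CDS.

    Each CDS position contributes 1 site, split 3-ways across its possible
    substitutions; the terminal stop codon is included (stop→stop changes are
    synonymous, stop→sense are nonsense).
    """
    seq = t.cds_sequence
    starts_with_atg = seq[:3] == "ATG"
    # accumulate integer change counts; divide by 3 once so that
    # n_sites + s_sites == 3 * codons holds exactly in floating point
    syn_changes = missense_changes = 0
    for pos in range(1, len(seq) + 1):
        codon, offset = t.codon_at(pos)
        syn, mis, non = _change_categories_cached(codon, offset, t.codon_table_id)
        syn_changes += syn
        first_codon_start = pos <= 3 and starts_with_atg
        if not first_codon_start and not t.in_splice_window(pos):
            missense_changes += mis
    s_sites = syn_changes / 3.0
    n_sites = 3.0 * t.n_codons - s_sites
    return SiteCounts(t.gene_id, n_sites, s_sites, missense_changes / 3.0)


def classify_snv(t: TranscriptModel, cds_pos: int, ref: str, alt: str) -> Consequence:
    """Consequence of a single-nucleotide change at a 1-based CDS position.

    The declared ``ref`` must match the transcript (a mismatch signals a
    coordinate or strand error upstream).  Positions inside the splice window
    of a declared exon boundary return ``splice_site`` regardless of the codon
    effect.
    """
    if not 1 <= cds_pos <= len(t.cds_sequence):
        raise ValueError(f"{t.gene_id}: CDS position {cds_pos} outside [1, {len(t.cds_sequence)}]")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"{t.gene_id}:{cds_pos}: ref and alt are both {ref!r}")
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"{t.gene_id}:{cds_pos}: non-ACGT allele {ref!r}>{alt!r}")
    actual = t.cds_sequence[cds_pos - 1]
    if actual != ref:
        raise ValueError(
            f"{t.gene_id}:{cds_pos}: declared ref {ref!r} does not match CDS base {actual!r}"
        )
    if t.in_splice_window(cds_pos):
        return Consequence.splice_site
    codon, offset = t.codon_at(cds_pos)
    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
    aa = codon_to_aa(t.codon_table_id)
    ref_aa, alt_aa = aa[codon], aa[alt_codon]
    if ref_aa == alt_aa:
        return Consequence.synonymous
    if cds_pos <= 3 and t.cds_sequence[:3] == "ATG":
        return Consequence.start_loss
    if alt_aa == "*":
        return Consequence.stop_gain
    if ref_aa == "*":
        return Consequence.stop_loss
    return Consequence.missense


def load_cds(fasta_path: str | Path, strict: bool = False) -> dict[str, TranscriptModel]:
    """Load one CDS per gene from FASTA (header token = gene id).

    Invalid records (length not a multiple of 3, non-ACGT bases, internal
    stops) are skipped with a warning, or raise in strict mode.  Duplicate ids
    keep the first record (error in strict mode).
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    transcripts: dict[str, TranscriptModel] = {}
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in transcripts:
            if strict:
                raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
            log.warning("duplicate gene_id %r: keeping first record", gene_id)
            n_skipped += 1
            continue
        try:
            transcripts[gene_id] = TranscriptModel(gene_id, str(rec.seq))
        except CdsValidationError as exc:
            if strict:
                raise
            log.warning("skipping %s: %s", gene_id, exc)
            n_skipped += 1
    if not transcripts and n_skipped == 0:
        raise ValueError(f"no FASTA records in {path}")
    if n_skipped:
        log.info("loaded %d transcripts, skipped %d invalid/duplicate", len(transcripts), n_skipped)
    return transcripts


def write_site_counts(counts: Iterable[SiteCounts], out_path: str | Path) -> None:
    """Export site counts as TSV (gene_id, n_sites, s_sites, missense_sites)."""
    with open(out_path, "w") as fh:
        fh.write("gene_id\tn_sites\ts_sites\tmissense_sites\n")
        for c in counts:
            fh.write(f"{c.gene_id}\t{c.n_sites:.6f}\t{c.s_sites:.6f}\t{c.missense_sites:.6f}\n")
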