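"""Genome and transcript-annotation handling.

Coordinate conventions
----------------------
Everything in this module is 1-based, fully closed (GTF convention).
bedGraph input/output elsewhere in the package is 0-based half-open;
every conversion between the two goes through :func:`one_based_to_bed`
or :func:`bed_to_one_based` so the off-by-one lives in exactly two
places.

A 3' splice site (acceptor) is the intron-terminal AG dinucleotide in
transcription order.  The methylatable adenosine is the A of that AG:
on the '+' strand it sits at ``intron_end - 1``, on the '-' strand at
``intron_start + 1``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_NT = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(ValueError):
    """Malformed FASTA/GTF input."""


class InvalidSiteError(ValueError):
    """A SpliceSite violates its own invariants."""


class GenomeBoundsError(ValueError):
    """A requested window falls outside its contig."""


def one_based_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GTF) interval -> 0-based half-open (BED)."""
    return start - 1, end


def bed_to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open (BED) interval -> 1-based inclusive (GTF)."""
    return start + 1, end


@dataclass(frozen=True)
class GenomeSequence:
    """A genome as a mapping of contig name -> uppercase DNA string."""

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID_NT
            if bad:
                raise AnnotationError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the '+'-strand sequence of [start, end], 1-based inclusive."""
        if contig not in self.contigs:
            raise GenomeBoundsError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise GenomeBoundsError(
                f"window {contig}:{start}-{end} outside contig bounds 1-{len(seq)}"
            )
        return seq[start - 1 : end]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sorted, non-overlapping exons plus an optional CDS span."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if end < start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon ({start},{end}) inverted"
                )
            if start <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.cds is not None:
            cs, ce = self.cds
            if not any(s <= cs and ce <= e for s, e in ((self.exons[0][0], self.exons[-1][1]),)):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS {self.cds} outside exon span"
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Introns between consecutive exons, 1-based inclusive."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class SpliceSite:
    """One 3' splice site (acceptor).

    ``acceptor_ag`` holds the genomic coordinates of the intron-terminal
    A and G in transcription order; ``target_a`` is the methylatable
    acceptor adenosine.  ``canonical`` is None until the genome sequence
    has been consulted (see :func:`classify_acceptor`).
    """

    contig: str
    strand: str
    intron_start: int
    intron_end: int
    acceptor_ag: tuple[int, int]
    target_a: int
    gene_id: str = ""
    transcript_id: str = ""
    canonical: bool | None = None

    def __post_init__(self) -> None:
        if self.intron_end - self.intron_start + 1 < 4:
            raise InvalidSiteError(
                f"intron {self.contig}:{self.intron_start}-{self.intron_end} "
                "shorter than 4 nt"
            )
        expected = (
            self.intron_end - 1 if self.strand == "+" else self.intron_start + 1
        )
        if self.target_a != expected:
            raise InvalidSiteError(
                f"target_a {self.target_a} inconsistent with {self.strand!r} strand "
                f"intron {self.intron_start}-{self.intron_end}"
            )


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA file, upper-casing sequences.

    Raises :class:`AnnotationError` on duplicate headers or an empty file.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise AnnotationError(f"duplicate FASTA header {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise AnnotationError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon and CDS features from a GTF file into transcript models.

    Exons are grouped per transcript and sorted by start; the CDS span is
    the min/max over that transcript's CDS features.  An exon line
    without ``transcript_id`` or overlapping exons within one transcript
    raise :class:`AnnotationError`.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: fewer than 9 GTF columns")
            contig, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in {"exon", "CDS"}:
                continue
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise AnnotationError(
                    f"{path}:{lineno}: {feature} feature without transcript_id"
                )
            gene = attributes.get("gene_id", tid)
            interval = (int(start), int(end))
            known = meta.setdefault(tid, (gene, contig, strand))
            if known != (gene, contig, strand):
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tid} changes gene/contig/strand"
                )
            (exons if feature == "exon" else cds).setdefault(tid, []).append(interval)

    transcripts = []
    for tid, intervals in exons.items():
        gene, contig, strand = meta[tid]
        intervals = sorted(intervals)
        for (s1, e1), (s2, _e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"transcript {tid}: overlapping exons ({s1},{e1}) and starting {s2}"
                )
        cds_span = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                contig=contig,
                strand=strand,
                exons=tuple(intervals),
                cds=cds_span,
            )
        )
    return transcripts


def enumerate_3ss(
    transcripts: Iterable[TranscriptModel],
    *,
    deduplicate: bool = True,
) -> list[SpliceSite]:
    """Enumerate 3' splice sites (one per intron per transcript).

    Sites are de-duplicated on (contig, strand, acceptor position) by
    default, keeping the first gene/transcript label encountered in
    coordinate order, and returned sorted by (contig, coordinate,
    strand).  Single-exon transcripts contribute nothing; introns
    shorter than 4 nt are skipped with a logged warning.
    """
    sites: list[SpliceSite] = []
    for tx in transcripts:
        for intron_start, intron_end in tx.introns:
            if intron_end - intron_start + 1 < 4:
                logger.warning(
                    "skipping <4 nt intron %s:%d-%d in %s",
                    tx.contig, intron_start, intron_end, tx.transcript_id,
                )
                continue
            if tx.strand == "+":
                target_a = intron_end - 1
                acceptor_ag = (intron_end - 1, intron_end)
            else:
                target_a = intron_start + 1
                acceptor_ag = (intron_start + 1, intron_start)
            sites.append(
                SpliceSite(
                    contig=tx.contig,
                    strand=tx.strand,
                    intron_start=intron_start,
                    intron_end=intron_end,
                    acceptor_ag=acceptor_ag,
                    target_a=target_a,
                    gene_id=tx.gene_id,
                    transcript_id=tx.transcript_id,
                )
            )
    sites.sort(key=lambda s: (s.contig, s.target_a, s.strand))
    if not deduplicate:
        return sites
    seen: set[tuple[str, str, int]] = set()
    unique = []
    for site in sites:
        key = (site.contig, site.strand, site.target_a)
        if key in seen:
            continue
        seen.add(key)
        unique.append(site)
    return unique


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def classify_acceptor(site: SpliceSite, genome: GenomeSequence) -> SpliceSite:
    """Return the site with ``canonical`` set: does its sense intron end in AG?"""
    a, g = site.acceptor_ag
    if site.strand == "+":
        dinuc = genome.fetch(site.contig, a, g)
    else:
        dinuc = reverse_complement(genome.fetch(site.contig, g, a))
    return replace(site, canonical=dinuc == "AG")


def fetch_window(genome: GenomeSequence, site: SpliceSite, flank: int) -> str:
    """Extract the sense-strand RNA window of length ``2*flank + 1``
    centered on the acceptor adenosine.

    Minus-strand sites are reverse-complemented so the returned string
    reads in transcription order; T is converted to U.  Raises
    :class:`GenomeBoundsError` if the window exceeds the contig.
    """
    lo, hi = site.target_a - flank, site.target_a + flank
    if site.contig not in genome.contigs:
        raise GenomeBoundsError(f"unknown contig {site.contig!r}")
    if lo < 1 or hi > len(genome.contigs[site.contig]):
        raise GenomeBoundsError(
            f"window {site.contig}:{lo}-{hi} around target A exceeds contig bounds"
        )
    raw = genome.fetch(site.contig, lo, hi)
    if site.strand == "-":
        raw = reverse_complement(raw)
    return dna_to_rna(raw)


def sites_to_bed(sites: Iterable[SpliceSite]) -> str:
    """Render splice sites as 6-column BED (0-based half-open, acceptor AG).

    name = gene:transcript-index, score = 0.
    """
    lines = []
    counter: dict[str, int] = {}
    for site in sites:
        lo = min(site.acceptor_ag)
        hi = max(site.acceptor_ag)
        bed_start, bed_end = one_based_to_bed(lo, hi)
        key = f"{site.gene_id}:{site.transcript_id}"
        counter[key] = counter.get(key, 0) + 1
        name = f"{key}-{counter[key]}"
        lines.append(
            f"{site.contig}\t{bed_start}\t{bed_end}\t{name}\t0\t{site.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
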