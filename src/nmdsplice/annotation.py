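"""Transcript annotation model: parsing, filtering and coordinate arithmetic.

The internal coordinate convention is 0-based half-open (``[start, end)``) on
the genomic forward strand.  GTF/GFF input and all exported tables use the
1-based inclusive convention; the conversion happens only at the I/O boundary.

Strandedness is never implemented by negating coordinates.  All 5'/3'
(upstream/downstream) comparisons go through :func:`stranded_key`, which maps a
genomic position to its transcript-oriented rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from gffutils.feature import feature_from_line

logger = logging.getLogger("nmdsplice")

#: Ensembl biotype used for annotated NMD targets.
NMD_BIOTYPE = "nonsense_mediated_decay"
CODING_BIOTYPE = "protein_coding"


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


def stranded_key(strand: str, pos: int) -> int:
    """Rank of a genomic position in transcript (5'→3') orientation."""
    if strand == "+":
        return pos
    if strand == "-":
        return -pos
    raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def from_gtf(cls, chrom: str, start1: int, end1: int, strand: str) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (exact, round-trips)."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_gtf(self) -> tuple[int, int]:
        """Export as 1-based inclusive (start, end)."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class Intron:
    """An intron keyed by (chrom, strand, donor, acceptor).

    The donor is the 5' splice site and the acceptor the 3' splice site in
    transcript orientation; both are boundary coordinates in the half-open
    system, so on the + strand ``donor == start`` and ``acceptor == end``,
    while on the − strand the roles are mirrored.
    """

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def overlaps_or_abuts(self, iv: GenomicInterval) -> bool:
        """True if the intron shares ≥1 bp with ``iv`` or a splice site of the
        intron coincides with an interval boundary."""
        if self.chrom != iv.chrom:
            return False
        return self.start <= iv.end and iv.start <= self.end


@dataclass
class Transcript:
    """A transcript: an ordered exon chain plus optional CDS anchors.

    ``exons`` are stored 5'→3' in transcript orientation.  ``start_codon`` and
    ``stop_codon`` are the genomic intervals of the annotated codons (Ensembl
    dialect: the stop codon lies outside the CDS; its own coordinates define
    the translation stop).  ``is_nmdt`` is None until annotated.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str = ""
    exons: list[GenomicInterval] = field(default_factory=list)
    start_codon: GenomicInterval | None = None
    stop_codon: GenomicInterval | None = None
    is_nmdt: bool | None = None
    tags: set[str] = field(default_factory=set)

    def finalize(self) -> None:
        """Sort exons 5'→3' and validate the chain."""
        self.exons.sort(key=lambda e: stranded_key(self.strand, e.start))
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            if lo.end > hi.start:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}: {a} / {b}"
                )

    # -- derived geometry ---------------------------------------------------

    @property
    def tx_start(self) -> int:
        """5' end of the transcript (genomic boundary coordinate)."""
        e = self.exons[0]
        return e.start if self.strand == "+" else e.end

    @property
    def tx_end(self) -> int:
        """3' end of the transcript (genomic boundary coordinate)."""
        e = self.exons[-1]
        return e.end if self.strand == "+" else e.start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[Intron]:
        """Gaps between consecutive exons, ordered 5'→3'."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            out.append(Intron(self.chrom, lo.end, hi.start, self.strand))
        return out

    def splice_sites(self) -> list[tuple[int, str]]:
        """Splice sites as (genomic boundary position, 'D'|'A'), 5'→3'.

        Each intron contributes its donor and acceptor; terminal exon ends are
        not splice sites.
        """
        sites: list[tuple[int, str]] = []
        for i in self.introns():
            sites.append((i.donor, "D"))
            sites.append((i.acceptor, "A"))
        return sites

    # -- coordinate arithmetic ---------------------------------------------

    def genomic_to_mrna(self, pos: int) -> int:
        """Map an exonic genomic position (0-based) to its mRNA offset.

        The first exonic base is offset 0; positions in introns raise.
        """
        offset = 0
        for e in self.exons:
            if e.start <= pos < e.end:
                if self.strand == "+":
                    return offset + (pos - e.start)
                return offset + (e.end - 1 - pos)
            offset += len(e)
        raise AnnotationError(
            f"position {pos} is not exonic in transcript {self.transcript_id}"
        )

    def mrna_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_mrna`."""
        if offset < 0:
            raise AnnotationError("negative mRNA offset")
        acc = 0
        for e in self.exons:
            if offset < acc + len(e):
                k = offset - acc
                return e.start + k if self.strand == "+" else e.end - 1 - k
            acc += len(e)
        raise AnnotationError(
            f"mRNA offset {offset} beyond transcript {self.transcript_id}"
        )

    def boundary_to_mrna(self, pos: int) -> int:
        """Map a genomic *boundary* coordinate (exon edge / splice site) to the
        number of exonic nucleotides 5' of it."""
        offset = 0
        for e in self.exons:
            lo5 = e.start if self.strand == "+" else e.end
            hi3 = e.end if self.strand == "+" else e.start
            if pos == lo5:
                return offset
            if pos == hi3:
                return offset + len(e)
            if e.start < pos < e.end:
                return offset + (
                    pos - e.start if self.strand == "+" else e.end - pos
                )
            offset += len(e)
        raise AnnotationError(
            f"boundary {pos} outside transcript {self.transcript_id}"
        )

    # -- CDS anchors ---------------------------------------------------------

    @property
    def cds_start_offset(self) -> int | None:
        """mRNA offset of the first base of the start codon."""
        if self.start_codon is None:
            return None
        first = (
            self.start_codon.start
            if self.strand == "+"
            else self.start_codon.end - 1
        )
        return self.genomic_to_mrna(first)

    @property
    def stop_end_offset(self) -> int | None:
        """mRNA offset of the last base of the stop codon."""
        if self.stop_codon is None:
            return None
        last = (
            self.stop_codon.end - 1 if self.strand == "+" else self.stop_codon.start
        )
        return self.genomic_to_mrna(last)

    @property
    def stop_start_offset(self) -> int | None:
        """mRNA offset of the first base of the stop codon."""
        if self.stop_codon is None:
            return None
        first = (
            self.stop_codon.start if self.strand == "+" else self.stop_codon.end - 1
        )
        return self.genomic_to_mrna(first)


@dataclass
class Gene:
    """A gene: a set of transcripts sharing a gene_id."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def nmdts(self) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.is_nmdt]

    @property
    def coding(self) -> list[Transcript]:
        return [
            t
            for t in self.transcripts.values()
            if t.is_nmdt is False and t.biotype == CODING_BIOTYPE
        ]

    @property
    def start_codons(self) -> set[GenomicInterval]:
        return {
            t.start_codon for t in self.transcripts.values() if t.start_codon
        }

    def exonic_span(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts.values() for e in t.exons]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_FEATURES = {"transcript", "exon", "start_codon", "stop_codon"}


def _records(path: str, dialect: str) -> Iterator[tuple[int, object]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, feature_from_line(line, strict=False)


def _attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    if not vals:
        return None
    return vals[0]


def parse_annotation(
    path: str,
    dialect: str = "gtf",
    require_biotype: bool = False,
) -> dict[str, Gene]:
    """Parse a GTF/GFF annotation into a mapping gene_id → :class:`Gene`.

    Only ``transcript``, ``exon``, ``start_codon`` and ``stop_codon`` features
    are considered, with the Ensembl-style ``gene_id``/``transcript_id``/
    ``transcript_type`` (or ``transcript_biotype``) attributes.  Records with
    malformed coordinates are rejected with a logged record-level error;
    records lacking a transcript_id are skipped with a warning.
    """
    genes: dict[str, Gene] = {}
    # transcripts scoped by (gene_id, transcript_id): transcript ids are
    # globally unique in Ensembl but this also tolerates per-gene reuse
    txs: dict[tuple[str, str], Transcript] = {}
    for lineno, feat in _records(path, dialect):
        if feat.featuretype not in _FEATURES:
            continue
        tid = _attr(feat, "transcript_id")
        gid = _attr(feat, "gene_id")
        if tid is None:
            logger.warning("%s:%d: record lacks transcript_id; skipped", path, lineno)
            continue
        try:
            iv = GenomicInterval.from_gtf(feat.seqid, feat.start, feat.end, feat.strand)
        except AnnotationError as exc:
            logger.error("%s:%d: malformed record: %s", path, lineno, exc)
            continue
        tx = txs.get((gid or "", tid))
        if tx is None:
            tx = Transcript(
                transcript_id=tid,
                gene_id=gid or "",
                chrom=iv.chrom,
                strand=iv.strand,
            )
            txs[(gid or "", tid)] = tx
        if feat.featuretype == "transcript":
            tx.gene_id = gid or tx.gene_id
            bt = _attr(feat, "transcript_type") or _attr(feat, "transcript_biotype")
            if bt:
                tx.biotype = bt
            elif require_biotype:
                logger.warning("%s:%d: transcript lacks transcript_type", path, lineno)
            tx.tags |= set(feat.attributes.get("tag", []))
        elif feat.featuretype == "exon":
            tx.exons.append(iv)
        elif feat.featuretype == "start_codon":
            tx.start_codon = _merge_codon(tx.start_codon, iv)
        elif feat.featuretype == "stop_codon":
            tx.stop_codon = _merge_codon(tx.stop_codon, iv)

    for tx in txs.values():
        if not tx.exons:
            logger.warning("transcript %s has no exons; skipped", tx.transcript_id)
            continue
        tx.finalize()
        gid = tx.gene_id or tx.transcript_id
        gene = genes.setdefault(gid, Gene(gid, tx.chrom, tx.strand))
        gene.transcripts[tx.transcript_id] = tx
    return genes


def _merge_codon(
    existing: GenomicInterval | None, iv: GenomicInterval
) -> GenomicInterval:
    """Codons split across exons appear as two features; keep the union span."""
    if existing is None:
        return iv
    return GenomicInterval(
        iv.chrom, min(existing.start, iv.start), max(existing.end, iv.end), iv.strand
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_genes(genes: dict[str, Gene]) -> dict[str, Gene]:
    """Drop transcripts lacking start or stop codon, then genes without both
    an NMD target and a protein-coding transcript.

    NMDT flags must already be set (from the biotype or the junction rule).
    """
    kept: dict[str, Gene] = {}
    for gid, gene in genes.items():
        g = Gene(gid, gene.chrom, gene.strand)
        for tid, tx in gene.transcripts.items():
            if tx.start_codon is None or tx.stop_codon is None:
                logger.debug("dropping %s: missing start/stop codon", tid)
                continue
            g.transcripts[tid] = tx
        if g.nmdts and g.coding:
            kept[gid] = g
    return kept


# ---------------------------------------------------------------------------
# secondary-input assignment
# ---------------------------------------------------------------------------


def _exonic_overlap(tx: Transcript, gene: Gene) -> int:
    """Exonic bases of ``tx`` covered by the union of the gene's exons."""
    if not gene.transcripts:
        return 0
    segs = sorted(
        (e.start, e.end)
        for e in gene.exonic_span()
        if e.chrom == tx.chrom
    )
    merged: list[list[int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = 0
    for ex in tx.exons:
        for s, e in merged:
            total += max(0, min(ex.end, e) - max(ex.start, s))
    return total


def assign_secondary(
    genes: dict[str, Gene],
    secondary: Iterable[Transcript],
    min_overlap: float = 0.5,
) -> list[Transcript]:
    """Attach secondary-input transcripts to genes.

    Each transcript goes to the gene with the maximum number of shared introns,
    requiring at least ``min_overlap`` of the transcript's exonic length to
    overlap the gene's exonic span.  Ties break by larger overlap fraction,
    then lexicographic gene_id (logged).  Returns the unassigned transcripts.
    """
    gene_introns = {
        gid: {i for t in g.transcripts.values() for i in t.introns()}
        for gid, g in genes.items()
    }
    unassigned: list[Transcript] = []
    for tx in secondary:
        tx.finalize()
        best: tuple[int, float, str] | None = None
        for gid, g in genes.items():
            if g.chrom != tx.chrom or g.strand != tx.strand:
                continue
            shared = len(set(tx.introns()) & gene_introns[gid])
            frac = _exonic_overlap(tx, g) / tx.exonic_length
            if frac < min_overlap:
                continue
            cand = (shared, frac, gid)
            if best is None:
                best = cand
            elif (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
            elif (cand[0], cand[1]) == (best[0], best[1]):
                logger.warning(
                    "secondary transcript %s ties between genes %s and %s; "
                    "assigned to %s",
                    tx.transcript_id,
                    best[2],
                    gid,
                    min(best[2], gid),
                )
                if gid < best[2]:
                    best = cand
        if best is None:
            unassigned.append(tx)
            continue
        tx.gene_id = best[2]
        genes[best[2]].transcripts[tx.transcript_id] = tx
    return unassigned


# ---------------------------------------------------------------------------
# writing (fixture round-trips and exports)
# ---------------------------------------------------------------------------


def write_gtf(genes: dict[str, Gene] | Sequence[Gene], path: str) -> None:
    """Write the internal model back to a GTF file (Ensembl dialect)."""
    if isinstance(genes, dict):
        gene_list = list(genes.values())
    else:
        gene_list = list(genes)

    def row(chrom, feature, iv, strand, attrs):
        s1, e1 = iv.to_gtf()
        a = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\tnmdsplice\t{feature}\t{s1}\t{e1}\t.\t{strand}\t.\t{a}\n"

    with open(path, "w") as fh:
        for gene in sorted(gene_list, key=lambda g: g.gene_id):
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                span = GenomicInterval(
                    tx.chrom,
                    min(e.start for e in tx.exons),
                    max(e.end for e in tx.exons),
                    tx.strand,
                )
                attrs = [("gene_id", gene.gene_id), ("transcript_id", tid)]
                if tx.biotype:
                    attrs.append(("transcript_type", tx.biotype))
                fh.write(row(tx.chrom, "transcript", span, tx.strand, attrs))
                for e in tx.exons:
                    fh.write(row(tx.chrom, "exon", e, tx.strand, attrs))
                if tx.start_codon:
                    fh.write(row(tx.chrom, "start_codon", tx.start_codon, tx.strand, attrs))
                if tx.stop_codon:
                    fh.write(row(tx.chrom, "stop_codon", tx.stop_codon, tx.strand, attrs))
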