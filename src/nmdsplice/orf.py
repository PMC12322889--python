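"""ORF inference, reading-frame phases, and the 50-nt NMD-target rule.

A transcript is an NMD target (NMDT) when an exon–exon junction lies at least
50 nt downstream of its stop codon in mRNA coordinates: exon-junction
complexes deposited there survive the pioneer round of translation and mark
the stop as premature.  Distances are measured from the last base of the stop
codon to the junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotation import NMD_BIOTYPE, AnnotationError, Gene, GenomicInterval, Transcript

logger = logging.getLogger("nmdsplice")

#: Default junction–stop distance (nt) that triggers NMD.
PTC_THRESHOLD = 50

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class OrfCall:
    """An inferred open reading frame for a transcript."""

    transcript_id: str
    start_codon: GenomicInterval
    stop_codon: GenomicInterval
    orf_length: int  # nt, start through stop codon inclusive; divisible by 3


def transcript_sequence(tx: Transcript, genome) -> str:
    """Spliced mRNA sequence of a transcript from an indexed FASTA.

    ``genome`` is a mapping chrom → sequence with slice access (pyfaidx.Fasta
    works).  Raises on a missing chromosome.
    """
    if tx.chrom not in genome:
        raise KeyError(f"chromosome {tx.chrom!r} absent from genome FASTA")
    chrom = genome[tx.chrom]
    parts = []
    exons = sorted(tx.exons, key=lambda e: e.start)
    for e in exons:
        parts.append(str(chrom[e.start : e.end]))
    seq = "".join(parts).upper()
    if tx.strand == "-":
        seq = seq.translate(_COMP)[::-1]
    return seq


def find_orf(
    tx: Transcript,
    genome,
    candidate_starts: set[GenomicInterval],
) -> OrfCall | None:
    """Select the longest ORF opened at any annotated start codon of the gene.

    Candidate start codons whose first base is not exonic in ``tx`` are
    ignored.  Among the remaining reading frames the longest one terminated by
    an in-frame stop codon within the transcript wins; an ORF-length tie
    breaks toward the 5'-most start.  Returns None when no candidate start is
    exonic or no in-frame stop exists.
    """
    seq = transcript_sequence(tx, genome)
    best: tuple[int, int] | None = None  # (orf_length, -start_offset)
    best_call: OrfCall | None = None
    for codon in candidate_starts:
        first = codon.start if tx.strand == "+" else codon.end - 1
        try:
            off = tx.genomic_to_mrna(first)
        except AnnotationError:
            continue
        if seq[off : off + 3] != "ATG":
            continue
        stop_off = None
        for i in range(off + 3, len(seq) - 2, 3):
            if seq[i : i + 3] in _STOPS:
                stop_off = i
                break
        if stop_off is None:
            continue
        orf_len = stop_off + 3 - off
        key = (orf_len, -off)
        if best is None or key > best:
            best = key
            stop_iv = _codon_interval(tx, stop_off)
            best_call = OrfCall(tx.transcript_id, codon, stop_iv, orf_len)
    return best_call


def _codon_interval(tx: Transcript, off: int) -> GenomicInterval:
    """Genomic span of the codon at mRNA offset ``off`` (union if split)."""
    g = [tx.mrna_to_genomic(off + k) for k in range(3)]
    return GenomicInterval(tx.chrom, min(g), max(g) + 1, tx.strand)


def apply_orf(tx: Transcript, call: OrfCall) -> None:
    """Attach an inferred ORF's codons to the transcript."""
    tx.start_codon = call.start_codon
    tx.stop_codon = call.stop_codon


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------


def splice_site_phase(tx: Transcript, site: int) -> int | None:
    """Reading-frame phase (0/1/2) of a splice site of ``tx``.

    The phase is the exonic distance from the first base of the start codon to
    the site, mod 3.  Sites 5' of the start codon or 3' of the stop codon
    (where the frame is undefined) return None.  ``site`` must be a splice
    site of the transcript.
    """
    if site not in {p for p, _ in tx.splice_sites()}:
        raise AnnotationError(
            f"{site} is not a splice site of {tx.transcript_id}"
        )
    if tx.start_codon is None or tx.stop_codon is None:
        return None
    start_off = tx.cds_start_offset
    stop_off = tx.stop_end_offset
    site_off = tx.boundary_to_mrna(site)
    if site_off < start_off or site_off > stop_off + 1:
        return None
    return (site_off - start_off) % 3


def phase_map(tx: Transcript) -> dict[tuple[int, str], int | None]:
    """Phases of all splice sites of a transcript, keyed by (position, D/A)."""
    return {
        (pos, kind): splice_site_phase(tx, pos) for pos, kind in tx.splice_sites()
    }


# ---------------------------------------------------------------------------
# the 50-nt rule
# ---------------------------------------------------------------------------


def annotate_nmdt(tx: Transcript, threshold: int = PTC_THRESHOLD) -> bool:
    """True iff an exon–exon junction lies ≥ ``threshold`` nt downstream of
    the last base of the stop codon, in mRNA coordinates."""
    if tx.stop_codon is None:
        raise AnnotationError(
            f"transcript {tx.transcript_id} has no stop codon"
        )
    stop_end = tx.stop_end_offset
    for intron in tx.introns():
        junction = tx.boundary_to_mrna(intron.donor)
        if junction - (stop_end + 1) >= threshold:
            return True
    return False


def annotate_gene(gene: Gene, threshold: int = PTC_THRESHOLD) -> None:
    """Set ``is_nmdt`` on every transcript of a gene.

    Transcripts already biotyped ``nonsense_mediated_decay`` keep the label;
    the junction rule is applied to the rest (it requires an annotated or
    inferred stop codon).
    """
    for tx in gene.transcripts.values():
        if tx.biotype == NMD_BIOTYPE:
            tx.is_nmdt = True
        elif tx.stop_codon is not None:
            tx.is_nmdt = annotate_nmdt(tx, threshold)
        else:
            tx.is_nmdt = None
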