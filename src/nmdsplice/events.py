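"""Construction of NMD-generating AS events.

For each NMD target (NMDT) a genomic *interval of interest* is built:

* 5' boundary — the 3'-most splice site shared by the NMDT and any
  protein-coding transcript of the gene with the same reading-frame phase;
  failing that, the start codon when it is shared with at least one coding
  transcript; failing that, the event is undetectable.
* 3' boundary — the 3' end of the exon containing the premature stop codon;
  or, when the NMDT shares its stop codon with a coding transcript (so NMD is
  triggered by the 3'-UTR structure), the nearest downstream transcript end.

The *characteristic introns* of the event are all introns of the NMDT or of
any coding transcript that overlap or abut the interval, except those shared
by the NMDT and at least one coding transcript.  Events from NMDTs sharing a
characteristic intron are merged into clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation import Gene, GenomicInterval, Intron, Transcript, stranded_key
from .orf import phase_map

logger = logging.getLogger("nmdsplice")


@dataclass
class EventDef:
    """One NMDT's interval of interest and its characteristic introns."""

    nmdt_id: str
    interval: GenomicInterval
    nmdt_introns: frozenset[Intron]
    coding_introns: frozenset[Intron]
    boundary_kind_5: str  # shared_splice_site | start_codon
    boundary_kind_3: str  # ptc_exon_end | transcript_end

    @property
    def all_introns(self) -> frozenset[Intron]:
        return self.nmdt_introns | self.coding_introns

    @property
    def has_characteristic(self) -> bool:
        return bool(self.nmdt_introns or self.coding_introns)


@dataclass
class Undetected:
    """An NMDT for which no event could be delimited."""

    nmdt_id: str
    reason: str


@dataclass
class EventCluster:
    """Connected component of EventDefs under the shared-intron relation."""

    cluster_id: str
    members: list[EventDef] = field(default_factory=list)

    @property
    def nmdt_introns(self) -> frozenset[Intron]:
        out: frozenset[Intron] = frozenset()
        for m in self.members:
            out |= m.nmdt_introns
        return out

    @property
    def coding_introns(self) -> frozenset[Intron]:
        out: frozenset[Intron] = frozenset()
        for m in self.members:
            out |= m.coding_introns
        return out

    @property
    def A(self) -> int:
        """Number of NMDT-supporting characteristic introns."""
        return len(self.nmdt_introns)

    @property
    def B(self) -> int:
        """Number of coding-supporting characteristic introns."""
        return len(self.coding_introns)

    @property
    def span(self) -> GenomicInterval:
        m0 = self.members[0]
        return GenomicInterval(
            m0.interval.chrom,
            min(m.interval.start for m in self.members),
            max(m.interval.end for m in self.members),
            m0.interval.strand,
        )

    @property
    def nmdt_ids(self) -> list[str]:
        return sorted(m.nmdt_id for m in self.members)


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------


def interval_5prime(
    nmdt: Transcript, coding: list[Transcript]
) -> tuple[int, str] | None:
    """5' boundary of the interval of interest.

    Returns (genomic boundary position, kind) or None when neither a
    same-phase shared splice site nor a shared start codon exists.
    """
    nmdt_phases = phase_map(nmdt)
    shared: list[int] = []
    coding_phases = [phase_map(c) for c in coding]
    for (pos, kind), ph in nmdt_phases.items():
        if ph is None:
            continue
        for cp in coding_phases:
            if cp.get((pos, kind)) == ph:
                shared.append(pos)
                break
    if shared:
        # 3'-most in transcript orientation
        best = max(shared, key=lambda p: stranded_key(nmdt.strand, p))
        return best, "shared_splice_site"
    if nmdt.start_codon is not None and any(
        c.start_codon == nmdt.start_codon for c in coding
    ):
        pos = (
            nmdt.start_codon.start
            if nmdt.strand == "+"
            else nmdt.start_codon.end
        )
        return pos, "start_codon"
    return None


def interval_3prime(
    nmdt: Transcript, coding: list[Transcript]
) -> tuple[int, str]:
    """3' boundary of the interval of interest.

    If the NMDT's stop codon is not shared with any coding transcript it is a
    genuine PTC and the boundary is the 3' end of the PTC-containing exon.
    Otherwise NMD is triggered by the 3'-UTR structure and the boundary is the
    nearest transcript end downstream of the stop codon.
    """
    stop = nmdt.stop_codon
    shared_stop = any(c.stop_codon == stop for c in coding)
    if not shared_stop:
        last = stop.end - 1 if nmdt.strand == "+" else stop.start
        for e in nmdt.exons:
            if e.start <= last < e.end:
                return (e.end if nmdt.strand == "+" else e.start), "ptc_exon_end"
        raise AssertionError("stop codon outside exons")  # pragma: no cover
    stop_3 = stop.end if nmdt.strand == "+" else stop.start
    ends = [nmdt.tx_end] + [c.tx_end for c in coding]
    downstream = [
        e for e in ends if stranded_key(nmdt.strand, e) >= stranded_key(nmdt.strand, stop_3)
    ]
    best = min(downstream, key=lambda e: stranded_key(nmdt.strand, e))
    return best, "transcript_end"


# ---------------------------------------------------------------------------
# characteristic introns
# ---------------------------------------------------------------------------


def characteristic_introns(
    nmdt: Transcript,
    coding: list[Transcript],
    interval: GenomicInterval,
    boundary_kind_5: str,
    boundary_kind_3: str,
) -> EventDef:
    """Collect and partition the characteristic introns of one NMDT."""
    nmdt_set = set(nmdt.introns())
    coding_set = {i for c in coding for i in c.introns()}
    shared = nmdt_set & coding_set
    nm = frozenset(
        i for i in nmdt_set - shared if i.overlaps_or_abuts(interval)
    )
    co = frozenset(
        i for i in coding_set - shared if i.overlaps_or_abuts(interval)
    )
    if not nm and not co:
        logger.info("NMDT %s: no characteristic introns", nmdt.transcript_id)
    return EventDef(
        nmdt_id=nmdt.transcript_id,
        interval=interval,
        nmdt_introns=nm,
        coding_introns=co,
        boundary_kind_5=boundary_kind_5,
        boundary_kind_3=boundary_kind_3,
    )


def build_event(
    nmdt: Transcript, coding: list[Transcript]
) -> EventDef | Undetected:
    """Construct the EventDef for one NMDT against its gene's coding set."""
    b5 = interval_5prime(nmdt, coding)
    if b5 is None:
        return Undetected(
            nmdt.transcript_id,
            "no same-phase shared splice site and no shared start codon",
        )
    pos5, kind5 = b5
    pos3, kind3 = interval_3prime(nmdt, coding)
    lo, hi = min(pos5, pos3), max(pos5, pos3)
    if lo == hi:  # degenerate: boundaries coincide
        hi = lo + 1
    interval = GenomicInterval(nmdt.chrom, lo, hi, nmdt.strand)
    ev = characteristic_introns(nmdt, coding, interval, kind5, kind3)
    if not ev.has_characteristic:
        return Undetected(nmdt.transcript_id, "no characteristic introns")
    return ev


def find_events(gene: Gene) -> tuple[list[EventDef], list[Undetected]]:
    """Events for every NMDT of a gene; undetectable NMDTs reported apart."""
    events: list[EventDef] = []
    undetected: list[Undetected] = []
    coding = gene.coding
    for nmdt in gene.nmdts:
        if nmdt.stop_codon is None:
            undetected.append(Undetected(nmdt.transcript_id, "no stop codon"))
            continue
        res = build_event(nmdt, coding)
        if isinstance(res, Undetected):
            undetected.append(res)
        else:
            events.append(res)
    return events, undetected


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_events(defs: list[EventDef], gene_id: str = "") -> list[EventCluster]:
    """Merge events sharing at least one characteristic intron (union-find).

    The result is independent of the input order: members are sorted by
    nmdt_id and clusters by their 5'-most member.
    """
    parent = list(range(len(defs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    by_intron: dict[Intron, int] = {}
    for idx, d in enumerate(defs):
        for intron in d.all_introns:
            if intron in by_intron:
                union(idx, by_intron[intron])
            else:
                by_intron[intron] = idx

    groups: dict[int, list[EventDef]] = {}
    for idx, d in enumerate(defs):
        groups.setdefault(find(idx), []).append(d)

    clusters = []
    ordered = sorted(
        groups.values(),
        key=lambda ms: (min(m.interval.start for m in ms), sorted(m.nmdt_id for m in ms)),
    )
    for k, members in enumerate(ordered, 1):
        cid = f"{gene_id}.e{k}" if gene_id else f"e{k}"
        clusters.append(
            EventCluster(cid, sorted(members, key=lambda m: m.nmdt_id))
        )
    return clusters
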