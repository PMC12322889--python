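"""Classification of NMD-generating AS events via splice-graph bubbles.

The NMDT and a reference coding transcript are laid out as two chains of
donor (D) and acceptor (A) splice sites in a directed acyclic splicing graph
(exons are A→D edges, introns D→A edges).  A *bubble* is a pair of
vertex-independent paths — paths sharing only their first and last node —
one from each transcript.  The alternating D/A labels of the two paths,
written ``nmdt_path:ref_path``, encode the event type: a poison exon is
``DADA:DA``, an intron retention ``AD:ADAD``, mutually exclusive exons
``DADA:DADA``, and so on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx

from .annotation import Gene, GenomicInterval, Intron, Transcript
from .events import EventCluster

logger = logging.getLogger("nmdsplice")


class ClassificationError(ValueError):
    pass


Node = tuple[int, str]  # (genomic boundary position, 'D' | 'A')
SRC: Node = (-1, "^")
SNK: Node = (-1, "$")


@dataclass
class SpliceGraph:
    """Two-transcript splicing graph with explicit source/sink anchors."""

    graph: nx.DiGraph
    nmdt_chain: list[Node]
    ref_chain: list[Node]
    chrom: str
    strand: str

    def shared_nodes(self) -> list[Node]:
        ref = set(self.ref_chain)
        return [n for n in self.nmdt_chain if n in ref]


@dataclass
class PathPair:
    """A bubble: the NMDT path and the reference path between two anchors."""

    source: Node
    sink: Node
    nmdt_path: list[Node]  # includes real anchors, excludes SRC/SNK
    ref_path: list[Node]
    nmdt_introns: frozenset[Intron]
    ref_introns: frozenset[Intron]

    @property
    def introns(self) -> frozenset[Intron]:
        return self.nmdt_introns | self.ref_introns


@dataclass(frozen=True)
class PathPairCode:
    nmdt_path: str
    ref_path: str

    @property
    def code(self) -> str:
        return f"{self.nmdt_path}:{self.ref_path}"


@dataclass(frozen=True)
class EventType:
    name: str
    code: str
    n: int = 0
    synonym: str = "-"


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def _window(
    tx: Transcript, other: list[Node], span: GenomicInterval | None
) -> list[Node]:
    """Restrict a transcript's site chain to the sites of introns that
    overlap or abut the event span, anchored by one shared site on each
    flank so that bubbles can close outside the span."""
    chain = _chain(tx)
    if span is None:
        return chain
    other_set = set(other)
    # site i belongs to intron i // 2 (the chain is D0 A0 D1 A1 …)
    introns = tx.introns()
    in_span = [
        i for i in range(len(chain)) if introns[i // 2].overlaps_or_abuts(span)
    ]
    if not in_span:
        return []
    lo, hi = in_span[0], in_span[-1]
    for i in range(lo - 1, -1, -1):
        if chain[i] in other_set:
            lo = i
            break
    for i in range(hi + 1, len(chain)):
        if chain[i] in other_set:
            hi = i
            break
    return chain[lo : hi + 1]


def _chain(tx: Transcript) -> list[Node]:
    return list(tx.splice_sites())


def build_splice_graph(
    nmdt: Transcript,
    ref: Transcript,
    span: GenomicInterval | None = None,
) -> SpliceGraph:
    """Build the two-transcript splicing graph over the event span.

    Raises :class:`ClassificationError` when the transcripts do not overlap
    the span (no classification is possible against this reference).
    """
    if nmdt.chrom != ref.chrom or nmdt.strand != ref.strand:
        raise ClassificationError("transcripts on different chromosome/strand")
    nchain = _window(nmdt, _chain(ref), span)
    rchain = _window(ref, _chain(nmdt), span)
    if span is not None and not rchain:
        raise ClassificationError(
            f"reference {ref.transcript_id} has no splice sites over the event span"
        )
    g = nx.DiGraph()
    g.add_node(SRC)
    g.add_node(SNK)
    for chain, tag in ((nchain, "nmdt"), (rchain, "ref")):
        for a, b in zip([SRC] + chain, chain + [SNK]):
            kind = "anchor"
            if a != SRC and b != SNK:
                kind = "intron" if a[1] == "D" else "exon"
            if g.has_edge(a, b):
                g[a][b]["sources"].add(tag)
            else:
                g.add_edge(a, b, kind=kind, sources={tag})
    return SpliceGraph(g, nchain, rchain, nmdt.chrom, nmdt.strand)


def _segment_introns(
    path: list[Node], chrom: str, strand: str
) -> frozenset[Intron]:
    out = set()
    for a, b in zip(path, path[1:]):
        if a[1] == "D" and b[1] == "A":
            out.add(Intron(chrom, min(a[0], b[0]), max(a[0], b[0]), strand))
    return frozenset(out)


def find_bubbles(
    g: SpliceGraph,
    characteristic: frozenset[Intron] | set[Intron] | None = None,
) -> list[PathPair]:
    """All bubbles: maximal path pairs between consecutive shared nodes whose
    interiors are disjoint.  With ``characteristic`` given, only bubbles
    containing at least one characteristic intron are returned."""
    nset, rset = set(g.nmdt_chain), set(g.ref_chain)
    shared = [n for n in g.nmdt_chain if n in rset]
    shared_ref_order = [n for n in g.ref_chain if n in nset]
    if shared != shared_ref_order:
        # shared sites out of order between the chains: no clean bubbles
        logger.warning("shared splice sites are not collinear; skipping")
        return []
    anchors: list[Node] = [SRC] + shared + [SNK]

    def interior(chain: list[Node], u: Node, v: Node) -> list[Node]:
        iu = chain.index(u) if u != SRC else -1
        iv = chain.index(v) if v != SNK else len(chain)
        return chain[iu + 1 : iv]

    bubbles: list[PathPair] = []
    for u, v in zip(anchors, anchors[1:]):
        ni = interior(g.nmdt_chain, u, v)
        ri = interior(g.ref_chain, u, v)
        if not ni and not ri:
            continue
        npath = ([u] if u != SRC else []) + ni + ([v] if v != SNK else [])
        rpath = ([u] if u != SRC else []) + ri + ([v] if v != SNK else [])
        pp = PathPair(
            source=u,
            sink=v,
            nmdt_path=npath,
            ref_path=rpath,
            nmdt_introns=_segment_introns(npath, g.chrom, g.strand),
            ref_introns=_segment_introns(rpath, g.chrom, g.strand),
        )
        if characteristic is not None and not (pp.introns & set(characteristic)):
            continue
        bubbles.append(pp)
    return bubbles


# ---------------------------------------------------------------------------
# encoding and the type catalogue
# ---------------------------------------------------------------------------


def encode_path_pair(pp: PathPair) -> PathPairCode:
    """Concatenate D/A labels of both paths, NMDT first."""
    n = "".join(k for _, k in pp.nmdt_path)
    r = "".join(k for _, k in pp.ref_path)
    for s in (n, r):
        if any(a == b for a, b in zip(s, s[1:])):
            raise AssertionError(f"non-alternating path labels: {s}")
    return PathPairCode(n, r)


def _rep(pattern: str) -> str:
    """Compile a catalogue pattern with an (AD)n group into a regex."""
    return "^" + pattern.replace("(AD)n", "((?:AD)+)") + "$"


# Ordered: fixed codes first, then parametric families.  ``base`` is the
# number of AD repeats already implied by the fixed part of the pattern, so
# n = matched repeats − base offset where noted.
_CATALOG: list[tuple[str, str, str, int, str]] = [
    # name, nmdt pattern, ref pattern, n_offset, synonym
    ("PE", "DADA", "DA", 0, "NMD_in"),
    ("EE", "DA", "DADA", 0, "NMD_ex"),
    ("A5SS", "ADA", "ADA", 0, "A5SS"),
    ("A3SS", "DAD", "DAD", 0, "A3SS"),
    ("A5SS+A3SS", "ADAD", "ADAD", 0, "A5SS,A3SS"),
    ("IR", "AD", "ADAD", 0, "nNMD_IR"),
    ("ID", "ADAD", "AD", 0, "NMD_IR"),
    ("MXE", "DADA", "DADA", 0, "-"),
    ("PEn", "D(AD)nA", "DA", 0, "multi_NMD_in"),
    ("EEn", "DA", "D(AD)nA", 0, "multi_NMD_ex"),
    ("A5SS+PEn", "AD(AD)nA", "ADA", 0, "-"),
    ("A5SS+EEn", "ADA", "AD(AD)nA", 0, "-"),
    ("PEn+A3SS", "D(AD)nAD", "DAD", 0, "-"),
    ("EEn+A3SS", "DAD", "D(AD)nAD", 0, "-"),
    ("A5SS+EE+A3SS", "ADAD", "AD(AD)nAD", 0, "-"),
]

#: The 15 named event types of the catalogue.
TYPE_NAMES = [row[0] for row in _CATALOG]


def classify_code(code: PathPairCode) -> EventType:
    """Match a path-pair code against the type catalogue.

    Parametric families use (AD)n repeats with n extracted from the match;
    codes outside the catalogue map to ``other`` with the raw code kept.
    """
    for name, pn, pr, _, syn in _CATALOG:
        mn = re.match(_rep(pn), code.nmdt_path)
        mr = re.match(_rep(pr), code.ref_path)
        if mn and mr:
            n = 0
            for m in (mn, mr):
                if m.groups():
                    n = len(m.group(1)) // 2
            return EventType(name, code.code, n, syn)
    return EventType("other", code.code, 0, "-")


# ---------------------------------------------------------------------------
# cluster classification
# ---------------------------------------------------------------------------


@dataclass
class Classification:
    cluster_id: str
    nmdt_id: str
    reference_id: str
    event_type: EventType
    n_characteristic: int
    reference_free: bool = False


def _classify_pair(
    cluster: EventCluster,
    nmdt: Transcript,
    ref: Transcript,
) -> list[tuple[EventType, int]]:
    g = build_splice_graph(nmdt, ref, cluster.span)
    char = cluster.nmdt_introns | cluster.coding_introns
    out = []
    for pp in find_bubbles(g, characteristic=char):
        code = encode_path_pair(pp)
        et = classify_code(code)
        if et.name == "other" and (pp.source == SRC or pp.sink == SNK):
            # open-ended bubble (the transcripts never reconverge, typical of
            # 3'-UTR events): call retention/excision from the intron balance
            if not pp.nmdt_introns and pp.ref_introns:
                et = EventType("IR", code.code, 0, "nNMD_IR")
            elif not pp.ref_introns and pp.nmdt_introns:
                et = EventType("ID", code.code, 0, "NMD_IR")
        out.append((et, len(pp.introns & char)))
    return out


def classify_event(
    cluster: EventCluster,
    gene: Gene,
    reference_ids: list[str] | None = None,
) -> list[Classification]:
    """Classify a cluster against reference transcripts.

    ``reference_ids`` restricts the reference set (MANE-Select or a user
    list); when None every protein-coding transcript of the gene is used
    iteratively.  3'-UTR events whose reference has no splice site over the
    span fall back to the nearest coding transcript spanning them, and
    finally to a reference-free call (IR when only coding-supporting introns
    exist — the NMDT retains them — else ``other``).
    """
    coding = {t.transcript_id: t for t in gene.coding}
    if reference_ids is not None:
        refs = [coding[r] for r in reference_ids if r in coding]
        if not refs:
            raise ClassificationError(
                f"none of the reference transcripts are coding in gene {gene.gene_id}"
            )
    else:
        refs = sorted(coding.values(), key=lambda t: t.transcript_id)

    results: list[Classification] = []
    for nmdt_id in cluster.nmdt_ids:
        nmdt = gene.transcripts[nmdt_id]
        got = False
        for ref in refs:
            try:
                pairs = _classify_pair(cluster, nmdt, ref)
            except ClassificationError:
                continue
            for et, nchar in pairs:
                results.append(
                    Classification(cluster.cluster_id, nmdt_id, ref.transcript_id, et, nchar)
                )
                got = True
        if not got and reference_ids is not None:
            # fall back to any coding transcript spanning the event
            for ref in sorted(coding.values(), key=lambda t: t.transcript_id):
                if ref.transcript_id in {r.transcript_id for r in refs}:
                    continue
                try:
                    pairs = _classify_pair(cluster, nmdt, ref)
                except ClassificationError:
                    continue
                for et, nchar in pairs:
                    results.append(
                        Classification(
                            cluster.cluster_id, nmdt_id, ref.transcript_id, et, nchar
                        )
                    )
                    got = True
                if got:
                    break
        if not got:
            # reference-free: an NMDT retaining coding-side introns is an IR
            name = "IR" if cluster.A == 0 and cluster.B > 0 else "other"
            results.append(
                Classification(
                    cluster.cluster_id,
                    nmdt_id,
                    "",
                    EventType(name, "", 0, "nNMD_IR" if name == "IR" else "-"),
                    cluster.A + cluster.B,
                    reference_free=True,
                )
            )
    return results


def headline(classifications: list[Classification]) -> Classification:
    """The cluster's headline call: the code containing the most
    characteristic introns, ties broken by longer code."""
    return max(
        classifications,
        key=lambda c: (c.n_characteristic, len(c.event_type.code), c.event_type.name),
    )
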