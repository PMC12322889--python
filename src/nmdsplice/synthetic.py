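"""Synthetic gene fixtures with known ground truth.

Every named event type of the classification catalogue, plus the pathological
cases (frame-compensated exon skipping, coordinated distant exons, mutually
exclusive exons, 3'-UTR intron retention, the 50-nt boundary), is realized as
a small toy gene built on a common scaffold:

* constitutive exons U1 [1000,1120) and U2 [2000,2120) with the start codon
  at [1000,1003), and constitutive exons D1 [8000,8120) and D2 [9000,9120)
  with the normal stop codon in D2;
* event-specific exons between U2 and D1.

All codon placements are frame-consistent (the mRNA offset of every stop
codon's first base is a multiple of 3 from the start codon) and every NMDT
carries a junction at the intended distance downstream of its premature stop,
so the fixtures exercise the 50-nt rule in the intended direction.

Ground truth (interval boundaries, characteristic introns, path-pair code,
event type, intron weights) is bundled with each gene.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .annotation import (
    CODING_BIOTYPE,
    NMD_BIOTYPE,
    Gene,
    GenomicInterval,
    Intron,
    Transcript,
)
from .events import EventCluster
from .quantify import IntronWeights, JunctionCounts

CHROM_LEN = 20000  # span used when mirroring fixtures to the − strand

# scaffold blocks
_U1 = (1000, 1120)
_U2 = (2000, 2120)
_D1 = (8000, 8120)
_D2 = (9000, 9120)
_START = (1000, 1003)
_STOP_D2 = (9099, 9102)  # in-frame normal stop for the U1,U2,D1,D2 chain


def _tx(
    tid: str,
    gid: str,
    chrom: str,
    exons: list[tuple[int, int]],
    start: tuple[int, int] | None,
    stop: tuple[int, int] | None,
    biotype: str,
    strand: str = "+",
) -> Transcript:
    t = Transcript(tid, gid, chrom, strand, biotype=biotype)
    t.exons = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    if start:
        t.start_codon = GenomicInterval(chrom, *start, strand)
    if stop:
        t.stop_codon = GenomicInterval(chrom, *stop, strand)
    t.finalize()
    return t


def _intron(chrom: str, s: int, e: int, strand: str = "+") -> Intron:
    return Intron(chrom, s, e, strand)


def _gene(gid: str, chrom: str, txs: list[Transcript]) -> Gene:
    g = Gene(gid, chrom, "+")
    for t in txs:
        g.transcripts[t.transcript_id] = t
    return g


def _coding_base(gid: str, chrom: str, tid: str = "C1") -> Transcript:
    """The scaffold coding transcript U1,U2,D1,D2."""
    return _tx(
        tid, gid, chrom, [_U1, _U2, _D1, _D2], _START, _STOP_D2, CODING_BIOTYPE
    )


# ---------------------------------------------------------------------------
# catalogue fixtures: one builder per named type
# ---------------------------------------------------------------------------
# Each builder returns (gene, expected) with expected holding the ground
# truth: interval, boundary kinds, side-tagged characteristic introns, the
# path-pair code against the named reference, the type name and n, and the
# intron weights.


def _expected(chrom, interval, kind5, kind3, nm, co, code, name, n, ref, k, r):
    return {
        "chrom": chrom,
        "interval": interval,  # (start, end) half-open bounds of interest
        "boundary_kind_5": kind5,
        "boundary_kind_3": kind3,
        "nmdt_introns": {_intron(chrom, *i) for i in nm},
        "coding_introns": {_intron(chrom, *i) for i in co},
        "code": code,
        "type": name,
        "n": n,
        "reference": ref,
        "weights_k": {_intron(chrom, *i): w for i, w in k.items()},
        "weights_r": {_intron(chrom, *i): w for i, w in r.items()},
    }


def _pe(gid, chrom):
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1, _D2],
        _START, (4009, 4012), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    exp = _expected(
        chrom, (2120, 4100), "shared_splice_site", "ptc_exon_end",
        [(2120, 4000), (4100, 8000)], [(2120, 8000)],
        "DADA:DA", "PE", 0, "C1",
        {(2120, 4000): 0.5, (4100, 8000): 0.5}, {(2120, 8000): 1.0},
    )
    return g, exp


def _pen(gid, chrom):
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (4000, 4100), (5000, 5100), _D1, _D2],
        _START, (5002, 5005), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    third = 1.0 / 3.0
    exp = _expected(
        chrom, (2120, 5100), "shared_splice_site", "ptc_exon_end",
        [(2120, 4000), (4100, 5000), (5100, 8000)], [(2120, 8000)],
        "DADADA:DA", "PEn", 2, "C1",
        {(2120, 4000): third, (4100, 5000): third, (5100, 8000): third},
        {(2120, 8000): 1.0},
    )
    return g, exp


def _ee(gid, chrom):
    coding = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1, _D2],
        _START, (9002, 9005), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom, [_U1, _U2, _D1, _D2], _START, (8009, 8012), NMD_BIOTYPE
    )
    g = _gene(gid, chrom, [coding, nmdt])
    exp = _expected(
        chrom, (2120, 8120), "shared_splice_site", "ptc_exon_end",
        [(2120, 8000)], [(2120, 4000), (4100, 8000)],
        "DA:DADA", "EE", 0, "C1",
        {(2120, 8000): 1.0}, {(2120, 4000): 0.5, (4100, 8000): 0.5},
    )
    return g, exp


def _een(gid, chrom):
    coding = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (4000, 4100), (5000, 5100), _D1, _D2],
        _START, (9001, 9004), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom, [_U1, _U2, _D1, _D2], _START, (8009, 8012), NMD_BIOTYPE
    )
    g = _gene(gid, chrom, [coding, nmdt])
    third = 1.0 / 3.0
    exp = _expected(
        chrom, (2120, 8120), "shared_splice_site", "ptc_exon_end",
        [(2120, 8000)], [(2120, 4000), (4100, 5000), (5100, 8000)],
        "DA:DADADA", "EEn", 2, "C1",
        {(2120, 8000): 1.0},
        {(2120, 4000): third, (4100, 5000): third, (5100, 8000): third},
    )
    return g, exp


def _a5ss(gid, chrom):
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, (2000, 2160), _D1, _D2],
        _START, (8002, 8005), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    exp = _expected(
        chrom, (2000, 8120), "shared_splice_site", "ptc_exon_end",
        [(2160, 8000)], [(2120, 8000)],
        "ADA:ADA", "A5SS", 0, "C1",
        {(2160, 8000): 1.0}, {(2120, 8000): 1.0},
    )
    return g, exp


def _a3ss(gid, chrom):
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (7960, 8120), _D2],
        _START, (7969, 7972), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    exp = _expected(
        chrom, (2120, 8120), "shared_splice_site", "ptc_exon_end",
        [(2120, 7960)], [(2120, 8000)],
        "DAD:DAD", "A3SS", 0, "C1",
        {(2120, 7960): 1.0}, {(2120, 8000): 1.0},
    )
    return g, exp


def _a5a3(gid, chrom):
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, (2000, 2160), (7960, 8120), _D2],
        _START, (7962, 7965), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    exp = _expected(
        chrom, (2000, 8120), "shared_splice_site", "ptc_exon_end",
        [(2160, 7960)], [(2120, 8000)],
        "ADAD:ADAD", "A5SS+A3SS", 0, "C1",
        {(2160, 7960): 1.0}, {(2120, 8000): 1.0},
    )
    return g, exp


def _ir(gid, chrom):
    coding = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1, _D2],
        _START, (9002, 9005), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (4000, 8120), _D2],
        _START, (4150, 4153), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [coding, nmdt])
    exp = _expected(
        chrom, (4000, 8120), "shared_splice_site", "ptc_exon_end",
        [], [(4100, 8000)],
        "AD:ADAD", "IR", 0, "C1",
        {}, {(4100, 8000): 1.0},
    )
    return g, exp


def _id(gid, chrom):
    coding = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (4000, 8120), _D2],
        _START, (9002, 9005), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1, _D2],
        _START, (8002, 8005), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [coding, nmdt])
    exp = _expected(
        chrom, (4000, 8120), "shared_splice_site", "ptc_exon_end",
        [(4100, 8000)], [],
        "ADAD:AD", "ID", 0, "C1",
        {(4100, 8000): 1.0}, {},
    )
    return g, exp


def _mxe(gid, chrom):
    coding_b = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (5000, 5100), _D1, _D2],
        _START, (9002, 9005), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (4000, 4101), _D1, _D2],
        _START, (8001, 8004), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [coding_b, nmdt])
    exp = _expected(
        chrom, (2120, 8120), "shared_splice_site", "ptc_exon_end",
        [(2120, 4000), (4101, 8000)], [(2120, 5000), (5100, 8000)],
        "DADA:DADA", "MXE", 0, "C1",
        {(2120, 4000): 0.5, (4101, 8000): 0.5},
        {(2120, 5000): 0.5, (5100, 8000): 0.5},
    )
    return g, exp


def _a5_pen(gid, chrom):
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, (2000, 2160), (4000, 4100), _D1, _D2],
        _START, (4002, 4005), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    exp = _expected(
        chrom, (2000, 4100), "shared_splice_site", "ptc_exon_end",
        [(2160, 4000), (4100, 8000)], [(2120, 8000)],
        "ADADA:ADA", "A5SS+PEn", 1, "C1",
        {(2160, 4000): 0.5, (4100, 8000): 0.5}, {(2120, 8000): 1.0},
    )
    return g, exp


def _a5_een(gid, chrom):
    coding = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1, _D2],
        _START, (9002, 9005), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, (2000, 2161), _D1, _D2],
        _START, (8001, 8004), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [coding, nmdt])
    exp = _expected(
        chrom, (2000, 8120), "shared_splice_site", "ptc_exon_end",
        [(2161, 8000)], [(2120, 4000), (4100, 8000)],
        "ADA:ADADA", "A5SS+EEn", 1, "C1",
        {(2161, 8000): 1.0}, {(2120, 4000): 0.5, (4100, 8000): 0.5},
    )
    return g, exp


def _pen_a3(gid, chrom):
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (4000, 4100), (7960, 8120), _D2],
        _START, (7962, 7965), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    exp = _expected(
        chrom, (2120, 8120), "shared_splice_site", "ptc_exon_end",
        [(2120, 4000), (4100, 7960)], [(2120, 8000)],
        "DADAD:DAD", "PEn+A3SS", 1, "C1",
        {(2120, 4000): 0.5, (4100, 7960): 0.5}, {(2120, 8000): 1.0},
    )
    return g, exp


def _een_a3(gid, chrom):
    coding = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1, _D2],
        _START, (9002, 9005), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, _U2, (7960, 8120), _D2],
        _START, (7969, 7972), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [coding, nmdt])
    exp = _expected(
        chrom, (2120, 8120), "shared_splice_site", "ptc_exon_end",
        [(2120, 7960)], [(2120, 4000), (4100, 8000)],
        "DAD:DADAD", "EEn+A3SS", 1, "C1",
        {(2120, 7960): 1.0}, {(2120, 4000): 0.5, (4100, 8000): 0.5},
    )
    return g, exp


def _a5_ee_a3(gid, chrom):
    coding = _tx(
        "C1", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1, _D2],
        _START, (9002, 9005), CODING_BIOTYPE,
    )
    nmdt = _tx(
        "N1", gid, chrom,
        [_U1, (2000, 2160), (7960, 8120), _D2],
        _START, (7962, 7965), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [coding, nmdt])
    exp = _expected(
        chrom, (2000, 8120), "shared_splice_site", "ptc_exon_end",
        [(2160, 7960)], [(2120, 4000), (4100, 8000)],
        "ADAD:ADADAD", "A5SS+EE+A3SS", 1, "C1",
        {(2160, 7960): 1.0}, {(2120, 4000): 0.5, (4100, 8000): 0.5},
    )
    return g, exp


TABLE_BUILDERS = {
    "PE": _pe,
    "PEn": _pen,
    "EE": _ee,
    "EEn": _een,
    "A5SS": _a5ss,
    "A3SS": _a3ss,
    "A5SS+A3SS": _a5a3,
    "IR": _ir,
    "ID": _id,
    "MXE": _mxe,
    "A5SS+PEn": _a5_pen,
    "A5SS+EEn": _a5_een,
    "PEn+A3SS": _pen_a3,
    "EEn+A3SS": _een_a3,
    "A5SS+EE+A3SS": _a5_ee_a3,
}


# ---------------------------------------------------------------------------
# pathological and boundary fixtures
# ---------------------------------------------------------------------------


def _hps1_like(gid, chrom):
    """Exon skipping compensated by a downstream splice-site shift.

    The NMDT skips exon E5 and joins E6a to E7, which disrupts the frame; a
    coding transcript also skips E5 but compensates via an alternative E7
    acceptor.  The only NMDT-supporting characteristic intron is the E6a–E7
    junction, and the 5' boundary is the E6a donor — the last splice site at
    which the NMDT frame matches a coding transcript.
    """
    u1 = (1000, 1120)
    e5 = (2000, 2100)
    e6 = (3200, 3292)
    e6a = (3000, 3080)
    e7 = (4000, 4120)
    e7x = (3999, 4120)
    d = (5000, 5120)
    d2 = (6000, 6120)
    start = (1000, 1003)
    coding1 = _tx(
        "C1", gid, chrom, [u1, e5, e6, d, d2], start, (5099, 5102), CODING_BIOTYPE
    )
    coding3 = _tx(
        "C2", gid, chrom, [u1, e6a, e7x, d], start, (5099, 5102), CODING_BIOTYPE
    )
    nmdt = _tx(
        "N1", gid, chrom, [u1, e6a, e7, d, d2], start, (5010, 5013), NMD_BIOTYPE
    )
    nmdt2 = _tx(
        "N2", gid, chrom, [u1, e5, e6a, e7x, d, d2], start, (5002, 5005), NMD_BIOTYPE
    )
    g = _gene(gid, chrom, [coding1, coding3, nmdt, nmdt2])
    exp = {
        "chrom": chrom,
        "n1_boundary5": 3080,  # donor of E6a, last same-phase shared site
        "n1_nmdt_introns": {_intron(chrom, 3080, 4000)},
        "clustered": True,  # N1 and N2 share coding-side characteristic introns
    }
    return g, exp


def _erlec1_like(gid, chrom):
    """Coordinated distant cassette exons with an alternative start codon.

    Including both X5 and X7 or neither preserves the frame; the NMDT
    includes only X5 and initiates at a downstream start codon, so no splice
    site shares its phase with a coding transcript and no shared start codon
    exists: the NMDT is undetectable (no characteristic introns).
    """
    u = (1000, 1120)
    x5 = (2000, 2100)
    m = (3000, 3120)
    x7 = (4000, 4104)
    d = (5000, 5120)
    d2 = (6000, 6120)
    start = (1000, 1003)
    coding_both = _tx(
        "C1", gid, chrom, [u, x5, m, x7, d, d2], start, (5099, 5102), CODING_BIOTYPE
    )
    coding_neither = _tx(
        "C2", gid, chrom, [u, m, d, d2], start, (5099, 5102), CODING_BIOTYPE
    )
    nmdt = _tx(
        "N1", gid, chrom, [u, x5, m, d, d2], (2011, 2014), (5001, 5004), NMD_BIOTYPE
    )
    g = _gene(gid, chrom, [coding_both, coding_neither, nmdt])
    return g, {"chrom": chrom, "undetected": "N1"}


def _fgfr2_like(gid, chrom):
    """Mutually exclusive exons whose joint inclusion generates the NMDT.

    Against each single-inclusion coding isoform the double-inclusion NMDT
    reads as a poison-exon insertion of the other exon.
    """
    u = (1000, 1120)
    xa = (3000, 3102)
    xb = (4000, 4102)
    d = (5000, 5120)
    d2 = (6000, 6120)
    start = (1000, 1003)
    coding_a = _tx(
        "C1", gid, chrom, [u, xa, d, d2], start, (5099, 5102), CODING_BIOTYPE
    )
    coding_b = _tx(
        "C2", gid, chrom, [u, xb, d, d2], start, (5099, 5102), CODING_BIOTYPE
    )
    nmdt = _tx(
        "N1", gid, chrom, [u, xa, xb, d, d2], start, (4003, 4006), NMD_BIOTYPE
    )
    g = _gene(gid, chrom, [coding_a, coding_b, nmdt])
    exp = {
        "chrom": chrom,
        "nmdt_introns": {_intron(chrom, 3102, 4000)},
        "coding_introns": {_intron(chrom, 3102, 5000), _intron(chrom, 1120, 4000)},
        "codes": {"DADA:DA"},
    }
    return g, exp


def _utr3_ir(gid, chrom):
    """Intron retention in the 3' UTR: the NMDT shares the coding stop codon
    but retains a UTR intron and splices a distant one, triggering NMD."""
    u = (1000, 1120)
    start = (1000, 1003)
    stop = (2099, 2102)
    coding = _tx(
        "C1", gid, chrom, [u, (2000, 2140), (2290, 2550)], start, stop, CODING_BIOTYPE
    )
    nmdt = _tx(
        "N1", gid, chrom, [u, (2000, 2600), (2800, 2900)], start, stop, NMD_BIOTYPE
    )
    g = _gene(gid, chrom, [coding, nmdt])
    exp = {
        "chrom": chrom,
        "boundary_kind_3": "transcript_end",
        "nmdt_introns": set(),
        "coding_introns": {_intron(chrom, 2140, 2290)},
        "type": "IR",
    }
    return g, exp


def _start_anchor(gid, chrom):
    """No same-phase shared splice site: the interval is anchored at the
    shared start codon (the NMDT shifts its first donor and its frame)."""
    nmdt = _tx(
        "N1", gid, chrom, [(1000, 1140), _D1, _D2], _START, (8001, 8004), NMD_BIOTYPE
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), nmdt])
    exp = {
        "chrom": chrom,
        "boundary_kind_5": "start_codon",
        "nmdt_introns": {_intron(chrom, 1140, 8000)},
        "coding_introns": {_intron(chrom, 1120, 2000), _intron(chrom, 2120, 8000)},
    }
    return g, exp


def _nested_pe(gid, chrom):
    """A cassette exon nested inside a larger alternative region: two NMDTs
    (region with and without the inner exon) against a region-skipping coding
    transcript.  Exercises the multiplicative nested-weight rule."""
    r1 = (3000, 3100)
    p = (4000, 4100)
    r2 = (5000, 5100)
    incl = _tx(
        "N1", gid, chrom,
        [_U1, _U2, r1, p, r2, _D1, _D2], _START, (5001, 5004), NMD_BIOTYPE,
    )
    skip = _tx(
        "N2", gid, chrom,
        [_U1, _U2, r1, r2, _D1, _D2], _START, (5002, 5005), NMD_BIOTYPE,
    )
    g = _gene(gid, chrom, [_coding_base(gid, chrom), incl, skip])
    third = 1.0 / 3.0
    exp = {
        "chrom": chrom,
        "weights_k": {
            _intron(chrom, 2120, 3000): third,
            _intron(chrom, 3100, 4000): third / 2,
            _intron(chrom, 4100, 5000): third / 2,
            _intron(chrom, 3100, 5000): third,
            _intron(chrom, 5100, 8000): third,
        },
        "weights_r": {_intron(chrom, 2120, 8000): 1.0},
    }
    return g, exp


def _ptc_boundary(gid, chrom):
    """Junctions exactly 50 nt (NMDT) and 49 nt (not NMDT) downstream of the
    stop codon."""
    at50 = _tx(
        "N50", gid, chrom,
        [_U1, _U2, (4000, 4101), _D1], _START, (4048, 4051), "",
    )
    at49 = _tx(
        "N49", gid, chrom,
        [_U1, _U2, (4000, 4100), _D1], _START, (4048, 4051), "",
    )
    coding = _tx(
        "C1", gid, chrom, [_U1, _U2, _D1], _START, (8009, 8012), CODING_BIOTYPE
    )
    g = _gene(gid, chrom, [coding, at50, at49])
    return g, {"chrom": chrom, "nmdt": {"N50"}, "not_nmdt": {"N49"}}


SPECIAL_BUILDERS = {
    "hps1_like": _hps1_like,
    "erlec1_like": _erlec1_like,
    "fgfr2_like": _fgfr2_like,
    "utr3_ir": _utr3_ir,
    "start_anchor": _start_anchor,
    "nested_pe": _nested_pe,
    "ptc_boundary": _ptc_boundary,
}


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _mirror_interval(iv: GenomicInterval) -> GenomicInterval:
    return GenomicInterval(
        iv.chrom, CHROM_LEN - iv.end, CHROM_LEN - iv.start,
        "-" if iv.strand == "+" else "+",
    )


def mirror_gene(gene: Gene) -> Gene:
    """Reflect a fixture onto the opposite strand (coordinates mirrored)."""
    out = Gene(gene.gene_id, gene.chrom, "-" if gene.strand == "+" else "+")
    for tid, tx in gene.transcripts.items():
        m = Transcript(tid, tx.gene_id, tx.chrom, out.strand, biotype=tx.biotype)
        m.exons = [_mirror_interval(e) for e in tx.exons]
        if tx.start_codon:
            m.start_codon = _mirror_interval(tx.start_codon)
        if tx.stop_codon:
            m.stop_codon = _mirror_interval(tx.stop_codon)
        m.is_nmdt = tx.is_nmdt
        m.finalize()
        out.transcripts[tid] = m
    return out


def make_toy_gene(event_type: str, strand: str = "+"):
    """Build the fixture gene for an event type or pathological case.

    Returns (gene, expected).  ``expected`` bundles the ground truth the test
    suite compares against; for − strand fixtures only the gene is mirrored
    (codes and types are strand-symmetric; coordinate expectations refer to
    the + strand layout).
    """
    builders = {**TABLE_BUILDERS, **SPECIAL_BUILDERS}
    if event_type not in builders:
        raise ValueError(
            f"unknown fixture {event_type!r}; valid: {sorted(builders)}"
        )
    chrom = "chr_" + event_type.replace("+", "p")
    gene, exp = builders[event_type](f"G_{event_type}", chrom)
    if strand == "-":
        gene = mirror_gene(gene)
    return gene, exp


def all_fixture_genes(strand: str = "+") -> dict[str, tuple[Gene, dict]]:
    return {
        name: make_toy_gene(name, strand)
        for name in list(TABLE_BUILDERS) + list(SPECIAL_BUILDERS)
    }


# ---------------------------------------------------------------------------
# simulated junction counts
# ---------------------------------------------------------------------------


def simulate_counts(
    cluster: EventCluster,
    weights: IntronWeights,
    transcripts: list,
    true_psi: float,
    depth: int,
    seed: int,
):
    """Poisson split-read counts consistent with a ground-truth Ψ.

    The NMDT side carries an expected ``depth·Ψ`` weighted reads and the
    coding side ``depth·(1−Ψ)``; an intron carried by m of the M side
    transcripts gets expectation scaled by m/M (side transcripts are modeled
    as equally expressed), which makes the weighted sums unbiased for the
    target.  Reproducible for a fixed seed.
    """
    if not 0.0 <= true_psi <= 1.0:
        raise ValueError("true_psi must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    nm_txs = [t for t in transcripts if t.is_nmdt and set(t.introns()) & set(weights.k)]
    co_txs = [
        t for t in transcripts if not t.is_nmdt and set(t.introns()) & set(weights.r)
    ]
    counts: JunctionCounts = {}
    for side, txs, frac in ((weights.k, nm_txs, true_psi), (weights.r, co_txs, 1 - true_psi)):
        M = len(txs) or 1
        for intron in side:
            m = sum(1 for t in txs if intron in t.introns())
            lam = depth * frac * m / M
            counts[intron] = int(rng.poisson(lam))
    return counts


def random_transcript_pair(rng, max_exons: int = 4):
    """Two random transcripts drawn over a shared pool of splice-site
    boundaries (so sites can coincide), for splice-graph stress tests.

    With ``max_exons`` ≤ 4 the joint splicing graph has at most 12 splice-site
    nodes.  No codons are attached; the pair is meant for graph construction
    and bubble detection only.
    """
    pool = sorted(rng.choice(np.arange(100, 10000, 10), size=10, replace=False))
    txs = []
    for tid in ("TA", "TB"):
        k = int(rng.integers(1, max_exons + 1))
        bounds = sorted(rng.choice(len(pool), size=2 * k, replace=False))
        exons = [
            (int(pool[bounds[2 * i]]), int(pool[bounds[2 * i + 1]]))
            for i in range(k)
        ]
        txs.append(_tx(tid, "G", "chrR", exons, None, None, "", strand="+"))
    return txs[0], txs[1]


# ---------------------------------------------------------------------------
# fixture directory (GTF + counts + expectations) for CLI runs
# ---------------------------------------------------------------------------


def _intron_str(i: Intron) -> str:
    s1, e1 = i.start + 1, i.end
    return f"{i.chrom}:{s1}-{e1}:{i.strand}"


def write_fixture_dir(outdir: str, strand: str = "+") -> dict[str, str]:
    """Write a combined fixture annotation, a PE junction-count table and the
    expected classifications into ``outdir``; returns the file paths."""
    from .annotation import write_gtf

    os.makedirs(outdir, exist_ok=True)
    fixtures = all_fixture_genes(strand)
    genes = {name: g for name, (g, _) in fixtures.items()}
    gtf = os.path.join(outdir, "fixtures.gtf")
    write_gtf(list(genes.values()), gtf)

    counts = os.path.join(outdir, "counts.tsv")
    pe_gene, pe_exp = fixtures["PE"]
    with open(counts, "w") as fh:
        fh.write("chrom\tstrand\tstart\tend\tcount\n")
        for i in sorted(
            pe_exp["nmdt_introns"] | pe_exp["coding_introns"],
            key=lambda x: (x.start, x.end),
        ):
            if strand == "-":
                i = Intron(
                    i.chrom, CHROM_LEN - i.end, CHROM_LEN - i.start, "-"
                )
            fh.write(f"{i.chrom}\t{i.strand}\t{i.start + 1}\t{i.end}\t10\n")

    expected = os.path.join(outdir, "expected.json")
    payload = {
        name: {
            "type": exp.get("type"),
            "code": exp.get("code"),
            "nmdt_introns": sorted(
                _intron_str(i) for i in exp.get("nmdt_introns", set())
            ),
            "coding_introns": sorted(
                _intron_str(i) for i in exp.get("coding_introns", set())
            ),
        }
        for name, (_, exp) in fixtures.items()
    }
    with open(expected, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {"gtf": gtf, "counts": counts, "expected": expected}
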