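"""Ψ (percent-spliced-in) quantification of NMD-generating AS events.

For an event cluster with NMDT-supporting characteristic introns
``i = 1..A`` (split-read counts ``a_i``) and coding-supporting introns
``j = 1..B`` (counts ``b_j``),

    Ψ = Σ k_i·a_i / (Σ k_i·a_i + Σ r_j·b_j)

The weights ``k_i`` and ``r_j`` account for how many times each
characteristic intron occurs across the transcripts: the weights of the
characteristic introns of every transcript must sum to 1 (separately for
NMDT and coding transcripts).  That linear system is always consistent but
usually underdetermined; the weights are fixed by a nested-bubble heuristic
that assigns equal weights within each vertex-independent path, reproducing
the standard Ψ definitions for the simple event types.  When the paths are
not nested the minimum-norm solution of the constraint system is used and
the estimate is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import Intron, Transcript
from .events import EventCluster

logger = logging.getLogger("nmdsplice")

JunctionCounts = dict[Intron, int]


class NonNestedError(RuntimeError):
    """The heuristic's nestedness assumption does not hold for this cluster."""


class InfeasibleWeights(RuntimeError):
    """The weight constraint system is inconsistent (upstream bug)."""


@dataclass
class IntronWeights:
    k: dict[Intron, float]  # NMDT-supporting introns
    r: dict[Intron, float]  # coding-supporting introns
    solver: str = "heuristic"  # heuristic | min_norm

    def weight(self, intron: Intron) -> float:
        return self.k.get(intron) or self.r.get(intron) or 0.0


@dataclass
class PsiEstimate:
    cluster_id: str
    psi: float | None
    numerator: float
    denominator: float
    A: int
    B: int
    completeness: float
    solver: str
    counts: JunctionCounts = field(default_factory=dict)
    weights: IntronWeights | None = None


# ---------------------------------------------------------------------------
# the intron graph and the nested-bubble heuristic
# ---------------------------------------------------------------------------

_S, _T = "__source__", "__sink__"


def intron_graph(
    cluster: EventCluster, transcripts: list[Transcript], side: str = "nmdt"
) -> nx.DiGraph:
    """Graph with one side's characteristic introns as vertices; each
    transcript of that side carrying characteristic introns contributes a
    source→…→sink path through them in transcript order.

    The two sides are independent: NMDT transcripts constrain the
    NMDT-supporting introns (weights k) and coding transcripts the
    coding-supporting ones (weights r).
    """
    char = cluster.nmdt_introns if side == "nmdt" else cluster.coding_introns
    g = nx.DiGraph()
    g.add_node(_S)
    g.add_node(_T)
    for tx in transcripts:
        if bool(tx.is_nmdt) != (side == "nmdt"):
            continue
        path = [i for i in tx.introns() if i in char]
        if not path:
            continue
        nodes = [_S] + path + [_T]
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b)
        g.graph.setdefault("tx_paths", {})[tx.transcript_id] = path
    return g


@dataclass(eq=False)  # identity hash: each contracted bubble is unique
class _Merged:
    """A contracted bubble interior: parallel paths of inner nodes."""

    paths: list[list[object]]


def _mergeable(g: nx.DiGraph):
    """Find a vertex pair connected only by vertex-independent paths whose
    interiors have no edges leaving the bubble.  Returns (u, v, paths) or
    None."""
    for u in g.nodes:
        for v in g.nodes:
            if u == v:
                continue
            if not g.has_edge(u, v) and not any(
                True for _ in nx.all_simple_paths(g, u, v, cutoff=len(g))
            ):
                continue
            paths = list(nx.all_simple_paths(g, u, v, cutoff=len(g)))
            interiors = [p[1:-1] for p in paths]
            total = sum(len(i) for i in interiors)
            if total == 0:
                continue
            seen: set = set()
            ok = True
            for inter in interiors:
                for w in inter:
                    if w in seen:
                        ok = False
                        break
                    seen.add(w)
                if not ok:
                    break
            if not ok:
                continue
            # closure: interiors connect only within their own path
            for inter, p in zip(interiors, paths):
                allowed = set(p)
                for w in inter:
                    if not (set(g.predecessors(w)) | set(g.successors(w))) <= allowed:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            if total == 1 and len(paths) == 1:
                continue  # contracting a lone chain vertex achieves nothing
            return u, v, paths
    return None


def heuristic_nested_weights(g: nx.DiGraph) -> dict[Intron, float]:
    """Iterative bubble-merging weight assignment.

    Repeatedly contracts the interior of a bubble (a vertex pair connected
    only by vertex-independent paths) into a single node; within each path
    the vertices receive equal values summing to the value later assigned to
    the contracted node; the procedure ends when a single chain of parallel
    top-level paths remains, which receives the value 1.  Raises
    :class:`NonNestedError` when no contraction sequence exists.
    """
    g = g.copy()
    while True:
        found = _mergeable(g)
        if found is None:
            break
        u, v, paths = found
        interiors = [p[1:-1] for p in paths]
        node = _Merged(interiors)
        for inter in interiors:
            g.remove_nodes_from(inter)
        g.add_edge(u, node)
        g.add_edge(node, v)

    top = list(nx.all_simple_paths(g, _S, _T, cutoff=len(g)))
    seen: set = set()
    for p in top:
        for w in p[1:-1]:
            if w in seen:
                raise NonNestedError("vertex-independent paths are not nested")
            seen.add(w)
    if set(g.nodes) - {_S, _T} - seen:
        raise NonNestedError("unreachable vertices after contraction")

    weights: dict[Intron, float] = {}

    def assign(node, value: float) -> None:
        if isinstance(node, _Merged):
            for path in node.paths:
                if not path:
                    continue
                for x in path:
                    assign(x, value / len(path))
        else:
            weights[node] = value

    for p in top:
        inter = p[1:-1]
        if not inter:
            continue
        for x in inter:
            assign(x, 1.0 / len(inter))
    return weights


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def _min_norm_side(
    introns: list[Intron], transcripts: list[list[Intron]]
) -> dict[Intron, float]:
    """Minimum-Euclidean-norm solution of the per-transcript sum-to-1 system."""
    if not introns:
        return {}
    idx = {i: j for j, i in enumerate(introns)}
    rows = [t for t in transcripts if t]
    A = np.zeros((len(rows), len(introns)))
    for ri, t in enumerate(rows):
        for i in t:
            A[ri, idx[i]] = 1.0
    b = np.ones(len(rows))
    x, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if not np.allclose(A @ x, b, atol=1e-8):
        raise InfeasibleWeights("weight constraint system is inconsistent")
    return {i: float(x[idx[i]]) for i in introns}


def solve_weights(
    cluster: EventCluster, transcripts: list[Transcript]
) -> IntronWeights:
    """Per-intron weights for a cluster.

    ``transcripts`` are all transcripts of the gene (NMDTs and coding); only
    those carrying characteristic introns enter the constraint system.
    """
    if not (cluster.nmdt_introns or cluster.coding_introns):
        raise ValueError("cluster has no characteristic introns")

    def _min_norm() -> dict[Intron, float]:
        nm_paths = [
            [i for i in t.introns() if i in cluster.nmdt_introns]
            for t in transcripts
            if t.is_nmdt
        ]
        co_paths = [
            [i for i in t.introns() if i in cluster.coding_introns]
            for t in transcripts
            if not t.is_nmdt
        ]
        w = _min_norm_side(_sorted_introns(cluster.nmdt_introns), nm_paths)
        w.update(_min_norm_side(_sorted_introns(cluster.coding_introns), co_paths))
        return w

    try:
        w = heuristic_nested_weights(intron_graph(cluster, transcripts, "nmdt"))
        w.update(
            heuristic_nested_weights(intron_graph(cluster, transcripts, "coding"))
        )
        k = {i: w[i] for i in cluster.nmdt_introns if i in w}
        r = {i: w[i] for i in cluster.coding_introns if i in w}
        _check_sums(transcripts, k, r)
        return IntronWeights(k, r, "heuristic")
    except (NonNestedError, InfeasibleWeights) as exc:
        logger.warning(
            "cluster %s: %s; falling back to the minimum-norm solution",
            cluster.cluster_id,
            exc,
        )
    w = _min_norm()
    k = {i: w[i] for i in cluster.nmdt_introns if i in w}
    r = {i: w[i] for i in cluster.coding_introns if i in w}
    _check_sums(transcripts, k, r)
    return IntronWeights(k, r, "min_norm")


def _sorted_introns(introns) -> list[Intron]:
    return sorted(introns, key=lambda i: (i.start, i.end))


def _check_sums(transcripts, k, r, tol=1e-6) -> None:
    """Per-transcript, per-side sum-to-1 check of the solved weights."""
    for tx in transcripts:
        side = k if tx.is_nmdt else r
        own = [side[i] for i in tx.introns() if i in side]
        if own and abs(sum(own) - 1.0) > tol:
            raise InfeasibleWeights(
                f"weights of transcript {tx.transcript_id} sum to {sum(own)}"
            )


# ---------------------------------------------------------------------------
# Ψ
# ---------------------------------------------------------------------------


def compute_psi(
    cluster: EventCluster,
    counts: JunctionCounts,
    weights: IntronWeights,
) -> PsiEstimate:
    """Weighted percent-spliced-in for a cluster.

    Counts missing for an annotated characteristic intron default to 0; the
    fraction of introns with observed counts is reported as completeness.
    Ψ is undefined (None) when both weighted sums are zero.
    """
    num = 0.0
    den_cod = 0.0
    present = 0
    used: JunctionCounts = {}
    for i, w in weights.k.items():
        c = counts.get(i)
        if c is not None:
            if c < 0:
                raise ValueError(f"negative count for intron {i}")
            present += 1
        used[i] = c or 0
        num += w * (c or 0)
    for j, w in weights.r.items():
        c = counts.get(j)
        if c is not None:
            if c < 0:
                raise ValueError(f"negative count for intron {j}")
            present += 1
        used[j] = c or 0
        den_cod += w * (c or 0)
    denom = num + den_cod
    total = len(weights.k) + len(weights.r)
    return PsiEstimate(
        cluster_id=cluster.cluster_id,
        psi=(num / denom) if denom > 0 else None,
        numerator=num,
        denominator=denom,
        A=cluster.A,
        B=cluster.B,
        completeness=present / total if total else 0.0,
        solver=weights.solver,
        counts=used,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------

_COLS = ["chrom", "strand", "start", "end", "count"]


def read_counts_table(
    path: str, zero_based: bool = False
) -> JunctionCounts:
    """Read a split-read junction count table.

    Expected TSV columns: chromosome, strand, intron start, intron end, read
    count; 1-based inclusive intron coordinates by default (``zero_based``
    switches to the half-open convention).  A header row is detected and
    skipped; duplicate intron rows are summed with a warning; unparsable rows
    are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 5:
        raise ValueError(f"{path}: expected ≥5 tab-separated columns")
    df = df.iloc[:, :5]
    df.columns = _COLS
    counts: JunctionCounts = {}
    dups = 0
    for row in df.itertuples(index=False):
        try:
            start, end, n = int(row.start), int(row.end), int(row.count)
        except (TypeError, ValueError):
            if row != tuple(_COLS):  # tolerate a header row silently
                logger.warning("%s: unparsable row %r skipped", path, tuple(row))
            continue
        if row.strand not in ("+", "-"):
            logger.warning("%s: bad strand %r skipped", path, row.strand)
            continue
        if not zero_based:
            start -= 1
        if n < 0:
            raise ValueError(f"{path}: negative count for {row.chrom}:{start}-{end}")
        intron = Intron(str(row.chrom), start, end, row.strand)
        if intron in counts:
            dups += 1
        counts[intron] = counts.get(intron, 0) + n
    if dups:
        logger.warning("%s: %d duplicate intron rows were summed", path, dups)
    return counts


def quantify_cluster(
    cluster: EventCluster,
    transcripts: list[Transcript],
    counts: JunctionCounts,
) -> PsiEstimate:
    """Solve weights and compute Ψ for one cluster."""
    weights = solve_weights(cluster, transcripts)
    return compute_psi(cluster, counts, weights)
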