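"""End-to-end orchestration: annotation → NMDT flags → events → types → Ψ.

The pipeline is deterministic: given identical inputs and configuration the
primary output tables are byte-identical (all iteration orders are sorted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import annotation, classify, events, orf, quantify

logger = logging.getLogger("nmdsplice")


@dataclass
class RunConfig:
    annotation_path: str
    secondary_path: str | None = None
    genome_fasta: str | None = None
    reference: str = "all_coding"  # all_coding | mane | file:<path>
    ptc_threshold: int = orf.PTC_THRESHOLD
    counts_path: str | None = None
    counts_zero_based: bool = False

    def validate(self) -> None:
        if self.secondary_path and not self.genome_fasta:
            raise ValueError(
                "a secondary annotation requires --genome-fasta for ORF inference"
            )
        if self.reference.startswith("file:"):
            path = self.reference[5:]
            with open(path):
                pass
        elif self.reference not in ("all_coding", "mane"):
            raise ValueError(
                f"unknown reference mode {self.reference!r}; "
                "use all_coding, mane or file:<path>"
            )


@dataclass
class RunResult:
    genes: dict[str, annotation.Gene]
    events: dict[str, list[events.EventDef]] = field(default_factory=dict)
    undetected: dict[str, list[events.Undetected]] = field(default_factory=dict)
    clusters: dict[str, list[events.EventCluster]] = field(default_factory=dict)
    classifications: dict[str, list[classify.Classification]] = field(default_factory=dict)
    psi: dict[str, quantify.PsiEstimate] = field(default_factory=dict)
    counts_matched: int = 0
    counts_total: int = 0


def _reference_ids(config: RunConfig, gene: annotation.Gene) -> list[str] | None:
    if config.reference == "all_coding":
        return None
    if config.reference == "mane":
        ids = [
            t.transcript_id
            for t in gene.coding
            if "MANE_Select" in t.tags
        ]
        return ids or None  # genes without a MANE transcript: all coding
    path = config.reference[5:]
    with open(path) as fh:
        wanted = {line.strip().split(".")[0] for line in fh if line.strip()}
    ids = [
        t.transcript_id
        for t in gene.coding
        if t.transcript_id.split(".")[0] in wanted
    ]
    return ids or None


def run(config: RunConfig) -> RunResult:
    config.validate()
    genes = annotation.parse_annotation(config.annotation_path)

    if config.secondary_path:
        import pyfaidx

        secondary = annotation.parse_annotation(config.secondary_path)
        sec_txs = [
            t for g in secondary.values() for t in g.transcripts.values()
        ]
        unassigned = annotation.assign_secondary(genes, sec_txs)
        if unassigned:
            logger.info("%d secondary transcripts unassigned", len(unassigned))
        genome = pyfaidx.Fasta(config.genome_fasta)
        for gene in genes.values():
            starts = gene.start_codons
            for tx in gene.transcripts.values():
                if tx.start_codon is None and starts:
                    call = orf.find_orf(tx, genome, starts)
                    if call is not None:
                        orf.apply_orf(tx, call)

    for gene in genes.values():
        orf.annotate_gene(gene, config.ptc_threshold)
    genes = annotation.filter_genes(genes)

    result = RunResult(genes=genes)
    counts = (
        quantify.read_counts_table(config.counts_path, config.counts_zero_based)
        if config.counts_path
        else None
    )

    for gid in sorted(genes):
        gene = genes[gid]
        evs, und = events.find_events(gene)
        result.events[gid] = evs
        result.undetected[gid] = und
        clusters = events.cluster_events(evs, gid)
        result.clusters[gid] = clusters
        ref_ids = _reference_ids(config, gene)
        txs = sorted(gene.coding + gene.nmdts, key=lambda t: t.transcript_id)
        for cl in clusters:
            result.classifications[cl.cluster_id] = classify.classify_event(
                cl, gene, ref_ids
            )
            if counts is not None:
                if cl.A == 0 and cl.B > 0:
                    # retention-only cluster: split reads alone cannot
                    # evidence the NMDT side
                    weights = quantify.solve_weights(cl, txs)
                    est = quantify.compute_psi(cl, counts, weights)
                    est.psi = None
                    result.psi[cl.cluster_id] = est
                else:
                    result.psi[cl.cluster_id] = quantify.quantify_cluster(
                        cl, txs, counts
                    )
    if counts is not None:
        annotated = {
            i
            for gene in genes.values()
            for t in gene.transcripts.values()
            for i in t.introns()
        }
        result.counts_total = len(counts)
        result.counts_matched = sum(1 for i in counts if i in annotated)
    return result


# ---------------------------------------------------------------------------
# tabular export (1-based inclusive coordinates throughout)
# ---------------------------------------------------------------------------


def _fmt_intron(i) -> str:
    return f"{i.chrom}:{i.start + 1}-{i.end}:{i.strand}"


def write_nmdt_table(result: RunResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tbiotype\tis_nmdt\n")
        for gid in sorted(result.genes):
            gene = result.genes[gid]
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                fh.write(f"{gid}\t{tid}\t{tx.biotype}\t{int(bool(tx.is_nmdt))}\n")


def write_cluster_table(result: RunResult, path: str, undetected_path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tgene_id\tnmdt_ids\tchrom\tstart\tend\tstrand\t"
            "A\tB\tnmdt_introns\tcoding_introns\n"
        )
        for gid in sorted(result.clusters):
            for cl in result.clusters[gid]:
                span = cl.span
                nm = ",".join(sorted(_fmt_intron(i) for i in cl.nmdt_introns))
                co = ",".join(sorted(_fmt_intron(i) for i in cl.coding_introns))
                fh.write(
                    f"{cl.cluster_id}\t{gid}\t{','.join(cl.nmdt_ids)}\t"
                    f"{span.chrom}\t{span.start + 1}\t{span.end}\t{span.strand}\t"
                    f"{cl.A}\t{cl.B}\t{nm}\t{co}\n"
                )
    with open(undetected_path, "w") as fh:
        fh.write("gene_id\tnmdt_id\treason\n")
        for gid in sorted(result.undetected):
            for u in result.undetected[gid]:
                fh.write(f"{gid}\t{u.nmdt_id}\t{u.reason}\n")


def write_classification_table(result: RunResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tnmdt_id\treference_id\tcode\ttype\tn\tsynonym\t"
            "n_characteristic\theadline\treference_free\n"
        )
        for cid in sorted(result.classifications):
            rows = result.classifications[cid]
            if not rows:
                continue
            head = classify.headline(rows)
            for c in rows:
                fh.write(
                    f"{c.cluster_id}\t{c.nmdt_id}\t{c.reference_id}\t"
                    f"{c.event_type.code}\t{c.event_type.name}\t{c.event_type.n}\t"
                    f"{c.event_type.synonym}\t{c.n_characteristic}\t"
                    f"{int(c is head)}\t{int(c.reference_free)}\n"
                )


def write_psi_table(result: RunResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tpsi\tnumerator\tdenominator\tA\tB\tcompleteness\tsolver\n"
        )
        for cid in sorted(result.psi):
            e = result.psi[cid]
            psi = "NA" if e.psi is None else f"{e.psi:.6g}"
            fh.write(
                f"{cid}\t{psi}\t{e.numerator:.6g}\t{e.denominator:.6g}\t"
                f"{e.A}\t{e.B}\t{e.completeness:.4g}\t{e.solver}\n"
            )
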