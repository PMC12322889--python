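"""Intron weights and Ψ quantification."""

import numpy as np
import pytest

from nmdsplice.annotation import Intron
from nmdsplice.quantify import (
    compute_psi,
    heuristic_nested_weights,
    intron_graph,
    read_counts_table,
    solve_weights,
)
from nmdsplice.synthetic import TABLE_BUILDERS, simulate_counts
from tests.conftest import prepared_gene, single_cluster


def _solved(name):
    gene, exp = prepared_gene(name)
    cluster = single_cluster(gene)
    txs = sorted(
        gene.coding + gene.nmdts, key=lambda t: t.transcript_id
    )
    return gene, cluster, txs, solve_weights(cluster, txs), exp


class TestWeights:
    def test_poison_exon_worked_example(self):
        """Inclusion-path introns weigh 0.5 each; the skipping intron 1."""
        _, cluster, _, w, exp = _solved("PE")
        assert w.solver == "heuristic"
        assert {i: round(v, 12) for i, v in w.k.items()} == exp["weights_k"]
        assert {i: round(v, 12) for i, v in w.r.items()} == exp["weights_r"]

    def test_essential_exon_mirror(self):
        _, _, _, w, exp = _solved("EE")
        assert list(w.k.values()) == [1.0]
        assert sorted(w.r.values()) == [0.5, 0.5]

    def test_single_intron_sides(self):
        _, _, _, w, _ = _solved("A5SS")
        assert list(w.k.values()) == [1.0]
        assert list(w.r.values()) == [1.0]

    def test_pen_equal_thirds(self):
        _, _, _, w, _ = _solved("PEn")
        assert all(abs(v - 1 / 3) < 1e-12 for v in w.k.values())
        assert list(w.r.values()) == [1.0]

    def test_nested_double_bubble(self):
        """The outer path value multiplies into the inner-path weights."""
        _, _, _, w, exp = _solved("nested_pe")
        assert w.solver == "heuristic"
        for intron, want in exp["weights_k"].items():
            assert w.k[intron] == pytest.approx(want, abs=1e-12)
        assert list(w.r.values()) == [1.0]

    @pytest.mark.parametrize(
        "name", sorted(set(TABLE_BUILDERS) | {"nested_pe", "hps1_like", "fgfr2_like"})
    )
    def test_per_transcript_sums_to_one(self, name):
        gene, cluster, txs, w, _ = _solved(name)
        for tx in txs:
            side = w.k if tx.is_nmdt else w.r
            own = [side[i] for i in tx.introns() if i in side]
            if own:
                assert sum(own) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("name", sorted(TABLE_BUILDERS))
    def test_heuristic_matches_exact_solution_when_unique(self, name):
        """Where the per-side constraint system has a unique solution, the
        heuristic reproduces the linear-algebra solution to 1e-9."""
        gene, cluster, txs, w, _ = _solved(name)
        for side_introns, side_w, is_nmdt in (
            (cluster.nmdt_introns, w.k, True),
            (cluster.coding_introns, w.r, False),
        ):
            if not side_introns:
                continue
            introns = sorted(side_introns, key=lambda i: (i.start, i.end))
            rows = [
                [1.0 if i in t.introns() else 0.0 for i in introns]
                for t in txs
                if bool(t.is_nmdt) == is_nmdt
                and set(t.introns()) & set(introns)
            ]
            A = np.array(rows)
            if np.linalg.matrix_rank(A) < len(introns):
                continue  # underdetermined: the heuristic's choice is free
            x, *_ = np.linalg.lstsq(A, np.ones(len(rows)), rcond=None)
            for i, xi in zip(introns, x):
                assert side_w[i] == pytest.approx(xi, abs=1e-9)

    def test_no_characteristic_introns_rejected(self):
        gene, cluster, txs, w, _ = _solved("PE")
        from nmdsplice.events import EventCluster

        empty = EventCluster("x", [])
        with pytest.raises(Exception):
            solve_weights(empty, txs)


class TestMinNormFallback:
    def test_crossing_paths_fall_back_to_min_norm(self):
        """Overlapping (non-nested) alternative choices defeat the bubble
        heuristic; the minimum-norm solution still satisfies the sums."""
        from nmdsplice.annotation import GenomicInterval, Transcript
        from nmdsplice.events import EventCluster, EventDef

        def tx(tid, exons):
            t = Transcript(tid, "G", "c", "+")
            t.exons = [GenomicInterval("c", s, e, "+") for s, e in exons]
            t.finalize()
            t.is_nmdt = True
            return t

        # i1/i2 are alternative first introns, i3/i4 alternative second ones;
        # the observed combinations (i1,i3), (i1,i4), (i2,i4) cross
        n1 = tx("N1", [(0, 100), (200, 300), (400, 500)])   # i1, i3
        n2 = tx("N2", [(0, 100), (200, 320), (400, 500)])   # i1, i4
        n3 = tx("N3", [(0, 100), (250, 320), (400, 500)])   # i2, i4
        introns = frozenset(i for t in (n1, n2, n3) for i in t.introns())
        ev = EventDef("N1", GenomicInterval("c", 0, 500, "+"), introns,
                      frozenset(), "shared_splice_site", "ptc_exon_end")
        cluster = EventCluster("x", [ev])
        w = solve_weights(cluster, [n1, n2, n3])
        assert w.solver == "min_norm"
        for t in (n1, n2, n3):
            assert sum(w.k[i] for i in t.introns()) == pytest.approx(1.0, abs=1e-9)
        # the symmetric crossing pattern makes every weight 0.5
        assert all(v == pytest.approx(0.5) for v in w.k.values())


class TestHeuristicGraph:
    def test_pe_graph_direct(self):
        gene, _ = prepared_gene("PE")
        cluster = single_cluster(gene)
        txs = gene.coding + gene.nmdts
        w = heuristic_nested_weights(intron_graph(cluster, txs, "nmdt"))
        assert sorted(w.values()) == [0.5, 0.5]
        w = heuristic_nested_weights(intron_graph(cluster, txs, "coding"))
        assert list(w.values()) == [1.0]


class TestPsi:
    def test_pe_arithmetic(self, pe_cluster):
        gene, cluster, _ = pe_cluster
        txs = gene.coding + gene.nmdts
        w = solve_weights(cluster, txs)
        counts = {i: 10 for i in cluster.nmdt_introns | cluster.coding_introns}
        est = compute_psi(cluster, counts, w)
        assert est.psi == pytest.approx(0.5)
        assert est.numerator == pytest.approx(10.0)
        assert est.denominator == pytest.approx(20.0)
        assert est.completeness == 1.0

    def test_zero_coding_counts_gives_one(self, pe_cluster):
        gene, cluster, _ = pe_cluster
        w = solve_weights(cluster, gene.coding + gene.nmdts)
        counts = {i: 7 for i in cluster.nmdt_introns}
        est = compute_psi(cluster, counts, w)
        assert est.psi == pytest.approx(1.0)

    def test_all_zero_undefined(self, pe_cluster):
        gene, cluster, _ = pe_cluster
        w = solve_weights(cluster, gene.coding + gene.nmdts)
        est = compute_psi(cluster, {}, w)
        assert est.psi is None
        assert est.completeness == 0.0

    def test_negative_count_rejected(self, pe_cluster):
        gene, cluster, _ = pe_cluster
        w = solve_weights(cluster, gene.coding + gene.nmdts)
        bad = {next(iter(cluster.nmdt_introns)): -1}
        with pytest.raises(ValueError):
            compute_psi(cluster, bad, w)

    def test_monotonicity(self, pe_cluster):
        """Ψ is non-decreasing in NMDT-side counts and non-increasing in
        coding-side counts."""
        gene, cluster, _ = pe_cluster
        w = solve_weights(cluster, gene.coding + gene.nmdts)
        rng = np.random.default_rng(7)
        base = {
            i: int(rng.integers(1, 50))
            for i in cluster.nmdt_introns | cluster.coding_introns
        }
        psi0 = compute_psi(cluster, base, w).psi
        for i in cluster.nmdt_introns:
            up = {**base, i: base[i] + 10}
            assert compute_psi(cluster, up, w).psi >= psi0
        for j in cluster.coding_introns:
            up = {**base, j: base[j] + 10}
            assert compute_psi(cluster, up, w).psi <= psi0


class TestCountsTable:
    def _write(self, tmp_path, rows, header=True):
        p = tmp_path / "counts.tsv"
        lines = (["chrom\tstrand\tstart\tend\tcount"] if header else []) + rows
        p.write_text("\n".join(lines) + "\n")
        return str(p)

    def test_matching_rows(self, tmp_path, pe_cluster):
        gene, cluster, _ = pe_cluster
        rows = [
            f"{i.chrom}\t{i.strand}\t{i.start + 1}\t{i.end}\t10"
            for i in cluster.nmdt_introns | cluster.coding_introns
        ]
        counts = read_counts_table(self._write(tmp_path, rows))
        matched = [i for i in cluster.nmdt_introns | cluster.coding_introns
                   if i in counts]
        assert len(matched) == 3

    def test_wrong_strand_unmatched(self, tmp_path, pe_cluster):
        gene, cluster, _ = pe_cluster
        i = next(iter(cluster.coding_introns))
        counts = read_counts_table(
            self._write(tmp_path, [f"{i.chrom}\t-\t{i.start + 1}\t{i.end}\t10"])
        )
        assert i not in counts

    def test_duplicates_summed(self, tmp_path):
        rows = ["c\t+\t101\t200\t4", "c\t+\t101\t200\t6"]
        counts = read_counts_table(self._write(tmp_path, rows, header=False))
        assert counts[Intron("c", 100, 200, "+")] == 10

    def test_zero_based_dialect(self, tmp_path):
        rows = ["c\t+\t100\t200\t4"]
        counts = read_counts_table(
            self._write(tmp_path, rows, header=False), zero_based=True
        )
        assert counts[Intron("c", 100, 200, "+")] == 4

    def test_unparsable_row_skipped(self, tmp_path):
        rows = ["c\t+\tfoo\t200\t4", "c\t+\t101\t200\t4"]
        counts = read_counts_table(self._write(tmp_path, rows, header=False))
        assert len(counts) == 1


class TestRecovery:
    def test_large_depth_recovers_psi(self, pe_cluster):
        """At depth 1e5 a simulated Ψ*=0.5 is recovered within 0.01."""
        gene, cluster, _ = pe_cluster
        txs = gene.coding + gene.nmdts
        w = solve_weights(cluster, txs)
        counts = simulate_counts(cluster, w, txs, 0.5, depth=100_000, seed=11)
        est = compute_psi(cluster, counts, w)
        assert est.psi == pytest.approx(0.5, abs=0.01)

    def test_psi_zero_means_no_nmdt_reads(self, pe_cluster):
        gene, cluster, _ = pe_cluster
        txs = gene.coding + gene.nmdts
        w = solve_weights(cluster, txs)
        counts = simulate_counts(cluster, w, txs, 0.0, depth=1000, seed=3)
        assert all(counts[i] == 0 for i in cluster.nmdt_introns)

    def test_seed_reproducible(self, pe_cluster):
        gene, cluster, _ = pe_cluster
        txs = gene.coding + gene.nmdts
        w = solve_weights(cluster, txs)
        c1 = simulate_counts(cluster, w, txs, 0.3, depth=1000, seed=5)
        c2 = simulate_counts(cluster, w, txs, 0.3, depth=1000, seed=5)
        assert c1 == c2

    def test_invalid_psi_rejected(self, pe_cluster):
        gene, cluster, _ = pe_cluster
        txs = gene.coding + gene.nmdts
        w = solve_weights(cluster, txs)
        with pytest.raises(ValueError):
            simulate_counts(cluster, w, txs, 1.5, depth=100, seed=0)
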