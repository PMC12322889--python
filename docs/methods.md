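# Methods

## Model overview

The package treats an NMD-generating alternative-splicing event as a *set of
characteristic introns* that discriminate an NMD target (NMDT) from the
protein-coding transcripts of its gene, localized to a genomic interval of
interest. This local-event model deliberately trades completeness for
interpretability: it captures cassette exons, alternative splice sites,
intron retention/excision and their compounds, but cannot capture NMD caused
by *coordination* of distant splicing decisions (where no single local event
is causal) — see Limitations.

### NMD-target annotation (50-nt rule)

A transcript with an annotated or inferred stop codon is an NMDT when some
exon–exon junction lies at least `ptc_threshold` nucleotides downstream of
the stop in mRNA coordinates. The distance is measured from the **last base
of the stop codon** to the junction, matching the mechanistic rationale:
exon-junction complexes deposited ≥ 50 nt past the stop survive the pioneer
round of translation. The threshold defaults to 50 nt (the value Ensembl
uses for automatic annotation) and is configurable (`--ptc-threshold`, e.g.
55 for the stricter variant). Transcripts already biotyped
`nonsense_mediated_decay` keep that label; the rule is applied to everything
else with a stop codon. The call is monotone in the threshold by
construction.

ORFs for secondary (annotation-free) transcript models are inferred from the
genome: among reading frames opened at any of the gene's annotated start
codons that fall in the transcript's exons, the longest one terminated by an
in-frame stop wins; length ties go to the 5'-most start (canonical
initiation). Secondary transcripts are first assigned to the gene with the
most shared introns, requiring ≥ 50 % of the *transcript's* exonic length to
overlap the gene's exonic span (one-sided denominator: monotone in
assignment confidence); ties break by larger overlap, then lexicographic
gene id, with a logged warning.

### Interval of interest

* 5' boundary: the 3'-most splice site shared — same genomic position, same
  donor/acceptor kind, same reading-frame phase — between the NMDT and any
  coding transcript of the gene. Phases are offsets from each transcript's
  own start codon mod 3, defined only inside the ORF; sites 5' of the start
  or 3' of the stop have no phase and cannot anchor. If no such site exists,
  the shared start codon (full-codon identity) anchors the interval; if
  neither exists, the NMDT is reported in the *undetected* class.
* 3' boundary: the 3' end of the exon containing the premature stop; if the
  NMDT's stop codon is shared with a coding transcript (NMD by 3'-UTR
  structure rather than a true PTC), the nearest transcript end downstream
  of the stop.

### Characteristic introns and clusters

All introns of the NMDT and of every coding transcript that overlap the
closed interval **or abut it** (a splice site coinciding with an interval
boundary counts — the flanking introns of a poison exon only touch the
interval at the shared donor) are collected; introns present in both the
NMDT and at least one coding transcript are removed; the remainder is
partitioned by origin into NMDT-supporting (A) and coding-supporting (B)
sides. Intron identity is (chromosome, strand, donor, acceptor); annotation
duplicates collapse. Events sharing at least one characteristic intron are
merged into clusters by union-find; clustering is order-independent and the
cluster's A and B are recomputed on the union sets. An event with no
characteristic introns on either side joins the undetected class.

### Classification by splice-graph bubbles

For an (NMDT, reference) pair, both transcripts' splice sites become nodes
of a directed acyclic splicing graph (exons are acceptor→donor edges,
introns donor→acceptor edges, 5'→3'). Node chains are restricted to the
sites of introns overlapping or abutting the cluster span, then extended by
one shared site on each flank so bubbles can close just outside the span.
A *bubble* is the pair of sub-paths between consecutive shared nodes whose
interiors differ; interiors are vertex-disjoint by construction, making the
pair vertex-independent, and only bubbles containing at least one
characteristic intron are reported. The concatenated D/A labels
(`nmdt_path:ref_path`, NMDT first) are matched against the type catalogue —
fixed codes first (PE `DADA:DA`, EE `DA:DADA`, A5SS `ADA:ADA`, A3SS
`DAD:DAD`, A5SS+A3SS `ADAD:ADAD`, IR `AD:ADAD`, ID `ADAD:AD`, MXE
`DADA:DADA`), then parametric families with `(AD)n` repeats (PEn, EEn,
A5SS+PEn, A5SS+EEn, PEn+A3SS, EEn+A3SS, A5SS+EE+A3SS) with n extracted from
the match. Unmatched codes map to `other` with the raw code preserved.

Reference resolution: MANE-Select (from `tag "MANE_Select"` attributes), a
user-supplied ID list, or — by default — every protein-coding transcript
iteratively. When the chosen references produce no bubble (typical of 3'-UTR
events that do not intersect the MANE isoform), the nearest coding
transcript spanning the event is tried; failing that the call is
reference-free. Open-ended bubbles (transcripts that never reconverge, e.g.
diverging 3' ends) that match no catalogue row are resolved from the intron
balance: only reference-path introns → the NMDT retains them → IR; only
NMDT-path introns → ID; this is a design choice where the procedure was
genuinely open, and such calls carry the raw truncated code. When a cluster
yields several codes, the headline call is the one containing the most
characteristic introns, ties broken by longer code.

### Weights and Ψ

Ψ = Σᵢ kᵢaᵢ / (Σᵢ kᵢaᵢ + Σⱼ rⱼbⱼ) with per-intron weights constrained so
that, for every transcript, the weights of its characteristic introns sum
to 1. The NMDT side (k, over NMDT transcripts) and the coding side (r, over
coding transcripts) are solved independently. The constraint system is
consistent by construction but usually underdetermined; weights are fixed by
the nested-bubble heuristic: characteristic introns of one side form a
graph (introns as vertices, connecting exon groups as edges, plus a global
source and sink); repeatedly find a vertex pair connected only by
vertex-independent paths, give each path's vertices equal values summing to
the value of the bubble, contract the interior into one node, and multiply
inner values through when the node's own value is assigned; at the top level
the value is 1. For a poison exon this yields 0.5/0.5 against 1; for a
cassette exon nested in a larger alternative region the outer path value
(1/3) multiplies into the inner weights (1/6). The heuristic assumes all
vertex-independent paths are nested; otherwise — or if its output violates a
per-transcript sum, which degenerate subset configurations can force — the
minimum-Euclidean-norm solution of the constraint system is used instead and
flagged (`solver=min_norm`). Solved weights are always validated against the
sum-to-1 constraints (tolerance 1e-6 at the validation boundary; the
solutions themselves are exact to ~1e-12).

Counts come from an IPSA-like TSV (chromosome, strand, intron start, intron
end, count; 1-based inclusive by default, half-open via a dialect flag);
introns match the annotation exactly by (chrom, strand, donor, acceptor);
duplicate rows are summed and unmatched rows tallied. Counts missing for an
annotated characteristic intron default to 0, with the observed fraction
reported as `completeness`. Ψ is undefined (NA) when both weighted sums are
zero, and clusters with A = 0 (pure retention: no NMDT-side junction exists)
are reported non-quantifiable from split reads alone.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `ptc_threshold` | 50 nt | junction–stop distance that triggers the NMDT call |
| `reference` | `all_coding` | classification reference: `mane`, `file:<ids>`, or all coding isoforms |
| secondary overlap | 0.5 | minimum fraction of a secondary transcript's exonic length covered by the gene |
| counts dialect | 1-based inclusive | junction table coordinate convention |

## The synthetic data generator

`nmdsplice.synthetic` builds one toy gene per catalogue type on a common
scaffold (constitutive ~120-nt exons around a variable event region, start
codon at the 5' end, normal stop in the last exon), with every codon
placement frame-consistent and every junction–stop distance engineered to
the intended side of the 50-nt rule; exon sizes ≥ 100 nt keep the rule
unambiguous, and a dedicated boundary fixture places junctions at exactly 50
and 49 nt. Pathological fixtures cover compensated exon skipping (the event
is the junction of the frame-disrupting exons, not the skipped exon),
coordinated distant exons with an alternative start (the undetected class),
mutually exclusive exons with a double-inclusion NMDT, a 3'-UTR retention
event, and a start-codon-anchored interval. Fixtures mirror exactly onto the
− strand for strand-symmetry tests.

Simulated junction counts are independent Poisson draws per intron with
expectation `depth·Ψ·m/M` on the NMDT side (and `depth·(1−Ψ)·m/M` on the
coding side), where m of the side's M transcripts carry the intron — i.e.
side transcripts are modeled as equally expressed, which makes the weighted
sums unbiased for the target. This emulates the *counting* statistics of
split reads, not their generation: no read-level sampling, no mappability or
GC bias, no overdispersion between introns of one transcript, and toy genes
lack the annotation redundancy, overlapping genes and biotype noise of real
transcriptomes. Passing tests therefore demonstrate correctness of the
method's logic and estimator consistency under the stated noise model, not
robustness to alignment artifacts.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GTF conversion happens only
  at I/O and round-trips exactly. All 5'/3' logic runs through a single
  strand-aware comparator; the − strand is handled by mirrored comparisons,
  never coordinate negation.
* ORF-length ties choose the 5'-most start; secondary-assignment ties the
  larger overlap, then lexicographic gene id.
* Degenerate interval (5' and 3' boundaries coincide) is widened to 1 bp so
  abutment tests stay well-defined.
* Shared splice sites appearing in different orders in the two transcripts
  cannot occur for genomically sorted chains; the guard logs and returns no
  bubbles rather than emitting non-alternating codes.
* Single-exon transcripts have no introns, no splice sites and can never be
  NMDTs; they participate only as potential references (no sites → no
  bubble → fallback).

## Limitations

* Coordinated distant splicing events are out of reach by design: when only
  the joint state of distant exons determines the reading frame, no local
  characteristic-intron set exists and the NMDT lands in the undetected
  output (the coordinated-exons fixture demonstrates this).
* At cluster level an NMDT can carry a *coding-supporting* characteristic
  intron contributed by another member's event; Ψ treats each intron once,
  by side, which is the method's cluster-level approximation.
* Retention-only clusters (A = 0) cannot be quantified from split reads;
  exonic coverage would be needed.
* The classification of open-ended 3'-UTR bubbles (IR/ID from the intron
  balance) is a convention; such calls are flagged reference-free or carry
  truncated codes for downstream filtering.
* NMD rules other than the junction rule (long 3'-UTRs, uORFs,
  selenocysteine recoding) are out of scope.
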