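# nmdsplice

Alternative splicing frequently produces transcripts that are not translated
into protein but degraded by nonsense-mediated decay (NMD) — so-called NMD
targets (NMDTs). Cells use this *unproductive splicing* to regulate gene
expression: a splicing switch toward an NMDT-producing isoform lowers the
protein output of a gene. Characterizing which local splicing event turns a
transcript into an NMD target, and how strongly that event is used, is the
problem this package addresses. It is written for transcriptomics
practitioners working from Ensembl-style annotations and split-read junction
counts from bulk or single-cell RNA-seq.

## What it computes

Starting from a transcript annotation (GTF/GFF with `transcript`, `exon`,
`start_codon`, `stop_codon` features), `nmdsplice`:

1. **Annotates NMD targets** by the 50-nt rule: a transcript is an NMDT if an
   exon–exon junction lies ≥ 50 nt downstream of its stop codon in mRNA
   coordinates (exon-junction complexes left there survive the pioneer round
   of translation and mark the stop as premature). Transcripts from a
   secondary annotation (e.g. StringTie models) are first assigned to genes
   by shared introns and ≥ 50 % exonic overlap, and their ORFs inferred from
   the genome sequence as the longest reading frame opened at an annotated
   start codon.
2. **Delimits the event** behind each NMDT as a genomic interval of interest:
   from the last splice site the NMDT shares, with equal reading-frame phase,
   with any protein-coding transcript (or the shared start codon if there is
   none), to the 3' end of the exon containing the premature stop (or the
   nearest downstream transcript end when the stop itself is shared and NMD
   is triggered by the 3'-UTR structure). The **characteristic introns** of
   the event are all introns overlapping or abutting this interval except
   those shared by the NMDT and a coding transcript; NMDTs sharing a
   characteristic intron are merged into non-redundant event clusters.
3. **Classifies each cluster** against a reference transcript (MANE-Select, a
   user list, or every coding isoform in turn) via *bubbles* — pairs of
   vertex-independent paths — in a splicing graph whose nodes are donor (D)
   and acceptor (A) splice sites. The alternating node labels of the two
   paths, written `nmdt:reference`, name the event: `DADA:DA` is a poison
   exon (PE), `DA:DADA` an essential exon (EE), `ADA:ADA` alternative 5'
   splice sites, `AD:ADAD` intron retention, `DADA:DADA` mutually exclusive
   exons, `D(AD)nA:DA` n consecutive poison exons, and so on through a
   catalogue of 15 named types (plus `other` for everything else).
4. **Quantifies each cluster** from split-read junction counts as a weighted
   percent-spliced-in,

   Ψ = Σᵢ kᵢaᵢ / (Σᵢ kᵢaᵢ + Σⱼ rⱼbⱼ),

   where aᵢ, bⱼ are read counts on the NMDT- and coding-supporting
   characteristic introns and the weights kᵢ, rⱼ satisfy, per transcript and
   per side, Σ(weights of its characteristic introns) = 1. The weights are
   fixed by a nested-bubble heuristic (equal weights within each
   vertex-independent path, multiplied down through nested bubbles), with a
   minimum-norm fallback for non-nested configurations.

## Worked example

The package ships a generator for toy genes realizing every event type in the
catalogue. Write the fixtures and run the whole pipeline:

```bash
nmdsplice fixtures --out demo
nmdsplice all --gtf demo/fixtures.gtf --counts demo/counts.tsv --out demo/run
# genes: 22; clusters: 21; counts matched: 3/3
```

For the poison-exon gene (a cassette exon whose inclusion introduces a
premature stop), the output tables contain:

```
$ grep G_PE. demo/run.clusters.tsv | cut -f1-9
G_PE.e1  G_PE  N1  chr_PE  2121  4100  +  2  1

$ grep G_PE. demo/run.types.tsv
G_PE.e1  N1  C1  DADA:DA  PE  0  NMD_in  3  1  0

$ grep G_PE. demo/run.psi.tsv
G_PE.e1  0.5  10  20  2  1  1  heuristic
```

Reading these rows: the event cluster spans positions 2,121–4,100, with A = 2
characteristic introns supporting the NMDT (the two introns flanking the
poison exon) and B = 1 supporting the coding isoform (the skipping intron).
Against reference `C1` the bubble code is `DADA:DA`, the poison-exon type
(synonym `NMD_in` in the NMD Classifier nomenclature). With 10 reads on each
of the three introns and solved weights (0.5, 0.5 | 1), Ψ = (0.5·10 + 0.5·10)
/ (10 + 10) = 0.5: half of the gene's splicing flux runs through the
NMD-targeted isoform.

Sub-commands `annotate`, `events`, `classify` and `quantify` run the stages
individually; `--reference mane` uses MANE_Select tags from the annotation,
`--reference file:ids.txt` a custom list; `--ptc-threshold` changes the 50-nt
rule; `--secondary-gtf` plus `--genome-fasta` add annotation-free transcript
models.

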