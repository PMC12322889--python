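#!/usr/bin/env python
"""Summary statistics on a real (user-supplied) Ensembl annotation.

Computes, from an Ensembl-dialect GTF: the number of transcripts of genes
with at least one NMD-target transcript, the number of NMD targets, the
number of NMDTs classified against the MANE-Select reference (from the GTF's
own MANE_Select tags or a supplied ID list) and the number of NMDTs without
characteristic introns.  The input file must already be on disk
(uncompressed); nothing is downloaded.

    python scripts/external_check.py --gtf Homo_sapiens.GRCh38.108.gtf \
        [--mane-list mane_ids.txt] [--out summary.json]
"""

import argparse
import json
import sys

from nmdsplice import annotation, classify, events, orf, pipeline


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--gtf", required=True)
    ap.add_argument("--mane-list", default=None)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    genes = annotation.parse_annotation(args.gtf)
    for gene in genes.values():
        orf.annotate_gene(gene)
    genes = annotation.filter_genes(genes)

    config = pipeline.RunConfig(
        annotation_path=args.gtf,
        reference=f"file:{args.mane_list}" if args.mane_list else "mane",
    )

    n_tr = sum(len(g.transcripts) for g in genes.values())
    n_nmdt = sum(len(g.nmdts) for g in genes.values())
    n_classified = 0
    n_no_char = 0
    for gid in sorted(genes):
        gene = genes[gid]
        evs, und = events.find_events(gene)
        n_no_char += len(und)
        clusters = events.cluster_events(evs, gid)
        try:
            ref_ids = pipeline._reference_ids(config, gene)
        except OSError:
            ref_ids = None
        classified = set()
        for cl in clusters:
            for c in classify.classify_event(cl, gene, ref_ids):
                if not c.reference_free:
                    classified.add(c.nmdt_id)
        n_classified += len(classified)

    summary = {
        "transcripts": n_tr,
        "nmdts": n_nmdt,
        "nmdt_percent": round(100.0 * n_nmdt / n_tr, 1) if n_tr else 0.0,
        "nmdts_classified_mane": n_classified,
        "nmdts_without_characteristic_introns": n_no_char,
    }
    text = json.dumps(summary, indent=1)
    print(text)
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(text + "\n")
    return 0


if __name__ == "__main__":
    sys.exit(main())
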