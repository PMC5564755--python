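#!/usr/bin/env python
"""Annotate nominated junctions: geometry, splice sites, reading frame.

For each surviving gene pair of the cascade run, classifies the partner
geometry (distance, strand, read-through plausibility), checks whether
the junction falls on annotated exon boundaries, predicts the reading
frame, and translates in-frame chimeric peptides. Writes
results/junction_annotation.tsv and results/peptides.fa.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from fusionnominate import filters, io, junctions

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    manifest = io.read_manifest(args.sim / "manifest.tsv")
    calls = []
    for f in sorted((args.sim / "calls").glob("*.tsv")):
        calls.extend(io.read_fusion_table(f, strict=False).calls)
    db = io.read_annotation(args.sim / "annotation.gtf", fasta=args.sim / "genome.fa")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = filters.run_cascade(calls, manifest, db)

    rows = []
    peptides = []
    for r in res.records:
        geom = junctions.classify_pair(r.gene5, r.gene3, db)
        ann = junctions.predict_frame(r.representative_call, db)
        rows.append({
            "gene_pair": r.pair_label,
            "same_chromosome": geom.same_chromosome,
            "distance_bp": geom.inner_distance_bp,
            "read_through_candidate": geom.read_through_candidate,
            "junction_at_splice_site": ann.at_splice_sites,
            "in_frame": ann.in_frame,
            "residues_from_5p": ann.residues_from_5p,
            "fusion_peptide_length": ann.fusion_peptide_length,
        })
        if ann.peptide:
            peptides.append((r.pair_label, ann.peptide))

    args.out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "junction_annotation.tsv", sep="\t", index=False)
    with open(args.out / "peptides.fa", "w") as fh:
        for label, pep in peptides:
            fh.write(f">{label} length={len(pep)}\n")
            for i in range(0, len(pep), 60):
                fh.write(pep[i:i + 60] + "\n")

    n_rt = int(df.read_through_candidate.sum())
    n_if = int(df.in_frame.sum())
    print(f"{len(df)} nominated junctions annotated: {n_rt} read-through candidates, "
          f"{int(df.junction_at_splice_site.sum())} at annotated splice sites, "
          f"{n_if} in frame ({len(peptides)} peptides translated)")


if __name__ == "__main__":
    main()
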