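#!/usr/bin/env python
"""Simulate the 20-isolate study panel and write its raw data artifacts.

Emits the synthetic circular reference (FASTA), the ORF annotation (TSV),
the per-site nucleotide count table (TSV + VCF) and the design ground truth
(JSON).  Raw data goes to scratch/study_data/ (it is large and fully
reproducible from the seed); downstream drivers recompute from the seed.
"""

import argparse
import json
from pathlib import Path

from gvpop import snpio, synth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("scratch/study_data"))
args = parser.parse_args()

out = args.out
out.mkdir(parents=True, exist_ok=True)

sp, matrix = synth.study_matrix(args.seed)
snpio.write_reference(sp.reference, out / "reference.fasta")
snpio.write_annotation_tsv(sp.annotation, out / "annotation.tsv")
snpio.write_count_table(matrix, out / "counts.tsv")
snpio.write_vcf_counts(matrix, out / "counts.vcf")
synth.write_truth(sp.truth, out / "truth.json")

depths = matrix.depths
print(f"panel: {len(matrix.isolates)} isolates "
      f"({len(sp.panel.ids('field'))} field), seed {args.seed}")
print(f"reference: {sp.reference.length:,} bp circular, "
      f"{len(sp.annotation)} ORFs")
print(f"count table: {matrix.n_sites} candidate sites "
      f"({sp.truth['n_positions']} designed SNP positions), "
      f"mean depth {depths.mean():.0f}")
print(f"wrote raw data to {out}/")
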