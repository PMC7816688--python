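# gvpop — consensus-free SNP analysis of granulovirus isolate mixtures

Naturally occurring baculovirus isolates — including the Cydia pomonella
granulovirus (CpGV) preparations sprayed as biological codling-moth control —
are usually *mixtures* of genotypes rather than clonal viruses.  A consensus
sequence built from deep-sequencing reads keeps only the majority base at
every position and silently erases that internal structure.  `gvpop`
implements the alternative: work directly on per-site nucleotide **read
counts** for a panel of isolates mapped against one common circular
reference, and let minority genotypes appear as intermediate allele
frequencies.

The core quantities, for isolate *i* at SNP position *s* with read depth
*d(i,s)* and first-alternative count *a(i,s)*:

- **alternative frequency** ƒ_alt(i,s) = a(i,s)/d(i,s);
- a position is **variable in isolate i** iff d(i,s) > 100, a(i,s) > 10 and
  max(ƒ_ref, ƒ_alt) > 0.05 (all strict);
- the **specificity label** of *s* is the exact set of isolates in which it
  is variable — one isolate: isolate-specific, several: group-specific;
- a **marker set** collects all positions with one label; the median of
  ƒ_alt over a genotype's marker set, evaluated in isolate *i*, estimates
  the proportion of that genotype in *i* (for the set identifying the
  mapping-reference genotype itself, the *reference* frequency is used).

Around this sit: arithmetic for collapsing combined lineage labels
(e.g. proportion(B) = median(BE set) − median(E set)); synonymous /
nonsynonymous SNP classification on a circular, wrap-around-aware genome
with per-class density ANOVA; flank-anchored counting of a 12-bp tandem
repeat (the *pe38* locus whose single-copy form marks resistance-overcoming
CpGV genotypes) directly from reads; and HCPC — PCA, Ward clustering on the
leading components, tree cut, k-means consolidation — to arrange isolates by
genotype composition.  A synthetic-data module generates reference genomes,
genotype panels, binomially sampled count matrices and repeat-locus reads
with exact ground truth, including a default 20-isolate CpGV-like panel.

## Layout

```
src/gvpop/          the library: snpio, variant_filter, specificity,
                    composition, orf_stats, pe38_repeats, hcpc, synth,
                    pipeline, study
analysis/           numbered drivers reproducing the worked analysis
results/            tables written by the drivers
scripts/acceptance.py   recomputes the headline numbers as JSON
docs/methods.md     model, parameters, numerical choices, limitations
```

## Worked example

```python
from gvpop import specificity, synth, variant_filter
from gvpop.composition import quantify

panel, matrix = synth.study_matrix(seed=1)         # 20 isolates, known truth
fm = variant_filter.apply_filters(matrix)           # depth>100, alt>10, f>0.05
assignment = specificity.assign_specificity(
    fm, within=list(synth.FIELD_ISOLATES))
sets = specificity.build_marker_sets(assignment)
print(fm.n_sites, len(sets))
```

Running the numbered drivers prints, for seed 1:

```
$ python analysis/02_filter_and_label.py
retained 753 variable positions (0.61% of the genome)
field-specific: 723; commercial-only: 30
reference anomalies (f_alt >= 92% everywhere): [105178]
...
         M:  58 SNPs (ref allele)
        E2:  68 SNPs (alt allele)

$ python analysis/03_composition.py
    KS1: {'M (58)': '69 (67–71)', 'BDEFG (75)': '31 (29–33)', ...}
    V15: {'M (58)': '9 (8–10)', 'E2 (68)': '42 (41–44)', 'DEFG (45)': '49 (47–50)'}
  V34: {'A': 32.8, 'B': 39.4, 'E': 27.9}        # B from the BE−E collapse
```

Read: 753 SNP positions survive filtering (0.61% of the 123,529 bp genome);
the KS1 isolate is ~69% reference-like (lineage A) and ~31% lineage-E
material; the commercial V15 is an E2/S mixture (42%/49%); the proportion of
lineage B in V34 (39%) is obtained by subtracting the collapsed E signal
from the combined BE signal.  `analysis/05_repeat_typing.py` and
`analysis/06_hcpc_clustering.py` print the repeat copy-number histograms
(the M-derived selection is ~96% single-copy) and the six-cluster HCPC
grouping in which the homogeneous pairs M/V003 and WW/S co-cluster.

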