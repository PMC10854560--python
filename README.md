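# mitocodon

Comparative analysis of annotated mitochondrial genomes, built around the
codon-usage-bias toolkit used in fish mitogenomics: relative synonymous
codon usage (RSCU), the effective number of codons (ENC), the codon
adaptation index (CAI), ΔRSCU optimal-codon screening, base-composition
and strand-skew summaries, RSCU-based hierarchical clustering of taxa,
control-region motif partitioning (TAS / central conserved domain /
CSB-1/2/3), and gene-order comparison against the canonical vertebrate
arrangement.

It is aimed at researchers comparing small sets of mitogenomes — for
example the eleven *Pseudogastromyzon* (hillstream loach) genomes that
motivated the feature set — who want the usual per-gene tables and
cluster figures reproducible from a script instead of a chain of web
tools.

## The statistics

For a codon *c* in a synonymous family of size *k* with family counts
*n₁…n_k*:

- **RSCU(c)** = *n_c · k / Σᵢ nᵢ* — 1 means no bias; values over a family
  sum to *k*. The conventional 59-codon vector drops ATG, TGG and the
  three standard stops.
- **ENC** (Wright) uses per-family homozygosity
  *F̂ = (n·Σp̂² − 1)/(n − 1)* averaged within degeneracy classes:
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61 (uniform usage);
  20 means one codon per amino acid.
- **CAI** is the count-weighted geometric mean of relative adaptiveness
  *w(c) = ref(c)/max_family ref*, computed against a reference usage
  table (default: the genome's own concatenated 13 PCGs).
- **ΔRSCU screening**: genes are ranked by ENC; the top 10% at each
  extreme form high-/low-expression groups, and a codon is *optimal*
  when ΔRSCU = RSCU_high − RSCU_low > 0.08 with RSCU_high > 1 and
  RSCU_low < 1 (all strict).

## Worked example

The synthetic-genome generator produces fully annotated ~16.6 kb
mitogenomes with known, planted codon preferences, which makes every
stage of the pipeline testable without downloads:

```python
import mitocodon as mc

spec = mc.SyntheticSpec(seed=11, gene_bias={"atp6": 5.0, "nad6": 0.0},
                        bias_strength=0.0)
rec = mc.build_synthetic_mitogenome(spec, accession="DEMO01")

stats = mc.base_composition(rec.sequence)
print(len(rec), f"{stats.at_content:.2f}%")          # 16571  54.36%

report = mc.screen_optimal_codons(rec, high="atp6", low="nad6")
print(len(report.optimal_codons), report.optimal_codons)
# 9 ('AAC', 'CAC', 'CCA', 'CTA', 'GAA', 'GCA', 'GGC', 'TTC', 'TTG')

part = mc.partition_control_region(mc.extract_gene_sequence(rec, "CR"))
print(part.tas, part.central, part.csb)              # (0, 221) (221, 327) (327, 890)
```

The genome carries bias 5 toward the planted preferred codons in `atp6`
and none in `nad6`; screening those two genes recovers eight of the
planted codons (`AAC, CAC, CCA, CTA, GAA, GCA, GGC, TTC`) plus one
chance call. The control region partitions into a 221 bp TAS domain, a
106 bp central conserved domain and the CSB block, exactly as
constructed.

Real data goes through the same interfaces: `mc.parse_genbank_record`
reads deposited GenBank flat files (see `scripts/fetch_accessions.py`
for the helper that downloads the eleven loach records), and the CLI
wraps the batch pipeline:

```
mitocodon simulate --seed 1 --n 3 --outdir demo
mitocodon run-all demo/*.gb --outdir demo_reports
mitocodon optimal --genome demo/SYN-profile0-00.gb --high atp6 --low nad6
```

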