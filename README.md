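# polredist

Gene-length-aware analytics for RNA polymerase II elongation. The package
is built for the question of what happens when a transcription elongation
factor (for example a PAF1-complex subunit such as CTR9) is depleted:
polymerase and its associated factors redistribute from the bodies of long
genes to promoter-proximal regions, nascent transcription decays with
distance from the TSS, long genes (DNA repair and replication genes among
them) are downregulated, and short genes (MHC class I antigen-presentation
genes among them) are released into productive elongation. `polredist`
implements the quantitative procedures this kind of study leans on, end to
end and testable at desk scale:

* **screen scoring** — high-content siRNA screen statistics: per-well
  z-scores (z = (x − µ)/σ over all wells of a readout), unpaired t-tests of
  each target against the pooled non-targeting control (two-sided for EdU
  incorporation, one-sided for pKAP1 positivity), per-readout hit
  thresholds (P < 0.05; P < 0.15 for the +ATR-inhibitor readout), and
  multi-readout intersection counts;
* **spike-in (ChIP-Rx) normalization** — factors
  `min_j(spike_j) / spike_i`, applied by seeded subsampling or track
  scaling, plus smallest-library read-count normalization for CUT&RUN-style
  data;
* **BLISS break quantification** — barcode demultiplexing with one
  mismatch, UMI deduplication, in-silico restriction digestion
  (AsiSI, `GCGATCGC`), counting of deduplicated breaks in restriction-site
  windows, cross-sample normalization anchored on the restriction cuts, and
  genomic-region annotation of breaks;
* **length-stratified profiles** — intronic-read filtering for nascent
  (4sU-seq-style) data, expressed-gene selection, gene-length quartiles
  (≥ 10 kb, quartile sizes differing by ≤ 1), TSS profiles, scaled
  gene-body metagenes, length-sorted log2FC occupancy heatmaps and a
  promoter/body redistribution statistic;
* **expression vs length** — gene counting in exonic / second-half /
  intronic modes, a fully specified differential statistic with
  Benjamini–Hochberg FDR, and Pearson correlation of gene length with
  expression log2FC over user-supplied gene sets;
* **synthetic data** — seeded generators for all of the above with
  recoverable ground truth, built around a promoter-pause + per-kb-survival
  elongation model whose body log2 fold change between conditions is
  analytically `d · log2(s_dep / s_ctrl)` at distance d kb from the TSS.

All genomic coordinates are 0-based half-open (BED convention); the TSS of
a minus-strand gene is `end − 1`.

## Worked example

Score a synthetic 86-target screen (planted ground truth: 4 targets
positive in all three readouts, 8 in exactly two):

```bash
polredist sim screen --seed 3 --out wells.tsv
polredist screen --wells wells.tsv --out scored.tsv
```

prints the intersection counts by cardinality:

```
{"1": 40, "2": 8, "3": 4}
```

i.e. 4 targets scored in all three readouts, 8 in exactly two and 40 in a
single readout; `scored.tsv` holds per-target z, p and hit calls.

The same from Python, together with an elongation-defect recovery:

```python
import numpy as np
from polredist import simulate, metagene
from polredist.core import build_coverage

anno = simulate.simulate_annotation(300, seed=50)
ctrl, dep = simulate.default_conditions()   # s: 0.999 vs 0.99/kb, pause 0.3 vs 0.5
ctrl.params.reads_total = dep.params.reads_total = 600_000
mc, _ = simulate.simulate_elongation_reads(anno, ctrl, seed=1)
md, _ = simulate.simulate_elongation_reads(anno, dep, seed=2)
tc, td = (build_coverage(x, anno.chrom_sizes) for x in (mc, md))
assign = metagene.stratify_by_length(anno.genes, min_length=10_000)
genes = {g: anno.genes[g] for g in assign.assignment}
print(metagene.redistribution_stat(td, tc, genes, assign).round(3))
print(round(metagene.body_log2fc_slope(td, tc, genes), 5))
```

```
   quartile  promoter_log2fc  body_log2fc
0         1            1.262        0.634
1         2            1.260        0.487
2         3            1.211        0.164
3         4            1.103       -0.576
-0.01198
```

Promoter-proximal signal is gained in every length quartile, gene-body
signal is lost progressively from the shortest (Q1) to the longest (Q4)
quartile, and the fitted per-kb body log2FC slope matches the analytic
value `log2(0.99/0.999) = −0.01306`.

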