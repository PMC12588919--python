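# ampelqtl

Landmark-based grapevine leaf morphometrics coupled to F1 QTL mapping.

Grapevine leaves are routinely digitised as 21 homologous landmarks
(vein bases, branch points, vein and lobe tips, sinuses).  `ampelqtl`
turns those coordinates into 16 ampelometric phenotypes, assembles them
into genotype × attribute trait matrices across leaf position (apical /
middle / basal), daylength (14 h / 13 h) and year, scans every
attribute against an ABH-coded F1 genotype matrix, clusters collocated
QTL into hotspots, and runs gene-window pathway enrichment.  A
seed-deterministic simulator generates every input (leaves, genotypes,
gene tables), so the whole pipeline is testable without experimental
data.

The intended users are plant geneticists mapping leaf-shape loci in
biparental crosses, and anyone who needs a compact, reproducible
landmark-to-QTL workflow.

## The statistics at the core

**Traits.** Vein lengths are Euclidean distances between landmarks (or
landmark midpoints); areas are shoelace-formula polygon areas over
configurable landmark cycles; six ratios summarise shape, including
`veins_to_blade` = ln(vein area / blade area).

**Genome scan.** At each marker, single-locus regression of the
phenotype on an additive code (A = −1, H = 0, B = +1) plus a dominance
indicator (H = 1):

    LOD = (n/2) · log10(RSS₀ / RSS₁)

Traits failing a Shapiro–Wilk gate go through a log / Box–Cox ladder;
traits that resist normalisation are rank-scanned (Kruskal–Wallis H,
LOD analog H / (2 ln 10)).  The genome-wide significance threshold is
the empirical 95th percentile of the maximum LOD over phenotype
permutations (1,000 by default, 5% level).  Percent variance explained
uses PVE = 100 (1 − 10^(−2·LOD/n)); the 95% credible interval is the
smallest contiguous cM span containing the peak and ≥95% of the
posterior mass ∝ 10^LOD.

**Hotspots and enrichment.** QTL sharing an identical peak marker with
pairwise-overlapping credible intervals (≥3 by default) form a
hotspot; genes within ±700 kb of the hotspot peak (a 1.4 Mb window)
are tested per pathway with a one-sided Fisher exact test (raw
p < 0.05 rule, Benjamini–Hochberg adjusted p reported alongside).

## Worked example

```python
import pandas as pd
from ampelqtl.simulate import SimulationConfig, PlantedQtl, simulate_genotypes, simulate_leaves
from ampelqtl.morphometrics import traits_table
from ampelqtl.trait_matrix import assemble_matrix
from ampelqtl.qtl import QTLScan

cfg = SimulationConfig(
    n_genotypes=135, n_lgs=19, markers_per_lg=10, seed=7,
    qtl=[PlantedQtl(marker="rh5_3000000", pve=0.15, affected=("size",))],
)
gmap, geno = simulate_genotypes(cfg)
matrix = assemble_matrix(traits_table(simulate_leaves(cfg, geno)))
res = QTLScan(matrix["total_area__basal__14h__2021"].dropna(),
              geno, gmap, trait="total_area basal 14h 2021").fit(n_perm=200, seed=5)
print(res.summary())
```

prints

```
QTL genome scan: total_area basal 14h 2021
  method: parametric (transform: identity)
  individuals: 135
  genome-wide threshold (alpha=0.05, 200 permutations): 3.695
  markers scanned: 190
  max LOD: 4.238 at rh5_3000000
  peaks above threshold: 1
    LG 5 rh5_3000000 @ 30.0 cM  LOD 4.24  PVE 13.5%  CI [10.0, 30.0] cM
```

The planted 15%-variance QTL is recovered at its marker: the peak LOD
4.24 clears the permutation threshold 3.70, and the back-computed PVE
(13.5%) is close to the planted value (single-replicate sampling error
is a few points at n = 135).

The same pipeline runs from the shell:

```bash
ampelqtl all --out run/ --seed 7 --n-perm 200
```

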