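# Methods

## Landmark scheme and trait extraction

A leaf is 21 labelled 2-D landmarks in cm: four vein-base width points
across the petiole insertion (1–4), three landmark triples at the
petiolar, distal-vein and midvein branch junctions (5–7, 8–10, 11–13),
and eight margin points — petiolar vein tip (14), proximal lobe tip
(15), proximal sinus (16), distal branch tip (17), distal lobe tip
(18), distal sinus (19), midvein branch tip (20) and leaf tip (21).
Coordinates are assumed already calibrated to cm (an optional uniform
scale factor is applied at read time); y increases toward the leaf
tip, and violations are QC flags rather than errors.

Lengths: L1 = |midpoint(P3,P4) → P21| (midvein), L2 = |midpoint(P2,P3)
→ P18| (distal), L3 = |P2 → P17| (xvii vein), L4 = |midpoint(P1,P2) →
P15| (proximal), L5 = |P6 → P14| (petiolar-sinus width; the endpoint
pair is configurable).  Areas use the absolute-value shoelace formula
over landmark cycles held in `PolygonConfig`:

* boundary: (14, 15, 16, 17, 18, 19, 20, 21) — the only landmarks on
  the margin; the closing edge 21→14 stands in for the unlandmarked
  half of the margin, so the polygon is the landmarked approximation
  of the blade, not a pixel area;
* veins: mid (4, 13, 21, 11, 20, 12, 3), dist (3, 10, 18, 8, 17, 9, 2),
  prox (2, 7, 15, 5, 14, 6, 1).  Each traverses base → width landmark →
  main tip → distal branch base → branch tip → proximal branch base →
  base, which is a simple polygon for any leaf laid out with this
  margin topology (orders consistent with the branch tips 14/17/20
  sitting on the proximal side of their veins, as the margin sequence
  requires).  Cycle orders are design choices — no published vertex
  order exists — and are fully configurable.

Derived: vein_area = mid + prox + dist; blade_area = total − vein
(must be positive); `veins_to_blade` uses the natural log (the log
base is unstated in the source material, so e is this package's
choice).  Sixteen phenotypes total: 4 lengths, 6 areas, 6 ratios.

QC (reported, never raised): boundary self-intersection (checked with
shapely's polygon validity), leaf tip not the most distal boundary
point, any vein length above 1.25× the boundary diameter
(configurable), duplicate coordinates (< 1e-6 apart).

## Trait matrix and descriptive statistics

The per-leaf table is widened to one row per genotype and one column
per (phenotype, position, daylength, year) attribute —
16 × 3 × 2 × 2 = 192 attributes for the full design; replicate leaves
in one cell are averaged (a strict mode rejects them, since the design
samples one leaf per cell and replicates indicate data errors).
Missing cells stay missing: pairwise-complete handling for Pearson
correlation, flagged mean-imputation for PCA (refused above 20%
missing), row dropping for the variance partition.

z-transformation pools all cells sharing (phenotype, position) and
standardises to mean 0, sample SD 1 (ddof = 1), removing the
allometric scale differences between leaf positions before pooled
display or comparison.  Grouping by position (rather than position ×
year) was an open choice; position is the dominant scale factor and
coarser pooling keeps year contrasts visible after transformation.

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
(df = groups − 1); all-tied data return H = 0, p = 1.  PCA operates on
correlation-scaled data by default (traits have heterogeneous units);
variance fractions come from the singular values and sum to 1.

The factor analysis of PC scores is a factorial linear model with
sequential (type-I) sums of squares in the fixed order year,
daylength, position, genotype, genotype×year, genotype×position;
fractions are term SS over total SS.  All design factors are
categorical, so a smoothing-spline model would reduce to exactly this
factorial fit; the sequential order is documented because type-I SS
depend on it.

## Genetic map and genotypes

Genotypes are ABH-coded F1 intercross calls (A/B major/minor
homozygote, H heterozygote, `-` missing) in the R/qtl CSV dialect
(marker names, linkage groups, cM as three header rows).  Physical
positions parse from marker names `rh<chromosome>_<bp>`; a sidecar map
CSV overrides the convention.  Map summaries: per-LG length = cM span;
mean spacing = total length / (markers − LGs); collinearity = per-LG
Spearman rank correlation between genetic and physical order
(average ranks under ties; ≥3 placed markers required).  The
genome-wide recombination rate divides total cM by the spanned Mbp of
parsed positions and is labelled approximate, since the proper
denominator (which physical length) is not well defined for a partial
map.

Two-locus recombination fractions treat the ABH calls as phase-known
intercross genotypes: each individual contributes two informative
meioses whose recombinant status is determined by the genotype pair
except in the double-heterozygote cell (0 or 2 recombinants), which EM
weights by r² / (r² + (1−r)²).  Estimates live in [0, 0.5] and need
≥20 doubly-typed individuals.

## Genome scan

Model: single-locus regression at the markers themselves — no
pseudomarker grid or hidden-Markov genotype probabilities.  At the
map densities this pipeline targets (≈1.8 cM between markers),
interval mapping adds little localisation; the marker-regression
model keeps the permutation scan exactly exchangeable and fast.
Coding is additive (−1/0/+1) plus dominance (H = 1), 2 df; markers
missing a genotype class fall back to the observed-class df, and
markers with <2 classes score LOD 0 with a flag.  Missing genotypes
are dropped per marker; n in the LOD formula is the per-marker
complete-case count.

Normality gate: Shapiro–Wilk at α = 0.05 (the gate level is this
package's choice).  Ladder: identity → natural log (positive traits) →
Box–Cox with profile-likelihood λ on the grid −2 … 2 step 0.1; the
first transform reaching p ≥ 0.05 wins, otherwise the trait is tagged
nonparametric and rank-scanned.

Threshold: empirical (1−α) quantile (type 7) of the genome-wide
maximum LOD over phenotype permutations (default 1,000 at α = 0.05; a
mandatory seed makes runs byte-reproducible).  Internally the sorted
phenotype vector is permuted, which makes the threshold exactly
invariant to relabelling individuals.  Permutation scans reuse
per-marker orthonormal design bases, so one threshold costs a few
hundred small matrix products.

PVE = 100(1 − 10^(−2·LOD/n)).  Credible interval: posterior mass at
markers ∝ 10^LOD normalised within the linkage group; the interval is
the smallest contiguous cM span containing the peak marker and ≥95% of
mass (flat curves return the whole LG, flagged).  Peak rule: at most
one peak per linkage group per trait — the maximal marker when it
exceeds the threshold.

`run_all` fans this over every attribute (skipping those with <30
phenotyped individuals), deriving one child seed per attribute from
the base seed and column position, so the full peak table is
bit-identical for a fixed seed.

## Hotspots and enrichment

Hotspots group peaks by identical peak marker and keep the largest
subset with pairwise-overlapping credible intervals (for 1-D
intervals, pairwise overlap is equivalent to a shared point, so a
sweep over endpoints finds the maximum subset).  The threshold is ≥3
member QTL (the source material states the rule both as "> 3" and
"three or greater"; the worked examples have 3-member hotspots, so 3
is the default and the knob is configurable).

Gene windows take genes whose annotated start (1-based) lies within
±700 kb of the peak's parsed bp — a closed 1.4 Mb interval; genes are
points, not spans (configurable choice, documented because
edge-spanning genes are excluded).  Enrichment: per pathway, one-sided
Fisher exact test of (window ∩ pathway) against the gene universe
(default: all annotated genes, since no published universe exists);
significance follows the raw p < 0.05 rule, with Benjamini–Hochberg
adjusted p always reported alongside.

## Synthetic data

`simulate_genotypes` draws, per individual and linkage group, two
independent gametes from heterozygous parents: the first allele is
fair, and each subsequent marker recombines with Haldane probability
(1 − e^(−2d/100))/2 for d cM.  Markers are evenly spaced; names encode
bp = cM × 10⁵ so physical-position code paths are exercisable without
a real physical map.  Intercross (1:2:1) coding is simulated rather
than outbred four-allele meiosis: the analysis layer consumes ABH
intercross coding, and that layer — not meiosis fidelity — is under
test.

`simulate_phenotype` builds y = μ + a·s + d·h + ε with Var(s) = 1/2,
Var(h) = 1/4 under 1:2:1 frequencies, solving a for a target PVE at
fixed residual SD.

`simulate_leaves` scales a per-position template by exp(genotype size
signal + daylength effect + year effect), with planted size-QTL
embedded in the genotype signal at their target variance share, an
anisotropic x/y stretch for shape-QTL, and independent Gaussian
landmark jitter.  Defaults mirror the target study design: 135
genotypes, three positions, 14 h/13 h daylengths, two years, with
apical templates smaller and relatively thicker-veined than basal
ones.  Template coordinates are stylised synthetic fixtures consistent
with the landmark topology, not measured leaves.  Default effect
sizes: daylength +4% and year +3% on the log size scale, genotype SD
0.08, landmark jitter 0.02 cm — values in the range a morphometric
screen of a segregating F1 would show, chosen once.

What the simulator does **not** emulate: lobing and sinus-depth
segregation, measurement operators (landmark placement bias),
genotype-specific vein architecture, spatial field effects, or
presentation (grafting) physiology — graft effects would enter only as
variance shrinkage on genotype effects.  Passing tests therefore
demonstrate correctness and calibration of the analysis machinery on
data satisfying its assumptions, not robustness to every artefact of
scanned herbarium leaves.

## Problem sizes and numerical choices

The test-suite and acceptance studies run at reduced but faithful
sizes chosen as this package's own calibration design: genome of 19
LGs × 10 markers (90 cM each), n = 135 individuals, 200 permutations
per threshold, 400 null simulations for threshold calibration, 20
end-to-end replicates for planted-QTL recovery.  Tie-breaks: credible
intervals prefer the smallest cM span, then the fewest markers;
permutation quantiles are type 7; degenerate inputs (constant traits,
single-class markers, flat LOD curves, empty attribute columns) are
flagged or skipped rather than fatal.

## Known limitations

Single-QTL-per-LG reporting (no multiple-QTL models, covariates or
epistasis); marker regression rather than interval mapping between
markers; the Bayes interval is computed on the marker grid, so its
resolution is the marker spacing; the recombination-rate summary
depends on an arbitrary bp convention in simulations; Fisher
enrichment treats genes as exchangeable points and ignores gene
length, linkage disequilibrium between neighbouring genes, and
annotation redundancy.
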