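# Methods

## Problem

Single-cell bisulfite sequencing observes each cell's CpG sites sparsely
(1–10% for scRRBS, 20–40% for scBS-seq), each site with a handful of reads.
The task is binary imputation: predict the methylation state of a CpG site
in a given cell from (a) the local DNA sequence, (b) structural genome
annotations, and (c) the states and distances of nearby observed sites in
the same cell and in the other cells of the dataset. Methylation is
spatially correlated along the chromosome and partially concordant across
cells, which is exactly the structure families (c) exploit.

## Labels

A site enters the labeled set only when covered by at least `min_cov`
reads (default 4). The state is the read majority: 1 when more than half
the reads are methylated, 0 when fewer than half. An exact tie carries no
majority and is excluded — ambiguous labels are unusable for training, and
"mostly methylated / mostly unmethylated" has no defined value at 50%.
Profile positions are 1-based coordinates of the C of the CpG dinucleotide
on the forward strand, assumed pre-collapsed across strands.

## Feature families

**Sequence (84).** Overlapping n-mer frequencies, n ∈ {1,2,3}, of the
(2·flank+1)-bp window centered on the site (flank default 50, so 101 bp):
f(v) = N(v)/(L−(n−1)). Columns are fixed in lexicographic order (A..T,
AA..TT, AAA..TTT). Near chromosome ends the window is padded with N to
keep a constant length; any window overlapping an ambiguous base counts
toward no n-mer while the denominator keeps the nominal length, so the
feature scale is identical at every site. (End-of-chromosome and
N-handling are our conventions; the alternative — shrinking L — would make
otherwise identical windows incomparable across sites.)

**Structural (175).** One column per annotation track in a manifest whose
order fixes the column order: binary point-membership for interval tracks,
raw value for per-position score tracks. The default manifest is 3
CGI-class + 144 TFBS + 15 chromatin-state + 10 histone-mark + 1 DHS binary
tracks plus iHS and constraint scores. BED input (0-based half-open) is
converted to 1-based closed intervals once at load; overlapping intervals
are merged with a warning. Missing scores are NaN, not 0: boosted trees
route missing values natively and 0 is a meaningful score value. Which
concrete tracks make up the manifest is data (a config file), not code.
A helper derives shore/shelf tracks from island intervals with the
conventional 2-kb shore and 2–4-kb shelf flanks, subtracting islands (and
shores from shelves) so the three classes are disjoint.

**Positional (4m + 8(m−1)).** For target site (cell *i*, position *p*)
and every cell *j*, the flanking block ℱ holds the signed distances and
states of the labeled sites immediately left and right of *p* in cell *j*;
when *p* itself is labeled in *j* at index *l*, the flanks are sites
*l*−1 and *l*+1, so the target's own label is never used when *j* = *i*.
For every *j* ≠ *i* the gap block 𝒟 holds four consecutive inter-site
gaps and the states at indices *l*−2, *l*, *l*, *l*+2 around *p* (the
state at *l* appears twice as written in the defining formulas; in the
absent case the central gap likewise fills two slots — we reproduce both
verbatim, with a `dedupe_absent_gap` switch that masks the repeated gap).
𝒟 is forbidden for *j* = *i* because it would contain the target's own
state. Distances are raw signed base pairs (left negative) with no
normalization, exactly as the formulas read. Missing neighbors (chromosome
boundaries, empty cells) are NaN for both distance and state; sentinel
values would distort tree splits. Blocks are concatenated with the target
cell's ℱ first, then the other cells in lexicographic cell-id order, so
models transfer across runs. Column names are relative to the target
(self, other-rank); the absolute cell of origin is recorded in the
sidecar manifest. This makes the per-cell models share one manifest, which
is what permits summing importance scores across cells.

The skip-k generalization used by the distance-decay analyses takes the
k-th-nearest labeled neighbor on each side (`rank_pair`) or all ranks
1..k (`window`); k = 1 on both sides is the production default, the
package's own experiments confirming that neighbor information decays
rapidly with rank.

## Classifier

One LightGBM binary model per target cell: 110 trees, max depth 5, 22
leaves, learning rate 0.04 (other parameters at the library's defaults;
`deterministic` and `force_row_wise` are set so a fixed seed with one
thread reproduces bit-identically). Prediction aligns columns by manifest
name, so column order is irrelevant. Feature importance is the per-feature
split participation count; aggregation across per-cell models is the
element-wise sum, sorted descending with ties stable by name. The
classification threshold is 0.5 and no class rebalancing is applied — the
imbalance-robust AUPR is reported instead.

GOSS and EFB, the two strategies that make this classifier fast, are also
provided as standalone reference implementations (the production trainer
uses LightGBM's internal, behaviorally equivalent versions):

* `goss_select` keeps the top ⌈a·n⌉ samples by |gradient| plus ⌈b·n⌉
  drawn uniformly from the remainder, up-weighted by (1−a)/b when
  amplification is on — the unique constant that keeps the expected
  weighted gradient sum unbiased given that b is a fraction of the total
  sample count. a, b are exposed (defaults 0.2 / 0.1); rounding is ceiling.
* `efb_bundle` builds the conflict graph w = (co-nonzero rows)/L, visits
  features in descending weighted-degree order (ties by column index) and
  joins the first bundle whose added conflict stays ≤ d (default 0.05;
  the non-strict comparison is what makes zero-conflict one-hot columns
  bundle at any d, including d = 0). `merge_bundles` collapses a bundle by
  offsetting each member's value range so ranges are disjoint, zero staying
  the shared zero bin; members must be non-negative, and on a conflict row
  the member latest in the set wins (bundles are built to make such rows
  rare, and the construction is exactly invertible when they are absent).

## Evaluation

Acc, Precision, SE, SP, Fscore and MCC follow the standard
confusion-matrix formulas; any zero denominator yields 0, and the report
flags which metrics were degenerate. AUC is the trapezoidal area under the
ROC curve and AUPR the step-integrated precision-recall area, both via
scikit-learn; an independent pairwise-comparison oracle cross-checks the
ROC estimator in the tests. The chromosome-holdout split assigns odd
chromosomes 1–11 to training, even 2–12 to testing and 13–19 to
validation; sites on unlisted chromosomes are dropped with a logged count.
Experiment drivers (skip-k decay tables, the importance-ranked top-k
sweep) evaluate on the test partition.

The cross-cell overlap summary counts N = distinct positions known in at
least one cell, N1 = positions known in ≥ 2 cells, N2 = positions where
≥ 2 cells share a state, and N3 = positions satisfying a concordance
predicate, by default "known in all m cells with one common state" — the
strictest reading of an ambiguous definition, exposed as a parameter so
other readings are one lambda away. Pk = 100·Nk/N.

## Simulator

The generator emulates the statistical regime the method targets, not the
human genome's composition:

* **Genome** — i.i.d. A/C/G/T background with CG dinucleotides planted at
  gaps of 1 + Geometric(1/(mean_gap−1)) bp (mean `mean_gap`, default
  100 bp ≈ genome-wide CpG density); accidental background CGs are
  scrubbed so the planted list is exactly the CpG set.
* **Latent landscape** — a symmetric two-state Markov chain in base-pair
  distance with per-bp switch probability s (default 0.001): over a gap g
  the state flips with probability (1−(1−2s)^g)/2, so neighbor agreement
  decays smoothly from ~0.91 at 100 bp to 1/2 beyond a few kb. This
  single latent path shared by all cells is what makes cross-cell
  features informative, mirroring the partial concordance observed in
  real multi-cell data.
* **Cells** — each cell copies the latent state with probability
  `concordance` (default 0.9), observes each site with probability
  `coverage` (default 0.3), draws depth 1 + Poisson(depth_mean−1)
  (default mean 6, so ~12% of observations fall under the 4-read floor
  and are genuinely excluded downstream) and methylated read counts
  binomially with per-read error 0.01 (bisulfite conversion error scale).
* **Tracks** — islands are 2-kb tiles accepted with probability
  base_rate·exp(enrichment·(unmeth_frac − ½)) (defaults 0.15 and 6), so
  islands concentrate in unmethylated latent regions the way real CpG
  islands are hypomethylated; enrichment 0 is the null mode with
  state-independent tracks. Shores/shelves are derived; all other binary
  tracks are random interval sets of plausible widths (TFBS ~100–400 bp,
  chromatin states 1–5 kb, histone domains 2–10 kb, DHS 150–600 bp); the
  two score tracks are Gaussian values on a random half of the CpG
  positions, missing elsewhere.

Every component draws from its own child stream of the master seed
(`numpy.random.SeedSequence.spawn`), so fixtures are bit-reproducible
component by component and across platforms.

What passing tests on this simulator do **not** show: performance on real
methylomes. The simulated genome carries no sequence–methylation coupling
(sequence features are a near-null family here, whereas on real data they
are informative), annotation tracks other than the CGI family are pure
noise, coverage is spatially uniform (real RRBS concentrates at CpG-dense
loci), and all cells share one latent landscape (no subclonal structure).
The simulator validates the machinery and the relative ordering of feature
families, not absolute real-data accuracy.

## Default experiment sizes

Library analyses and the acceptance script run on the simulator defaults
(5 cells, two 1-Mb chromosomes, ~10,000 CpGs per chromosome, ~6,000
observed sites per cell), training on chr1 and testing on chr2, three
simulation seeds for the feature-family comparison — sizes at which every
stage's behaviour is already stable while the full suite runs in well
under a minute.

## Known limitations

* The gap-block slot duplication (S^l twice; the central gap twice in the
  absent case) is reproduced as defined; trees are insensitive to
  duplicated columns, but linear models built on these features would
  double-weight them.
* `merge_bundles` is lossy on rows where bundled features conflict; it is
  a reference construction, not the production path.
* The N3 overlap count implements one reading of an ambiguous definition
  (see above) and is parameterized rather than settled.
* Score tracks are stored as dense per-position arrays; genome-scale wig
  tracks would need a block-compressed backend (e.g. bigWig), out of scope
  here.
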