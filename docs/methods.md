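# Methods

## The question the pipeline operationalizes

DEG lists from independent expression studies of the same cancer
disagree strongly; enriched-pathway lists appear far more stable. The
pipeline makes that comparison quantitative: identify outlier genes per
dataset, enrich them against a common gene-set collection, and compare
the cross-dataset agreement of the two signature levels with paired
tests. A second question — do datasets fall into groups by the
similarity of their pathway profiles — is answered with a threshold
network over pathway-overlap percentages.

## Preprocessing

Two-channel arrays are background-corrected by subtracting the median
background from the median foreground per spot in each channel. Spots
with a non-positive corrected intensity in either channel become
missing rather than being clamped: a fabricated log-ratio would bias
the LOWESS fit. Within-chip normalization fits a locally weighted
regression of M = log2(R/G) on A = (log2 R + log2 G)/2 (span 2/3, one
robustness iteration — the span is a convention, exposed as a
parameter) and keeps the residual M − f(A). Between-chip normalization
median-centers every array and rescales it so all arrays share a common
MAD, the median of the per-array MADs; this applies to whatever value
matrix enters the stage (log-ratios for two-channel data, log
intensities otherwise). Genes missing in ≥ 60% of samples are removed;
the boundary is inclusive (a flag flips it to strict). Throughout, the
MAD carries the 1.4826 normal-consistency constant and the median of an
even count is the mean of the two central order statistics.

## COPA outlier calling

Per gene, `t = (x − median) / (1.4826 · MAD)` with both statistics over
the gene's non-missing values across **all** samples (option
`center_on="normal"` restricts them to normals). Genes with zero MAD
are flagged degenerate and excluded from counting rather than raising —
constant rows are common after filtering and are not an input error. A
tumor sample is an outlier when `t > 1.7`, strictly: a tie at the
cutoff does not count (the cutoff's provenance makes no statement about
ties, so the strict rule is fixed and documented). Only overexpression
is counted by default; `two_sided=True` counts `|t| > 1.7`. The
pre-filter keeps genes whose outlier count reaches the nearest-rank
percentile of the count distribution (default 95th): the threshold is
the `ceil(0.95·G)`-th order statistic, and ties at the threshold are
kept. Retained genes are ordered by count, then by maximum transformed
tumor value, then by identifier, making the output deterministic. The
retained list *is* the dataset's DEG signature downstream; no secondary
cut is applied.

## Enrichment

One-sided hypergeometric upper tail `P(X ≥ k)` per gene set, computed
through the survival function (log-space internally) so small p-values
survive; `k = 0` returns exactly 1. The universe is the intersection of
the dataset's (filtered) gene list with the collection's universe — the
conservative standard choice, configurable. Query genes outside the
universe are dropped with a logged count. Sets with zero overlap are
excluded before the BH adjustment (flag to include them). Two
significance rules are provided: `p < α` and `p < α AND q < α`
(defaults α = 0.05); the first is the pipeline default.

## Concordance

Overlap percentage = `100·|A∩B| / (|A|+|B|−|A∩B|)`. An empty list gives
0% with a warning (the 0/0 case has no meaningful value). For D
datasets all D(D−1)/2 unordered pairs are computed at both levels; the
pathway-level lists are significant-set *names*. The paired t-test uses
d = pathway − gene with df = n−1. The Wilcoxon signed-rank test drops
zero differences, assigns average ranks on |d| ties, and takes W = the
sum of positive-difference ranks; the p-value is exact — a dynamic
programme over rank sums, identical to enumerating all 2^n sign
vectors — when n ≤ 25 and |d| has no ties, otherwise a normal
approximation with tie correction and a 0.5 continuity correction.
Both tests default to two-sided, with `side="greater"` for the
directional hypothesis; outputs carry both.

## Similarity network

Datasets are embedded as binary indicator vectors over the union of
significant pathways (an option substitutes the overlap-percent rows).
Five distances are emitted: Euclidean, Manhattan, Hamming (count of
differing positions; equal to Manhattan on binary vectors), Pearson
1 − r (the phi coefficient on binary vectors) and Kendall 1 − τ_b.
Correlational distances are undefined for a constant row and raise,
naming the dataset. Edges connect pairs whose pathway overlap
percentage is **strictly** greater than two-thirds (200/3 %,
configurable); connected components, ordered by smallest member name,
are the dataset groups.

## Synthetic data generator

The generator emulates a multi-study compendium. Baseline expression is
Gaussian on the log2 scale: per dataset, gene means μ_g ~ N(8, 1) and
values x[g,s] ~ N(μ_g, σ). P = 20 gene sets of 15–40 genes are sampled
from a G = 2000 gene universe; T = 8 of them are the true cancer
pathways, shared by all datasets in a group. Per dataset, an
independent q-fraction of each true pathway's members becomes DE
(default q = 0.3), plus background genes at rate b = 0.005; each DE
gene gains +δ log2 units (default δ = 3) in a fresh random f-fraction
of tumor samples only (default f = 0.4 of 15 tumor samples, with 15
normals). The per-dataset resampling of the q-fraction is the core
design point: it is the mechanism that produces divergent gene lists
(expected truth-level Jaccard for two independent 30% subsets is
q/(2−q) ≈ 0.18) under identical pathway-level truth. Defaults were
chosen as a realistic desk-scale version of a five-study microarray
compendium: 2000 genes stands in for a filtered gene-level matrix,
δ = 3 log2 units is a strong but plausible outlier amplification, and
15 + 15 samples per study matches typical early microarray cohorts.

The two-group configuration (network recovery) uses D = 6 datasets in
two groups of three, P = 24 pathways with 8 disjoint true pathways per
group, and q = 0.5 instead of 0.3. The higher penetrance is deliberate:
group recovery requires each dataset's *enriched-set profile* to be a
reliable readout of its group's pathways, and with q = 0.3 a 15-member
pathway contributes only ~4 genes to a ~160-gene outlier list — a
hypergeometric overlap at the significance boundary, so a single missed
pathway can drop a within-group overlap below the two-thirds edge rule.
With q = 0.5 every true pathway is detected essentially always and the
planted partition is recovered in ≈ 98% of replicates.

What the generator does **not** emulate: platform-specific probe
effects, dye bias, heavy-tailed intensity noise, correlated genes
within pathways, missing values, or under-expression outliers. Passing
tests therefore demonstrate the pipeline's statistical machinery and
its qualitative behavior under the planted model, not performance on
real microarray data.

## Numerical and design choices

- All randomness flows from one `numpy.random.Generator` seeded by the
  config; identical config ⇒ bit-identical outputs, and the pipeline's
  run directory is byte-reproducible under a fixed seed.
- Degenerate inputs fail loudly and specifically: duplicate gene IDs,
  unlabeled samples, constant arrays under MAD scaling, constant rows
  under correlational distances, zero-variance paired differences.
- Acceptance-style checks run the 100-replicate recovery experiments at
  the default problem size (5 or 6 datasets × 2000 genes × 30 samples),
  about one second per replicate.

## Known limitations

- The Gaussian additive-shift signal model is favorable to COPA; the
  observed recovery rates are upper bounds relative to heavy-tailed
  real data.
- Gene identifiers are opaque strings; no probe-to-gene collapsing or
  alias resolution is performed — inputs must already be gene-level.
- The GSEA weighted-KS statistic is not implemented; enrichment is
  over-representation only.
- GMT files carry no universe; a file-based rerun reads an optional
  sibling `universe.txt` (written by the pipeline) to keep the
  hypergeometric N identical, else falls back to the union of set
  members.
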