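# Methods

This note documents the models and procedures `amdvir` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence comparison and clustering

**ANI / AF.** Average nucleotide identity is the alignment-length-weighted
mean percent identity over non-redundant local-alignment intervals;
aligned fraction is the merged coverage of the *shorter* sequence. Hits are
consumed best-score-first and only the novel coverage each contributes is
weighted, so redundant overlapping hits cannot inflate either statistic. A
pair with no hits scores (0, 0) rather than erroring.

**Built-in aligner.** Exact 21-mer seeds on a shared diagonal are chained,
extended with an X-drop rule (match +1, mismatch −2, drop 12) and rescored
with a global edit-distance alignment (edlib) of the spanned subregions.
This is accurate for the substitution-dominated divergence the generator
produces and for near-exact shared segments; for arbitrary real data an
external search tool's 12-column tabular output can be supplied and is
treated identically. Random uniform sequences essentially never share a
21-mer (expected ≈ L²·4⁻²¹), which keeps background pairs at zero hits.

**vOTU clustering** is greedy-centroid: genomes sorted by length
descending (ties lexicographic), each joining the first representative at
ANI ≥ 95 and AF ≥ 85, else founding a cluster. Whether the field's vOTU
dereplication uses centroid or connected-component grouping is not
universally fixed, so `linkage="single"` is available; centroid is the
default because it guarantees every member meets both thresholds against
its representative (a property the tests verify by brute force).
**Prokaryotic dereplication** is single-linkage at 97/70 with the
representative maximizing `completeness − 4 × contamination`; single
linkage is used because the representative rule only makes sense after the
group is formed. **Protein clustering** aligns the shorter protein as an
infix of the longer (end gaps free), charging every edit against the
shorter length; with this built-in route the coverage-of-shorter criterion
is satisfied by construction, and the 80% threshold becomes active when
externally computed local alignments are supplied instead.

## Coverage and abundance

`tpmean` sorts the per-base depths and removes ⌊trim·L⌋ positions from
each end (trim = 0.05), interpreting "regions" as positions — the behaviour
of the standard coverage parser this reproduces. Abundance is
`tpmean / library_reads × mean_library_reads`, which is invariant under
joint rescaling of a sample's depths and library size; the tests check
this to machine precision. Read alignments are pre-filtered at ≥ 95%
identity over ≥ 75% of the read. Protein-cluster abundance rolls up as the
*sum* of member genes (the only roll-up consistent with read counting);
population abundance is the representative genome's abundance.

## Virus–host linkage

CRISPR arrays are detected by a minimal exact-repeat detector: ≥ 3
identical repeats of 19–47 bp whose gaps (spacers) are 20–58 bp and
mutually distinct. The repeat unit is the seed word extended by the
*common* agreement of all adjacent copies, which keeps the boundary exact
even when two spacers happen to share a first base. Degenerate
(mismatched) repeats are out of scope. Spacer matching is exact substring
search on both strands: at spacer lengths ≥ 20 bp a zero-mismatch,
full-length criterion makes any E-value bound redundant, so no alignment
statistics are computed; shorter spacers are rejected with a warning.
Homology linkage filters tabular hits at E ≤ 10⁻³, bit ≥ 50, length
≥ 2.5 kb, identity ≥ 70%; prophage linkage uses recorded provenance
(source scaffold → binned population) because viral identification itself
is out of scope. Genome-level pairs map through the clusterings with
evidence flags unioned and support = distinct genome pairs.

## Lineage dynamics

VHR is the per-sample ratio of summed linked-virus abundance to summed
host-phylum abundance, summarized as the mean of log₁₀ ratios
(`mean-of-ratios`; `ratio-of-means` available). Viruses linked to several
phyla contribute their full abundance to each — matching the "viruses
infecting the same host lineage" reading — with an equal-split option.
Correlations use only samples where both sums are positive and require
≥ 3 such samples. Host range / viral range are distinct-partner counts on
the population-level link set, averaged within phyla. Lifestyle trends
regress each class's summed relative abundance on total prokaryotic
abundance; group contrasts use the unpaired two-sided Wilcoxon
(Mann–Whitney) test. Polynomial fits of viral on prokaryotic abundance
default to degree 2 (exposed as a parameter).

## Bipartite network structure

Barber's bipartite modularity is maximized with BRIM: alternate
optimization of row labels given column labels and vice versa, which is
monotone and converges to a fixed point. Each run restarts from two
deterministic labelings plus `n_restarts` random ones, alternating the
initial module count between min(rows, cols) and max(rows, cols), and
interleaves a greedy module-merging pass with further alternation until
neither improves. Starting at up to min(rows, cols) modules (rather than
⌈√min⌉) lets partitions with many small modules — e.g. collections of
disconnected edges — be reached; merging then shrinks the count. On every
random graph with ≤ 10 nodes tried in the tests (hundreds), the result
equals the exhaustive-search optimum computed by enumerating set
partitions of the smaller side.

NODF follows the overlap-and-decreasing-fill definition: for each pair of
rows (and columns) with strictly different marginal totals, the percentage
of the poorer line's 1s present in the richer line; equal totals contribute
zero; the score is the mean over all row and column pairs, in [0, 100].
Isolated nodes are kept in sub-network node lists but dropped from metric
matrices. Permutation nulls are `equiprobable` (Bernoulli at the observed
fill; the default, recorded in the output metadata) or `degree-preserving`
(checkerboard swaps), with add-one empirical p-values
`(1 + #{null ≥ obs}) / (1 + n_perm)` so finite permutation runs never
report p = 0.

## Biogeography

Community matrices are Hellinger-transformed (√ of row-relative
abundance); environmental tables are column z-scores. Bray–Curtis is used
for communities, Euclidean for environment; a pair of all-zero samples
gets distance 0 with a warning. PCoA is classical scaling with negative
eigenvalues reported but their axes dropped (no Lingoes/Cailliez
correction, matching plain PCoA usage); axis signs are fixed by making the
largest-magnitude loading positive. The Mantel statistic is Pearson r over
strictly-lower-triangle entries with joint row/column permutation;
pairwise Pearson correlation matrices carry analytic two-tailed p-values
adjusted by Benjamini–Hochberg step-up across all pairs (permutation
p-values are reserved for Mantel, where exchangeability is well defined).
Distance-decay regressions treat sample *pairs* as units — as such plots
are conventionally drawn — with no correction for pair non-independence;
the Mantel test is the inferentially sound companion. Pairs at zero
geographic distance are assigned half the smallest positive distance
before log₁₀ (flagged in output). The local/regional split is at 1 km.

## Path models

Only observed-variable recursive models with independent errors are
supported (the drivers diagrams this reproduces contain no latent
variables). Data are standardized, each endogenous variable is fitted by
OLS on its stated parents (maximum likelihood for this class), and the
model-implied covariance Σ(θ) = (I − B)⁻¹ Ψ (I − B)⁻ᵀ is compared with the
sample covariance through F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p, χ² = (n − 1)F,
df = p(p+1)/2 − (#edges + #free covariances + p variances). A saturated
model reproduces S exactly (χ² = 0, flagged saturated, RMSEA 0). Model
specs are plain-text edge lists (`A -> B`, `A ~~ B`); the shipped example
spec frees all exogenous covariances, since which covariances a final
fitted model freed is usually not recoverable from a published diagram.
Model refinement is manual, not automated search.

## The synthetic community generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline is meant to exercise: 18 sites × 5 samples (90
libraries), four host phyla × 3 host populations × 2 viral clusters,
genomes of 10–20 kb (the lower end of the 10–350 kb range the pipeline
targets, chosen so alignment-based tests run in seconds), divergence
levels {0, 3%, 10%} straddling the 95% ANI threshold, planted per-phylum
VHRs log-spaced 1–10, prophage/CRISPR planting probabilities 0.3/0.5 with
a ≥ 2.5 kb shared segment guaranteed whenever neither fires, a −0.10
distance-decay target, one generalist virus per phylum, and lognormal
multiplicative noise (σ = 0.1). End-to-end checks use a 10-site × 3-sample
(30-sample) configuration of the same community.

Design points worth knowing:

- **Substitutions only** (no indels), with exactly ⌊d·L⌉ mutated
  positions, so expected ANI is analytically 100(1 − d) and clustering
  tests can be exact. Background genomes are i.i.d. uniform ACGT; at
  ≥ 10 kb the chance of a spurious ≥ 2.5 kb homology is negligible, so the
  truth table is clean.
- **Truth is verified against the constructed sequences**: a CRISPR link
  is recorded for every cluster member whose protospacer region survived
  mutation intact (a coordinate lookup, not a search), and homology links
  are recorded for every member — including members promoted to their own
  vOTU by divergence — whose shared segment still exceeds the 70%/2.5 kb
  thresholds. This keeps linkage precision/recall measurable without
  re-implementing the detectors.
- **Ecology**: host abundances are lognormal bases modulated by an
  exponential spatial kernel on site coordinates and a latitudinal
  richness gradient over nested presence ranks; virus abundance flows from
  linked hosts through the planted VHRs (each host's contribution split
  over its linked viruses, so phylum sums reproduce the planted ratio
  exactly in the noise-free limit). The kernel length is chosen from a
  small grid to approximate the requested distance-decay slope, and the
  *achieved* noise-free slope and per-phylum VHRs are stored in the truth
  table rather than assumed exact — generalist cross-phylum links
  deliberately contaminate phylum VHRs, and the truth records what was
  actually planted.
- **Generalism gradient**: each phylum's generalist additionally links
  into the rarest hosts of other phyla, and presence ranks are nested, so
  species-poor samples see near one-to-one (modular) sub-networks while
  rich samples gain the cross-phylum generalist edges (nested). This is
  what makes the modularity-decreasing / nestedness-increasing directions
  testable.
- **Depth tracks** are uniform per (entity, sample) at
  `abundance × 1000 × library-size factor`, rounded to integers; the
  coverage pipeline therefore recovers the planted abundances up to
  quantization (relative error < 1% above depth ~50). Tracks are written
  in a compact uniform-depth TSV encoding.
- **Metadata** come from the configurable recursive DAG (latitude entering
  as the observed coordinate's z-score, other exogenous variables standard
  normal); they are synthetic covariates for the path-model stage, not
  derived from the simulated communities. Lifestyle labels are assigned
  assortatively by each virus's correlation with total prokaryotic
  abundance (90% assortment), planting the virulent-increasing trend
  without touching abundances.
- Per-site sample dispersion is a free parameter (`site_jitter_km`,
  default 0.3 km) — small enough that within-site pairs fall under the
  1-km distance-decay breakpoint.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level noise and assembly artefacts
(depth is uniform, not a pileup of stochastic reads), indels and
rearrangements, degenerate CRISPR repeats, genuinely shared gene content
between unrelated genomes, realistic geochemical covariance structure, and
host/virus taxonomy beyond the supplied labels. Statistical calibration
(Mantel type-I error, χ² behaviour, BH arithmetic) is checked on direct
simulations independent of the community generator.

## Determinism and problem sizes

Every simulation and permutation consumes a `numpy` Generator seeded from
explicit integers; the pipeline fans one global seed into per-stage
streams by hashing stage names (seeds stay below 2³¹), so stage-level
reruns reproduce byte-identical outputs. The default test suite and the
acceptance script run 30-sample communities, 100-graph metric oracles,
1000-replicate Mantel calibration and 200-replicate path-model recovery —
sizes chosen so the whole validation completes in a few minutes on one
CPU while keeping every statistical check's Monte-Carlo error well inside
its tolerance.

## Known limitations

- The built-in aligner targets near-identical or exact-copy homology; real
  divergent homology detection should come from an external search tool's
  tabular output (supported everywhere hits are consumed).
- BRIM is a heuristic; optimality is only guaranteed empirically (and
  verified) on small graphs.
- OLS p-values in distance-decay fits ignore pair non-independence by
  design (see above).
- The LCA support threshold on real annotation data is a convention; the
  default (> 50% per rank) is exposed as a parameter.
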