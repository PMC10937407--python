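# Methods

This note documents the models and procedures implemented in `mtlineage`,
the parameter defaults and why they were chosen, what the simulator does
and does not emulate, and the package's numerical conventions.

## Generative model (`mtlineage.simulate`)

The simulator produces the study conditions for every downstream test: a
clonally structured cell population accruing heteroplasmic mtDNA mutations,
sequenced at molecule resolution with endogenous-UMI structure.

**Population.** A single ancestral cell divides through a random Yule
topology into `n_clones` founders (`founder_divisions` divisions
root-to-founder, default 120 — standing for decades of stem-cell history,
which is what makes clones mutationally distinguishable), and each founder
divides into `cells_per_clone` sampled cells (`divisions_per_cell` more
divisions, default 15). `cells_per_clone` may be a per-clone list to build
oligoclonal ("aged") compositions.

**mtDNA dynamics.** Every cell carries `mt_copies` genomes (default 300).
At each division all genomes replicate once; each newly synthesised genome
gains `Poisson(mu)` substitutions at uniform random positions (recurrent
mutation allowed — homoplasy is a real feature the prior-weighted distance
must absorb); the `2 × mt_copies` genomes are partitioned binomially
between daughters, the simplest neutral drift model. At a branch point the
two daughters are the complementary halves of one division, so sibling
heteroplasmies are properly anti-correlated. Mutations are tracked as
per-cell copy counts; linkage between mutations on one genome is not
tracked (carrier genomes are re-drawn as random cyclic blocks at capture
time). No statistic in the pipeline depends on within-genome linkage, but
analyses of co-occurring heteroplasmies would need a finer model.

**Sequencing.** Library preparation fragments every genome copy, so the
number of captured fragments per cell is
`Poisson(mt_copies × capture_rate × L / fragment_len_mean)` and the
expected per-position coverage (genome copies seen per position) is
`mt_copies × capture_rate` — default `300 × 0.04 = 12`. This is a
deliberately scaled-down sequencing depth chosen so that the full
pipeline runs comfortably at ~5,000 cells on one CPU; the consequence of
lower coverage is reduced sensitivity to low-heteroplasmy variants, which
the mutation-rate default compensates (below). Each fragment is one
molecule/eUMI: reads per group are `1 + Poisson(reads_per_eumi_mean − 1)`
(mean 4.8, matching the reported typical eUMI group size), alternating
plus/minus mates spanning the whole fragment, corrupted at
`seq_error_rate = 1e-3` per base. Fragments are sampled on the linear
coordinate frame (no origin-spanning fragments); eUMI collisions arise
naturally when two molecules draw the same interval (~1–3% at defaults).

**Calibration.** `mu = 0.022` new substitutions per genome replication was
calibrated once so that, at the default 50 × 40-cell regime, consensus
calling and filtering yield a **median of ~9 detected variants per cell**,
the burden scale of the deep mtDNA single-cell data this pipeline targets.
This is the one calibrated constant; everything downstream (clone
recovery, propagation accuracy) is measured, not tuned. The literal
per-replication rate is higher than in vivo estimates because it also
compensates the scaled-down coverage and the truncated (120 + 15 division)
history.

**Cell states.** Per clone, lineage proportions over
{Myeloid, Erythroid, MK, Lymphoid} are drawn once from a symmetric
`Dirichlet(bias_alpha)` (default 0.8 → pronounced biases) and reused at
every timepoint, so clone biases are persistent by construction; stem
cells are flagged i.i.d. with `frac_hsc = 0.2`; timepoints are uniform.
The simulator emits **labels only** — no RNA/ATAC readout, no selection on
mtDNA variants, no cell-state-dependent division rates. Passing tests
therefore demonstrate the pipeline's correctness under neutral, perfectly
labelled conditions, not robustness to doublets, ambient contamination,
alignment artefacts or state-dependent capture biases in real data.

## Consensus calling and filtering (`mtlineage.consensus`)

Reads are grouped by the exact eUMI key (cell, fragment start, fragment
end) — no fuzzy endpoint merging; the small collision rate is tolerated.
Groups below `min_group_size = 2` are rejected; a non-reference consensus
base needs a consensus score (supporting reads / group size) ≥ 0.75 and,
when the group contains both mates, support on both strands. The
`specific` preset tightens to ≥3 reads and unanimity. Variant filters:
blacklist positions 300–316 and 3106–3110 (rCRS poly-C artefact regions);
germline/haplogroup variants, defined as heteroplasmy ≥ 0.9 in ≥ 90% of
covered cells; variants in fewer than 2 cells. These numeric defaults are
this package's choices implementing the standard "stringent multistep
filtering" intent; they are all exposed in `FilterConfig`.

The per-sample **eUMI filtering rate** is defined as (groups passing the
size filter) / (all groups). **Coverage** per cell is total retained
fragment length / genome length. **Burden** is
`n_mutations / (filtering rate × coverage)`; note that burden is a
normalised rate — doubling every molecule doubles coverage and (for
coverage-limited detection) the detected mutation count, leaving burden
stable. **Signatures** classify each variant by substitution and
trinucleotide context on the pyrimidine-reference strand, labelling the
strand L when the sense (light-strand) base is the pyrimidine; the
circular genome provides context across the origin.

## Matrix algebra (`mtlineage.matrix`)

Heteroplasmy `H = C / copies-per-position`, capped at 1. The weighted
Jaccard denominator sums priors over the **union** of the two cells'
variants (classical weighted Jaccard); the alternative all-variant reading
would make distances depend on variants carried by neither cell. Two empty
profiles are at distance 0, empty vs non-empty at 1. LSI uses
row-normalised TF, `IDF = log(1 + n_cells/df)`, truncated SVD with a fixed
seed and a deterministic sign convention; all computed components are
kept. These are the common single-cell LSI conventions; the dialect is
configurable.

## Phylogeny and clonal groups (`mtlineage.tree`)

Neighbour joining (scikit-bio) on weighted-Jaccard distances or LSI
Euclidean distances; rooting by an artificial outgroup with an empty
mutation profile (distance 1 to every cell under weighted Jaccard) —
chosen because an unmutated ancestor is the natural root when distances
measure mutation sharing; negative NJ lengths are clamped to zero.

Branch assignment maximises, over every edge (the root edge, covering all
leaves, included),

    log L(e) = |O∩C_e| log s + |C_e∖O| log(1−s) + |O∖C_e| log f + |rest| log(1−f)

with defaults `s = 0.9` (mtDNA variant dropout is substantial) and
`f = 0.001` (consensus-corrected false carriers are rare); probabilities
are the softmax over edges and "confident" means ≥ 0.6. This is a generic
reconstruction of maximum-likelihood variant placement for single-cell
mtDNA trees; the exact internals of prior implementations are not
reproduced. Tree cutting selects minimal (deepest qualifying, disjoint)
clades with ≥ m cells (default 50) and ≥ n confident variants on the based
edge (default 1); clones below the dump threshold are discarded. For
simulated regimes the analysis sets `m` below the simulated clone size
(e.g. 25 for 40-cell clones) — `m` is an analysis parameter matched to
the expected clone scale, and clone-recovery scores are computed on the
clone-assigned cells (the assigned fraction is reported alongside).

`collapse_short_branches` converts near-zero NJ edges into
multifurcations; the coalescent expansion test needs this, since on a
strictly binary node its sister-comparison p-value is `(n−b)/(n−1)`,
which is never small.

## Propagation (`mtlineage.propagation`)

The "damping factor 0.05" is implemented as the restart probability: the
fraction of walk mass returned to the seed distribution each step. W is
the column-stochastic transition matrix of the unweighted mutual-KNN
adjacency (k = 30; distance-weighted edges available but off by default);
degree-zero nodes become absorbing self-loops; convergence is L1 change
< 1e-6 (iterative and closed-form solutions agree to ≤1e-8 on small
graphs, and scores conserve mass to ≤1e-9). Per cell, clone scores are
normalised to sum 1 and the arg-max clone is accepted when its probability
exceeds 0.7. In the self-assignment benchmark seed cells stay in the
network (matching how such benchmarks are run); a leave-self-out mode is
available for stricter generalisation estimates, and the permutation
oracle (scoring against shuffled truth) gives chance-level accuracy.

## Clone-level statistics (`mtlineage.clonal`)

Lineage biases: per clone × lineage and timepoint, an exact binomial test
one-sided toward the observed direction against the background proportion
of all progeny at that timepoint; Fisher's method (χ², 4 df for two
timepoints) combines the timepoints; Storey q-values correct the whole
clone × lineage family together; a clone is *biased* only when the
fold-change direction agrees at both timepoints (direction-consistency,
not magnitude, is the implemented reading of "consistent enrichment").
Significance bands: \*, FDR 0.05–0.20; \*\*, 0.01–0.05; \*\*\*, <0.01.
Clone-to-state preferences use hypergeometric upper tails with the
composite cutoff combined P < 0.01, FDR < 0.05 and log2 fold change >
0.25 at both timepoints. Lineage-informative variant selection tests each
variant's carrier frequency between every pair of the four trajectories
with a two-sided exact binomial test against the pooled rate (vectorised
double-tail convention, conservative under the null); variants with all
pairwise p > 0.05 are removed as randomly distributed. Clones are matched
across timepoints by Jaccard ≥ 0.5 of their defining variant sets
(greedy best-first), a rule this package defines since re-observation of
clones needs an explicit matching criterion. Storey's q-value estimator
uses `pi0 = #{p > 0.5} / (0.5 m)` clipped to (0, 1]; pass `pi0=1` for the
BH-equivalent conservative variant on small families.

## Ageing analyses (`mtlineage.aging`)

Shannon index `S = −Σ (size_i/n) ln(size_i/n)` (natural log). The
coalescent clade test uses the exact pmf
`P(b|n,m) = C(n−b−1, m−2)/C(n−1, m−1)` and the hockey-stick closed-form
tail `C(n−b, m−1)/C(n−1, m−1)`; expanded clades are maximal flagged clades
(p < 0.01 and ≥ 5% of cells; an absolute-size option exists). The fitness
proxy is the local branching index — exponentially discounted tree length
via two-pass message passing, default `tau = 0.3 ×` mean leaf depth; it is
a tree-shape proxy in the same literature lineage as full probabilistic
fitness inference, and exact fitness coefficients are not reproduced. LOY:
the expected chrY fragment fraction defaults to the aggregate ratio
(median-of-ratios available as a robust alternative); a cell is LOY iff
its chrY count is tenfold below expectation **and** the exact binomial
lower tail is < 0.001; clade enrichment reports LOY density, a z-score
with binomial variance (the variance convention is this package's choice),
a one-tailed binomial p and Storey q-values.

## Numerical conventions and problem sizes

1-based inclusive coordinates on a circular genome (default 16,569 bp);
variant ids `{pos}_{ref}_{alt}`; a deterministic synthetic reference
sequence keeps the package free of genome data files. All randomness
flows from explicit integer seeds through split substreams, so identical
seeds give byte-identical outputs. Likelihoods use `xlogy` so that
`0·log 0 = 0` and `f = 0` stays finite in log space. The test suite and
acceptance script run their end-to-end checks at 200–5,000 cells with
coverage ~12 — sizes chosen as the package's desk-scale defaults; all
statistics are formulated per-cell/per-molecule and scale unchanged to
larger datasets.

## Known limitations

- Substitutions only: no indels, no base-quality modelling, no alignment.
- The simulator's capture model draws fragments independently per genome
  copy; real tagmentation produces correlated, non-uniform fragmentation.
- The germline filter assumes a single donor; mixed-donor data would need
  haplogroup-aware handling.
- The expansion test requires multifurcations to have power; apply
  `collapse_short_branches` to NJ trees first.
- The LBI fitness proxy ranks cells by local tree density; it does not
  estimate selection coefficients.
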