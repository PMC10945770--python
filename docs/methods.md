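# Methods

## Model and assumptions

The package treats a gene's rooted phylogenetic tree, with branch lengths
in substitutions per aligned site, as a complete record of its molecular
evolution in the sampled species. Three measurement scales follow
directly: the total tree length (all evolution since the last common
ancestor), the root-to-tip distance of each lineage, and the patristic
distance between any two sequences. These are purely additive path sums —
no substitution model is fitted here; branch lengths are taken as given
(typically maximum-likelihood estimates from an external tree builder).
Because the same alignment length and model underlie every branch of one
tree, tree-length comparisons between genes are meaningful only when the
input trees were inferred under a shared model, which is the caller's
responsibility.

The directional-selection test assumes the trait of tip *i* is linear in
that tip's root-to-tip distance with independent Gaussian residuals,
`trait_i = a + b·rtt_i + ε_i`, and fits it by ordinary least squares. The
intercept estimates the ancestral trait because the ancestor sits at
rtt = 0. Residual independence across tips is an explicit simplification:
phylogenetic residual correlation is not modelled (no PGLS), so p-values
are anti-conservative to the extent that closely related species share
trait deviations. This is a known limitation, not an oversight; the
estimator surface is the plain least-squares one throughout.

## Preprocessing

Codon alignments are produced by threading coding sequences through their
aligned proteins (each residue → its codon, each gap → `---`), with a
single terminal stop codon dropped silently and internal stops treated as
errors. Trimming keeps only ubiquitously aligned (gap-free) columns, in
whole codons for codon alignments. Cohort hygiene follows two rules: a
sequence is dropped when shorter than 50% of the median length of all
*other* sequences in its cohort (leave-one-out median, so a truncated
record cannot shelter itself), and an alignment enters the analysis only
with strictly more than 50 ubiquitously aligned positions (51 passes, 50
fails — the threshold is read as a strict inequality). Transit peptides
and other non-ubiquitous leading regions are removed implicitly by the
gap-free trim; no peptide predictor is included.

## Stratified bootstrap

Multi-copy families inflate a tree's total length relative to single-copy
genes. The stratified bootstrap removes this: each of `n_reps` (default
1000) replicates samples exactly one leaf per species uniformly at random,
prunes the tree to that sample while collapsing unary nodes by summing
incident branch lengths (so all retained path lengths are exact), and
records the pruned total length. The summary is the mean and sample SD
(ddof = 1) over replicates; a seed is mandatory and replicates are
bit-reproducible. The input tree is fixed across replicates — trees are
not re-inferred per sample — which is consistent with branch lengths being
per-site estimates on a fixed alignment and keeps the procedure exactly
reproducible at desk scale.

## Percentile ranking

For one species pair, the background cohort is the set of patristic
distances between that pair's orthologous sequences across all orthogroup
trees containing both species. By default every cross-species leaf pair in
an orthogroup counts (which over-counts when in-paralogs are present); an
explicit ortholog-pair list, e.g. exported from an orthology tool,
overrides the default. The focal gene's rank is
`100 · (#{d > focal} + ½·#{d = focal}) / n` — the percentage of the
background evolving faster, with midrank tie handling. Pairs with
`n < 100` background measurements are retained and flagged rather than
silently dropped, and excluded from summaries. When duplications give one
species pair several focal comparisons, their percentiles are averaged and
the group's smallest background size is reported.

## Neutral expectation

The expected protein change per nucleotide change without selection is
computed by exhaustive enumeration: for each codon the 9 single-nucleotide
mutants are listed, mutants that are stop codons are excluded, and the
nonsynonymous fraction of the remainder is averaged over codons (uniform
mutation model — no transition/transversion or codon-usage bias, as none
is warranted without a fitted mutation model). Because protein branch
lengths are per amino-acid site (3 nucleotides), the neutral line for the
percentage ratio of protein to nucleotide tree length is `300 · f_N`. A
sequential-substitution simulator (uniform proposals, stop-creating
proposals rejected and redrawn) provides the Monte-Carlo cross-check; its
realised amino-acid-change fraction is compared with the enumeration
averaged over the start and end sequences, since composition drifts
slightly over a long run.

## Rate-conversion chain

With `n_sites` aligned positions and clade age `T` My, the fitted slope is
converted as: change per substitution `b/n_sites`; substitution interval
`T/(mean(rtt)·n_sites)` My; relative improvement per substitution
`100·(b/n_sites)/a` %; improvement per My = the previous quantity divided
by the substitution interval, always computed from unrounded intermediate
values and rounded only for display (one decimal for per-substitution
percentages, two for per-My values). The default clade age is 160 My (the
age of the angiosperm radiation, the clade the package's motivating
analysis concerns); it is a plain parameter everywhere.

## Synthetic data

The generator produces data with exactly the structure the estimators
assume. Species trees are Yule: from two lineages, the next speciation
arrives after an Exponential(k·λ) wait among k active lineages, with one
final Exponential(n·λ) stretch so all pendant edges are positive; the
expected root-to-tip depth is `(1/λ)·Σ_{k=2..n} 1/k`, which the tests use
as a closed-form oracle. Orthogroup cohorts multiply every branch of the
species tree by a gene rate `r_g ~ LogNormal(μ, σ)` — heavy-tailed rate
variation, the regime in which percentile ranking is informative — plus
optional per-branch Gamma jitter with mean 1 and a stated CV. Multi-copy
families replace species tips by stars of copies whose pendant lengths are
uniform on (0, divergence), so copies genuinely differ and the stratified
bootstrap has non-zero variance (equal pendants would make it exactly
degenerate). Traits are `a + b·rtt + Normal(0, σ_noise)` on a
rate-jittered gene tree (an ultrametric species tree has constant rtt and
no regression signal; the jitter CV for the focal gene tree defaults to
0.3).

Defaults are fixed once as the study conditions of the motivating
analysis: 93 taxa (the C3 angiosperm kinetic sample), intercept 81.1 (the
inferred ancestral CO2/O2 specificity), slope 20 trait units per
substitutions-per-site with noise SD 5, LogNormal(0, 1) gene rates over
200 orthogroups, copy-number distribution {1: 0.35, 2: 0.30, 3: 0.20,
4: 0.15} (mean ≈ 2.2 copies, the multi-copy small-subunit flavour), clade
age 160 My. All simulators require an explicit seed and are
bit-reproducible.

What the generator deliberately does *not* emulate: phylogenetically
correlated trait residuals, sequence-level evolution (other than the
neutral-oracle simulator), gene-tree/species-tree discordance, alignment
error, and non-uniform mutation. Passing tests therefore demonstrate that
the estimators recover the generative model they assume — they do not
demonstrate robustness of the scientific conclusions to violations of that
model on real data.

## Numerical choices and degenerate inputs

Negative branch lengths are rejected on parse (ML outputs should be
non-negative; silent clamping hides corrupt input) with an opt-in
clamp-to-zero. Missing branch lengths are errors naming the node. Path
and pruning invariants are held to 1e-9 relative tolerance in tests; the
OLS implementation agrees with closed-form normal equations to 1e-10. A
constant response gives slope 0, r² = 0, p = 1 (the no-evidence
convention for a zero-variance test statistic); a constant predictor is an
error. Rerooting splits the chosen edge at its midpoint, which preserves
total length and every leaf-to-leaf distance (any split point would; the
midpoint is the tie-break). Empty trimmed alignments are returned with a
warning rather than raised, since a caller filtering many orthogroups
wants to count them, not crash.

Problem sizes in the test-suite simulations (500-orthogroup cohorts,
500-replicate recovery experiments, 2000 null regressions, 100-tree
invariant sweeps, 10 000-substitution neutral runs) were chosen so each
Monte-Carlo check has comfortable statistical power — bias thresholds of
0.1 replicate-SD and 3-SE bands — while the whole suite stays desk-scale.

## Pipelines and reproducibility

Each pipeline emits a manifest: SHA-256 checksums of its inputs, the
configuration snapshot, seeds, package version and per-stage row counts.
Identical inputs, config and seed reproduce identical numeric output.
Tabular output is tab-separated, `.` decimal, `NA` for missing. The CLI is
a thin layer over the library; the importable API is the primary surface.
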