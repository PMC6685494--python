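# Methods

## Divergence as an insertion-age proxy

A TE copy accumulates substitutions roughly neutrally after insertion,
so its Kimura 2-parameter (K2P) distance to the family consensus is a
clock-readable age. K2P is computed on gap/N-excluded columns of an
aligned pair as d = −½·ln[(1−2P−Q)·√(1−2Q)], with P and Q the transition
and transversion proportions; no CpG adjustment is applied (plain Kimura
1980). Saturation — a non-positive log argument — raises rather than
returning a clamped value.

The clock converts divergence to absolute time as
age_years = d / (lineage_factor · μ · g) with defaults
μ = 1.9×10⁻⁹ substitutions/site/generation and g = 4 generations/year.
`lineage_factor` defaults to 2 (pairwise convention: substitutions
accrue on both the copy lineage and the consensus lineage), which makes
the standard conversions come out at d = 0.2 → 13.2 Myr,
0.1 → 6.6 Myr, 0.05 → 3.3 Myr. A single-lineage reading
(`lineage_factor = 1`) doubles these ages and is available because both
conventions appear in the comparative literature; the factor is an
explicit, configurable model choice, not a hidden constant.

Insertions with d < 0.05 are classified "recent", d ≥ 0.05 "old" — the
boundary itself is old because "recent" is defined strictly as below the
cutoff. Landscapes bin hit bp by divergence (default width 0.01,
left-closed right-open, d = 1.0 in the last bin) and divide by genome
size; bins sum exactly to the total annotated proportion.

## Genome proportions and comparative summaries

Proportions are raw annotated bp over genome size with **no overlap
collapsing** — the masked-bp convention. Cells can therefore slightly
exceed what a collapsed annotation would give; recent + old = all holds
exactly per cell, and class-level cells equal the sum of their family
cells. Clade comparisons use Welch's unequal-variance t-test (the safer
default when clade variances differ). PCA operates on column-centered
(optionally scaled) proportions via SVD, with each component's sign
fixed so its largest-magnitude loading is positive. Pearson correlations
between recent SINE and LINE family proportions leave constant columns
as missing (NaN) rather than coercing them to zero.

## Presence scoring and branch origination rates

A family is scored per species from the total bp attributable to it in
the full annotation: 1 if ≥ 5,000 bp, 0 if < 500 bp, 0.5 between. A
family's origin branch is the stem of the smallest clade C containing
all its score-1 species, accepted iff (i) the presence sum over C
reaches the clade threshold — n − 0.5 for an n-member clade,
generalizing the worked 4 → 3.5 example, overridable per clade — with a
single-tip clade requiring a full score of 1, and (ii) every tip outside
C scores exactly 0 (a 0.5 outside blocks assignment by default;
a config flag relaxes this to "no score-1 outside"). Families that fail
are reported as unassigned with a reason (no presence, sum below
threshold, nonzero outside the clade, or an origin older than the root);
nothing is silently dropped. This is a parsimony-style placement, not a
probabilistic ancestral-state reconstruction — hybridization or
incomplete sorting will surface as unassigned families, which is the
intended behavior.

Origination rate per branch is assigned-family count divided by branch
duration (parent age − child age, Myr); rates scale inversely with a
uniform rescaling of node ages. Lineage contributions sum the bp of all
hits of branch-assigned families per descendant species.

## SINE subfamily detection

Copies ≥ 240 nt are locally aligned to trimmed reference consensuses;
the core is the span from the minimum alignment start to the maximum
alignment end across references, and cores < 235 nt are discarded (with
counted reasons). The similarity network joins cores sharing exact
8-mers (plus strand only, top 50 candidates per query by shared-word
count), weighted by the local alignment score with match +1, mismatch
−2, gap open −5, gap extend −2 — a seeded-search stand-in for a BLASTN
all-vs-all with word size 8. The default edge gate (score ≥ 50) sits
far above the null score of unrelated 300-nt sequences (a
`random_score_threshold` helper recomputes a null quantile for other
lengths) and far below within-subfamily scores (~250+).

Communities minimize the Reichardt–Bornholdt Potts Hamiltonian with the
configuration null model, optimized by the seeded Leiden algorithm
(`leidenalg.RBConfigurationVertexPartition`), which optimizes exactly
this quality function. **The resolution γ is scale-dependent**: the null
term γ·s_i·s_j/2m grows with total graph weight, so the value γ = 59
appropriate for a genome-scale network of ~4×10⁵ copies shatters a
desk-scale network of ~10³ copies into singletons. The module exposes γ
(default 59, honoring the genome-scale setting); the pipeline default
and the synthetic-scale tests use γ = 1, at which planted partitions are
recovered with ARI 1.0. Community labels are canonicalized (by
decreasing size, then first member) so output is deterministic.

Per community, up to 30 members are sampled without replacement
(seeded), multiple-aligned with the in-package center-star aligner
(global pairwise alignments to the highest-total-score member, merged
column-wise, "once a gap always a gap"), and summarized by column
majority with gap-majority columns dropped. Communities whose
consensuses share an exact run covering ≥ 95% of the shorter consensus
(100% identity / 95% coverage) are merged transitively (union-find) and
their consensuses recomputed. Subfamily consensuses are grouped by
greedy incremental clustering in decreasing-length order at ≥ 95%
identity over the full length of the shorter sequence (edlib infix
alignment); library collapsing uses the same scheme at 90% identity with
the aligned span required to cover ≥ 90% of each sequence.

## SINE–LINE partnerships and tails

Nonautonomous SINEs are mobilized by partner LINEs that recognize their
3′ end. The partner call locally aligns the SINE's 3′-terminal 100 bp
against each LINE's 3′-terminal 300 bp and accepts the best-scoring LINE
with identity ≥ 0.70 over ≥ 40 aligned bp (gates chosen to reject random
tails by a wide margin, given that a ~300-nt random pair rarely aligns
past ~20 bp at these scores); ties break by name, so the call is
independent of library order.

Tail composition samples, per species × stratum (recent/old at d =
0.05), up to 100 full-length copies (consensus coverage ≥ 90%) without
replacement, 10 replicates, seeded. The tail is everything 3′ of the
last consensus-aligned column of the copy. Base counts are pooled per
replicate and all six unordered pair ratios reported as
log₂(x+1) − log₂(y+1) (the +1 pseudocount prevents log 0; computing the
ratio as a difference of logs makes antisymmetry exact). Strata with no
eligible copies yield flagged empty profiles.

## Alignment utilities

Trimming drops columns whose non-gap occupancy falls below 0.6 but never
below a floor of 60% of the original columns (the floor retains the
highest-occupancy columns, ties broken by position) — an interpretation
of trimal's `-gt 0.6 -cons 60`. The plurality consensus emits a
column's most frequent residue only when its count reaches 3 and it is a
strict plurality among non-gaps; ties and under-threshold columns emit
N, all-gap columns are dropped. Divergence summaries align members to a
consensus with free end gaps and report mean/range K2P distances,
excluding (and counting) saturated pairs.

## Phylogenetic statistics

Z-transformation standardizes tip traits to mean 0 and sample SD 1
(n − 1). Independent contrasts follow Felsenstein's pruning algorithm:
at each internal node of the (strictly bifurcating, positive-branch)
tree the contrast (x_L − x_R)/√(v_L + v_R), the weighted-average
ancestral value, and the inflated parent branch v + v_L·v_R/(v_L + v_R).
As a linear map A of tip values, the contrasts satisfy A·C·Aᵀ = I for
the Brownian covariance C — the property the tests verify against a
covariance matrix built directly from shared root-to-MRCA path lengths.
Contrast regression goes through the origin (standard for PIC); p-values
come from the t distribution with n_contrasts − 1 degrees of freedom.
Multiple-testing correction defaults to Holm (uniformly no weaker than
Bonferroni); Bonferroni is available.

Note on the "slope within 2 SE" recovery check: at small tip counts the
t interval at ±2 SE covers well under 95% (df = 6 covers ~91%), so the
simulation-based check runs on a 64-tip tree where 2-SE coverage is
close to its nominal ~95%.

## The synthetic generator — what it emulates and what it does not

`simulate_history` plants families on branches as a Poisson process
(per-class rates, defaults of order 0.05–0.5 families/Myr as observed on
heliconiine terminal branches), deposits lognormal copy counts in every
descendant tip with class-typical lengths (SINE ~300 bp, LINE ~2.5 kb,
LTR ~3 kb, DNA ~800 bp, RC ~1.5 kb), draws insertion ages uniformly over
the family's lifespan, and sets divergence = 2μg · age (optionally with
truncated Gaussian noise). Old, long copies are thinned with probability
1 − exp(−k·length·age) (default k = 2×10⁻⁶ per bp·Myr), emulating
removal of larger elements by recombination-driven turnover. Genome
sizes are ~330 Mb ± 10%. With `min_bp_per_tip` set, every descendant tip
is topped up past the presence threshold, giving histories whose branch
placements are exactly recoverable — the regime used for the recovery
tests. The 19-tip fixture tree mirrors the heliconiine clade structure
(outgroups; doris; wallacei; erato; sara; melpomene; sylvaniform) with
round node ages; it is a test fixture, not a published chronogram.

`simulate_sine_families` draws K master sequences (~300 nt) with an
enforced ≥ 10% pairwise divergence, embeds the 3′ 80 nt of a distinct
LINE consensus per master, mutates each copy at a planted divergence
(default uniform 1–6%; the recovery checks use a fixed 2%), and appends
a poly-A/T tail whose A fraction is taxon-biased and optionally
stratum-dependent (young vs old) for the tail-contrast analyses.

What the generator does **not** emulate: genomic context and nested
insertions, CpG hypermutability, RepeatMasker's fragmentation of single
insertions into multiple hits, 5′ truncation gradients of LINE copies,
horizontal transfer, and assembly artifacts. Passing recovery tests
therefore demonstrates the correctness of the inference machinery under
the stated model, not robustness to every failure mode of real
annotations.

## Problem sizes and determinism

The test and acceptance runs use desk-scale data: ~10³ SINE copies for
subfamily recovery, ~50–170 planted families for rate recovery, 8-tip
trees for the contrast oracle and a 64-tip tree for slope recovery.
Every stochastic step takes an explicit seed (NumPy `default_rng`,
seeded Leiden, seeded subsampling), and identical seeds give
byte-identical outputs, including the pipeline manifest checksums.
Serialized `.out` tables store divergence as a percentage with six
decimals, so file round trips preserve divergence to 10⁻⁸ of a fraction
and everything else exactly.

## Known limitations

- Branch placement is parsimony-style on presence scores; it cannot
  distinguish loss from hybrid origin and reports such conflicts as
  unassigned.
- The similarity search is a seeded heuristic (top-50 neighbors); in
  extremely large or highly uniform copy sets it can miss low-scoring
  edges a full all-vs-all would find.
- The center-star MSA is adequate for closely related copies but
  degrades for divergent sets; external alignments can be supplied to
  the consensus tools instead.
- γ must be chosen for the scale and weighting of the network at hand;
  no automatic selection is attempted beyond the null-score helper and
  sweep-friendly API.
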