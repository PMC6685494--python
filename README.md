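# tedyn

Comparative transposable-element (TE) dynamics across a clade of genomes
on a dated phylogeny — built for the heliconiine butterflies (genus
*Heliconius* and relatives), where TE repertoires diverged rapidly among
recently separated lineages, but applicable to any clade with
RepeatMasker-style annotations, a repeat library, and an ultrametric
species tree.

`tedyn` post-processes per-insertion repeat annotations; it does not run
RepeatMasker, BLAST, or MUSCLE. Its pieces:

- **Divergence and age** — Kimura 2-parameter distance
  d = −½·ln[(1−2P−Q)·√(1−2Q)] from transition (P) and transversion (Q)
  proportions; conversion of divergence to absolute age under a neutral
  clock (default μ = 1.9×10⁻⁹ substitutions/site/generation, 4
  generations/year, pairwise convention: age = d/(2μg)); recent/old
  stratification at d = 0.05; TE landscapes (genome proportion per
  divergence bin).
- **Accumulation** — stratified genome-proportion tables by class or
  family, Welch t-tests between clades, PCA of species-by-element
  matrices, SINE×LINE Pearson correlation of recent accumulation.
- **Lineage rates** — presence scoring per family and species from
  masked bp (1 if ≥5,000 bp, 0 if <500 bp, 0.5 between), assignment of
  each family to the stem branch of the smallest clade containing its
  presence pattern (presence sum ≥ n − 0.5 inside, strict absence
  outside), and branch origination rates (families/Myr).
- **SINE subfamilies** — copies trimmed to the consensus-homologous core
  (≥235 nt), a score-weighted similarity network (seeded local
  alignment, word size 8), community detection on the
  Reichardt–Bornholdt configuration-null quality function
  H = −Σ(w_ij − γ·s_i s_j/2m)·δ(c_i,c_j), 30-member majority-rule
  consensuses, merging of identical consensuses (100% identity / 95%
  coverage), and greedy 95%-identity clustering (or 90%/90% library
  collapsing).
- **SINE–LINE partnerships** — partner LINE identification from 3′-end
  similarity (~100 bp SINE tail vs ~300 bp LINE 3′ end), and tail
  nucleotide composition of young vs old insertions via repeated seeded
  subsampling (100 copies × 10 replicates, log₂ pair ratios with +1
  pseudocount).
- **Phylogenetic statistics** — Z-transformation, Felsenstein's
  independent contrasts, contrast regression through the origin for
  genome size vs TE content, Holm/Bonferroni correction.
- **Synthetic data** — a ground-truthed generator that plants TE
  families on branches of a 19-tip fixture tree, deposits copies with
  clock-driven divergences, and descends SINE copies from master
  sequences with diagnostic mutations, embedded LINE 3′ regions and
  biased poly-A/T tails, so the whole pipeline is testable end to end.

## Worked example

Simulate a history on the 19-tip tree with family presence guaranteed to
respect the 5,000/500 bp scoring thresholds, then recover branch-specific
origination rates:

```python
from tedyn.synthetic_data import SimConfig, simulate_history, default_tree, DEFAULT_CLADES
from tedyn.lineage_rates import presence_matrix, assign_branch, origination_rates

cfg = SimConfig(seed=1, min_bp_per_tip=6000, deletion_per_bp_myr=0.0)
hits, genomes, truth = simulate_history(cfg)
tree = default_tree()
assignment = assign_branch(presence_matrix(hits), tree)
rates = origination_rates(assignment, tree)
```

With seed 1 this plants 172 families; all 172 are assigned, and all 172
land on their true branch. The erato-clade stem branch (4 Myr) received
3 families, an origination rate of 0.75 families/Myr. A clade contrast
on the recent SINE proportions:

```python
from tedyn.accumulation import proportion_table, clade_proportion_test
table = proportion_table(hits, genomes, "class", "recent")
t, p = clade_proportion_test(table, DEFAULT_CLADES["erato_sara"],
                             DEFAULT_CLADES["melpomene_sylvaniform"], "SINE")
# t = 2.12, p = 0.068
```

prints a Welch t of 2.12 (p = 0.068): with this seed the two clades'
recent SINE accumulation does not differ significantly.

The same stages run from the shell via the `tedyn` CLI
(`tedyn simulate`, `tedyn rates`, `tedyn sine-subfam`, `tedyn partners`,
`tedyn gsize`, …) or end to end with `tedyn run --config run.yaml`.

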