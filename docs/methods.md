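# Methods

## The model system

`phyloerosion` studies how mass extinctions erode the branching history of
phylogenies, using a community of digital organisms as the study system.  The
community is a fixed-size, well-mixed population of asexual replicators.  An
organism's genotype is a triple (trait bit-vector, neutral tag, lethal flag).
Each trait is a resource-linked function; resources form a cross-feeding
cascade in which only the two basal pools receive exogenous inflow and every
deeper pool exists solely as a by-product of organisms consuming an upstream
pool.  Time is measured in *updates*, and every age, branch length and
schedule in the package is expressed in updates.

### Resource dynamics

Per update, pool *j* with concentration `C_j` undergoes

```
C_j <- (1 - decay) * C_j + inflow_j
consumed_j = uptake_fraction * C_j        (if at least one performer)
C_d <- C_d + consumed_j / conversion_factor   for each downstream pool d
```

Because at most the `uptake_fraction <= 1` of a pool is removed per update,
concentrations are non-negative by construction.  The organism-free
equilibrium of an inflowing pool is `inflow / decay`, which is what a press
episode scales down.

### Consumption, merit and fitness

Consumption of pool *j* is divided among performers in proportion to
*metabolic effort*: an organism with *k* traits devotes weight `1/k` to each
of its functions.  Its merit gain from pool *j* is `reward_j` per unit
consumed, and its fitness is

```
fitness = (base_merit + resource merit) / (1 + trait_cost * n_traits)
```

Each update, `round(birth_rate * population_size)` birth events occur;
parents are drawn fitness-proportionally from the population at the start of
the update, and each offspring replaces a distinct, uniformly chosen organism
(vacant slots left by a cull are refilled first).  Offspring mutate per
birth: each trait flips with probability `mu_trait`, the neutral tag mutates
with probability `mu_tag`, and with probability `mu_lethal` the offspring is
non-viable (zero fitness, never a parent, never a cull survivor).  *Any*
mutation creates a new genotype record — this genotype convention is what
defines cladogenesis, so branching is dominated by near-neutral tag variants
and is largely decoupled from phenotypic change, producing the stemmy trees
characteristic of such systems.

**Why effort-weighted sharing.**  With an equal split of the uptake fraction
among performers, per-organism resource merit is additive across traits while
the gestation cost is divisive, so a generalist expressing every function
strictly dominates all specialists whenever traits pay at all.  The community
then collapses to one clade and no stable deep root can exist.  The `1/k`
effort weighting makes a crowded guild less profitable per capita than a rare
one, i.e. negative frequency-dependent selection, and the population settles
into several coexisting resource-specialist clades.  Their ancient splits
anchor the phylogenetic root, which is the phenomenon the whole analysis
depends on — unperturbed controls then retain their root while strong
extinctions destabilize it.

### Extinction treatments

* **Pulse** — an instantaneous cull to `pulse_survivors` organisms (defaults
  4 for strong, 36 for weak), drawn uniformly from the viable organisms, with
  no environmental change.  The population refills via births over the next
  few dozen updates.
* **Press** — the exogenous inflows are multiplied by
  `press_inflow_factor` (0.01 strong, 0.1 weak) for `press_duration` updates
  and then restored.  Selectivity is emergent: with resources scarce, the
  divisive trait cost favours trait-free fast replicators that subsist on the
  base merit ("disaster taxa"), and trait-bearing clades collapse.
* **Control** — run as a press window with factor 1.0, so all treatments
  share one absolute timeline (pre + window + recovery).

Snapshots (extant genotype censuses) are taken immediately before the event
and at fixed offsets into the recovery; offset 0 is the immediate post-event
population, which for a pulse is the survivor census itself.

## From genealogy to phylogeny

Tips are the genotypes extant at the sampling time.  Every child-origin event
along an ancestor's timeline is a potential node; it is retained only when at
least two lines of descent from it survive to the sampling time, counting the
ancestor's own continuation when the ancestor is extant or leads to extant
descendants.  All other events collapse into branch length.  Consequences of
this construction, chosen deliberately:

* node age = the origin update of the child genotype whose appearance created
  the divergence; stem lengths are age differences, and the root keeps a stem
  back to the founder's origin so ages survive newick round trips;
* an extant ancestor appears as a tip attached at its last retained branching
  event (a zero-length tail is possible), keeping the tree strictly
  ultrametric for the LTT arithmetic;
* same-update events on one timeline form a genuine multifurcation rather
  than an arbitrary binary resolution; downstream statistics treat an
  *m*-child node as *m − 1* simultaneous splits separated by zero-length
  internode intervals;
* children are ordered by smallest descendant genotype id, so serialization
  is reproducible.

For any two sampling times `t1 < t2` of one replicate, the node ages `<= t1`
of the later tree form a sub-multiset of the earlier tree's ages: history can
only be lost.  This is the basis of the retention analysis' `<= 100%` bound
and of its monotone decline over the recovery.

## Statistics

* **Pybus–Harvey gamma.**  With internode intervals `g_k` (k lineages),
  `T = sum k*g_k` and partial sums `A_i`, the statistic is
  `[mean(A_2..A_{n-1}) - T/2] / (T * sqrt(1/(12(n-2))))`.  It is undefined
  for fewer than 3 tips or zero height; such trees are reported missing and
  excluded from time-point aggregates.  Gamma is invariant to uniform time
  rescaling and approximately standard normal on constant-rate pure-birth
  trees, which the Yule calibration checks.
* **Noncumulative stemminess (NCS).**  Per internal non-root node with stem
  `l_j` and child branch lengths `{l_c}`, the default `rohlf1990` score is
  `l_j / (l_j + sum l_c)` (bounded in [0, 1]); the `inverse-ratio` variant
  `sum(l_c) / l_j` is also provided because stemminess is often described on
  a scale exceeding 1 (short stems near the root inflate it), which the
  bounded form cannot express.  Zero-length stems are skipped and counted,
  not treated as infinite; every output records which variant was used.
* **Root-gap distances.**  `d1`/`d2` are the age differences between the
  root and the next two oldest splits (multifurcation multiplicity included,
  so a multifurcating root gives `d1 = 0`); missing splits are reported
  absent rather than imputed.
* **Retention.**  Node ages are binned into half-open intervals
  `[iB, (i+1)B)` anchored at update 0 (boundary handling chosen for
  reproducibility); later trees are pruned at the event start before binning.
  Bins empty at both time points are excluded; zero scores are real losses
  and enter the averages; cross-replicate means use only replicates whose
  pre-extinction bin was occupied and carry two-standard-error bars.
* **Root retention.**  Two trees share a root when the root's age and the id
  of the ancestral genotype hosting the branching event agree — an exact
  match given the genealogy, with an age-only fallback for trees parsed from
  plain newick.
* **Treatment comparisons.**  One-way ANOVA with Tukey-HSD pairwise
  comparisons for retention and gamma; Kruskal–Wallis with a Tukey-type
  (Nemenyi) comparison on average pooled ranks for the heavily skewed NCS.
  `alpha = 0.05` throughout.  Compact letter displays use insert-and-absorb;
  groups sharing no letter differ significantly.  Gamma aggregates keep only
  replicates that retained the pre-extinction root to the end of the run (to
  avoid comparing trees of very different heights); NCS is summarized
  separately for root-retaining and root-losing replicates.

## Size profiles and defaults

Two profiles fix the study conditions.  The `paper` profile uses 3600
organisms, 100,000 updates of pre-extinction history, a 5,000-update press
window, 100,000 updates of recovery, sampling offsets
{0, 2000, 5000, 10000, 25000, 50000, 75000, 100000} and 5,000-update
retention bins.  The `desk` profile divides all times by ten (400 organisms,
10,000 + 1,000 + 10,000 updates, 500-update bins) so that a
multi-treatment, multi-replicate grid runs on one CPU in a few minutes; the
pulse survivor counts stay at the absolute 4 and 36.  Desk-scale results are
qualitative reproductions — orderings and directions of treatment effects —
not quantitative matches to full-scale runs.

Ecology defaults (all configurable): inflow 100/update per basal resource,
decay 0.01 (organism-free equilibrium 10,000 units), uptake fraction 0.1,
conversion factor 3, rewards (1, 2, 2, 2, 4, 4, 4, 8, 8) increasing along
the cascade, base merit 1, trait cost 0.25, birth rate 0.1 per slot per
update (mean generation time ≈ 10 updates), `mu_trait` 0.002 per function,
`mu_tag` 0.05, `mu_lethal` 0.02 per birth.  The mutation rates are sized so
a desk run yields trees with on the order of a hundred tips and tens of
thousands of genealogy records; the trait cost and inflow are sized so that
resource merit dominates base merit in normal conditions (strong ecology)
but collapses below it during a strong press (strong emergent selectivity).
A single seeded generator drives every stochastic step; replicate seeds are
derived by xor-ing a treatment/replicate checksum into the base seed.

## What the generator does and does not emulate

It emulates: a fixed-size asexual population with drift by replacement,
depletable global resources with a two-inflow cross-feeding cascade,
density-dependent competition, genotype-level genealogies with near-neutral
cladogenesis, random pulse culls of viable organisms, and press episodes
whose selectivity is emergent rather than imposed.  It does not execute
instruction-set genomes on a virtual CPU, has no spatial structure, no
recombination, no per-instruction mutation model, and no phenotypic traits
beyond the resource functions; passing tests therefore demonstrate the
pruning, metric and statistical machinery and the *direction* of treatment
effects in a resource-structured community, not the behaviour of any
specific full-scale system.

## Numerical choices and degenerate inputs

Fewer than two extant genotypes is a degenerate tree (error; the replicate is
excluded from tree metrics and itemized).  Gamma with n < 3 and NCS without
an internal non-root node are undefined-statistic errors, reported as missing
in pipeline tables.  Newick inputs must carry branch lengths and be
ultrametric within `1e-6` of tree height.  Aggregation drops nothing
silently: excluded replicates and skipped nodes are counted in the outputs.
A failed replicate (whole population non-viable) still returns its genealogy,
flagged.

## Known limitations

Desk-scale strong-pulse trees have only four tips at the post-event point, so
their gamma and NCS are often undefined there, mirroring the sparse-data
handling described above.  The Nemenyi rank comparison is conservative for
small groups and applies no tie correction in the pairwise stage.  The weak
press level is not calibrated to match weak-pulse attrition; it is simply a
tenth of the strong reduction.  Cross-feeding topology beyond the stated
basal links is a modelling choice (each level feeds the whole next level) and
is configurable.
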