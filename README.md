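# phyloerosion

Mass extinctions do not just remove species — they erase *branching history*
from the phylogenies of the survivors.  `phyloerosion` is a laboratory for
studying that erosion.  It couples an individual-based digital ecology
(communities of asexual replicators competing for cross-feeding resources)
with the phylogenetic machinery needed to measure the damage: genealogy →
ultrametric tree pruning, lineage-through-time (LTT) analysis, the
Pybus–Harvey gamma statistic, noncumulative stemminess (NCS), temporal
node-retention analysis, and Tukey-corrected treatment comparisons.

It is written for researchers in phylogenetics, macroevolution and artificial
life who want a reproducible, fully seeded test bed for questions like: does
a random mass cull ("pulse") leave the same long-term signature in tree shape
as an equally severe episode of resource collapse ("press")?

## The core quantities

For an ultrametric tree with `n` tips, branching times `t_2 ≤ … ≤ t_n` and
internode intervals `g_k = t_{k+1} − t_k` (with `t_{n+1}` the sampling time),
let `T = Σ k·g_k` and `A_i = Σ_{k≤i} k·g_k`.  The Pybus–Harvey gamma is

```
γ = [ (1/(n−2)) Σ_{i=2}^{n−1} A_i − T/2 ] / ( T · sqrt(1/(12(n−2))) )
```

— negative when branching concentrates toward the root, approximately
standard normal under constant-rate pure birth.  Noncumulative stemminess
scores each internal non-root node by its stem length `l_j` against its
children's branch lengths: `s_j = l_j/(l_j + Σ l_c)` (Rohlf variant, in
[0, 1]).  Retention analysis bins branching-node ages into fixed temporal
intervals and reports, per bin, the percentage of pre-extinction nodes still
present in a later tree of the same replicate.

Five treatments are built in: `control`, `pulse-strong` (instant cull to 4
random viable survivors), `pulse-weak` (36 survivors), `press-strong`
(exogenous inflows ×0.01 for the press window) and `press-weak` (×0.1).

## Worked example

```python
import phyloerosion as pe

cfg = pe.profile_config("desk")          # 400 organisms, reduced timeline
sched = pe.make_schedule("control", "desk", pre_updates=3000,
                         press_duration=300, recovery_updates=3000,
                         sampling_offsets=(0, 3000))
result = pe.run_experiment(cfg, sched, seed=11)
snap = result.snapshots["pre"]
tree = pe.build_tree(result.log, snap.update, extant=snap.genotypes)
print(tree.n_tips, tree.root_age)
print(pe.pybus_harvey_gamma(pe.ltt(tree)))
```

Running `python examples/01_simulate_and_build_trees.py` prints:

```
simulated 6300 updates, 21520 genotype records
      pre: update 3000, 88 extant genotypes, 85 branching nodes, root age 9
 rec_3000: update 6300, 87 extant genotypes, 84 branching nodes, root age 9
```

The root age of 9 updates at both sampling points means the community's most
recent common ancestor is an ancient split between coexisting
resource-specialist clades — unperturbed communities keep their deep history.
`examples/04_compare_treatments.py` runs a miniature treatment grid and
prints:

```
root-retention fraction (end of run):
         control: 1.00
    press-strong: 0.75
    pulse-strong: 0.50
mean deep-bin retention immediately post-event (%):
         control:   95.8
    press-strong:   60.0
    pulse-strong:   14.7
```

— strong extinctions lose the pre-extinction root more often than controls
and erase far more of the deep branching history.  The other examples cover
the tree statistics on hand-checkable trees (`02`) and the per-bin retention
accounting after a press episode (`03`).

A thin CLI mirrors the library: `phyloerosion simulate`, `build-trees`,
`metrics`, `retention`, `compare` and `pipeline` (see `--help`).

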