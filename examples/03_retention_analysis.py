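"""Percent retention of branching nodes after a strong press episode.

One strong-press replicate is simulated at reduced scale; node ages of the
immediate pre-extinction tree are binned temporally, and the end-of-press tree
(pruned at the event start so both trees share temporal support) is scored
against it.  100% means every branching event in that age bin survived; 0%
means the whole bin's history was erased; an excluded bin (NaN) was empty on
both sides.
"""

import numpy as np

import phyloerosion as pe

cfg = pe.profile_config("desk")
sched = pe.make_schedule("press-strong", "desk", pre_updates=4000,
                        press_duration=400, recovery_updates=4000,
                        sampling_offsets=(0, 4000))
result = pe.run_experiment(cfg, sched, seed=3)

cutoff, width = sched.event_start, 500
pre = result.snapshots["pre"]
pre_tree = pe.build_tree(result.log, pre.update, extant=pre.genotypes)
pre_binned = pe.bin_node_ages(
    pe.prune_nodes_after(pe.ltt(pre_tree).branching_ages, cutoff), width)

for label in ("rec_0", "rec_4000"):
    snap = result.snapshots[label]
    tree = pe.build_tree(result.log, snap.update, extant=snap.genotypes)
    ages = pe.prune_nodes_after(pe.ltt(tree).branching_ages, cutoff)
    vals = pe.percent_retention(
        pre_binned, pe.bin_node_ages(ages, width, n_bins=pre_binned.counts.size))
    pretty = ["excl" if np.isnan(v) else f"{v:.0f}" for v in vals]
    print(f"{label:>9} retention per {width}-update bin (old -> recent): "
          + " ".join(pretty))
print("root age pre vs end:", pre_tree.root_age, "->", tree.root_age,
      "| retained:", pe.root_retained(pre_tree, tree))
print("genotype turnover during the press (orig, ext, persist):",
      pe.turnover_counts(result.log, (cutoff, cutoff + 400)))
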