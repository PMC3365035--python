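"""Simulate a short control community and extract its phylogeny.

Runs a reduced unperturbed replicate of the digital ecology, then prunes the
genotype genealogy down to the ultrametric tree of genotypes extant at two
sampling times.  The printed root age is the origin time (in updates) of the
population's most recent common ancestor; a stable root across sampling times
means the deepest clades are coexisting rather than turning over.
"""

import phyloerosion as pe

cfg = pe.profile_config("desk")
sched = pe.make_schedule("control", "desk", pre_updates=3000,
                        press_duration=300, recovery_updates=3000,
                        sampling_offsets=(0, 3000))
result = pe.run_experiment(cfg, sched, seed=11)
print(f"simulated {sched.total_updates} updates, "
      f"{len(result.log)} genotype records")

for label in ("pre", "rec_3000"):
    snap = result.snapshots[label]
    tree = pe.build_tree(result.log, snap.update, extant=snap.genotypes)
    print(f"{label:>9}: update {snap.update}, {tree.n_tips} extant genotypes, "
          f"{len(tree.internal_nodes())} branching nodes, "
          f"root age {tree.root_age:.0f}")

# a tree can be written to newick (branch lengths in updates) and read back
nwk = pe.to_newick(tree)
print("newick preview:", nwk[:70], "...")
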