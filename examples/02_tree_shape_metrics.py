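"""Tree-shape statistics on a hand-checkable tree and on pure-birth trees.

The three-tip worked tree has its single divergence deep in the past, so the
Pybus-Harvey gamma is negative (branching concentrated rootward) and the
Rohlf noncumulative stemminess is small (a short stem above long terminal
branches).  On constant-rate pure-birth (Yule) trees gamma is calibrated to
be approximately standard normal, which the sample mean and variance show.
"""

import numpy as np

import phyloerosion as pe

tree = pe.from_newick("((G1:70.0,G3:70.0):20.0,G2:90.0):10.0;")
series = pe.ltt(tree)
print("branching ages:", [float(a) for a in series.branching_ages],
      "internode intervals:", [float(g) for g in series.intervals()])
print(f"gamma  = {pe.pybus_harvey_gamma(series):+.4f}  (negative: rootward)")
print(f"NCS    = {pe.ncs(tree, 'rohlf1990').value:.4f}  (rohlf1990, in [0,1])")
d1, d2 = pe.root_gap_distances(tree)
print(f"root at {tree.root_age:.0f}; distance to next-oldest node d1 = {d1:.0f}")

rng = np.random.default_rng(0)
gammas = np.array([pe.pybus_harvey_gamma(pe.yule_ltt(50, rng))
                   for _ in range(200)])
print(f"Yule calibration (200 trees, 50 tips): "
      f"mean {gammas.mean():+.3f}, variance {gammas.var(ddof=1):.3f} "
      "(expected ~0 and ~1)")
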