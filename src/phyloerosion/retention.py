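"""Erosion-of-history analyses: binned node retention, root fate, turnover.

The central comparison: bin the branching-node ages of the immediate
pre-extinction tree into fixed temporal intervals, do the same for a later
tree of the same replicate (with nodes younger than the event start pruned
away), and report the percentage of nodes that persisted per bin.  Because a
later tree can only lose pre-cutoff nodes, retention is bounded by 100% and
is non-increasing in sampling time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genealogy import EXTANT, GenealogyLog
from .phylogeny import PhyloTree


@dataclass
class BinnedAges:
    """Node-age counts in half-open bins ``[i*B, (i+1)*B)`` anchored at 0."""

    bin_width: float
    counts: np.ndarray

    @property
    def n_ages(self) -> int:
        return int(self.counts.sum())


def bin_node_ages(ages, bin_width: float, n_bins: int | None = None) -> BinnedAges:
    """Count node ages per temporal bin (boundary ages go to the upper bin)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ages = np.asarray(ages, dtype=np.float64)
    if ages.size and ages.min() < 0:
        raise ValueError("ages must be nonnegative")
    idx = np.floor(ages / bin_width).astype(np.int64)
    length = n_bins if n_bins is not None else (int(idx.max()) + 1 if idx.size else 0)
    counts = np.bincount(idx, minlength=length) if idx.size else np.zeros(length, int)
    return BinnedAges(bin_width=float(bin_width), counts=counts.astype(np.int64))


def percent_retention(pre: BinnedAges, post: BinnedAges) -> np.ndarray:
    """Per-bin percent of pre-extinction nodes still present in the later tree.

    Bins empty at both time points are excluded (NaN).  A bin empty before
    the event but occupied after violates the node-age subset invariant and
    raises, since later trees cannot gain pre-cutoff nodes; callers must
    prune the later tree's ages at the event start first.
    """
    if pre.bin_width != post.bin_width:
        raise ValueError("bin widths differ between the two snapshots")
    width = max(pre.counts.size, post.counts.size)
    a = np.zeros(width, dtype=np.int64)
    b = np.zeros(width, dtype=np.int64)
    a[: pre.counts.size] = pre.counts
    b[: post.counts.size] = post.counts
    if ((a == 0) & (b > 0)).any():
        raise ValueError(
            "subset violation: later tree has nodes in a bin that was empty "
            "pre-extinction (were the later ages pruned at the cutoff?)"
        )
    out = np.full(width, np.nan)
    nz = a > 0
    out[nz] = 100.0 * b[nz] / a[nz]
    return out


@dataclass
class RetentionTable:
    """Cross-replicate per-bin summary: mean retention, 2*SE, replicate count."""

    bin_width: float
    table: pd.DataFrame  # columns: bin, bin_lower, bin_upper, mean, two_se, n_replicates


def aggregate_retention(
    tables: Sequence[np.ndarray], bin_width: float
) -> RetentionTable:
    """Average per-bin retention across replicates.

    A replicate contributes to a bin only when the bin held at least one node
    in its pre-extinction tree (its value is non-NaN); zero-retention scores
    are real losses and are included in the mean.  Bins excluded in every
    replicate are absent from the output.  Error bars are two standard errors
    (ddof=1); a single-replicate bin has no SE.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    width = max(t.size for t in tables)
    stacked = np.full((len(tables), width), np.nan)
    for i, t in enumerate(tables):
        stacked[i, : t.size] = t
    rows = []
    for b in range(width):
        col = stacked[:, b]
        vals = col[~np.isnan(col)]
        if vals.size == 0:
            continue
        two_se = (
            2.0 * vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        )
        rows.append(
            dict(
                bin=b,
                bin_lower=b * bin_width,
                bin_upper=(b + 1) * bin_width,
                mean=float(vals.mean()),
                two_se=two_se,
                n_replicates=int(vals.size),
            )
        )
    return RetentionTable(bin_width=float(bin_width), table=pd.DataFrame(rows))


def root_retained(pre_tree: PhyloTree, post_tree: PhyloTree) -> bool:
    """True iff the later tree's root is the same branching event as the
    pre-extinction root, matched by age and by the ancestral genotype on
    whose timeline the event occurred (falls back to age alone when host ids
    are unavailable, e.g. for trees parsed from plain newick)."""
    if pre_tree.root_age != post_tree.root_age:
        return False
    if pre_tree.root.host is None or post_tree.root.host is None:
        return True
    return pre_tree.root.host == post_tree.root.host


def root_age_histogram(
    root_ages: Mapping[str, Sequence[float]],
    bin_width: float,
    event_window: tuple[float, float] | None = None,
    young_threshold: float = 5000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histograms of replicate root ages per time point, plus summary fractions.

    Returns ``(hist, summary)``: ``hist`` has one row per (timepoint, bin)
    with a count; ``summary`` has, per timepoint, the fraction of replicates
    whose root is younger than ``young_threshold`` updates and -- when an
    ``event_window = (start, end)`` in absolute updates is given -- the
    fractions whose root originated during and after the event.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hist_rows, summary_rows = [], []
    for timepoint, ages in root_ages.items():
        ages = np.asarray(list(ages), dtype=np.float64)
        if ages.size:
            idx = np.floor(ages / bin_width).astype(np.int64)
            for b, count in zip(*np.unique(idx, return_counts=True)):
                hist_rows.append(
                    dict(
                        timepoint=timepoint,
                        bin=int(b),
                        bin_lower=b * bin_width,
                        bin_upper=(b + 1) * bin_width,
                        count=int(count),
                    )
                )
        summary = dict(
            timepoint=timepoint,
            n_replicates=int(ages.size),
            frac_young=float((ages < young_threshold).mean()) if ages.size else np.nan,
        )
        if event_window is not None:
            start, end = event_window
            if ages.size:
                summary["frac_during_event"] = float(
                    ((ages >= start) & (ages <= end)).mean()
                )
                summary["frac_after_event"] = float((ages > end).mean())
            else:
                summary["frac_during_event"] = np.nan
                summary["frac_after_event"] = np.nan
        summary_rows.append(summary)
    return pd.DataFrame(hist_rows), pd.DataFrame(summary_rows)


def turnover_counts(log: GenealogyLog, interval: tuple[int, int]):
    """Genotype turnover over ``[t0, t1)``: (originations, extinctions,
    persistences).  Originations/extinctions count events inside the
    interval; persistences count genotypes extant through the whole of it."""
    t0, t1 = interval
    if not t0 < t1:
        raise ValueError("interval must satisfy t0 < t1")
    _, origin, ext = log.arrays()
    alive_end = (ext == EXTANT) | (ext > t1)
    originations = int(((origin >= t0) & (origin < t1)).sum())
    extinctions = int(((ext != EXTANT) & (ext >= t0) & (ext < t1)).sum())
    persistences = int(((origin <= t0) & alive_end).sum())
    return originations, extinctions, persistences
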