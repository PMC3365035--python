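"""End-to-end experiment orchestration: treatments x replicates x seeds.

For every treatment and replicate the pipeline simulates the ecology, builds
the ultrametric tree at the immediate pre-extinction point and at every
recovery sampling offset, computes the tree-shape metrics, scores per-bin node
retention against the pre-extinction tree (node ages pruned at the event
start), and runs the treatment-comparison statistics.  Replicates whose trees
are degenerate at a time point (fewer than two extant genotypes, or a
statistic undefined for the tree) contribute missing values there and are
itemized; gamma aggregates include only replicates that kept the
pre-extinction root to the end of the run, while stemminess is summarized
separately for root-retaining and root-losing replicates.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PROFILE_BIN_WIDTH, TREATMENTS, make_schedule, profile_config
from .ecology import run_experiment
from .errors import DegenerateTreeError, UndefinedStatisticError
from .phylogeny import PhyloTree, build_tree, prune_nodes_after, to_newick
from .retention import (
    aggregate_retention,
    bin_node_ages,
    percent_retention,
    root_retained,
)
from .stats_compare import anova_tukey, kruskal_tukey
from .tree_metrics import ltt, ncs, pybus_harvey_gamma, root_gap_distances


def replicate_seed(base_seed: int, treatment: str, replicate: int) -> int:
    """Deterministic per-replicate seed: a treatment/replicate checksum xor'd
    into the base seed (kept below 2**31)."""
    crc = zlib.crc32(f"{treatment}/{replicate}".encode())
    return (int(base_seed) ^ crc) & 0x7FFFFFFF


@dataclass(frozen=True)
class ExperimentManifest:
    """Declarative description of a full pipeline run."""

    treatments: tuple = TREATMENTS
    replicates: int = 20
    base_seed: int = 0
    profile: str = "desk"
    config_overrides: dict = field(default_factory=dict)
    schedule_overrides: dict = field(default_factory=dict)
    bin_width: float | None = None  # defaults to the profile's width

    def __post_init__(self) -> None:
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments: {sorted(unknown)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def effective_bin_width(self) -> float:
        return self.bin_width or PROFILE_BIN_WIDTH[self.profile]


@dataclass
class PipelineResult:
    """All pipeline tables plus the raw per-replicate experiment results."""

    manifest: ExperimentManifest
    metrics: pd.DataFrame
    retention_long: pd.DataFrame
    retention_summary: pd.DataFrame
    comparisons: pd.DataFrame
    root_summary: pd.DataFrame
    exclusions: pd.DataFrame
    experiments: dict = field(default_factory=dict, repr=False)

    def root_retention_fraction(self) -> pd.Series:
        """Per treatment: fraction of usable replicates that kept the
        pre-extinction root to the end of the experiment."""
        per_rep = self.metrics.groupby(["treatment", "replicate"])[
            "root_retained_end"
        ].first()
        return per_rep.groupby("treatment").mean()

    def deep_bin_retention(self, timepoint: int, depth_fraction: float = 1 / 3
                           ) -> pd.DataFrame:
        """Per-replicate mean retention over the oldest ``depth_fraction`` of
        temporal bins, at one recovery offset."""
        df = self.retention_long[self.retention_long.timepoint == timepoint]
        n_bins = df["bin"].max() + 1 if len(df) else 0
        deep = df[df["bin"] < max(1, int(np.ceil(n_bins * depth_fraction)))]
        out = (
            deep.dropna(subset=["retention"])
            .groupby(["treatment", "replicate"])["retention"]
            .mean()
            .reset_index(name="deep_retention")
        )
        return out

    def write(self, out_dir, write_trees: bool = False) -> None:
        """Write every table as TSV plus a machine-readable run summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("metrics", "retention_long", "retention_summary",
                     "comparisons", "root_summary", "exclusions"):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        summary = dict(
            version=__version__,
            treatments=list(self.manifest.treatments),
            replicates=self.manifest.replicates,
            base_seed=self.manifest.base_seed,
            profile=self.manifest.profile,
            bin_width=self.manifest.effective_bin_width,
            n_excluded=int(len(self.exclusions)),
        )
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
        if write_trees:
            for (treatment, rep), result in self.experiments.items():
                d = out / treatment
                d.mkdir(exist_ok=True)
                result.log.to_tsv(d / f"genealogy_rep{rep}.tsv")
                manifest_rows = []
                for label, snap in result.snapshots.items():
                    try:
                        tree = build_tree(result.log, snap.update,
                                          extant=snap.genotypes)
                    except DegenerateTreeError:
                        continue
                    path = d / f"rep{rep}_{label}.nwk"
                    path.write_text(to_newick(tree) + "\n")
                    manifest_rows.append(
                        dict(label=label, update=snap.update, path=path.name)
                    )
                pd.DataFrame(manifest_rows).to_csv(
                    d / f"rep{rep}_snapshots.tsv", sep="\t", index=False
                )


def _tree_metrics_row(tree: PhyloTree, ncs_variants=("rohlf1990", "inverse-ratio")):
    d1, d2 = root_gap_distances(tree)
    row = dict(
        n_tips=tree.n_tips,
        n_internal=len(tree.internal_nodes()),
        root_age=tree.root_age,
        d1=d1 if d1 is not None else np.nan,
        d2=d2 if d2 is not None else np.nan,
    )
    try:
        row["gamma"] = pybus_harvey_gamma(ltt(tree))
    except UndefinedStatisticError:
        row["gamma"] = np.nan
    for variant, col in zip(ncs_variants, ("ncs_rohlf", "ncs_inverse")):
        try:
            res = ncs(tree, variant)
            row[col] = res.value
            row[f"{col}_skipped"] = res.n_skipped
        except UndefinedStatisticError:
            row[col] = np.nan
            row[f"{col}_skipped"] = np.nan
    return row


def run_pipeline(manifest: ExperimentManifest, keep_experiments: bool = False
                 ) -> PipelineResult:
    """Run the full experiment grid and compute every result table."""
    bin_width = manifest.effective_bin_width
    metric_rows, retention_rows, exclusion_rows = [], [], []
    experiments: dict = {}

    for treatment in manifest.treatments:
        cfg = profile_config(manifest.profile, **manifest.config_overrides)
        sched = make_schedule(treatment, manifest.profile,
                              **manifest.schedule_overrides)
        cutoff = sched.event_start
        for rep in range(manifest.replicates):
            seed = replicate_seed(manifest.base_seed, treatment, rep)
            result = run_experiment(cfg, sched, seed)
            if keep_experiments:
                experiments[(treatment, rep)] = result
            if result.failed or "pre" not in result.snapshots:
                exclusion_rows.append(
                    dict(treatment=treatment, replicate=rep, seed=seed,
                         reason="population failed before sampling completed")
                )
                if "pre" not in result.snapshots:
                    continue
            pre_snap = result.snapshots["pre"]
            try:
                pre_tree = build_tree(result.log, pre_snap.update,
                                      extant=pre_snap.genotypes)
            except DegenerateTreeError:
                exclusion_rows.append(
                    dict(treatment=treatment, replicate=rep, seed=seed,
                         reason="degenerate pre-extinction tree")
                )
                continue
            pre_ages = ltt(pre_tree).branching_ages
            pre_binned = bin_node_ages(prune_nodes_after(pre_ages, cutoff),
                                       bin_width)

            pre_row = dict(treatment=treatment, replicate=rep, seed=seed,
                           timepoint=-1, label="pre", update=pre_snap.update,
                           root_retained=True, **_tree_metrics_row(pre_tree))
            metric_rows.append(pre_row)

            last_tree = None
            offsets = [
                (label, snap)
                for label, snap in result.snapshots.items()
                if label.startswith("rec_")
            ]
            for label, snap in offsets:
                offset = int(label.split("_", 1)[1])
                try:
                    tree = build_tree(result.log, snap.update,
                                      extant=snap.genotypes)
                except DegenerateTreeError:
                    exclusion_rows.append(
                        dict(treatment=treatment, replicate=rep, seed=seed,
                             reason=f"degenerate tree at {label}")
                    )
                    continue
                last_tree = tree
                metric_rows.append(
                    dict(treatment=treatment, replicate=rep, seed=seed,
                         timepoint=offset, label=label, update=snap.update,
                         root_retained=root_retained(pre_tree, tree),
                         **_tree_metrics_row(tree))
                )
                post_ages = prune_nodes_after(ltt(tree).branching_ages, cutoff)
                vals = percent_retention(
                    pre_binned, bin_node_ages(post_ages, bin_width,
                                              n_bins=pre_binned.counts.size)
                )
                for b, v in enumerate(vals):
                    retention_rows.append(
                        dict(treatment=treatment, replicate=rep,
                             timepoint=offset, bin=b,
                             bin_lower=b * bin_width, retention=v)
                    )
            end_retained = (
                root_retained(pre_tree, last_tree) if last_tree is not None else False
            )
            for row in metric_rows:
                if row["treatment"] == treatment and row["replicate"] == rep:
                    row["root_retained_end"] = end_retained

    metrics = pd.DataFrame(metric_rows)
    retention_long = pd.DataFrame(retention_rows)
    exclusions = pd.DataFrame(
        exclusion_rows, columns=["treatment", "replicate", "seed", "reason"]
    )

    retention_summary = _summarize_retention(retention_long, bin_width)
    comparisons = _run_comparisons(metrics, retention_long, bin_width)
    root_summary = _root_summary(metrics)

    return PipelineResult(
        manifest=manifest,
        metrics=metrics,
        retention_long=retention_long,
        retention_summary=retention_summary,
        comparisons=comparisons,
        root_summary=root_summary,
        exclusions=exclusions,
        experiments=experiments,
    )


def _summarize_retention(retention_long: pd.DataFrame, bin_width: float
                         ) -> pd.DataFrame:
    rows = []
    if retention_long.empty:
        return pd.DataFrame(rows)
    for (treatment, timepoint), df in retention_long.groupby(
        ["treatment", "timepoint"]
    ):
        tables = [
            g.sort_values("bin")["retention"].to_numpy()
            for _, g in df.groupby("replicate")
        ]
        if len(tables) < 2:
            continue
        table = aggregate_retention(tables, bin_width).table
        table.insert(0, "treatment", treatment)
        table.insert(1, "timepoint", timepoint)
        rows.append(table)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _groups_for_test(df: pd.DataFrame, value: str) -> dict:
    groups = {}
    for treatment, g in df.groupby("treatment"):
        vals = g[value].dropna().to_numpy()
        if vals.size >= 2:
            groups[treatment] = vals
    return groups


def _letters_str(letters: dict) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(letters.items()))


def _run_comparisons(metrics: pd.DataFrame, retention_long: pd.DataFrame,
                     bin_width: float) -> pd.DataFrame:
    rows = []
    if metrics.empty:
        return pd.DataFrame(rows)
    post = metrics[metrics.timepoint >= 0]

    # gamma: ANOVA + Tukey, root-retaining (to end) replicates only
    gamma_df = post[post.root_retained_end]
    for timepoint, df in gamma_df.groupby("timepoint"):
        groups = _groups_for_test(df, "gamma")
        if len(groups) >= 2:
            rep = anova_tukey(groups)
            rows.append(dict(quantity="gamma", timepoint=timepoint, bin=np.nan,
                             test=rep.test, statistic=rep.statistic,
                             pvalue=rep.pvalue, degenerate=rep.degenerate,
                             letters=_letters_str(rep.letters)))

    # stemminess: Kruskal-Wallis + rank Tukey, split by root fate
    for retained, subset in post.groupby("root_retained_end"):
        for timepoint, df in subset.groupby("timepoint"):
            groups = _groups_for_test(df, "ncs_rohlf")
            if len(groups) >= 2:
                rep = kruskal_tukey(groups)
                rows.append(dict(
                    quantity=f"ncs_{'retained' if retained else 'lost'}",
                    timepoint=timepoint, bin=np.nan, test=rep.test,
                    statistic=rep.statistic, pvalue=rep.pvalue,
                    degenerate=rep.degenerate,
                    letters=_letters_str(rep.letters)))

    # retention: ANOVA + Tukey per temporal bin at the immediate post point
    if not retention_long.empty:
        at_post = retention_long[retention_long.timepoint == 0]
        for b, df in at_post.groupby("bin"):
            groups = _groups_for_test(df.rename(columns={"retention": "v"}), "v")
            if len(groups) >= 2:
                rep = anova_tukey(groups)
                rows.append(dict(quantity="retention", timepoint=0, bin=b,
                                 test=rep.test, statistic=rep.statistic,
                                 pvalue=rep.pvalue, degenerate=rep.degenerate,
                                 letters=_letters_str(rep.letters)))
    return pd.DataFrame(rows)


def _root_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment end-of-run root ages and root-gap distances (medians and
    quartiles) for replicates that kept the pre-extinction root."""
    rows = []
    if metrics.empty:
        return pd.DataFrame(rows)
    post = metrics[metrics.timepoint >= 0]
    last = post.timepoint.max()
    end = post[(post.timepoint == last) & post.root_retained_end]
    for treatment, df in end.groupby("treatment"):
        row = dict(treatment=treatment, n=len(df))
        for col in ("root_age", "d1", "d2"):
            vals = df[col].dropna()
            row[f"{col}_median"] = vals.median() if len(vals) else np.nan
            row[f"{col}_q25"] = vals.quantile(0.25) if len(vals) else np.nan
            row[f"{col}_q75"] = vals.quantile(0.75) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
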