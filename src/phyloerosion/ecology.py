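"""Individual-based digital ecology with cross-feeding resources.

The simulator emulates a well-mixed community of asexual replicators.  Each
organism carries a genotype = (trait bit-vector, neutral tag, lethal flag).
Traits are resource-linked functions: an organism expressing function *j*
draws on resource pool *j* and converts part of what it consumes into the
downstream by-product resources of the cascade.  Fitness is merit per unit
gestation effort, and parents are sampled fitness-proportionally each update
(a mass-action Moran-style scheme; the resources are global, so there is no
spatial structure).

Resource dynamics per update for pool *j* with concentration ``C_j``::

    C_j <- (1 - decay) * C_j + inflow_j            # outflow then inflow
    consumed_j = alpha * C_j   (if any performer)  # removed by consumption
    C_d <- C_d + consumed_j / conversion_factor    # for each downstream d

Consumption is shared among performers in proportion to metabolic effort: an
organism with *k* traits devotes weight ``1/k`` to each of them, so rare
specialists obtain a larger per-capita share of "their" resource than members
of crowded guilds do.  This negative frequency dependence is what sustains
the coexisting resource-specialist clades whose deep splits anchor the
phylogenetic root.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .config import EcologyConfig, TreatmentSchedule
from .errors import CullError, SimulationError
from .genealogy import GenealogyLog


@dataclass
class ResourceState:
    """Per-resource concentrations (resource units); never negative."""

    concentrations: np.ndarray

    def copy(self) -> "ResourceState":
        return ResourceState(self.concentrations.copy())


@dataclass
class PopulationState:
    """Slot-based population: fixed capacity, refilled after culls by births.

    ``genotype[i]`` is the genealogy-record index occupying slot *i*;
    ``alive`` marks occupied slots (all True except transiently after a pulse
    cull); ``counts[g]`` tracks how many organisms currently carry genotype
    *g*, which is what drives extinction bookkeeping in the log.
    """

    genotype: np.ndarray
    traits: np.ndarray
    viable: np.ndarray
    alive: np.ndarray
    n_traits: np.ndarray
    merit: np.ndarray
    counts: np.ndarray
    update: int
    log: GenealogyLog
    next_tag: int = 1
    failed: bool = False

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def extant_genotypes(self) -> np.ndarray:
        """Sorted unique genotype indices currently carried by organisms."""
        return np.unique(self.genotype[self.alive])

    def _ensure_counts(self, n: int) -> None:
        if n > self.counts.size:
            grown = np.zeros(max(n, 2 * self.counts.size), dtype=np.int64)
            grown[: self.counts.size] = self.counts
            self.counts = grown


def init_state(cfg: EcologyConfig) -> tuple[PopulationState, ResourceState]:
    """Fresh population of trait-free founder clones and empty resource pools."""
    n, f = cfg.population_size, cfg.n_functions
    log = GenealogyLog()
    log.add(parent=-1, origin=0, n_traits=0, viable=True, tag=0)
    counts = np.zeros(16, dtype=np.int64)
    counts[0] = n
    pop = PopulationState(
        genotype=np.zeros(n, dtype=np.int64),
        traits=np.zeros((n, f), dtype=np.float64),
        viable=np.ones(n, dtype=bool),
        alive=np.ones(n, dtype=bool),
        n_traits=np.zeros(n, dtype=np.int64),
        merit=np.zeros(n, dtype=np.float64),
        counts=counts,
        update=0,
        log=log,
    )
    res = ResourceState(np.zeros(f, dtype=np.float64))
    return pop, res


class _Params:
    """Numpy views of an EcologyConfig, cached per config instance."""

    __slots__ = ("rewards", "inflow", "bymat", "one_minus_decay")

    def __init__(self, cfg: EcologyConfig) -> None:
        f = cfg.n_functions
        self.rewards = np.asarray(cfg.rewards, dtype=np.float64)
        self.inflow = np.asarray(cfg.inflow, dtype=np.float64)
        self.one_minus_decay = 1.0 - cfg.decay
        bymat = np.zeros((f, f), dtype=np.float64)
        for j, downs in enumerate(cfg.byproducts):
            for d in downs:
                bymat[j, d] = 1.0 / cfg.conversion_factor
        self.bymat = bymat


@lru_cache(maxsize=32)
def _compile(cfg: EcologyConfig) -> _Params:
    return _Params(cfg)


def step_update(
    pop: PopulationState,
    res: ResourceState,
    cfg: EcologyConfig,
    rng: np.random.Generator,
) -> tuple[PopulationState, ResourceState]:
    """Advance the ecology by one update (state is modified in place).

    Order of events: resource decay + inflow; consumption and merit; by-product
    production; fitness; a batch of fitness-proportional births replacing (or
    refilling) slots; per-birth mutation; extinction bookkeeping for genotypes
    whose carrier count reaches zero.
    """
    p = _compile(cfg)
    u = pop.update + 1
    C = res.concentrations

    C *= p.one_minus_decay
    C += p.inflow

    act = pop.alive & pop.viable
    k = pop.n_traits
    w = np.where(act & (k > 0), 1.0 / np.maximum(k, 1), 0.0)
    eff = pop.traits.T @ w  # effort-weighted performer count per function
    performing = eff > 0.0
    consumed = np.where(performing, cfg.uptake_fraction * C, 0.0)
    share = np.where(performing, consumed / np.where(performing, eff, 1.0), 0.0)
    merit = (pop.traits @ (p.rewards * share)) * w
    C -= consumed
    if C.min() < -1e-9:  # must be impossible: uptake_fraction <= 1
        raise SimulationError("negative resource concentration")
    np.clip(C, 0.0, None, out=C)
    C += consumed @ p.bymat

    fitness = np.where(act, (cfg.base_merit + merit) / (1.0 + cfg.trait_cost * k), 0.0)
    pop.merit = merit
    total_fitness = float(fitness.sum())
    pop.update = u
    if total_fitness <= 0.0:
        pop.failed = True
        return pop, res

    n_births = int(round(cfg.birth_rate * cfg.population_size))
    if n_births == 0:
        return pop, res

    n_slots = pop.genotype.size
    # fitness-proportional parent sampling (inverse-CDF; faster than choice)
    cdf = np.cumsum(fitness)
    parents = np.searchsorted(cdf, rng.random(n_births) * cdf[-1], side="right")
    np.clip(parents, 0, n_slots - 1, out=parents)

    vacant = np.flatnonzero(~pop.alive)
    if vacant.size:
        n_fill = min(vacant.size, n_births)
        targets = np.empty(n_births, dtype=np.int64)
        targets[:n_fill] = vacant[:n_fill]
        if n_births > n_fill:
            alive_idx = np.flatnonzero(pop.alive)
            targets[n_fill:] = rng.choice(
                alive_idx, size=n_births - n_fill, replace=False
            )
    else:
        targets = rng.choice(n_slots, size=n_births, replace=False)

    flips = rng.random((n_births, cfg.n_functions)) < cfg.mu_trait
    tag_mut = rng.random(n_births) < cfg.mu_tag
    lethal = rng.random(n_births) < cfg.mu_lethal

    child_g = pop.genotype[parents].copy()
    child_traits = pop.traits[parents].copy()
    child_viable = pop.viable[parents].copy()
    child_k = pop.n_traits[parents].copy()

    log = pop.log
    for b in np.flatnonzero(flips.any(axis=1) | tag_mut | lethal):
        row = child_traits[b]
        if flips[b].any():
            row = np.where(flips[b], 1.0 - row, row)
            child_traits[b] = row
        kb = int(row.sum())
        if tag_mut[b]:
            tag = pop.next_tag
            pop.next_tag += 1
        else:
            tag = log.tag[child_g[b]]
        viable_b = bool(child_viable[b]) and not bool(lethal[b])
        gid = log.add(parent=int(child_g[b]), origin=u, n_traits=kb,
                      viable=viable_b, tag=tag)
        child_g[b] = gid
        child_k[b] = kb
        child_viable[b] = viable_b

    pop._ensure_counts(len(log))
    replaced = pop.genotype[targets][pop.alive[targets]]
    np.add.at(pop.counts, replaced, -1)
    pop.genotype[targets] = child_g
    pop.traits[targets] = child_traits
    pop.viable[targets] = child_viable
    pop.n_traits[targets] = child_k
    pop.alive[targets] = True
    np.add.at(pop.counts, child_g, 1)
    for g in np.unique(replaced):
        if pop.counts[g] == 0:
            log.set_extinct(int(g), u)
    return pop, res


def apply_pulse_cull(
    pop: PopulationState, survivors_k: int, rng: np.random.Generator
) -> PopulationState:
    """Instant mass cull: keep ``survivors_k`` organisms, drawn uniformly
    without replacement from the *viable* organisms; resources are untouched.

    Genotypes losing their last carrier go extinct at ``update + 1`` (they
    were extant through the pre-event snapshot, gone from the next update on).
    The population refills in subsequent updates via births.
    """
    viable_idx = np.flatnonzero(pop.alive & pop.viable)
    if survivors_k < 2:
        raise CullError("survivors_k must be >= 2")
    if viable_idx.size < survivors_k:
        raise CullError(
            f"only {viable_idx.size} viable organisms; cannot keep {survivors_k}"
        )
    keep = rng.choice(viable_idx, size=survivors_k, replace=False)
    before = pop.extant_genotypes()
    pop.alive[:] = False
    pop.alive[keep] = True
    counts = np.zeros_like(pop.counts)
    surv, n = np.unique(pop.genotype[pop.alive], return_counts=True)
    counts[surv] = n
    pop.counts = counts
    gone = np.setdiff1d(before, surv, assume_unique=True)
    for g in gone:
        pop.log.set_extinct(int(g), pop.update + 1)
    return pop


def set_press_inflows(cfg: EcologyConfig, factor: float) -> EcologyConfig:
    """Return a config with every exogenous inflow multiplied by ``factor``.

    ``factor`` must be positive; restoring pre-press conditions is applying
    the reciprocal (or reinstalling the original config).
    """
    if factor <= 0:
        raise ValueError("inflow factor must be positive")
    return replace(cfg, inflow=tuple(i * factor for i in cfg.inflow))


@dataclass
class Snapshot:
    """Population census at one labeled time point."""

    label: str
    update: int
    genotypes: np.ndarray  # extant genotype record indices
    n_organisms: int


@dataclass
class ExperimentResult:
    """Everything one replicate produces: the log plus labeled snapshots."""

    log: GenealogyLog
    snapshots: dict
    cfg: EcologyConfig
    schedule: TreatmentSchedule
    seed: int
    failed: bool = False

    @property
    def pre(self) -> Snapshot:
        return self.snapshots["pre"]


def run_experiment(
    cfg: EcologyConfig, sched: TreatmentSchedule, seed: int
) -> ExperimentResult:
    """Run one replicate: pre-extinction evolution, the event, the recovery.

    Snapshots are taken at the immediate pre-event point (label ``pre``) and
    at every sampling offset into the recovery (labels ``rec_{offset}``;
    offset 0 is the immediate post-event population).  Identical
    (cfg, sched, seed) inputs yield bit-identical genealogy logs.  If the
    whole population becomes non-viable the replicate is labeled failed and
    the log is still returned.
    """
    rng = np.random.default_rng(seed)
    pop, res = init_state(cfg)
    snapshots: dict[str, Snapshot] = {}

    def snap(label: str) -> None:
        snapshots[label] = Snapshot(
            label=label,
            update=pop.update,
            genotypes=pop.extant_genotypes(),
            n_organisms=pop.n_alive,
        )

    def advance(cfg_now: EcologyConfig, until: int) -> bool:
        while pop.update < until and not pop.failed:
            step_update(pop, res, cfg_now, rng)
        return not pop.failed

    ok = advance(cfg, sched.pre_updates)
    if ok:
        snap("pre")
        if sched.kind == "pulse":
            apply_pulse_cull(pop, sched.pulse_survivors, rng)
        else:
            factor = sched.press_inflow_factor if sched.kind == "press" else 1.0
            pressed = set_press_inflows(cfg, factor)
            ok = advance(pressed, sched.pre_updates + sched.press_duration)
    if ok:
        for offset in sched.sampling_offsets:
            if not advance(cfg, sched.event_end + offset):
                break
            snap(f"rec_{offset}")
    return ExperimentResult(
        log=pop.log, snapshots=snapshots, cfg=cfg, schedule=sched, seed=seed,
        failed=pop.failed,
    )
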