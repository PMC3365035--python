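"""Configuration for the digital ecology and the extinction treatments.

The ecology is a fixed-size, well-mixed population of asexual replicators
competing for depletable resources arranged in a cross-feeding cascade: two
basal resources flow in exogenously, every other resource exists only as a
by-product of organisms consuming an upstream resource.  Time is measured in
*updates*; every age, branch length and schedule in the package uses updates.

Two size profiles are provided.  The ``paper`` profile mirrors the original
experimental scale (3600 organisms, 100,000 updates of pre-extinction history,
a 5,000-update press window, 100,000 updates of recovery).  The ``desk``
profile is a tenfold reduction (400 organisms, 10,000 + 1,000 + 10,000
updates) sized so that a full multi-treatment experiment runs on one CPU in
minutes while still producing trees with hundreds of nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import yaml

#: Names of the resource-linked functions, ordered by cascade depth.
FUNCTIONS = ("NOT", "NAND", "AND", "ORN", "OR", "ANDN", "NOR", "XOR", "EQU")

#: Per-function merit rewards, increasing with cascade depth (configurable).
DEFAULT_REWARDS = (1.0, 2.0, 2.0, 2.0, 4.0, 4.0, 4.0, 8.0, 8.0)

#: Exogenous inflow (resource units / update); only the two basal resources.
DEFAULT_INFLOW = (100.0, 100.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

#: Cross-feeding topology: byproducts[j] lists the resources fed by consuming
#: resource j.  Both basal functions feed the second level, the second level
#: feeds the third, and the third feeds the apex function.
DEFAULT_BYPRODUCTS = (
    (2, 3, 4),
    (2, 3, 4),
    (5, 6, 7),
    (5, 6, 7),
    (5, 6, 7),
    (8,),
    (8,),
    (8,),
    (),
)

TREATMENTS = (
    "control",
    "pulse-strong",
    "pulse-weak",
    "press-strong",
    "press-weak",
)


@dataclass(frozen=True)
class EcologyConfig:
    """Parameters of the digital ecology.

    Parameters
    ----------
    population_size
        Number of organism slots; the population is held at this size except
        transiently after a pulse cull, while births refill the vacancies.
    n_functions
        Number of resource-linked functions in the cascade.
    rewards
        Merit reward per unit of resource consumed, one entry per function.
    inflow
        Exogenous inflow per resource (units/update); nonzero only for the
        basal resources by default.
    decay
        Per-update fractional outflow of every resource pool.
    uptake_fraction
        Fraction alpha of a resource pool removed per update when at least one
        organism performs the associated function.
    conversion_factor
        Units of consumed resource required to produce one unit of each
        downstream by-product.
    base_merit
        Merit available to every viable organism regardless of traits; this is
        what sustains "disaster taxa" during a press episode.
    trait_cost
        Per-trait increment to gestation effort; fitness is divided by
        ``1 + trait_cost * n_traits``.
    birth_rate
        Expected births per organism slot per update (sets generation time).
    mu_trait
        Per-function gain/loss mutation probability per birth.
    mu_tag
        Neutral-tag mutation probability per birth; this is what drives
        near-neutral cladogenesis.
    mu_lethal
        Probability that a birth carries a lethal (non-viable) mutation.
    """

    population_size: int = 3600
    n_functions: int = 9
    rewards: tuple = DEFAULT_REWARDS
    inflow: tuple = DEFAULT_INFLOW
    decay: float = 0.01
    uptake_fraction: float = 0.1
    conversion_factor: float = 3.0
    base_merit: float = 1.0
    trait_cost: float = 0.25
    birth_rate: float = 0.1
    mu_trait: float = 0.002
    mu_tag: float = 0.05
    mu_lethal: float = 0.02
    byproducts: tuple = DEFAULT_BYPRODUCTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0.0 < self.decay < 1.0):
            raise ValueError("decay must lie in (0, 1)")
        if not (0.0 < self.uptake_fraction <= 1.0):
            raise ValueError("uptake_fraction must lie in (0, 1]")
        if self.conversion_factor <= 0:
            raise ValueError("conversion_factor must be positive")
        for name in ("mu_trait", "mu_tag", "mu_lethal"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.birth_rate < 0:
            raise ValueError("birth_rate must be nonnegative")
        for t, n in (("rewards", "reward"), ("inflow", "inflow")):
            vals = getattr(self, t)
            if len(vals) != self.n_functions:
                raise ValueError(f"{t} must have one entry per function")
        if any(r <= 0 for r in self.rewards):
            raise ValueError("rewards must be positive")
        if any(i < 0 for i in self.inflow):
            raise ValueError("inflow entries must be nonnegative")
        if len(self.byproducts) != self.n_functions:
            raise ValueError("byproducts must have one entry per function")
        for downs in self.byproducts:
            if any(not (0 <= d < self.n_functions) for d in downs):
                raise ValueError("byproduct index out of range")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Timing and strength of one extinction treatment.

    ``kind`` is one of ``control``, ``pulse`` or ``press``.  A control is run
    as a press window with inflow factor 1.0 so that all three kinds share the
    same absolute timeline (pre + window + recovery), mirroring the way the
    unperturbed runs span the same total number of updates as the press runs.
    ``sampling_offsets`` are measured in updates into the recovery (offset 0 is
    the immediate post-event point); the immediate pre-extinction point is
    always snapshot as well.
    """

    kind: str
    strength: str = "none"
    pre_updates: int = 100_000
    press_duration: int = 5_000
    press_inflow_factor: float = 1.0
    pulse_survivors: int = 0
    recovery_updates: int = 100_000
    sampling_offsets: tuple = (0, 2000, 5000, 10000, 25000, 50000, 75000, 100000)

    def __post_init__(self) -> None:
        if self.kind not in ("control", "pulse", "press"):
            raise ValueError(f"unknown treatment kind: {self.kind!r}")
        if self.kind == "pulse" and self.pulse_survivors < 2:
            raise ValueError("pulse treatments need pulse_survivors >= 2")
        if not (0.0 < self.press_inflow_factor <= 1.0):
            raise ValueError("press_inflow_factor must lie in (0, 1]")
        if list(self.sampling_offsets) != sorted(self.sampling_offsets):
            raise ValueError("sampling_offsets must be sorted ascending")
        if self.sampling_offsets and self.sampling_offsets[-1] > self.recovery_updates:
            raise ValueError("sampling_offsets must not exceed recovery_updates")
        if min(self.pre_updates, self.press_duration, self.recovery_updates) < 0:
            raise ValueError("durations must be nonnegative")

    @property
    def event_start(self) -> int:
        return self.pre_updates

    @property
    def event_end(self) -> int:
        """Update at which the recovery clock starts."""
        if self.kind == "pulse":
            return self.pre_updates
        return self.pre_updates + self.press_duration

    @property
    def total_updates(self) -> int:
        return self.event_end + self.recovery_updates


_PROFILE_TIMING = {
    "paper": dict(
        pre_updates=100_000,
        press_duration=5_000,
        recovery_updates=100_000,
        sampling_offsets=(0, 2000, 5000, 10000, 25000, 50000, 75000, 100000),
    ),
    "desk": dict(
        pre_updates=10_000,
        press_duration=1_000,
        recovery_updates=10_000,
        sampling_offsets=(0, 200, 500, 1000, 2500, 5000, 7500, 10000),
    ),
}

#: Retention bin width (updates) per profile; the paper-scale width is 5000.
PROFILE_BIN_WIDTH = {"paper": 5000, "desk": 500}


def profile_config(profile: str = "desk", **overrides) -> EcologyConfig:
    """Return the EcologyConfig for a size profile (``desk`` or ``paper``)."""
    if profile not in _PROFILE_TIMING:
        raise ValueError(f"unknown profile: {profile!r}")
    base = dict(population_size=400 if profile == "desk" else 3600)
    base.update(overrides)
    return EcologyConfig(**base)


def make_schedule(treatment: str, profile: str = "desk", **overrides) -> TreatmentSchedule:
    """Build the TreatmentSchedule for a named treatment at a given profile.

    Treatments: ``control`` (unperturbed), ``pulse-strong`` (instant cull to 4
    random viable survivors), ``pulse-weak`` (36 survivors), ``press-strong``
    (basal inflows x0.01 for the press window), ``press-weak`` (x0.1).
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment: {treatment!r}")
    timing = dict(_PROFILE_TIMING[profile])
    timing.update(overrides)
    if treatment == "control":
        return TreatmentSchedule(kind="control", strength="none", **timing)
    kind, strength = treatment.split("-")
    if kind == "pulse":
        survivors = 4 if strength == "strong" else 36
        return TreatmentSchedule(
            kind="pulse", strength=strength, pulse_survivors=survivors, **timing
        )
    factor = 0.01 if strength == "strong" else 0.1
    return TreatmentSchedule(
        kind="press", strength=strength, press_inflow_factor=factor, **timing
    )


# ---------------------------------------------------------------------------
# flat YAML round trip

_SEQ_FIELDS = ("rewards", "inflow", "sampling_offsets")


def save_config(cfg: EcologyConfig, path, schedule: TreatmentSchedule | None = None) -> None:
    """Write a flat YAML file mirroring the config (and optional schedule)."""
    data: dict = {k: list(v) if k in _SEQ_FIELDS else v for k, v in vars(cfg).items()}
    data["byproducts"] = [list(d) for d in cfg.byproducts]
    if schedule is not None:
        sched = {k: list(v) if k in _SEQ_FIELDS else v for k, v in vars(schedule).items()}
        data["schedule"] = sched
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> tuple[EcologyConfig, TreatmentSchedule | None]:
    """Read a flat YAML config; returns (EcologyConfig, schedule or None)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    sched_data = data.pop("schedule", None)
    for k in _SEQ_FIELDS:
        if k in data:
            data[k] = tuple(data[k])
    if "byproducts" in data:
        data["byproducts"] = tuple(tuple(d) for d in data["byproducts"])
    cfg = EcologyConfig(**data)
    schedule = None
    if sched_data is not None:
        for k in _SEQ_FIELDS:
            if k in sched_data:
                sched_data[k] = tuple(sched_data[k])
        schedule = TreatmentSchedule(**sched_data)
    return cfg, schedule
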