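"""Shared fixtures: worked genealogies, random-log generators, and one
session-scoped multi-treatment simulation grid reused by the directional
tests (it is by far the most expensive thing the suite runs)."""

from __future__ import annotations

import numpy as np
import pytest

from phyloerosion import ExperimentManifest, GenealogyLog, run_pipeline

#: Fixed suite-wide seed for every stochastic check.
SUITE_SEED = 20260920


@pytest.fixture()
def worked_log() -> GenealogyLog:
    """The four-genotype worked example: founder G0 (extinct), G1 and G2
    children of G0 at t=10 and t=20, G3 child of G1 at t=30; extant at
    t=100: G1, G2, G3.  The t=20 event collapses because only one line of
    descent from it survives."""
    log = GenealogyLog()
    g0 = log.add(-1, 0, 0, True, 0)
    g1 = log.add(g0, 10, 0, True, 1)
    log.add(g0, 20, 0, True, 2)
    log.add(g1, 30, 0, True, 3)
    log.set_extinct(g0, 50)
    return log


def random_log(
    rng: np.random.Generator,
    n_genotypes: int = 10,
    horizon: int = 100,
    p_extinct: float = 0.5,
) -> GenealogyLog:
    """Random genealogy forest with a single founder: children attach to any
    earlier genotype; a genotype may go extinct at a random time after its
    origin, but never before its last child's origin (a parent must be alive
    to give birth, as in any real genealogy)."""
    log = GenealogyLog()
    log.add(-1, 0, 0, True, 0)
    origins = [0]
    parents = [-1]
    for i in range(1, n_genotypes):
        origin = int(rng.integers(origins[-1] + 1, origins[-1] + 10))
        parent = int(rng.integers(0, i))
        # parent must originate strictly earlier
        while origins[parent] >= origin:
            parent = int(rng.integers(0, i))
        log.add(parent, origin, int(rng.integers(0, 4)), True, i)
        origins.append(origin)
        parents.append(parent)
    for i in range(n_genotypes):
        if rng.random() < p_extinct:
            lo = max(
                [origins[i]] + [origins[c] for c in range(n_genotypes)
                                if parents[c] == i]
            )
            log.set_extinct(i, int(rng.integers(lo, max(lo + 1, horizon))))
    return log


@pytest.fixture()
def random_log_factory():
    return random_log


DIRECTIONAL_TREATMENTS = ("control", "press-strong", "pulse-strong")
DIRECTIONAL_REPLICATES = 20


@pytest.fixture(scope="session")
def directional_runs():
    """Desk-profile grid of 20 replicates for control and both strong
    treatments; shared by the root-retention and deep-bin-retention
    directional checks."""
    manifest = ExperimentManifest(
        treatments=DIRECTIONAL_TREATMENTS,
        replicates=DIRECTIONAL_REPLICATES,
        base_seed=SUITE_SEED,
    )
    return run_pipeline(manifest)
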