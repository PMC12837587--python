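"""Island-continent migration as an affine frequency map with its fold.

Each generation a fraction m of the island is replaced by migrants drawn
from a continent with fixed frequencies q_C:

    q_I(t+1) = (1 - m) q_I(t) + m q_C.

The map is affine, not multiplicative, but the Jeffreys divergence between
consecutive island states is still well defined and quantifies the
information change induced by migration.  The continent distribution is the
unique fixed point (for m > 0), where the fold vanishes; each allele
approaches it geometrically, p(t) = P + (1-m)^t (p0 - P).

Selection can be composed with migration within a generation; the default
order is selection first, then migration (the standard island-model
recursion), configurable via ``order``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import FrequencyDistribution
from .divergence import jeffreys_divergence
from .replicator import FoldSeries, select_update


@dataclass(frozen=True)
class MigrationSpec:
    """Migration rate m in [0, 1] and the fixed continent distribution."""

    m: float
    continent: FrequencyDistribution

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("migration rate must lie in [0, 1]")


def migrate(q_island: FrequencyDistribution, spec: MigrationSpec) -> FrequencyDistribution:
    """One migration step: the convex combination (1-m) q_I + m q_C."""
    q_island.same_support(spec.continent, "migrate")
    v = (1.0 - spec.m) * q_island.values + spec.m * spec.continent.values
    return FrequencyDistribution(q_island.labels, v)


def migration_fold(
    q_next: FrequencyDistribution, q_island: FrequencyDistribution, smoothing: bool = False
) -> float:
    """J(q_I(t+1), q_I(t)): zero exactly at the fixed point q_I = q_C."""
    return jeffreys_divergence(q_next, q_island, smoothing=smoothing)


def iterate_migration(
    q0: FrequencyDistribution,
    spec: MigrationSpec,
    steps: int,
    w=None,
    order: str = "selection-first",
) -> tuple[list[FrequencyDistribution], FoldSeries]:
    """Iterate migration (optionally composed with selection) for ``steps``
    generations; returns the trajectory and per-step folds.

    Without selection the per-step folds decrease monotonically to zero as
    the island converges geometrically to the continent distribution.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if order not in ("selection-first", "migration-first"):
        raise ValueError("order must be 'selection-first' or 'migration-first'")
    traj = [q0]
    folds = FoldSeries()
    q = q0
    for t in range(steps):
        if w is not None and order == "selection-first":
            q_mid = select_update(q, np.asarray(w, dtype=float))
        else:
            q_mid = q
        q_next = migrate(q_mid, spec)
        if w is not None and order == "migration-first":
            q_next = select_update(q_next, np.asarray(w, dtype=float))
        J = migration_fold(q_next, q)
        folds.append(t, J_r=J, J_rt=J)
        traj.append(q_next)
        q = q_next
    return traj, folds


def closed_form(p0: float, P: float, m: float, t: int) -> float:
    """Biallelic island frequency after t generations of pure migration:
    p(t) = P + (1-m)^t (p0 - P)."""
    return P + (1.0 - m) ** t * (p0 - P)
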