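"""Two-level (tragedy-of-the-commons) selection and its information flows.

Each group holds two haploid genotypes with competitiveness x1, x2 at
frequencies q and 1-q.  Within a group, the more competitive type wins:

    y  = q*x1 + (1-q)*x2          (mean competitiveness of the group)
    q' = q * x1 / y

with a within-group fold J_q, the binary Jeffreys divergence between q and
q'.  Between groups, selection of intensity s favors groups with *lower*
mean competitiveness — the tragedy — through the group fitness k - y*s
(k > 0 keeps it positive), reweighting the ensemble distribution p_q with a
between-group fold J_G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import FrequencyDistribution
from .divergence import jeffreys_divergence


@dataclass(frozen=True)
class GroupState:
    """One group: frequency q of genotype 1 and competitiveness values."""

    q: float
    x1: float
    x2: float

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.x1 <= 0 or self.x2 <= 0:
            raise ValueError("competitiveness values must be > 0")

    @property
    def y(self) -> float:
        """Mean competitiveness of the group."""
        return self.q * self.x1 + (1.0 - self.q) * self.x2


@dataclass(frozen=True)
class GroupEnsemble:
    """Distribution p_q over groups differing in their initial q.

    ``grid`` holds the initial q of each group, ``p`` their probabilities
    (a FrequencyDistribution over the grid); x1, x2 are shared; s >= 0 is
    the intensity of between-group selection and k the positivity offset,
    required to exceed max(y)*s so every group fitness k - y*s stays
    positive.
    """

    grid: np.ndarray
    p: FrequencyDistribution
    x1: float
    x2: float
    s: float = 0.0
    k: float = 1.0

    def __init__(self, grid, p: FrequencyDistribution, x1: float, x2: float,
                 s: float = 0.0, k: float = 1.0) -> None:
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size != len(p):
            raise ValueError("grid and p must have matching lengths")
        if np.any(grid < 0) or np.any(grid > 1):
            raise ValueError("grid frequencies must lie in [0, 1]")
        if x1 <= 0 or x2 <= 0:
            raise ValueError("competitiveness values must be > 0")
        if s < 0:
            raise ValueError("between-group selection intensity s must be >= 0")
        y = grid * x1 + (1.0 - grid) * x2
        bad = np.where(k - y * s <= 0)[0]
        if bad.size:
            raise ValueError(
                f"group fitness k - y*s is non-positive at grid point(s) "
                f"{grid[bad].tolist()} (k={k}, s={s})"
            )
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "k", k)

    def groups(self) -> list[GroupState]:
        return [GroupState(float(q), self.x1, self.x2) for q in self.grid]

    @property
    def y(self) -> np.ndarray:
        """Mean competitiveness of each group."""
        return self.grid * self.x1 + (1.0 - self.grid) * self.x2


def within_group_update(g: GroupState) -> float:
    """Within-group competitive update q' = q*x1 / (q*x1 + (1-q)*x2).

    Equal competitiveness returns q unchanged (exactly), so the neutral case
    generates exactly zero information."""
    if g.x1 == g.x2:
        return g.q
    return g.q * g.x1 / g.y


def within_group_info(q: float, q_next: float) -> float:
    """Binary Jeffreys divergence between the group states q and q'.

    Defined as 0 at a boundary fixed point (q in {0, 1} with q' = q); any
    other boundary input is an error, as the log-ratio is undefined there.
    """
    if q == q_next and q in (0.0, 1.0):
        return 0.0
    if not (0.0 < q < 1.0 and 0.0 < q_next < 1.0):
        raise ValueError("within_group_info requires interior frequencies (0, 1)")
    return float(
        (q_next - q) * np.log(q_next / q) + (q - q_next) * np.log((1.0 - q_next) / (1.0 - q))
    )


def mean_intra_info(e: GroupEnsemble) -> float:
    """Average within-group information before between-group selection:
    Jbar_x = sum_q p_q * J_q."""
    total = 0.0
    for p_q, g in zip(e.p.values, e.groups()):
        total += float(p_q) * within_group_info(g.q, within_group_update(g))
    return total


def inter_group_update(e: GroupEnsemble) -> tuple[FrequencyDistribution, float]:
    """Between-group reweighting and its fold.

    Group fitness is k - y*s; omega_G divides by the ensemble mean so the
    new group distribution p'_q = p_q * omega_G stays on the simplex.
    Returns (p', J_G).
    """
    fitness = e.k - e.y * e.s
    wbar = float(np.sum(e.p.values * fitness))
    p_next = FrequencyDistribution(e.p.labels, e.p.values * fitness / wbar)
    return p_next, jeffreys_divergence(p_next, e.p)


def cycle(e: GroupEnsemble) -> tuple[GroupEnsemble, float, float]:
    """One full two-stage episode: within-group competition in every group
    (updating each q and hence y), then between-group reweighting of the
    ensemble at the updated competitiveness.

    Jbar_x is computed before between-group selection, from the initial q of
    each group.  Returns (advanced ensemble, Jbar_x, J_G)."""
    jbar = mean_intra_info(e)
    new_grid = np.array([within_group_update(g) for g in e.groups()])
    e_within = GroupEnsemble(new_grid, e.p, e.x1, e.x2, e.s, e.k)
    p_next, J_G = inter_group_update(e_within)
    e_next = GroupEnsemble(new_grid, p_next, e.x1, e.x2, e.s, e.k)
    return e_next, jbar, J_G
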