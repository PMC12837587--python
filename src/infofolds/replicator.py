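"""Discrete replicator dynamics within a lineage, with per-step
informational folds.

One generation is: selection (p' = p * w / wbar), optionally followed by
transmission through a column-stochastic kernel T (mutation/recombination-
like reshuffling), p'' = T @ p'.  Two folds are attached to the step:

* ``J_r``  = J(p', p)   — information generated by selection alone;
* ``J_rt`` = J(p'', p)  — information generated by selection plus
  transmission.

The transmission residual ``J_rt - J_r`` is reported as-is; it may be
negative (full mixing can undo the selective reallocation entirely).
Equilibria are states whose one-step fold vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .distributions import FrequencyDistribution
from .divergence import jeffreys_divergence

FitnessLike = Sequence[float] | np.ndarray
FitnessSchedule = FitnessLike | Sequence[FitnessLike] | Callable[[FrequencyDistribution, int], FitnessLike]


@dataclass(frozen=True)
class LineageState:
    """State of lineage ``lineage`` at generation ``t``: a frequency
    distribution over its coexisting substates."""

    lineage: str
    distribution: FrequencyDistribution
    t: int = 0

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("generation index t must be >= 0")


@dataclass(frozen=True)
class TransmissionKernel:
    """Column-stochastic matrix T[s', s]: probability that a type-s parent
    contributes a type-s' offspring."""

    matrix: np.ndarray

    def __init__(self, matrix) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("transmission kernel must be a square matrix")
        if np.any(matrix < 0) or np.any(matrix > 1):
            raise ValueError("transmission kernel entries must lie in [0, 1]")
        colsums = matrix.sum(axis=0)
        bad = np.where(np.abs(colsums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"transmission kernel columns {bad.tolist()} sum to "
                f"{colsums[bad].tolist()}, not 1"
            )
        object.__setattr__(self, "matrix", matrix)

    @classmethod
    def symmetric_mutation(cls, n: int, mu: float) -> "TransmissionKernel":
        """n-type kernel with per-generation mutation rate mu spread evenly
        over the other n-1 types."""
        if not 0 <= mu <= 1:
            raise ValueError("mutation rate must lie in [0, 1]")
        m = np.full((n, n), mu / (n - 1))
        np.fill_diagonal(m, 1.0 - mu)
        return cls(m)


@dataclass
class FoldSeries:
    """Per-step informational folds of a trajectory and their running sum.

    Each record holds (t, J_r, J_rt, J_repr, J_total); ``J_total`` is the
    step's bookkeeping fold (J_rt plus any reproductive fold), and
    ``cumulative`` is the sum of J_total over recorded steps.
    """

    records: list = field(default_factory=list)

    def append(self, t: int, J_r: float, J_rt: float, J_repr: float = 0.0) -> None:
        J_total = J_rt + J_repr
        self.records.append(
            {"t": t, "J_r": J_r, "J_rt": J_rt, "J_repr": J_repr, "J_total": J_total}
        )

    @property
    def cumulative(self) -> float:
        return float(sum(r["J_total"] for r in self.records))

    def per_step(self, key: str = "J_total") -> np.ndarray:
        return np.array([r[key] for r in self.records])

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["t", "J_r", "J_rt", "J_repr", "J_total"])
        df["cumulative"] = df["J_total"].cumsum()
        return df


def _as_fitness(w, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"fitness vector of length {w.size} for {n} types")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("fitness must be finite and strictly positive")
    return w


def select_update(p: FrequencyDistribution, w) -> FrequencyDistribution:
    """One selection step of the discrete replicator: p'_s = p_s w_s / wbar."""
    w = _as_fitness(w, len(p))
    v = p.values * w
    return FrequencyDistribution(p.labels, v / v.sum())


def transmit_update(p: FrequencyDistribution, T: TransmissionKernel) -> FrequencyDistribution:
    """Push frequencies through the transmission kernel: p'' = T @ p."""
    if T.matrix.shape[0] != len(p):
        raise ValueError("transmission kernel dimension does not match distribution")
    v = T.matrix @ p.values
    return FrequencyDistribution(p.labels, v / v.sum())


def step_folds(
    p: FrequencyDistribution,
    w,
    T: TransmissionKernel | None = None,
    smoothing: bool = False,
) -> tuple[FrequencyDistribution, float, float]:
    """One full generation and its folds.

    Returns ``(p_next, J_r, J_rt)`` where J_r = J(post-selection, p) and
    J_rt = J(post-transmission, p).  Without a kernel, J_rt = J_r.
    """
    p_sel = select_update(p, w)
    J_r = jeffreys_divergence(p_sel, p, smoothing=smoothing)
    if T is None:
        return p_sel, J_r, J_r
    p_next = transmit_update(p_sel, T)
    J_rt = jeffreys_divergence(p_next, p, smoothing=smoothing)
    return p_next, J_r, J_rt


def _fitness_at(schedule: FitnessSchedule, p: FrequencyDistribution, t: int) -> np.ndarray:
    if callable(schedule):
        return _as_fitness(schedule(p, t), len(p))
    arr = np.asarray(schedule, dtype=float)
    if arr.ndim == 2:  # per-step list of fitness vectors
        return _as_fitness(arr[t], len(p))
    return _as_fitness(arr, len(p))


def iterate_lineage(
    p0: FrequencyDistribution,
    fitness: FitnessSchedule,
    T: TransmissionKernel | None = None,
    steps: int = 1,
    smoothing: bool = False,
) -> tuple[list[FrequencyDistribution], FoldSeries]:
    """Iterate selection(+transmission) for ``steps`` generations.

    Fitness may be a constant vector, a per-step sequence of vectors, or a
    callable ``(p, t) -> w`` evaluated at the pre-selection state.  Returns
    the trajectory ``[p0, p1, ..., p_steps]`` and the fold series.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    traj = [p0]
    folds = FoldSeries()
    p = p0
    for t in range(steps):
        w = _fitness_at(fitness, p, t)
        p, J_r, J_rt = step_folds(p, w, T, smoothing=smoothing)
        folds.append(t, J_r, J_rt)
        traj.append(p)
    return traj, folds


def is_equilibrium(
    p: FrequencyDistribution,
    w,
    T: TransmissionKernel | None = None,
    tol: float = 1e-9,
) -> bool:
    """True iff one step changes the state by less than ``tol`` in fold.

    Monomorphic states without a kernel are fixed points by definition (no
    variation, no change), even though the fold is undefined off the shared
    support.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    _, _, J_rt = step_folds(p, w, T)
    return J_rt < tol


def trajectory_frame(traj: Sequence[FrequencyDistribution]) -> pd.DataFrame:
    """Tidy trajectory: one row per (t, label) with the frequency."""
    rows = [
        {"t": t, "label": lab, "frequency": float(v)}
        for t, p in enumerate(traj)
        for lab, v in zip(p.labels, p.values)
    ]
    return pd.DataFrame(rows, columns=["t", "label", "frequency"])
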