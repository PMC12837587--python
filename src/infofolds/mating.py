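"""Pair-formation (mating) dynamics and the reproductive informational fold.

A pairing table q[i, j] holds the frequencies of (female-type i, male-type j)
pairs; a mating fitness matrix m[i, j] gives the relative pair-formation
propensities.  The mating update reweights the table exactly like a
replicator step, q' = q * m / mean(m), and the reproductive fold is the
flattened Jeffreys divergence J_repr = sum (q'-q) ln(q'/q).

The fold splits additively into intra-lineage (same lineage on both sides)
and inter-lineage cells, and the full mating partition
J = J_S1 + J_S2 + J_PSI + E (sexual-selection marginals, pair sexual
isolation, interaction residual) is the holobiont partition with the two
axes read as the two sexes.

Fecundity aggregation rules G combine the two parental rates into the rate
of the cross: G_L = x, G_R = y, G_mean = (x+y)/2, G_geom = sqrt(xy),
G_lambda = lam*x + (1-lam)*y, G_hybrid = I_xy * (x+y)/2 where the isolation
factor I_xy = 0 means complete isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import holobiont
from .distributions import JointTable
from .divergence import jeffreys_divergence
from .holobiont import InfoPartition

PairingTable = JointTable

RULES = ("L", "R", "mean", "geom", "lambda", "hybrid")


@dataclass(frozen=True)
class MatingFitness:
    """Relative pair-formation propensities m[i, j] >= 0, not all zero."""

    matrix: np.ndarray

    def __init__(self, matrix) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValueError("mating fitness must be a 2-D matrix")
        if not np.all(np.isfinite(matrix)) or np.any(matrix < 0):
            raise ValueError("mating fitness must be finite and >= 0")
        if not np.any(matrix > 0):
            raise ValueError("mating fitness must not be all zero")
        object.__setattr__(self, "matrix", matrix)


@dataclass(frozen=True)
class FecundityRule:
    """One of the aggregation hypotheses G, with its parameters.

    ``lam`` applies to the ``lambda`` rule; ``isolation`` (I_xy >= 0)
    applies to ``hybrid``.
    """

    rule: str
    lam: float = 0.5
    isolation: float = 1.0

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"unknown fecundity rule {self.rule!r}; choose from {RULES}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.isolation < 0:
            raise ValueError("isolation factor must be >= 0")


def pairing_update(q: PairingTable, m: MatingFitness | np.ndarray) -> PairingTable:
    """Mating-fitness reweighting q'_ij = q_ij m_ij / sum(q m).

    The division by the mean mating fitness keeps q' on the simplex, so the
    reproductive fold compares two probability distributions.
    """
    mat = m.matrix if isinstance(m, MatingFitness) else MatingFitness(m).matrix
    if mat.shape != q.shape:
        raise ValueError(f"mating fitness shape {mat.shape} does not match table {q.shape}")
    mass = float(np.sum(q.values * mat))
    if mass <= 0:
        raise ValueError("all weighted pairing mass is zero")
    return JointTable(q.axis_names, q.axis_labels, q.values * mat / mass)


def reproductive_fold(
    q_after: PairingTable, q_before: PairingTable, smoothing: bool = False
) -> float:
    """J_repr = sum (q'-q) ln(q'/q) over all pair cells, in nats."""
    return jeffreys_divergence(q_after.flatten(), q_before.flatten(), smoothing=smoothing)


def intra_inter_split(
    q_after: PairingTable,
    q_before: PairingTable,
    lineage_of: Mapping,
) -> tuple[float, float]:
    """Split J_repr into intra-lineage and inter-lineage contributions.

    Each term-wise Jeffreys summand (q'_ij - q_ij) ln(q'_ij / q_ij) is
    assigned to the intra part when ``lineage_of`` maps the row and column
    labels to the same lineage, else to the inter part; the two parts sum to
    J_repr exactly.
    """
    q_after.same_support(q_before, "intra_inter_split")
    rows, cols = q_after.axis_labels
    for lab in (*rows, *cols):
        if lab not in lineage_of:
            raise ValueError(f"intra_inter_split: label {lab!r} has no lineage assignment")
    a, b = q_after.values, q_before.values
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intra_inter_split: zero cell; shared positive support required")
    terms = (a - b) * np.log(a / b)
    same = np.array(
        [[lineage_of[r] == lineage_of[c] for c in cols] for r in rows], dtype=bool
    )
    intra = float(terms[same].sum())
    inter = float(terms[~same].sum())
    return intra, inter


def aggregate_rates(x: float, y: float, rule: FecundityRule) -> float:
    """Post-mating rate of the cross from the two parental rates."""
    if x < 0 or y < 0:
        raise ValueError("rates must be >= 0")
    if rule.rule == "L":
        return float(x)
    if rule.rule == "R":
        return float(y)
    if rule.rule == "mean":
        return (x + y) / 2.0
    if rule.rule == "geom":
        return math.sqrt(x * y)
    if rule.rule == "lambda":
        return rule.lam * x + (1.0 - rule.lam) * y
    return rule.isolation * (x + y) / 2.0  # hybrid


def mating_partition(
    q_after: PairingTable, q_before: PairingTable, smoothing: bool = False
) -> InfoPartition:
    """Mating-model reading of the holobiont partition.

    The two table axes are read as the two sexes and the components as
    J = J_S1 + J_S2 + J_PSI + E; numerically identical to
    :func:`infofolds.holobiont.partition` on the same tables.
    """
    return holobiont.partition(q_before, q_after, smoothing=smoothing)
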