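"""Holobiont selection and the informational partition
J_total = J_H + sum_k J_Mk + J_assoc + E.

A holobiont class is one joint configuration (host type, microbiome types);
the population state is a :class:`~infofolds.distributions.JointTable` q over
those classes.  Selection is the replicator update q' = q * W / wbar with a
multiplicatively decomposed fitness

    W[i, j1..jK] = W_H(i) * prod_k W_Mk(jk) * a[i, j1..jK],

where the association factor ``a`` captures non-independent host-microbiome
interaction effects (a = 1 everywhere means host and microbiome contribute
independently).

The total Jeffreys fold of the step decomposes against the independence
reference r = outer product of the *post*-selection marginals:

* J_H, J_Mk — Jeffreys divergences of the host and per-component marginals;
* J_assoc = T4 = sum (q'-r) ln(q'/r) >= 0 — information in the pairing
  structure beyond the product of marginals (the holobiont analogue of the
  pair sexual-isolation statistic PSI);
* E = J_total - J_H - sum_k J_Mk - J_assoc — non-additive interaction
  residual, which may be slightly negative.

The four T-terms of the underlying algebraic split (with T1+T2+T3+T4 =
J_total exactly, and T3 = 0 whenever the initial q is a product of its own
marginals) are attached as diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distributions import FrequencyDistribution, JointTable
from .divergence import SMOOTHING_EPS, jeffreys_divergence


@dataclass(frozen=True)
class HolobiontFitness:
    """Multiplicative holobiont fitness specification.

    ``w_host`` is the per-host-type contribution, ``w_components`` one vector
    per microbiome component, and ``association`` the per-cell interaction
    factor (same shape as the joint table).  All strictly positive.
    """

    w_host: np.ndarray
    w_components: tuple
    association: np.ndarray

    def __init__(self, w_host, w_components: Sequence, association) -> None:
        w_host = np.asarray(w_host, dtype=float)
        w_components = tuple(np.asarray(w, dtype=float) for w in w_components)
        association = np.asarray(association, dtype=float)
        shape = (w_host.size,) + tuple(w.size for w in w_components)
        if association.shape != shape:
            raise ValueError(
                f"association factor shape {association.shape} does not match "
                f"marginal fitness shape {shape}"
            )
        for arr, what in ((w_host, "w_host"), (association, "association"), *(
            (w, f"w_components[{k}]") for k, w in enumerate(w_components)
        )):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{what} must be finite and strictly positive")
        object.__setattr__(self, "w_host", w_host)
        object.__setattr__(self, "w_components", w_components)
        object.__setattr__(self, "association", association)


@dataclass(frozen=True)
class InfoPartition:
    """Informational partition of one holobiont selection step (nats).

    ``E`` is defined as the residual ``J_total - J_H - sum(J_M) - J_assoc``,
    so the components sum to the total by construction.  ``T2`` is the
    algebraic interaction term of the four-way split; it coincides with E
    only when the initial table is a product of its own marginals, and both
    are therefore reported.  ``I_assoc = J_assoc + E``.
    """

    J_total: float
    J_H: float
    J_M: tuple
    J_assoc: float
    E: float
    T1: float
    T2: float
    T3: float
    T4: float

    @property
    def I_assoc(self) -> float:
        return self.J_assoc + self.E

    def components(self) -> dict:
        d = {"J_total": self.J_total, "J_H": self.J_H}
        for k, j in enumerate(self.J_M, start=1):
            d[f"J_M{k}"] = j
        d.update(J_assoc=self.J_assoc, E=self.E, I_assoc=self.I_assoc)
        return d

    def as_dict(self) -> dict:
        d = self.components()
        d.update(T1=self.T1, T2=self.T2, T3=self.T3, T4=self.T4)
        return d

    def summary(self) -> str:
        lines = ["Informational partition (nats)"]
        for key, val in self.as_dict().items():
            lines.append(f"  {key:<8s} {val: .6f}")
        return "\n".join(lines)


def compose_fitness(spec: HolobiontFitness) -> np.ndarray:
    """Joint fitness array W = W_H (x) prod_k W_Mk * a."""
    w = spec.w_host.copy()
    for wk in spec.w_components:
        w = np.multiply.outer(w, wk)
    return w * spec.association


def decompose_fitness(W) -> HolobiontFitness:
    """Log-linear (ANOVA-style) decomposition of a positive fitness array.

    Writes ln W as grand mean + host main effect + per-component main
    effects + interaction residual, each effect mean-centered (unweighted);
    the grand mean is folded into the host factor and the residual
    exponentiates to the association factor, so
    ``compose_fitness(decompose_fitness(W))`` reproduces W to 1e-12.  The
    (W_H, W_M, a) factorization is only identifiable up to this gauge.
    """
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)) or np.any(W <= 0):
        raise ValueError("fitness array must be finite and strictly positive")
    logW = np.log(W)
    mu = logW.mean()
    effects = []
    for axis in range(W.ndim):
        other = tuple(a for a in range(W.ndim) if a != axis)
        effects.append(logW.mean(axis=other) - mu)
    resid = logW - mu
    for axis, eff in enumerate(effects):
        shape = [1] * W.ndim
        shape[axis] = eff.size
        resid = resid - eff.reshape(shape)
    return HolobiontFitness(
        w_host=np.exp(mu + effects[0]),
        w_components=tuple(np.exp(e) for e in effects[1:]),
        association=np.exp(resid),
    )


def holobiont_select(q: JointTable, W) -> tuple[JointTable, float]:
    """Replicator-like holobiont update q' = q * W / wbar; returns (q', wbar)."""
    W = np.asarray(W, dtype=float)
    if W.shape != q.shape:
        raise ValueError(f"fitness shape {W.shape} does not match table shape {q.shape}")
    if not np.all(np.isfinite(W)) or np.any(W <= 0):
        raise ValueError("fitness must be finite and strictly positive")
    wbar = float(np.sum(q.values * W))
    return JointTable(q.axis_names, q.axis_labels, q.values * W / wbar), wbar


def marginalize(q: JointTable) -> tuple[FrequencyDistribution, tuple]:
    """(host marginal, tuple of per-component marginals)."""
    host = q.marginal(0)
    comps = tuple(q.marginal(k) for k in range(1, q.values.ndim))
    return host, comps


def independence_reference(q_post: JointTable) -> JointTable:
    """Joint distribution expected under independence of the post-state:
    the outer product r = p' (x) m'_1 (x) ... of all post-state marginals."""
    host, comps = marginalize(q_post)
    return JointTable.product((host, *comps), axis_names=q_post.axis_names)


def _jeffreys_terms(a: np.ndarray, b: np.ndarray, smoothing: bool, op: str):
    """Aligned positive arrays for term-wise (x-y) ln(w/z) sums."""
    if smoothing:
        a = a + SMOOTHING_EPS
        b = b + SMOOTHING_EPS
        return a / a.sum(), b / b.sum()
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError(f"{op}: zero cell without smoothing enabled")
    return a, b


def t_terms(
    q: JointTable, q_post: JointTable, smoothing: bool = False
) -> tuple[float, float, float, float]:
    """Four-term algebraic split of the total fold against the independence
    reference r of the post-state:

        T1 = sum (r - q) ln(r / q)     marginal information
        T2 = sum (r - q) ln(q'/ r)     interaction term
        T3 = sum (q'- r) ln(r / q)     (0 when q is a product of its marginals)
        T4 = sum (q'- r) ln(q'/ r)     association information (>= 0)

    with T1 + T2 + T3 + T4 = J(q', q) exactly.
    """
    q.same_support(q_post, "t_terms")
    r = independence_reference(q_post).values
    qa, qb = _jeffreys_terms(q_post.values, q.values, smoothing, "t_terms")
    r = r if not smoothing else (r + SMOOTHING_EPS) / (r + SMOOTHING_EPS).sum()
    T1 = float(np.sum((r - qb) * np.log(r / qb)))
    T2 = float(np.sum((r - qb) * np.log(qa / r)))
    T3 = float(np.sum((qa - r) * np.log(r / qb)))
    T4 = float(np.sum((qa - r) * np.log(qa / r)))
    return T1, T2, T3, T4


def partition(q: JointTable, q_post: JointTable, smoothing: bool = False) -> InfoPartition:
    """Informational partition of the move q -> q' (one selection step).

    J_total is the flattened Jeffreys divergence; J_H and J_Mk are the
    Jeffreys divergences of the axis marginals; J_assoc = T4; E is the
    residual closing the partition.
    """
    q.same_support(q_post, "partition")
    J_total = jeffreys_divergence(q_post.flatten(), q.flatten(), smoothing=smoothing)
    host_pre, comps_pre = marginalize(q)
    host_post, comps_post = marginalize(q_post)
    J_H = jeffreys_divergence(host_post, host_pre, smoothing=smoothing)
    J_M = tuple(
        jeffreys_divergence(a, b, smoothing=smoothing)
        for a, b in zip(comps_post, comps_pre)
    )
    T1, T2, T3, T4 = t_terms(q, q_post, smoothing=smoothing)
    J_assoc = T4
    E = J_total - J_H - sum(J_M) - J_assoc
    return InfoPartition(J_total, J_H, J_M, J_assoc, E, T1, T2, T3, T4)


def association_information_direct(
    q: JointTable, q_post: JointTable, spec: HolobiontFitness
) -> float:
    """Association information computed directly from the fitness gauge:
    sum (q' - q) * ln(a).

    Depends on the (non-identifiable) gauge chosen for the association
    factor; reported alongside the partition-based ``I_assoc`` and may be
    negative.  Not asserted equal to the partition value.
    """
    q.same_support(q_post, "association_information_direct")
    a = spec.association
    if a.shape != q.shape:
        raise ValueError("association factor shape does not match table shape")
    return float(np.sum((q_post.values - q.values) * np.log(a)))


def permutation_test_association(
    counts: JointTable | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    pseudocount: float = 0.5,
) -> tuple[float, np.ndarray, float]:
    """Permutation test for host-microbiome association in a count table.

    The statistic is the association Jeffreys divergence of the observed
    table against the product of its own marginals, computed on
    pseudocount-adjusted frequencies (default 0.5 per cell, so zero cells
    stay finite; the identical statistic is applied to the null tables, so
    the test stays calibrated).  The null is generated by randomly
    re-pairing host labels against microbiome configurations, which
    preserves both marginal count vectors exactly.

    Returns ``(observed statistic, null distribution, p-value)`` with
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(counts, JointTable):
        raise ValueError(
            "pass raw integer counts (array), not a normalized JointTable; "
            "read_table keeps the raw counts for this purpose"
        )
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("permutation test requires a non-negative integer count table")
    counts2d = arr.reshape(arr.shape[0], -1).astype(np.int64)  # host x flat config
    row_tot = counts2d.sum(axis=1)
    col_tot = counts2d.sum(axis=0)

    def stat(tab: np.ndarray) -> float:
        f = tab + pseudocount
        f = f / f.sum()
        r = np.multiply.outer(f.sum(axis=1), f.sum(axis=0))
        return float(np.sum((f - r) * np.log(f / r)))

    observed = stat(counts2d.astype(float))
    if np.count_nonzero(row_tot) < 2 or np.count_nonzero(col_tot) < 2:
        warnings.warn("degenerate margins: a single category on one axis; p = 1")
        return observed, np.zeros(n_perm), 1.0

    rng = np.random.default_rng(seed)
    hosts = np.repeat(np.arange(counts2d.shape[0]), row_tot)
    configs = np.repeat(np.arange(counts2d.shape[1]), col_tot)
    null = np.empty(n_perm)
    flat_dim = counts2d.shape[1]
    for b in range(n_perm):
        perm = rng.permutation(configs)
        tab = np.bincount(
            hosts * flat_dim + perm, minlength=counts2d.size
        ).reshape(counts2d.shape)
        null[b] = stat(tab.astype(float))
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return observed, null, p


def toy_model() -> tuple[JointTable, np.ndarray, JointTable, InfoPartition]:
    """Packaged 2x2 example: two host genotypes x two microbiome types,
    initially independent and uniform (q = 0.25 per cell), with fitness
    W = [[1, 0.7], [0.7, 2]] giving a synergistic advantage to the
    (H1, M1) pairing.  Returns (q, W, q', partition)."""
    q = JointTable.uniform(("host", "M1"), (("H0", "H1"), ("M0", "M1")))
    W = np.array([[1.0, 0.7], [0.7, 2.0]])
    q_post, _ = holobiont_select(q, W)
    return q, W, q_post, partition(q, q_post)
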