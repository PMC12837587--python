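"""Seeded generators for every input the other modules consume.

All randomness flows from one integer seed through ``numpy``'s
``SeedSequence`` spawning (PCG64 streams), so each generator purpose gets
its own substream and adding a call for one purpose never perturbs the
draws of another.  Identical configuration => identical output, on any
platform.

Simplex draws are symmetric Dirichlet with a concentration parameter
(concentration -> infinity approaches the uniform distribution); fitness
effects are log-normal around 1 with separate spreads for host, microbiome
components and the association factor, matching the strict-positivity
requirement of the holobiont fitness decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distributions import FrequencyDistribution, JointTable
from .group_selection import GroupEnsemble
from .holobiont import HolobiontFitness

#: purpose tags -> fixed substream index, so streams are stable across calls
_PURPOSES = ("distribution", "joint", "fitness", "counts", "ensemble")


@dataclass
class GeneratorConfig:
    """Configuration for the synthetic generators.

    Parameters
    ----------
    seed
        Master seed; fans out to per-purpose substreams.
    n_host
        Number of host types.
    component_sizes
        Types per microbiome component (length K).
    n_types
        Types per single lineage (for plain distributions).
    concentration
        Symmetric Dirichlet concentration for simplex draws (> 0); large
        values concentrate near uniform.
    sigma_host, sigma_component
        Log-scale spread of host / per-component fitness effects (>= 0).
    sigma_association
        Log-scale spread of the association factor; 0 => a == 1 everywhere.
    n_sample
        Default multinomial sample size for count draws.
    """

    seed: int
    n_host: int = 2
    component_sizes: tuple = (2,)
    n_types: int = 2
    concentration: float = 1.0
    sigma_host: float = 0.2
    sigma_component: float = 0.2
    sigma_association: float = 0.2
    n_sample: int = 1000

    def __post_init__(self):
        if self.n_host < 1 or self.n_types < 1 or any(s < 1 for s in self.component_sizes):
            raise ValueError("dimensions must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        for s in (self.sigma_host, self.sigma_component, self.sigma_association):
            if s < 0:
                raise ValueError("scales must be >= 0")
        self.component_sizes = tuple(self.component_sizes)

    def rng(self, purpose: str, salt: int = 0) -> np.random.Generator:
        """Fresh generator on the substream reserved for ``purpose``."""
        idx = _PURPOSES.index(purpose)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx, salt))
        return np.random.default_rng(ss)

    @property
    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "bit_generator": "PCG64",
            "n_host": self.n_host,
            "component_sizes": list(self.component_sizes),
            "n_types": self.n_types,
            "concentration": self.concentration,
            "sigma_host": self.sigma_host,
            "sigma_component": self.sigma_component,
            "sigma_association": self.sigma_association,
            "n_sample": self.n_sample,
        }


def _simplex(rng: np.random.Generator, n: int, concentration: float) -> np.ndarray:
    return rng.dirichlet(np.full(n, concentration))


def random_distribution(cfg: GeneratorConfig, salt: int = 0) -> FrequencyDistribution:
    """Random point on the simplex over ``n_types`` lineage types."""
    rng = cfg.rng("distribution", salt)
    labels = tuple(f"s{i}" for i in range(cfg.n_types))
    return FrequencyDistribution(labels, _simplex(rng, cfg.n_types, cfg.concentration))


def _axes(cfg: GeneratorConfig):
    names = ("host",) + tuple(f"M{k}" for k in range(1, len(cfg.component_sizes) + 1))
    labels = (tuple(f"H{i}" for i in range(cfg.n_host)),) + tuple(
        tuple(f"m{k}_{j}" for j in range(size))
        for k, size in enumerate(cfg.component_sizes, start=1)
    )
    return names, labels


def random_joint(cfg: GeneratorConfig, product: bool = False, salt: int = 0) -> JointTable:
    """Random joint table over host x microbiome-component axes.

    With ``product=True`` the table is the outer product of independent
    marginal draws, so it lies exactly on the independence manifold (and the
    T3 term of any subsequent selection step vanishes).
    """
    rng = cfg.rng("joint", salt)
    names, labels = _axes(cfg)
    sizes = (cfg.n_host,) + cfg.component_sizes
    if product:
        margs = [
            FrequencyDistribution(lab, _simplex(rng, n, cfg.concentration))
            for lab, n in zip(labels, sizes)
        ]
        return JointTable.product(margs, axis_names=names)
    flat = _simplex(rng, int(np.prod(sizes)), cfg.concentration)
    return JointTable(names, labels, flat.reshape(sizes))


def random_fitness(cfg: GeneratorConfig, salt: int = 0) -> HolobiontFitness:
    """Log-normal holobiont fitness around 1: strictly positive W_H, W_Mk
    and association factor; ``sigma_association = 0`` gives a == 1."""
    rng = cfg.rng("fitness", salt)
    sizes = (cfg.n_host,) + cfg.component_sizes
    w_host = np.exp(rng.normal(0.0, cfg.sigma_host, size=cfg.n_host))
    w_components = tuple(
        np.exp(rng.normal(0.0, cfg.sigma_component, size=s)) for s in cfg.component_sizes
    )
    if cfg.sigma_association == 0:
        assoc = np.ones(sizes)
    else:
        assoc = np.exp(rng.normal(0.0, cfg.sigma_association, size=sizes))
    return HolobiontFitness(w_host, w_components, assoc)


def sample_counts(q, n: int, seed: int) -> np.ndarray:
    """Multinomial counts of size n from a distribution or joint table.

    Returns an integer array shaped like the input's values; counts sum to n
    and the empirical frequencies converge to q as n grows.
    """
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    rng = np.random.default_rng(seed)
    probs = q.values if hasattr(q, "values") else np.asarray(q, dtype=float)
    flat = rng.multinomial(n, probs.reshape(-1))
    return flat.reshape(probs.shape)


def group_ensemble(
    cfg: GeneratorConfig,
    grid_size: int,
    mode: str = "uniform",
    x1: float = 2.0,
    x2: float = 1.0,
    s: float = 0.5,
    k: float | None = None,
    founder_size: int | None = None,
) -> GroupEnsemble:
    """Ensemble of groups over an interior grid of initial frequencies.

    The grid q = i/(G+1), i = 1..G avoids fixation boundaries, where the
    within-group fold is undefined.  ``mode='uniform'`` gives p_q = 1/G;
    ``mode='binomial'`` weights the grid by binomial founder sampling
    (founder allele frequency 0.5, ``founder_size`` founders, default G),
    renormalized over the interior grid.  ``k`` defaults to
    ``1 + s * max(x1, x2)`` so every group fitness is positive.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    grid = np.arange(1, grid_size + 1) / (grid_size + 1.0)
    labels = tuple(f"q={q:.6g}" for q in grid)
    if mode == "uniform":
        p = FrequencyDistribution.uniform(labels)
    elif mode == "binomial":
        N = founder_size if founder_size is not None else grid_size
        weights = stats.binom.pmf(np.round(grid * N).astype(int), N, 0.5)
        p = FrequencyDistribution(labels, weights / weights.sum())
    else:
        raise ValueError("mode must be 'uniform' or 'binomial'")
    if k is None:
        k = 1.0 + s * max(x1, x2)
    return GroupEnsemble(grid, p, x1, x2, s, k)
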