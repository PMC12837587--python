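"""Labeled probability containers used throughout the package.

Two containers cover every level of the calculus:

* :class:`FrequencyDistribution` — a labeled point on the simplex, the state
  of one population/lineage (allele, genotype or holobiont-class frequencies).
* :class:`JointTable` — a labeled non-negative array over two or more axes
  (host x microbiome component(s), or female x male mating classes) summing
  to one.

Both validate on construction (non-negativity, unit mass within ``ATOL``,
unique labels) and renormalize exactly, so downstream information measures
never see accumulated floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: absolute tolerance accepted on input normalization
ATOL = 1e-9


def _check_labels(labels: Sequence, n: int, what: str) -> tuple:
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError(f"{what}: {len(labels)} labels for {n} entries")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if list(labels).count(l) > 1})
        raise ValueError(f"{what}: duplicate labels {dupes}")
    return labels


@dataclass(frozen=True)
class FrequencyDistribution:
    """A labeled non-negative vector on the probability simplex.

    Parameters
    ----------
    labels
        Unique, hashable type identifiers, one per entry.
    values
        Frequencies; must be >= 0 and sum to 1 within ``1e-9``.  They are
        renormalized exactly after validation.
    """

    labels: tuple
    values: np.ndarray

    def __init__(self, labels: Iterable, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise ValueError("FrequencyDistribution requires a 1-D vector")
        labels = _check_labels(labels, values.size, "FrequencyDistribution")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite frequency")
        if np.any(values < 0):
            bad = labels[int(np.argmin(values))]
            raise ValueError(f"negative frequency for label {bad!r}")
        total = values.sum()
        if abs(total - 1.0) > ATOL:
            raise ValueError(f"frequencies sum to {total!r}, not 1")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values / total)
        self.values.flags.writeable = False

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, label):
        return float(self.values[self.labels.index(label)])

    def same_support(self, other: "FrequencyDistribution", op: str) -> None:
        """Raise if the two distributions are not defined over identical labels."""
        if self.labels != other.labels:
            mism = set(self.labels).symmetric_difference(other.labels)
            if mism:
                raise ValueError(f"{op}: label mismatch, offending labels {sorted(map(str, mism))}")
            raise ValueError(f"{op}: labels in different order: {self.labels} vs {other.labels}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.labels), name="frequency")

    @classmethod
    def from_counts(cls, labels: Iterable, counts) -> "FrequencyDistribution":
        counts = np.asarray(counts, dtype=float)
        if counts.sum() <= 0:
            raise ValueError("counts sum to zero")
        return cls(labels, counts / counts.sum())

    @classmethod
    def uniform(cls, labels: Iterable) -> "FrequencyDistribution":
        labels = tuple(labels)
        return cls(labels, np.full(len(labels), 1.0 / len(labels)))


@dataclass(frozen=True)
class JointTable:
    """Labeled joint frequency array over ``K+1`` axes (host first, then
    microbiome components; or the two sexes for mating tables).

    ``axis_names`` names each axis (e.g. ``("host", "M1")``) and
    ``axis_labels`` holds one label tuple per axis.  Entries are >= 0 and sum
    to 1 within ``1e-9``; K >= 1.
    """

    axis_names: tuple
    axis_labels: tuple
    values: np.ndarray

    def __init__(self, axis_names: Sequence[str], axis_labels: Sequence[Sequence], values) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim < 2:
            raise ValueError("JointTable requires at least two axes")
        axis_names = _check_labels(axis_names, values.ndim, "JointTable axes")
        if len(axis_labels) != values.ndim:
            raise ValueError("one label sequence required per axis")
        axis_labels = tuple(
            _check_labels(lab, values.shape[k], f"JointTable axis {axis_names[k]!r}")
            for k, lab in enumerate(axis_labels)
        )
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite table entry")
        if np.any(values < 0):
            raise ValueError("negative table entry")
        total = values.sum()
        if abs(total - 1.0) > ATOL:
            raise ValueError(f"table entries sum to {total!r}, not 1")
        object.__setattr__(self, "axis_names", axis_names)
        object.__setattr__(self, "axis_labels", axis_labels)
        object.__setattr__(self, "values", values / total)
        self.values.flags.writeable = False

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_components(self) -> int:
        """Number of non-host axes (K)."""
        return self.values.ndim - 1

    def same_support(self, other: "JointTable", op: str) -> None:
        if self.axis_names != other.axis_names or self.axis_labels != other.axis_labels:
            raise ValueError(f"{op}: joint tables are defined over different axes/labels")

    def flatten(self) -> FrequencyDistribution:
        """Flatten to a distribution over joint cells, labels as tuples."""
        cells = [tuple(idx) for idx in np.ndindex(*self.shape)]
        labels = tuple(tuple(self.axis_labels[k][i] for k, i in enumerate(cell)) for cell in cells)
        return FrequencyDistribution(labels, self.values.reshape(-1))

    def marginal(self, axis: int) -> FrequencyDistribution:
        keep = self.values.sum(axis=tuple(a for a in range(self.values.ndim) if a != axis))
        return FrequencyDistribution(self.axis_labels[axis], keep)

    def as_frame(self) -> pd.DataFrame:
        """Long-format view: one row per cell plus a frequency column."""
        rows = []
        for idx in np.ndindex(*self.shape):
            row = {self.axis_names[k]: self.axis_labels[k][i] for k, i in enumerate(idx)}
            row["frequency"] = self.values[idx]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_counts(cls, axis_names, axis_labels, counts) -> "JointTable":
        counts = np.asarray(counts, dtype=float)
        if counts.sum() <= 0:
            raise ValueError("counts sum to zero")
        return cls(axis_names, axis_labels, counts / counts.sum())

    @classmethod
    def uniform(cls, axis_names, axis_labels) -> "JointTable":
        shape = tuple(len(l) for l in axis_labels)
        return cls(axis_names, axis_labels, np.full(shape, 1.0 / int(np.prod(shape))))

    @classmethod
    def product(cls, marginals: Sequence[FrequencyDistribution], axis_names=None) -> "JointTable":
        """Outer product of marginals — a point on the independence manifold."""
        if axis_names is None:
            axis_names = ("host",) + tuple(f"M{k}" for k in range(1, len(marginals)))
        vals = marginals[0].values
        for m in marginals[1:]:
            vals = np.multiply.outer(vals, m.values)
        return cls(axis_names, tuple(m.labels for m in marginals), vals)
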