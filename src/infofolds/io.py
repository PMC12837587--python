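"""Tabular input/output for frequency tables and information reports.

The canonical tabular dialect is TSV (UTF-8, ``#``-prefixed comment lines
ignored); CSV is accepted by extension sniffing.  Two layouts are read:

* ``matrix`` — 2-D table with row labels in the first column and column
  labels in the header (hosts as rows, microbiome configurations as
  columns);
* ``long`` — one row per cell with columns ``host``, ``m1`` ... ``mK`` and a
  final ``count`` or ``freq`` column.

Counts are normalized on load and the raw integer counts retained, so
downstream permutation tests can operate on the original sample.

Reports are written as JSON (schema-versioned, deterministic key order, all
information values in nats) or TSV (one row per component).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import FrequencyDistribution, JointTable
from .holobiont import InfoPartition

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class LoadedTable:
    """A validated joint table plus, when the file held counts, the raw
    integer count array (same shape) and its total."""

    table: JointTable
    counts: np.ndarray | None = None

    @property
    def n(self) -> int | None:
        return None if self.counts is None else int(self.counts.sum())


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _fail(path: Path, message: str) -> ValueError:
    return ValueError(f"{path}: {message}")


def read_table(path, layout: str = "matrix") -> LoadedTable:
    """Read a host x microbiome table from TSV/CSV.

    Values may be frequencies (summing to 1) or counts; counts are detected
    by integer values summing to more than 1 and are normalized with the
    raw array retained.
    """
    path = Path(path)
    if layout not in ("matrix", "long"):
        raise ValueError("layout must be 'matrix' or 'long'")
    try:
        df = pd.read_csv(path, sep=_sep(path), comment="#", index_col=0 if layout == "matrix" else None)
    except pd.errors.ParserError as exc:
        raise _fail(path, f"malformed table: {exc}") from exc
    if layout == "matrix":
        # pandas silently mangles duplicate headers; check the raw header line
        for line in path.read_text().splitlines():
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split(_sep(path))[1:]
                if len(set(header)) != len(header):
                    raise _fail(path, f"duplicate column labels in header {header}")
                break
    if layout == "matrix":
        return _from_matrix(path, df)
    return _from_long(path, df)


def _classify(path: Path, values: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    if not np.all(np.isfinite(values)):
        raise _fail(path, "non-finite entry")
    if np.any(values < 0):
        raise _fail(path, "negative entry")
    total = values.sum()
    if total <= 0:
        raise _fail(path, "table mass is zero")
    is_counts = np.allclose(values, np.round(values)) and total > 1.5
    counts = np.round(values).astype(np.int64) if is_counts else None
    return values / total, counts


def _from_matrix(path: Path, df: pd.DataFrame) -> LoadedTable:
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise _fail(path, "duplicate row or column labels")
    values = df.to_numpy(dtype=float)
    freqs, counts = _classify(path, values)
    table = JointTable(
        ("host", "M1"), (tuple(map(str, df.index)), tuple(map(str, df.columns))), freqs
    )
    return LoadedTable(table, counts)


def _from_long(path: Path, df: pd.DataFrame) -> LoadedTable:
    cols = list(df.columns)
    if "host" not in cols:
        raise _fail(path, "long layout requires a 'host' column")
    value_col = next((c for c in ("count", "freq") if c in cols), None)
    if value_col is None:
        raise _fail(path, "long layout requires a 'count' or 'freq' column")
    axis_cols = ["host"] + [c for c in cols if c not in ("host", value_col)]
    dup = df.duplicated(subset=axis_cols)
    if dup.any():
        raise _fail(path, f"duplicate cell at line {int(dup.idxmax()) + 2}")
    axis_labels = tuple(tuple(map(str, pd.unique(df[c]))) for c in axis_cols)
    shape = tuple(len(l) for l in axis_labels)
    values = np.zeros(shape)
    index = [{lab: i for i, lab in enumerate(labs)} for labs in axis_labels]
    for _, row in df.iterrows():
        idx = tuple(ix[str(row[c])] for c, ix in zip(axis_cols, index))
        values[idx] = float(row[value_col])
    freqs, counts = _classify(path, values)
    table = JointTable(tuple(axis_cols), axis_labels, freqs)
    return LoadedTable(table, counts)


def write_table(table: JointTable | FrequencyDistribution, path) -> None:
    """Write a table (2-D matrix layout) or distribution (two-column TSV)."""
    path = Path(path)
    if isinstance(table, FrequencyDistribution):
        table.as_series().rename_axis("label").to_csv(path, sep=_sep(path))
        return
    if table.values.ndim != 2:
        df = table.as_frame()
    else:
        df = pd.DataFrame(table.values, index=table.axis_labels[0], columns=table.axis_labels[1])
    df.to_csv(path, sep=_sep(path))


def _serializable(result) -> dict:
    if isinstance(result, InfoPartition):
        body = result.as_dict()
    elif hasattr(result, "as_dict"):
        body = result.as_dict()
    elif isinstance(result, dict):
        body = result
    else:
        raise TypeError(f"cannot serialize report of type {type(result).__name__}")
    return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v) for k, v in body.items()}


def write_report(result, path, fmt: str = "json", **metadata) -> None:
    """Serialize a result (InfoPartition or mapping) with metadata.

    JSON reports carry the schema version and the unit of every information
    value (nats, natural log); keys are written in deterministic order.
    """
    path = Path(path)
    body = _serializable(result)
    if fmt == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "log_base": "e",
            "units": "nats",
            **{k: metadata[k] for k in sorted(metadata)},
            "values": body,
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    elif fmt == "tsv":
        lines = ["component\tvalue"]
        lines += [f"{k}\t{v!r}" for k, v in body.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("fmt must be 'json' or 'tsv'")


def read_report(path) -> dict:
    """Round-trip reader for JSON reports; returns the values mapping."""
    doc = json.loads(Path(path).read_text())
    return doc["values"]
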