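"""CSV/JSON readers and writers for work sets and benchmark tables.

Two plain-text interchange formats:

* Work sets: a CSV with columns ``direction`` ∈ {forward, reverse} and
  ``work_kcal_mol``, plus a JSON sidecar (``<name>.json``) recording
  beta, the label and, when applicable, the generating seed.
* Benchmark tables: a per-molecule CSV with ``molecule_id``,
  ``elements`` (or ``smiles``), ``dG_exp``, one or more
  ``dG_calc_<label>`` / ``dG_corr_<label>`` / ``dG_corr_err_<label>``
  columns and optional ``n_rot``.  Unknown columns are preserved.
  Deposited files with different headers are handled through an
  explicit column mapping rather than guessing.

Energies in files are always kcal/mol; temperature-derived quantities
are computed at load time and never stored.  Logging goes to standard
error; results only to files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import ANI2X_ELEMENTS, _element_set
from .units import beta_from_temperature
from .worksets import ValidationError, WorkSet

__all__ = [
    "read_workset_csv",
    "write_workset_csv",
    "read_benchmark_csv",
    "write_benchmark_csv",
    "element_filter",
    "SchemaError",
    "config_hash",
]

logger = logging.getLogger("neqfe")

_FLOAT_FMT = "%.10g"  # 10 significant digits, diff-stable


class SchemaError(ValidationError):
    """Raised when a file is missing a mandatory column."""


def write_workset_csv(works: WorkSet, path: str | Path,
                      seed: int | None = None) -> None:
    path = Path(path)
    rows = [("forward", w) for w in works.forward] + \
           [("reverse", w) for w in works.reverse]
    df = pd.DataFrame(rows, columns=["direction", "work_kcal_mol"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {"beta": works.beta, "label": works.label}
    if seed is not None:
        sidecar["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")


def read_workset_csv(path: str | Path, beta: float | None = None) -> WorkSet:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("direction", "work_kcal_mol"):
        if col not in df.columns:
            raise SchemaError(f"work-set file {path} is missing column {col!r}")
    label = ""
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        beta = beta if beta is not None else meta.get("beta")
        label = meta.get("label", "")
    if beta is None:
        beta = beta_from_temperature()
    fwd = df.loc[df["direction"] == "forward", "work_kcal_mol"].to_numpy(float)
    rev = df.loc[df["direction"] == "reverse", "work_kcal_mol"].to_numpy(float)
    return WorkSet(fwd, rev, beta, label=label)


_MANDATORY = ("molecule_id", "dG_exp")


def read_benchmark_csv(path: str | Path,
                       column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-molecule benchmark CSV.

    ``column_map`` renames file headers to the canonical schema (e.g.
    ``{"expt": "dG_exp"}``) before validation.  Rows whose ``dG_exp``
    is missing or unparseable are excluded with a logged count; a
    malformed numeric entry elsewhere becomes NaN with a logged row
    number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if column_map:
        df = df.rename(columns=column_map)
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"benchmark file {path} is missing column {col!r}")
    has_calc = any(c.startswith("dG_calc_") for c in df.columns)
    if not has_calc:
        raise SchemaError(f"benchmark file {path} has no dG_calc_<label> column")
    numeric_cols = [c for c in df.columns
                    if c.startswith(("dG_", "n_rot")) or c == "n_rot"]
    for col in numeric_cols:
        raw = df[col]
        df[col] = pd.to_numeric(raw, errors="coerce")
        bad = df[col].isna() & raw.notna() & (raw.str.strip() != "")
        for i in df.index[bad]:
            logger.warning("%s: unparseable value %r in column %s at line %d",
                           path.name, raw[i], col, i + 2)
    n_before = len(df)
    df = df.dropna(subset=["dG_exp"]).reset_index(drop=True)
    dropped = n_before - len(df)
    if dropped:
        logger.warning("%s: excluded %d row(s) without a valid dG_exp",
                       path.name, dropped)
    return df


def write_benchmark_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a benchmark table with deterministic column order and floats."""
    lead = [c for c in ("molecule_id", "elements", "smiles", "dG_exp", "n_rot")
            if c in table.columns]
    rest = sorted(c for c in table.columns if c not in lead)
    table[lead + rest].to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def element_filter(table: pd.DataFrame,
                   allowed: frozenset[str] = ANI2X_ELEMENTS
                   ) -> tuple[pd.DataFrame, int]:
    """Keep rows whose element set is covered by ``allowed``.

    Elements come from an ``elements`` column (symbols separated by
    spaces or commas) or, failing that, a naive symbol scan of a
    ``formula`` column.  Rows whose elements cannot be derived are
    excluded from both the kept set and the removed count, with a log
    message.
    """
    if "elements" in table.columns:
        source = table["elements"]
    elif "formula" in table.columns:
        import re
        source = table["formula"].map(
            lambda f: " ".join(re.findall(r"[A-Z][a-z]?", str(f))))
    else:
        raise SchemaError("no elements or formula column to filter on")
    derivable = source.notna() & (source.astype(str).str.strip() != "")
    n_underivable = int((~derivable).sum())
    if n_underivable:
        logger.warning("element filter: %d row(s) with underivable elements "
                       "excluded from both sets", n_underivable)
    usable = table[derivable]
    keep_mask = usable["elements" if "elements" in table.columns else "formula"] \
        .index.map(lambda i: _element_set(source[i]) <= set(allowed))
    kept = usable[np.asarray(keep_mask, dtype=bool)]
    removed = len(usable) - len(kept)
    return kept.reset_index(drop=True), removed


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
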