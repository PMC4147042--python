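"""On-disk formats: datasets, ΔOFV pools, power surfaces, fit summaries.

All CSV artifacts carry a first-line format tag (``# mixpower/<kind> v1``)
so stale or foreign files are rejected early.  Datasets follow the
NONMEM rectangular convention: one row per event, ``EVID`` 1 for dose
rows (``DV`` empty) and 0 for observations, ``OCC`` 1-based,
concentrations on the natural scale (any log transform for the
additive-on-log residual model happens inside the estimator, keyed by
the model's residual flag).
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import yaml

from .mcmp import DeltaOFVPool, LRTSettings, PowerSurface
from .popsim import PKDataset

__all__ = [
    "read_dataset", "write_dataset",
    "read_pool", "write_pool",
    "read_surface", "write_surface",
    "read_config",
]

_TAGS = {"dataset": "# mixpower/dataset v1",
         "pool": "# mixpower/pool v1",
         "surface": "# mixpower/surface v1"}


class SchemaError(ValueError):
    """A file violates the expected schema; message names the problem."""


def _check_tag(path, kind: str) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first != _TAGS[kind]:
        raise SchemaError(f"{path}: line 1: expected format tag {_TAGS[kind]!r}, found {first!r}")


def _write_tagged(df: pd.DataFrame, path, kind: str) -> None:
    with open(path, "w") as fh:
        fh.write(_TAGS[kind] + "\n")
        df.to_csv(fh, index=False)


def write_dataset(ds: PKDataset, path) -> None:
    df = ds.df.copy()
    df.insert(len(df.columns), "DESIGN", ds.design)
    _write_tagged(df, path, "dataset")


def read_dataset(path) -> PKDataset:
    _check_tag(path, "dataset")
    df = pd.read_csv(path, skiprows=1)
    required = ["ID", "OCC", "TIME", "EVID", "AMT", "DV", "ARM"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    bad = df[(df.EVID == 0) & df.DV.isna()]
    if len(bad):
        raise SchemaError(
            f"{path}: line {bad.index[0] + 3}: observation row (EVID=0) with missing DV"
        )
    neg = df[df.TIME < 0]
    if len(neg):
        raise SchemaError(f"{path}: line {neg.index[0] + 3}: negative TIME")
    design = df.DESIGN.iloc[0] if "DESIGN" in df.columns else "parallel"
    covs = [c for c in df.columns if c not in required + ["DESIGN"]]
    return PKDataset(df.drop(columns=["DESIGN"], errors="ignore"), covs, design)


def write_pool(pool: DeltaOFVPool, path) -> None:
    df = pool.entries.copy()
    df.insert(0, "POOL", pool.arm)
    _write_tagged(df, path, "pool")


def read_pool(path) -> DeltaOFVPool:
    _check_tag(path, "pool")
    df = pd.read_csv(path, skiprows=1)
    for col in ("POOL", "ID", "ARM", "COV", "DOFV"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return DeltaOFVPool(df.drop(columns=["POOL"]), df.POOL.iloc[0])


def write_surface(surface: PowerSurface, path) -> None:
    df = surface.table.copy()
    df["threshold"] = surface.settings.threshold
    df["n_draws"] = surface.settings.n_draws
    df["seed"] = surface.seed
    df["balance"] = surface.balance
    _write_tagged(df, path, "surface")


def read_surface(path) -> PowerSurface:
    _check_tag(path, "surface")
    df = pd.read_csv(path, skiprows=1)
    for col in ("n_dense", "n_sparse", "power", "threshold", "n_draws", "seed"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    settings = LRTSettings(threshold=float(df.threshold.iloc[0]),
                           n_draws=int(df.n_draws.iloc[0]))
    balance = bool(df.balance.iloc[0]) if "balance" in df.columns else True
    return PowerSurface(df[["n_dense", "n_sparse", "power"]].copy(), settings,
                        int(df.seed.iloc[0]), balance)


def read_config(path) -> dict:
    """Load a structured workflow configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
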