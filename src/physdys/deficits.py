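"""Deficits index (frailty index) construction.

The deficits index (DI) of a subject is the sum of their deficit scores
divided by the number of deficit items actually measured in that subject:
dichotomous items are coded 1 (deficit present) / 0 (absent), and ordinal
items are mapped to fractional scores in [0, 1] via user-supplied recoding
tables. The DI therefore always lies in [0, 1] and tolerates item-level
missingness by construction.

A sensitivity rule optionally declares the DI missing for subjects in whom
20% or more of the items are unmeasured (subjects with strictly less than
20% missing keep their DI).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["compute_di", "recode_items", "deficit_columns"]


def deficit_columns(table: pd.DataFrame, prefix: str = "deficit_") -> list[str]:
    """Columns holding deficit items, by naming convention."""
    return [c for c in table.columns if c.startswith(prefix)]


def recode_items(
    table: pd.DataFrame,
    recode_maps: Mapping[str, Mapping[object, float]],
) -> pd.DataFrame:
    """Map raw ordinal/categorical item values to deficit scores in [0, 1].

    ``recode_maps`` is per-item ``{raw value: score}``; values absent from
    the map (and NaN) become missing. Items without a map pass through.
    """
    out = table.copy()
    for item, mapping in recode_maps.items():
        if item not in out.columns:
            raise KeyError(f"unknown deficit item {item!r}")
        out[item] = out[item].map(mapping).astype(float)
    return out


def compute_di(
    panel: pd.DataFrame,
    items: Sequence[str] | None = None,
    max_missing_frac: float = 1.0,
) -> pd.Series:
    """Per-subject deficits index.

    DI = (sum of non-missing item scores) / (number of items measured).
    The DI is missing when no item is measured or when the fraction of
    missing items reaches ``max_missing_frac`` (strict rule: a subject is
    retained only if their missing fraction is < ``max_missing_frac``).
    The main analysis uses ``max_missing_frac=1.0`` (no cap); the
    sensitivity variant uses 0.2.
    """
    items = list(items) if items is not None else deficit_columns(panel)
    if not items:
        raise ValueError("no deficit items")
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    x = panel[items].to_numpy(dtype=float)
    measured = np.isfinite(x)
    if measured.any():
        vals = x[measured]
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("deficit item values must lie in [0, 1]")
    n_meas = measured.sum(axis=1)
    total = np.nansum(np.where(measured, x, 0.0), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        di = np.where(n_meas > 0, total / np.maximum(n_meas, 1), np.nan)
    frac_missing = 1.0 - n_meas / len(items)
    if max_missing_frac < 1.0:
        di = np.where(frac_missing < max_missing_frac, di, np.nan)
    else:
        di = np.where(n_meas > 0, di, np.nan)
    return pd.Series(di, index=panel.index, name="di")
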