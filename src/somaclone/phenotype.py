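"""Reproductive-performance indices from per-inflorescence counts.

Inflorescences are tagged before flowering; flowers are counted from the
fallen calyptras and the ripe cluster is scored into seeded berries,
seedless berries and live green ovaries (LGOs). From these counts:

* fruitset rate — the proportion of flowers that develop into berries
  (seeded or seedless);
* coulure index (0-10) — excess flower drop/desiccation; the default form
  is 10 x (1 - (seeded + seedless) / flowers), the complement of fruitset
  on a 0-10 scale;
* millerandage index (0-10) — excess conversion of post-flowering organs
  into seedless berries or LGOs; default
  10 x (seedless + LGOs) / (seeded + seedless + LGOs).

The published index formulas live in viticulture references rather than in
a single canonical form, so both index functions accept an injectable
replacement formula. Indices are computed per inflorescence and then
averaged per clone (mean of ratios, not ratio of means).
"""

from __future__ import annotations

import math
from collections.abc import Callable

import pandas as pd

__all__ = [
    "fruitset_rate",
    "coulure_index",
    "millerandage_index",
    "compute_indices",
    "summarize_clone",
]


def fruitset_rate(flowers: float, seeded: float, seedless: float) -> float:
    """Proportion of flowers that develop into berries (seeded or seedless)."""
    _check_counts(flowers=flowers, seeded=seeded, seedless=seedless)
    if flowers == 0:
        raise ValueError("fruitset rate is undefined for zero flowers")
    return (seeded + seedless) / flowers


def coulure_index(
    flowers: float,
    seeded: float,
    seedless: float,
    formula: Callable[[float, float, float], float] | None = None,
) -> float:
    """Flower-drop (coulure) index on a 0-10 scale."""
    _check_counts(flowers=flowers, seeded=seeded, seedless=seedless)
    if flowers == 0:
        raise ValueError("coulure index is undefined for zero flowers")
    if formula is not None:
        return formula(flowers, seeded, seedless)
    return 10.0 * (1.0 - (seeded + seedless) / flowers)


def millerandage_index(
    seeded: float,
    seedless: float,
    lgos: float,
    formula: Callable[[float, float, float], float] | None = None,
) -> float:
    """Millerandage index on a 0-10 scale.

    With zero post-flowering organs the index is undefined and returned as
    NaN (flagged missing, never silently zero).
    """
    _check_counts(seeded=seeded, seedless=seedless, lgos=lgos)
    organs = seeded + seedless + lgos
    if organs == 0:
        return math.nan
    if formula is not None:
        return formula(seeded, seedless, lgos)
    return 10.0 * (seedless + lgos) / organs


def _check_counts(**counts: float) -> None:
    for name, value in counts.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative")


def compute_indices(
    records: pd.DataFrame,
    coulure_formula: Callable | None = None,
    millerandage_formula: Callable | None = None,
) -> pd.DataFrame:
    """Add fruitset_rate, coulure_index and millerandage_index columns.

    ``records`` needs columns clone, flowers, seeded, seedless, lgos and
    must satisfy seeded + seedless + lgos <= flowers per row.
    """
    required = {"clone", "flowers", "seeded", "seedless", "lgos"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    organs = records["seeded"] + records["seedless"] + records["lgos"]
    if (organs > records["flowers"]).any():
        bad = records.index[organs > records["flowers"]].tolist()
        raise ValueError(f"outcome counts exceed flowers in rows {bad[:5]}")
    out = records.copy()
    out["fruitset_rate"] = [
        fruitset_rate(r.flowers, r.seeded, r.seedless) for r in records.itertuples()
    ]
    out["coulure_index"] = [
        coulure_index(r.flowers, r.seeded, r.seedless, coulure_formula)
        for r in records.itertuples()
    ]
    out["millerandage_index"] = [
        millerandage_index(r.seeded, r.seedless, r.lgos, millerandage_formula)
        for r in records.itertuples()
    ]
    return out


def summarize_clone(records: pd.DataFrame, **formula_kwargs) -> pd.DataFrame:
    """Per-clone mean, standard deviation and n of each index.

    Indices are computed per inflorescence first, then averaged; rows with
    an undefined millerandage index are excluded from that variable's mean
    and its ``n``.
    """
    indexed = compute_indices(records, **formula_kwargs)
    rows = []
    for clone, grp in indexed.groupby("clone", sort=True):
        row = {"clone": clone, "n_inflorescences": len(grp)}
        for var in ("flowers", "seeded", "seedless", "lgos",
                    "fruitset_rate", "coulure_index", "millerandage_index"):
            vals = grp[var].dropna()
            row[f"{var}_mean"] = float(vals.mean()) if len(vals) else math.nan
            row[f"{var}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{var}_n"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)
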