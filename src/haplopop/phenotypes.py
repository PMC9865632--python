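"""Trait-table summaries: per-condition coefficient of variation and the
lipid-content unit convention (1% of dry cell weight = 10 mg fatty acids
per g of dry cells)."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def trait_cv(values) -> float:
    """Coefficient of variation over non-missing values.

    Sample standard deviation (n - 1 denominator) divided by the mean;
    NaN (flagged undefined) when the mean is zero.
    """
    x = pd.Series(values, dtype=float).dropna().to_numpy()
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(x.std(ddof=1) / mean)


def lipid_content_dcw(fatty_acid_mass_mg: float, dry_cell_mass_g: float) -> float:
    """Lipid content as percent of dry cell weight.

    10 mg fatty acids per g of dry cells corresponds to 1% DCW.
    """
    if fatty_acid_mass_mg <= 0 or dry_cell_mass_g <= 0:
        raise ValueError("masses must be positive")
    return 100.0 * fatty_acid_mass_mg / (dry_cell_mass_g * 1000.0)


def dcw_to_fatty_acid_mg(content_pct: float, dry_cell_mass_g: float = 1.0) -> float:
    """Inverse of :func:`lipid_content_dcw` (mg fatty acids for a given %DCW)."""
    if content_pct <= 0 or dry_cell_mass_g <= 0:
        raise ValueError("inputs must be positive")
    return content_pct * 10.0 * dry_cell_mass_g


def condition_screen(table: pd.DataFrame, exclusion_list=()) -> pd.DataFrame:
    """Drop excluded conditions and rank the rest by CV, descending.

    ``table`` is strains x conditions; returns a DataFrame indexed by
    condition with columns ``cv`` and ``rank``.
    """
    unknown = set(exclusion_list) - set(table.columns)
    if unknown:
        raise KeyError(f"unknown conditions in exclusion list: {sorted(unknown)}")
    kept = table.drop(columns=list(exclusion_list))
    cvs = {c: trait_cv(kept[c]) for c in kept.columns}
    out = pd.DataFrame({"cv": pd.Series(cvs)}).sort_values("cv", ascending=False)
    finite = out["cv"].notna()
    out["rank"] = np.nan
    out.loc[finite, "rank"] = range(1, int(finite.sum()) + 1)
    return out
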