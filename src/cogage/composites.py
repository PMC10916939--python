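"""Episodic-memory (EM) and non-memory (NM) cognition composites.

Equally weighted z-score composites stand in for factor-analytic composites:
each constituent test is z-scored against the pool used for classification
cutoffs, timed measures are sign-flipped so higher = better, and the mean is
re-standardized to unit variance in that pool.  An optional external weight
vector can emulate factor loadings when available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EM_TESTS",
    "NM_TESTS",
    "compute_em_composite",
    "compute_nm_composite",
    "age_adjust",
]

#: verbal_paired_associates is optional — used when the table provides it.
EM_TESTS = [
    "cvlt_sdfr",
    "cvlt_ldfr",
    "visual_reproduction_i",
    "visual_reproduction_ii",
    "logical_memory_total",
    "verbal_paired_associates",
]

#: trails_b_minus_a is derived internally from tmt_b - tmt_a.
#: Timed constituents (tmt_a, trails_b_minus_a) are flipped before averaging.
NM_TESTS = [
    "stroop_60s",
    "digit_symbol",
    "tmt_a",
    "trails_b_minus_a",
    "digit_span_backward",
    "animal_naming",
    "vegetable_naming",
]

_NM_FLIPPED = {"tmt_a", "trails_b_minus_a"}


def _z_composite(
    pool: pd.DataFrame,
    constituents: list[str],
    flipped: set[str],
    weights: dict[str, float] | None,
    standardize: bool,
) -> np.ndarray:
    cols = [c for c in constituents if c in pool.columns]
    if not cols:
        raise ValueError(f"none of the constituent tests present: {constituents}")
    parts = []
    wts = []
    for c in cols:
        x = pool[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"constituent {c!r} has zero variance in the pool")
        z = (x - x.mean()) / sd
        if c in flipped:
            z = -z
        parts.append(z)
        wts.append(1.0 if weights is None else float(weights.get(c, 0.0)))
    wts = np.asarray(wts)
    comp = np.average(np.column_stack(parts), axis=1, weights=wts)
    if standardize:
        comp = (comp - comp.mean()) / comp.std(ddof=1)
    return comp


def compute_em_composite(
    pool: pd.DataFrame,
    weights: dict[str, float] | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """EM composite over the classification pool (higher = better memory)."""
    return _z_composite(pool, EM_TESTS, set(), weights, standardize)


def compute_nm_composite(
    pool: pd.DataFrame,
    weights: dict[str, float] | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """NM composite; timed constituents sign-flipped so higher = better."""
    pool = pool.copy()
    if "trails_b_minus_a" not in pool.columns:
        if "tmt_b" not in pool.columns or "tmt_a" not in pool.columns:
            raise ValueError("need tmt_a and tmt_b to derive trails_b_minus_a")
        if pool["tmt_b"].isna().any() or (pool["tmt_b"] < 0).any():
            raise ValueError("tmt_b missing or negative: timed scores inconsistent")
        pool["trails_b_minus_a"] = pool["tmt_b"] - pool["tmt_a"]
    return _z_composite(pool, NM_TESTS, _NM_FLIPPED, weights, standardize)


def age_adjust(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """OLS residuals of values on age (the 'age-regressed residuals')."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 points to age-adjust")
    if np.ptp(ages) == 0:
        raise ValueError("constant age: residualization undefined")
    slope, intercept = np.polyfit(ages, values, 1)
    return values - (slope * ages + intercept)
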