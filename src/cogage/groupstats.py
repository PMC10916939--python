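"""Group-comparison statistics for SA vs TA contrasts.

Welch two-sample t with Cohen's d for continuous demographics, chi-square with
Cramér's V for categorical ones, ANCOVA (OLS with covariates, Type-II sums of
squares for the group term) with partial η² for imaging outcomes, plus the
small imaging utilities: TIV adjustment of hippocampal volume by
residualization, the DVR→Centiloid conversion, the amyloid-positivity
threshold, and Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "welch_t_cohens_d",
    "chisq_cramers_v",
    "ancova_eta2",
    "adjust_tiv",
    "convert_dvr_to_centiloid",
    "centiloid_int",
    "abeta_positive",
    "bh_fdr",
]

# DVR -> Centiloid conversion coefficients of the amyloid-PET pipeline
CL_SLOPE = 142.73
CL_INTERCEPT = -141.99

ABETA_DVR_THRESHOLD = 1.065


@dataclass
class GroupComparisonResult:
    outcome: str
    statistic: float          # t or chi2 or F
    df: float | tuple
    p: float
    effect_size: float        # Cohen's d, Cramér's V, or partial eta^2
    effect_name: str
    n: int
    covariates: list[str] = field(default_factory=list)
    undefined: bool = False

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if isinstance(d["df"], tuple):
            d["df"] = list(d["df"])
        return d


def welch_t_cohens_d(x: np.ndarray, y: np.ndarray, outcome: str = "") -> GroupComparisonResult:
    """Welch t-test (Satterthwaite df) with pooled-SD Cohen's d.

    d uses the pooled SD with (n1−1, n2−1) weighting and no small-sample
    correction.  Two zero-variance identical samples are flagged undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return GroupComparisonResult(outcome, np.nan, np.nan, np.nan, np.nan,
                                     "cohens_d", len(x) + len(y), undefined=True)
    res = stats.ttest_ind(x, y, equal_var=False)
    pooled = np.sqrt(((len(x) - 1) * vx + (len(y) - 1) * vy) / (len(x) + len(y) - 2))
    d = (x.mean() - y.mean()) / pooled
    return GroupComparisonResult(
        outcome=outcome,
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        effect_size=float(d),
        effect_name="cohens_d",
        n=len(x) + len(y),
    )


def chisq_cramers_v(
    table: np.ndarray, outcome: str = "", correction: bool = True
) -> GroupComparisonResult:
    """Pearson chi-square with Cramér's V.

    ``correction=True`` applies the Yates continuity correction on 2×2 tables
    (the convention behind the reported demographic chi-squares); larger
    tables are never corrected.  V is computed from the same statistic.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2-D contingency table with >= 2 rows and columns")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    n = table.sum()
    v = np.sqrt(chi2 / (n * min(table.shape[0] - 1, table.shape[1] - 1)))
    return GroupComparisonResult(
        outcome=outcome,
        statistic=float(chi2),
        df=float(dof),
        p=float(p),
        effect_size=float(v),
        effect_name="cramers_v",
        n=int(n),
    )


def _check_collinear(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify a column whose removal does not reduce the rank
        for j, name in enumerate(X.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear design: column {name!r} is redundant")
        raise ValueError("collinear design")


def ancova_eta2(
    outcome: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "",
) -> GroupComparisonResult:
    """ANCOVA for a binary group effect adjusting for covariates.

    OLS of outcome on group + covariates; the group F uses Type-II sums of
    squares (full vs group-dropped model), which for a single binary factor
    with continuous covariates coincides with Type III.  Partial η² =
    SS_group / (SS_group + SS_residual).  With no covariates this reduces
    exactly to the one-way ANOVA (F = pooled t²).
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("group must be binary (0/1)")
    parts = {"group": g}
    if covariates is not None and covariates.shape[1] > 0:
        for c in covariates.columns:
            parts[str(c)] = covariates[c].to_numpy(dtype=float)
    X = pd.DataFrame(parts)
    mask = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[mask], X.loc[mask].reset_index(drop=True)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few complete observations for the ANCOVA")
    design = sm.add_constant(X, has_constant="add")
    _check_collinear(design)

    full = sm.OLS(y, design).fit()
    reduced = sm.OLS(y, design.drop(columns="group")).fit()
    # Type-II SS is non-negative by construction; guard float cancellation
    ss_group = max(float(reduced.ssr - full.ssr), 0.0)
    ss_resid = float(full.ssr)
    df_resid = int(full.df_resid)
    F = (ss_group / 1.0) / (ss_resid / df_resid)
    p = float(stats.f.sf(F, 1, df_resid))
    eta2 = ss_group / (ss_group + ss_resid)
    return GroupComparisonResult(
        outcome=outcome_name,
        statistic=float(F),
        df=(1, df_resid),
        p=p,
        effect_size=float(eta2),
        effect_name="partial_eta2",
        n=len(y),
        covariates=[c for c in X.columns if c != "group"],
    )


def adjust_tiv(hippocampal_volume: np.ndarray, tiv: np.ndarray) -> np.ndarray:
    """TIV-adjusted volume: OLS residual of volume on TIV, re-centered at the
    pool mean volume (residual method, not a ratio)."""
    v = np.asarray(hippocampal_volume, dtype=float)
    t = np.asarray(tiv, dtype=float)
    if (v <= 0).any() or (t <= 0).any():
        raise ValueError("volumes must be positive")
    if np.ptp(t) == 0:
        raise ValueError("constant TIV: adjustment undefined")
    slope, intercept = np.polyfit(t, v, 1)
    return v - (slope * t + intercept) + v.mean()


def convert_dvr_to_centiloid(dvr: float | np.ndarray) -> float | np.ndarray:
    """Centiloid value from global PiB DVR: CL = DVR·142.73 − 141.99."""
    dvr = np.asarray(dvr, dtype=float)
    if (dvr <= 0).any():
        raise ValueError("DVR must be positive")
    cl = dvr * CL_SLOPE + CL_INTERCEPT
    return float(cl) if cl.ndim == 0 else cl


def centiloid_int(dvr: float) -> int:
    """Reporting convention: Centiloid rounded to the nearest integer."""
    return int(np.rint(convert_dvr_to_centiloid(dvr)))


def abeta_positive(dvr: float | np.ndarray) -> bool | np.ndarray:
    """Amyloid positivity: global PiB DVR strictly above 1.065."""
    dvr = np.asarray(dvr, dtype=float)
    if (dvr <= 0).any():
        raise ValueError("DVR must be positive")
    pos = dvr > ABETA_DVR_THRESHOLD
    return bool(pos) if pos.ndim == 0 else pos


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
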