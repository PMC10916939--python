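"""Cognitive age model: PLS regression of chronological age on test scores.

The model regresses chronological age at each visit (the response) on the
19-test neuropsychological battery plus session number (20 predictors), using
partial least squares with a univariate response (PLS1).  Predictors are
variance-normalized with the training-cohort mean and SD, frozen at fit time
and reused verbatim for test-cohort prediction; the response is left on its
natural scale (years).

PLS1 is implemented with the NIPALS recursion, for which NIPALS and SIMPLS
coincide in prediction, so any conforming cross-decomposition implementation
produces the same predicted ages.

The raw cognitive age gap (CAG = predicted age − chronological age) carries the
usual regression-to-the-mean bias (young overestimated, old underestimated).
The correction fits Offset = α·age + β by OLS of raw CAG on age over the
training predictions and subtracts the offset from each predicted age; on its
own fitting set the corrected CAG is exactly orthogonal to age.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TEST_NAMES

__all__ = [
    "PLSModel",
    "BiasCorrection",
    "CAGResult",
    "AccuracyMetrics",
    "StabilityResult",
    "DEFAULT_PREDICTORS",
    "fit_age_model",
    "predict_age",
    "fit_bias_correction",
    "apply_bias_correction",
    "accuracy",
    "bootstrap_stability",
    "save_model",
    "load_model",
]

DEFAULT_PREDICTORS: list[str] = TEST_NAMES + ["session_number"]

AGE_COLUMN = "age_at_session"


class FittingError(ValueError):
    """Raised when the design cannot support the requested fit."""


@dataclass
class PLSModel:
    """Fitted PLS1 age model with frozen training normalization."""

    predictors: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray       # W, predictors x components
    x_loadings: np.ndarray    # P, predictors x components
    y_loadings: np.ndarray    # q, components
    coef: np.ndarray          # regression vector in normalized-predictor space
    n_components: int
    x_variance_explained: np.ndarray  # fraction of X variance per component
    y_variance_explained: np.ndarray  # fraction of y variance per component
    n_rows: int = 0

    def predict(self, sessions: pd.DataFrame) -> np.ndarray:
        return predict_age(self, sessions)


@dataclass
class BiasCorrection:
    """Offset = alpha * age + beta, fitted on raw CAG vs chronological age."""

    alpha: float
    beta: float
    fit_cohort: str = "train"


@dataclass
class CAGResult:
    predicted_age_raw: np.ndarray
    predicted_age_corrected: np.ndarray
    cag_raw: np.ndarray
    cag_corrected: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predicted_age_raw": self.predicted_age_raw,
                "predicted_age_corrected": self.predicted_age_corrected,
                "cag_raw": self.cag_raw,
                "cag_corrected": self.cag_corrected,
            }
        )


@dataclass
class AccuracyMetrics:
    r: float
    r2: float
    mae: float


@dataclass
class StabilityResult:
    """Bootstrap weight stability: z = mean(weight) / SD(weight) per entry."""

    predictors: list[str]
    mean: np.ndarray        # predictors x components
    sd: np.ndarray
    z: np.ndarray           # NaN where SD == 0 (flagged via `undefined`)
    undefined: np.ndarray   # boolean mask, True where z is undefined
    n_samples: int          # resamples actually used
    n_skipped: int          # degenerate resamples (zero-variance predictor)


def _design(sessions: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    missing = [p for p in predictors if p not in sessions.columns]
    if missing:
        raise FittingError(f"missing predictor column(s): {missing}")
    return sessions[predictors].to_numpy(dtype=float)


def _nipals_pls1(Xz: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS recursion for a single response on pre-normalized data.

    Returns (W, P, q, coef) with coef = W (PᵀW)⁻¹ q, the regression vector such
    that ŷc = Xz · coef.
    """
    n, p = Xz.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    X = Xz.copy()
    y = yc.copy()
    for k in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise FittingError(
                f"response deflated to zero covariance at component {k + 1}"
            )
        w /= norm
        t = X @ w
        tt = float(t @ t)
        P[:, k] = X.T @ t / tt
        q[k] = float(y @ t) / tt
        W[:, k] = w
        X = X - np.outer(t, P[:, k])
        y = y - q[k] * t
    coef = W @ np.linalg.solve(P.T @ W, q)
    return W, P, q, coef


def fit_age_model(
    sessions: pd.DataFrame,
    n_components: int = 5,
    predictors: list[str] | None = None,
) -> PLSModel:
    """Fit the PLS1 age model on all sessions (each visit is one row).

    Chronological age at the visit is the response; the default predictor set
    is the 19 battery tests plus session number.  Raises :class:`FittingError`
    for too few rows or a zero-variance predictor (named).
    """
    predictors = list(predictors) if predictors is not None else list(DEFAULT_PREDICTORS)
    X = _design(sessions, predictors)
    y = sessions[AGE_COLUMN].to_numpy(dtype=float)
    n = len(y)
    if n < n_components + 1:
        raise FittingError(f"need at least {n_components + 1} sessions, got {n}")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(x_sd == 0)
    if dead.size:
        raise FittingError(f"zero-variance predictor: {predictors[dead[0]]!r}")
    Xz = (X - x_mean) / x_sd
    y_mean = float(y.mean())
    yc = y - y_mean

    W, P, q, coef = _nipals_pls1(Xz, yc, n_components)

    # per-component variance explained (both conventions emitted)
    T = np.zeros((n, n_components))
    Xd = Xz.copy()
    for k in range(n_components):
        t = Xd @ W[:, k]
        T[:, k] = t
        Xd = Xd - np.outer(t, P[:, k])
    ssx = float((Xz**2).sum())
    ssy = float((yc**2).sum())
    xve = np.array([(T[:, k] ** 2).sum() * (P[:, k] ** 2).sum() / ssx
                    for k in range(n_components)])
    yve = np.array([(q[k] ** 2) * (T[:, k] ** 2).sum() / ssy for k in range(n_components)])

    return PLSModel(
        predictors=predictors,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        n_components=n_components,
        x_variance_explained=xve,
        y_variance_explained=yve,
        n_rows=n,
    )


def predict_age(model: PLSModel, sessions: pd.DataFrame) -> np.ndarray:
    """Predict age for new sessions using the frozen training normalization.

    Column alignment is by name, so predictor column order is irrelevant.
    """
    X = _design(sessions, model.predictors)
    Xz = (X - model.x_mean) / model.x_sd
    return model.y_mean + Xz @ model.coef


def fit_bias_correction(cag_raw: np.ndarray, age: np.ndarray,
                        fit_cohort: str = "train") -> BiasCorrection:
    """OLS of raw CAG on chronological age: Offset = alpha * age + beta."""
    age = np.asarray(age, dtype=float)
    cag_raw = np.asarray(cag_raw, dtype=float)
    if len(age) < 3:
        raise FittingError("need at least 3 points to fit the bias correction")
    if np.ptp(age) == 0:
        raise FittingError("degenerate age variance: cannot fit bias correction")
    alpha, beta = np.polyfit(age, cag_raw, 1)
    return BiasCorrection(alpha=float(alpha), beta=float(beta), fit_cohort=fit_cohort)


def apply_bias_correction(
    correction: BiasCorrection, predicted_age_raw: np.ndarray, age: np.ndarray
) -> CAGResult:
    """Subtract the age-dependent offset from each raw predicted age."""
    predicted_age_raw = np.asarray(predicted_age_raw, dtype=float)
    age = np.asarray(age, dtype=float)
    offset = correction.alpha * age + correction.beta
    corrected = predicted_age_raw - offset
    return CAGResult(
        predicted_age_raw=predicted_age_raw,
        predicted_age_corrected=corrected,
        cag_raw=predicted_age_raw - age,
        cag_corrected=corrected - age,
    )


def accuracy(predicted_age_raw: np.ndarray, age: np.ndarray) -> AccuracyMetrics:
    """Pearson r, total variance explained R², and MAE of raw predictions.

    Reported pre-correction: the bias correction by construction cannot change
    MAE-style accuracy honestly, so performance is quoted on raw predictions.
    """
    pred = np.asarray(predicted_age_raw, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(age) < 2:
        raise FittingError("need at least 2 sessions for accuracy metrics")
    ss_tot = float(((age - age.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FittingError("zero variance in age: correlation undefined")
    r = float(np.corrcoef(pred, age)[0, 1]) if np.ptp(pred) > 0 else float("nan")
    r2 = 1.0 - float(((age - pred) ** 2).sum()) / ss_tot
    mae = float(np.abs(age - pred).mean())
    return AccuracyMetrics(r=r, r2=r2, mae=mae)


def bootstrap_stability(
    sessions: pd.DataFrame,
    n_components: int = 5,
    B: int = 1000,
    seed: int = 0,
    unit: str = "session",
    predictors: list[str] | None = None,
) -> StabilityResult:
    """Bootstrap the PLS weights B times and form z = mean / SD per weight.

    Resampling is by session row (default) or by participant (``unit``).  Each
    resampled model's components are sign-aligned to the reference model by the
    dot product of the weight vectors before averaging, since PLS components
    carry a sign indeterminacy.  Resamples in which a predictor loses all
    variance are skipped and counted.
    """
    if B < 2:
        raise FittingError("B must be >= 2 (SD undefined otherwise)")
    if unit not in {"session", "participant"}:
        raise ValueError("unit must be 'session' or 'participant'")
    predictors = list(predictors) if predictors is not None else list(DEFAULT_PREDICTORS)
    reference = fit_age_model(sessions, n_components=n_components, predictors=predictors)

    rng = np.random.default_rng(seed)
    n = len(sessions)
    pids = sessions["participant_id"].to_numpy() if "participant_id" in sessions else None
    unique_pids = np.unique(pids) if pids is not None else None

    samples = np.zeros((B, len(predictors), n_components))
    used = 0
    skipped = 0
    for _ in range(B):
        if unit == "participant":
            if unique_pids is None:
                raise FittingError("participant-level bootstrap needs participant_id")
            chosen = rng.choice(unique_pids, size=len(unique_pids), replace=True)
            idx = np.concatenate([np.flatnonzero(pids == p) for p in chosen])
        else:
            idx = rng.integers(0, n, size=n)
        boot = sessions.iloc[idx]
        try:
            m = fit_age_model(boot, n_components=n_components, predictors=predictors)
        except FittingError:
            skipped += 1
            continue
        W = m.weights.copy()
        for k in range(n_components):
            if W[:, k] @ reference.weights[:, k] < 0:
                W[:, k] = -W[:, k]
        samples[used] = W
        used += 1

    if used < 2:
        raise FittingError("fewer than 2 usable bootstrap resamples")
    samples = samples[:used]
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(undefined, np.nan, mean / np.where(undefined, 1.0, sd))
    return StabilityResult(
        predictors=predictors,
        mean=mean,
        sd=sd,
        z=z,
        undefined=undefined,
        n_samples=used,
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# model persistence

def save_model(model: PLSModel, path: str | Path,
               bias: BiasCorrection | None = None,
               provenance: dict | None = None) -> None:
    payload = {
        "predictors": model.predictors,
        "x_mean": model.x_mean.tolist(),
        "x_sd": model.x_sd.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "n_components": model.n_components,
        "x_variance_explained": model.x_variance_explained.tolist(),
        "y_variance_explained": model.y_variance_explained.tolist(),
        "n_rows": model.n_rows,
        "bias": None if bias is None else {"alpha": bias.alpha, "beta": bias.beta,
                                           "fit_cohort": bias.fit_cohort},
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[PLSModel, BiasCorrection | None]:
    data = json.loads(Path(path).read_text())
    model = PLSModel(
        predictors=data["predictors"],
        x_mean=np.array(data["x_mean"]),
        x_sd=np.array(data["x_sd"]),
        y_mean=data["y_mean"],
        weights=np.array(data["weights"]),
        x_loadings=np.array(data["x_loadings"]),
        y_loadings=np.array(data["y_loadings"]),
        coef=np.array(data["coef"]),
        n_components=data["n_components"],
        x_variance_explained=np.array(data["x_variance_explained"]),
        y_variance_explained=np.array(data["y_variance_explained"]),
        n_rows=data.get("n_rows", 0),
    )
    bias = None
    if data.get("bias"):
        bias = BiasCorrection(**data["bias"])
    return model, bias
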