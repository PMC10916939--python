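"""Synthetic longitudinal cohort generator.

Emulates the data structure of a longitudinal aging study: two cohorts of
cognitively normal older adults (a training cohort with sparse follow-up and a
test cohort with dense follow-up), a 19-test neuropsychological battery
administered at each visit, and per-participant imaging-derived outcomes
(hippocampal volume, total intracranial volume, global amyloid-PET DVR,
entorhinal and inferior-temporal tau-PET SUVR).

The generative model is a single latent general-ability factor per participant:

    g(i, s) = ability_i - age_slope_g * (age_is - 70) + practice_effect * (s - 1)

where ``ability_i ~ N(0, 1)`` (shifted by ``sa_ability_shift`` for a
``sa_fraction`` subpopulation of participants aged 70+), and each test score is
an affine function of ``g`` plus independent Gaussian noise, with the sign
inverted for timed tests (higher = worse).  Latent truth (ability, SA
membership) is emitted only in a separate truth table so downstream
classification can never read it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "Cohort",
    "SchemaError",
    "TEST_NAMES",
    "TIMED_TESTS",
    "generate_cohort",
    "simulate_roi_groups",
    "write_cohort",
    "read_cohort",
    "validate_sessions",
    "noise_sd_for_target_r2",
    "theoretical_r2",
]

# (name, intercept, loading, timed) — intercepts/loadings are plausible fixed
# scales for each test; exact values are immaterial downstream because the age
# model variance-normalizes every predictor.
TEST_SPECS: list[tuple[str, float, float, bool]] = [
    ("cvlt_trials_1_5", 50.0, 8.0, False),
    ("cvlt_sdfr", 11.0, 3.0, False),
    ("cvlt_sdcr", 12.0, 3.0, False),
    ("cvlt_ldfr", 11.0, 2.6, False),   # discretized to integers 0..16 below
    ("cvlt_ldcr", 12.0, 2.6, False),
    ("tmt_a", 35.0, 10.0, True),
    ("tmt_b", 80.0, 28.0, True),
    ("stroop_60s", 95.0, 15.0, False),
    ("fas", 44.0, 11.0, False),
    ("animal_naming", 21.0, 5.0, False),
    ("vegetable_naming", 14.0, 4.0, False),
    ("digit_symbol", 50.0, 11.0, False),
    ("logical_memory_total", 28.0, 7.0, False),
    ("visual_reproduction_i", 8.5, 2.2, False),
    ("visual_reproduction_ii", 7.0, 2.8, False),
    ("visual_reproduction_recognition", 5.2, 1.1, False),
    ("digit_span_forward", 10.8, 2.2, False),
    ("digit_span_backward", 7.5, 2.2, False),
    ("boston_naming", 55.0, 4.0, False),
]

TEST_NAMES: list[str] = [name for name, *_ in TEST_SPECS]
TIMED_TESTS: frozenset[str] = frozenset(n for n, _, _, timed in TEST_SPECS if timed)

#: emitted in addition to the 19 battery tests; used only by the episodic-memory
#: composite, never by the age model.
EXTRA_TESTS: list[tuple[str, float, float, bool]] = [
    ("verbal_paired_associates", 18.0, 5.0, False),
]

SESSION_COLUMNS = ["participant_id", "session_number", "age_at_session"]
MAX_SESSIONS = 12
CVLT_MAX = 16

_ROI_BASE = {
    # name -> (location function of (age, tiv), residual SD)
    "hippocampal_volume": 600.0,
    "pib_dvr": 0.20,
    "ftp_ec_suvr": 0.25,
    "ftp_it_suvr": 0.22,
}


class SchemaError(ValueError):
    """A table violates the cohort schema (missing column, incomplete battery...)."""


def _default_roi_effects() -> dict[str, float]:
    return {
        "hippocampal_volume": 0.45,
        "ftp_ec_suvr": -0.6,
        "ftp_it_suvr": -0.35,
        "pib_dvr": 0.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions the generator targets: cohort sizes
    293/238, ages 55–97, mean sessions per participant 1.56 (training) and 4.79
    (test), an age-prediction signal giving R² ≈ 0.45, a 30% elevated-ability
    subpopulation among the 70+, and a −0.6 SD planted entorhinal-tau group
    effect with no amyloid effect.
    """

    n_train: int = 293
    n_test: int = 238
    age_range: tuple[float, float] = (55.0, 97.0)
    sessions_lambda: float = 3.8          # mean extra sessions, test cohort
    sessions_lambda_train: float = 0.56   # mean extra sessions, training cohort
    age_slope_g: float = 0.076            # latent-ability decline per year
    practice_effect: float = 0.04         # latent gain per repeated session
    noise_sd: float = 0.8                 # residual SD per test, latent units
    ability_sd: float = 1.0               # between-participant ability SD
    sa_fraction: float = 0.3              # of 70+ participants
    sa_ability_shift: float = 1.0         # latent offset for that subpopulation
    roi_effects: dict[str, float] = field(default_factory=_default_roi_effects)
    ftp_fraction: float = 0.62            # of test cohort with tau PET
    seed: int = 0

    def validate(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("cohort sizes must be positive")
        lo, hi = self.age_range
        if not (55.0 <= lo < hi <= 97.0):
            raise ValueError("age_range must be increasing and within [55, 97]")
        if self.sessions_lambda < 0 or self.sessions_lambda_train < 0:
            raise ValueError("sessions_lambda must be non-negative")
        if self.noise_sd < 0 or self.ability_sd < 0:
            raise ValueError("noise_sd and ability_sd must be non-negative")
        if not 0.0 <= self.sa_fraction <= 1.0:
            raise ValueError("sa_fraction must be in [0, 1]")
        if not 0.0 <= self.ftp_fraction <= 1.0:
            raise ValueError("ftp_fraction must be in [0, 1]")


@dataclass
class Cohort:
    """Analysis-facing tables plus the segregated latent-truth table."""

    sessions: pd.DataFrame      # one row per neuropsychological visit
    participants: pd.DataFrame  # demographics, incl. cohort assignment
    roi: pd.DataFrame           # imaging outcomes, test cohort only
    truth: pd.DataFrame         # generator-internal latent truth

    def sessions_for(self, cohort: str) -> pd.DataFrame:
        ids = self.participants.loc[self.participants["cohort"] == cohort, "participant_id"]
        return self.sessions[self.sessions["participant_id"].isin(ids)].reset_index(drop=True)


def _draw_sessions(rng: np.random.Generator, n: int, lam: float) -> np.ndarray:
    return np.minimum(1 + rng.poisson(lam, size=n), MAX_SESSIONS)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate training + test cohorts deterministically from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range

    n_total = config.n_train + config.n_test
    cohorts = np.array(["train"] * config.n_train + ["test"] * config.n_test)
    pids = np.array([f"P{i:04d}" for i in range(n_total)])

    baseline_age = rng.uniform(lo, hi, size=n_total)
    sex = np.where(rng.random(n_total) < 0.56, "F", "M")
    education = np.clip(rng.normal(16.8, 2.2, size=n_total).round(1), 8.0, 20.0)
    apoe = rng.choice(
        ["e2_carrier", "e3_homozygote", "e4_carrier"], size=n_total, p=[0.09, 0.66, 0.25]
    )
    family_history = rng.random(n_total) < 0.33

    # SA subpopulation lives among participants 70+ at baseline
    is_sa = (baseline_age >= 70) & (rng.random(n_total) < config.sa_fraction)
    ability = (
        config.ability_sd * rng.normal(0.0, 1.0, size=n_total)
        + config.sa_ability_shift * is_sa
    )

    n_sessions = np.empty(n_total, dtype=int)
    n_sessions[cohorts == "train"] = _draw_sessions(
        rng, config.n_train, config.sessions_lambda_train
    )
    n_sessions[cohorts == "test"] = _draw_sessions(rng, config.n_test, config.sessions_lambda)

    rows: dict[str, list] = {c: [] for c in SESSION_COLUMNS}
    all_tests = TEST_SPECS + EXTRA_TESTS
    for name, *_ in all_tests:
        rows[name] = []

    for i in range(n_total):
        for s in range(1, n_sessions[i] + 1):
            age = baseline_age[i] + (s - 1)  # annual visits
            g = (
                ability[i]
                - config.age_slope_g * (age - 70.0)
                + config.practice_effect * (s - 1)
            )
            rows["participant_id"].append(pids[i])
            rows["session_number"].append(s)
            rows["age_at_session"].append(round(age, 2))
            noise = rng.normal(0.0, config.noise_sd, size=len(all_tests))
            for (name, intercept, loading, timed), eps in zip(all_tests, noise):
                latent = g + eps
                sign = -1.0 if timed else 1.0
                value = intercept + sign * loading * latent
                if timed:
                    value = max(value, 3.0)  # completion times floored at 3 s
                if name == "cvlt_ldfr":
                    value = float(np.clip(np.rint(value), 0, CVLT_MAX))
                rows[name].append(round(float(value), 3))

    sessions = pd.DataFrame(rows)

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "cohort": cohorts,
            "sex": sex,
            "education_years": education,
            "apoe_group": apoe,
            "family_history": family_history,
        }
    )

    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "latent_ability": ability.round(6),
            "is_sa_truth": is_sa,
        }
    )

    roi = _generate_roi(rng, config, pids[cohorts == "test"],
                        baseline_age[cohorts == "test"], is_sa[cohorts == "test"])
    return Cohort(sessions=sessions, participants=participants, roi=roi, truth=truth)


def _generate_roi(
    rng: np.random.Generator,
    config: SimulationConfig,
    pids: np.ndarray,
    age: np.ndarray,
    is_sa: np.ndarray,
) -> pd.DataFrame:
    """ROI outcomes with standardized planted group effects between latent SA/TA."""
    n = len(pids)
    effects = {**{k: 0.0 for k in _ROI_BASE}, **config.roi_effects}
    sa = is_sa.astype(float)

    tiv = rng.normal(1.45e6, 1.3e5, size=n)
    hv_sd = _ROI_BASE["hippocampal_volume"]
    hv = (
        3800.0
        + 0.0025 * tiv
        - 45.0 * (age - 75.0)
        + hv_sd * (effects["hippocampal_volume"] * sa + rng.normal(size=n))
    )
    dvr_sd = _ROI_BASE["pib_dvr"]
    dvr = np.maximum(
        1.12 + 0.004 * (age - 75.0) + dvr_sd * (effects["pib_dvr"] * sa + rng.normal(size=n)),
        0.7,
    )
    ec_sd = _ROI_BASE["ftp_ec_suvr"]
    ec = np.maximum(
        1.25 + 0.008 * (age - 75.0) + ec_sd * (effects["ftp_ec_suvr"] * sa + rng.normal(size=n)),
        0.5,
    )
    it_sd = _ROI_BASE["ftp_it_suvr"]
    it = np.maximum(
        1.30 + 0.006 * (age - 75.0) + it_sd * (effects["ftp_it_suvr"] * sa + rng.normal(size=n)),
        0.5,
    )
    # time between anchor scan and index cognitive session: mostly <= 6 months
    short = rng.random(n) < 0.93
    days = np.where(short, rng.integers(0, 184, size=n), rng.integers(184, 366, size=n))

    has_ftp = rng.random(n) < config.ftp_fraction
    ec = np.where(has_ftp, ec, np.nan)
    it = np.where(has_ftp, it, np.nan)

    return pd.DataFrame(
        {
            "participant_id": pids,
            "hippocampal_volume": hv.round(1),
            "tiv": tiv.round(0),
            "pib_dvr": dvr.round(4),
            "ftp_ec_suvr": np.round(ec, 4),
            "ftp_it_suvr": np.round(it, 4),
            "days_scan_to_cognition": days.astype(int),
        }
    )


def simulate_roi_groups(
    n_sa: int,
    n_ta: int,
    effect: float,
    seed: int,
    roi: str = "ftp_ec_suvr",
) -> pd.DataFrame:
    """Two-group ROI draw with a planted standardized effect.

    Covariates (age, sex, education) are drawn independently of group, so the
    planted ``effect`` is the population standardized mean difference SA − TA.
    Used for effect-size calibration experiments at fixed group sizes.
    """
    rng = np.random.default_rng(seed)
    n = n_sa + n_ta
    group = np.array([1] * n_sa + [0] * n_ta)
    sd = _ROI_BASE.get(roi, 1.0)
    base = {"ftp_ec_suvr": 1.25, "ftp_it_suvr": 1.30, "pib_dvr": 1.12,
            "hippocampal_volume": 7400.0}.get(roi, 0.0)
    return pd.DataFrame(
        {
            "group": group,
            "age": rng.uniform(70.0, 95.0, size=n),
            "sex": (rng.random(n) < 0.56).astype(int),
            "education_years": np.clip(rng.normal(16.8, 2.2, size=n), 8, 20),
            roi: base + sd * (effect * group + rng.normal(size=n)),
        }
    )


# ---------------------------------------------------------------------------
# signal-strength bookkeeping

def theoretical_r2(
    age_slope_g: float,
    noise_sd: float,
    age_var: float = 42.0**2 / 12.0,
    ability_sd: float = 1.0,
    n_tests: int = len(TEST_NAMES),
) -> float:
    """Population R² of the best linear age prediction under the generative model.

    The battery carries a single latent factor, so averaging the tests leaves a
    residual of variance ``ability_sd² + noise_sd²/n_tests`` against the age
    signal of variance ``age_slope_g² · age_var``.
    """
    signal = age_slope_g**2 * age_var
    return signal / (signal + ability_sd**2 + noise_sd**2 / n_tests)


def noise_sd_for_target_r2(
    target_r2: float,
    age_slope_g: float,
    age_var: float = 42.0**2 / 12.0,
    ability_sd: float = 1.0,
    n_tests: int = len(TEST_NAMES),
) -> float:
    """Invert :func:`theoretical_r2` for ``noise_sd``; errors if unattainable."""
    signal = age_slope_g**2 * age_var
    resid = signal * (1.0 - target_r2) / target_r2 - ability_sd**2
    if resid < 0:
        raise ValueError(
            f"target R²={target_r2} unreachable: ability variance alone "
            f"exceeds the allowed residual (increase age_slope_g)"
        )
    return float(np.sqrt(n_tests * resid))


# ---------------------------------------------------------------------------
# I/O

_FILES = {
    "sessions": "sessions.csv",
    "participants": "participants.csv",
    "roi": "roi.csv",
    "truth": "truth.csv",
}

_REQUIRED = {
    "sessions": SESSION_COLUMNS + TEST_NAMES,
    "participants": ["participant_id", "cohort", "sex", "education_years",
                     "apoe_group", "family_history"],
    "roi": ["participant_id", "hippocampal_volume", "tiv", "pib_dvr",
            "ftp_ec_suvr", "ftp_it_suvr", "days_scan_to_cognition"],
    "truth": ["participant_id", "latent_ability", "is_sa_truth"],
}


def validate_sessions(sessions: pd.DataFrame) -> None:
    """Schema + invariant checks for a session table.

    Enforces the complete-battery rule (a session missing any of the 19 tests
    is rejected, naming the test), strictly increasing session numbers, and
    non-decreasing age within participant.
    """
    for col in _REQUIRED["sessions"]:
        if col not in sessions.columns:
            raise SchemaError(f"sessions table is missing required column {col!r}")
    for test in TEST_NAMES:
        if sessions[test].isna().any():
            bad = sessions.loc[sessions[test].isna(), "participant_id"].iloc[0]
            raise SchemaError(
                f"incomplete battery: test {test!r} missing for participant {bad!r}"
            )
    for pid, grp in sessions.groupby("participant_id", sort=False):
        sn = grp["session_number"].to_numpy()
        if not (np.diff(sn) > 0).all():
            raise SchemaError(f"session_number not strictly increasing for {pid!r}")
        age = grp["age_at_session"].to_numpy()
        if not (np.diff(age) >= 0).all():
            raise SchemaError(f"age_at_session decreases for {pid!r}")


def _validate_table(df: pd.DataFrame, kind: str) -> None:
    if kind == "sessions":
        validate_sessions(df)
        return
    for col in _REQUIRED[kind]:
        if col not in df.columns:
            raise SchemaError(f"{kind} table is missing required column {col!r}")


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write the four tables as UTF-8 CSV with full-precision values."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, fname in _FILES.items():
        df = getattr(cohort, kind)
        _validate_table(df, kind)
        df.to_csv(directory / fname, index=False)


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort directory; unknown extra columns are accepted and kept."""
    directory = Path(directory)
    tables = {}
    for kind, fname in _FILES.items():
        df = pd.read_csv(directory / fname)
        _validate_table(df, kind)
        tables[kind] = df
    return Cohort(**tables)


def config_to_file(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    data = asdict(config)
    data["age_range"] = list(data["age_range"])
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def config_from_file(path: str | Path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    data["age_range"] = tuple(data["age_range"])
    return SimulationConfig(**data)
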