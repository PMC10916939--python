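"""End-to-end orchestration: simulate → age model → SA classification →
agreement → group comparisons, emitting one structured, reproducible report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import agemodel, composites, groupstats
from .classify import SA_DEFINITIONS, classify as classify_pool
from .simulate import Cohort, SimulationConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "report_to_json", "index_sessions"]

log = logging.getLogger("cogage")

ROI_OUTCOMES = ["hippocampal_volume_adj", "pib_dvr", "ftp_ec_suvr", "ftp_it_suvr"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; embedded verbatim in the report."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_components: int = 5
    bootstrap_B: int = 0          # 0 disables the weight-stability stage
    bootstrap_seed: int = 0
    min_age: float = 70.0
    sa_percentile: float = 20.0
    cvlt_threshold: int = 14
    index_session: str = "first"  # session used for classification: first|latest
    covariates: tuple[str, ...] = ("age", "sex", "education_years")
    extra_covariate: str | None = "days_scan_to_cognition"
    matched_n: int | None = None  # None -> size of the smallest SA group

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["age_range"] = list(d["sim"]["age_range"])
        d["covariates"] = list(d["covariates"])
        return d


def index_sessions(sessions: pd.DataFrame, which: str = "first") -> pd.DataFrame:
    """One row per participant: the session anchoring classification."""
    if which not in {"first", "latest"}:
        raise ValueError("index_session must be 'first' or 'latest'")
    grouped = sessions.sort_values(["participant_id", "session_number"]).groupby(
        "participant_id", sort=True
    )
    picked = grouped.head(1) if which == "first" else grouped.tail(1)
    return picked.reset_index(drop=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    text = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _stage(name: str, started: float) -> None:
    log.info("stage %-18s %6.2fs", name, time.perf_counter() - started)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run the full analysis; deterministic given the seeds in ``config``."""
    notes: list[str] = []
    t0 = time.perf_counter()
    if cohort is None:
        cohort = generate_cohort(config.sim)
    _stage("simulate", t0)

    train = cohort.sessions_for("train")
    test = cohort.sessions_for("test")

    t0 = time.perf_counter()
    model = agemodel.fit_age_model(train, n_components=config.n_components)
    acc_train = agemodel.accuracy(agemodel.predict_age(model, train),
                                  train["age_at_session"].to_numpy())
    pred_test = agemodel.predict_age(model, test)
    acc_test = agemodel.accuracy(pred_test, test["age_at_session"].to_numpy())
    bias = agemodel.fit_bias_correction(
        agemodel.predict_age(model, train) - train["age_at_session"].to_numpy(),
        train["age_at_session"].to_numpy(),
    )
    _stage("age_model", t0)

    stability = None
    if config.bootstrap_B >= 2:
        t0 = time.perf_counter()
        stab = agemodel.bootstrap_stability(
            train, n_components=config.n_components,
            B=config.bootstrap_B, seed=config.bootstrap_seed,
        )
        stability = {
            "predictors": stab.predictors,
            "z": stab.z,
            "n_samples": stab.n_samples,
            "n_skipped": stab.n_skipped,
        }
        _stage("stability", t0)

    # --- classification pool: index session per test participant, age >= min_age
    t0 = time.perf_counter()
    idx = index_sessions(test, config.index_session)
    cag = agemodel.apply_bias_correction(
        bias, agemodel.predict_age(model, idx), idx["age_at_session"].to_numpy()
    )
    idx = idx.assign(cag=cag.cag_corrected)
    pool_sessions = idx[idx["age_at_session"] >= config.min_age].reset_index(drop=True)

    pool = pd.DataFrame(
        {
            "participant_id": pool_sessions["participant_id"],
            "age": pool_sessions["age_at_session"],
            "cag": pool_sessions["cag"],
            "cvlt_ldfr": pool_sessions["cvlt_ldfr"],
        }
    )
    em = composites.compute_em_composite(pool_sessions)
    nm = composites.compute_nm_composite(pool_sessions)
    pool["em_resid"] = composites.age_adjust(em, pool["age"].to_numpy())
    pool["nm_resid"] = composites.age_adjust(nm, pool["age"].to_numpy())

    labels = classify_pool(
        pool,
        min_age=config.min_age,
        sa_percentile=config.sa_percentile,
        cvlt_threshold=config.cvlt_threshold,
    )
    sizes = labels.sizes()
    for definition, size in sizes.items():
        if size == 0:
            notes.append(f"group {definition} is empty under this configuration")
    _stage("classify", t0)

    # --- agreement
    t0 = time.perf_counter()
    kappas = agr.kappa_table(labels)
    overlaps = agr.overlap_matrix(labels)
    smallest = min(sizes[d] for d in SA_DEFINITIONS)
    matched_n = config.matched_n if config.matched_n is not None else smallest
    matched = None
    if 0 < matched_n <= smallest:
        matched = agr.matched_kappa(labels, matched_n, mode="rank")
    else:
        notes.append(f"matched reanalysis skipped (matched_n={matched_n})")
    _stage("agreement", t0)

    # --- group comparisons
    t0 = time.perf_counter()
    data = (
        labels.labels.merge(cohort.participants, on="participant_id")
        .merge(cohort.roi, on="participant_id", how="left")
    )
    data["sex_f"] = (data["sex"] == "F").astype(float)
    data["hippocampal_volume_adj"] = groupstats.adjust_tiv(
        data["hippocampal_volume"].to_numpy(), data["tiv"].to_numpy()
    )

    comparisons: list[dict] = []
    ta = data[data["ta"]]
    for definition in ["sa_all"] + SA_DEFINITIONS:
        sa = data[data[definition]]
        if len(sa) < 2:
            notes.append(f"comparisons skipped for {definition}: fewer than 2 members")
            continue
        comparisons.extend(_compare_groups(sa, ta, definition, config, notes))
    _stage("comparisons", t0)

    group_dvr_cl = {
        definition: groupstats.centiloid_int(float(data.loc[data[definition], "pib_dvr"].mean()))
        for definition in ["ta", "sa_all"] + SA_DEFINITIONS
        if data[definition].sum() > 0
    }

    report = {
        "config": config.to_dict(),
        "accuracy": {
            "train": asdict(acc_train),
            "test": asdict(acc_test),
            "n_sessions_train": len(train),
            "n_sessions_test": len(test),
        },
        "bias_correction": asdict(bias),
        "variance_explained": {
            "x_per_component": model.x_variance_explained,
            "y_per_component": model.y_variance_explained,
        },
        "stability": stability,
        "pool": {"n": len(pool), "min_age": config.min_age},
        "group_sizes": sizes,
        "cutoffs": labels.cutoffs,
        "kappa": kappas.to_dict(orient="records"),
        "kappa_matched": None if matched is None else matched.to_dict(orient="records"),
        "matched_n": matched_n,
        "overlaps": overlaps,
        "comparisons": comparisons,
        "group_mean_dvr_centiloid": group_dvr_cl,
        "abeta_positive_fraction": {
            definition: float(
                groupstats.abeta_positive(data.loc[data[definition], "pib_dvr"].dropna().to_numpy()).mean()
            )
            for definition in ["ta", "sa_all"] + SA_DEFINITIONS
            if data.loc[data[definition], "pib_dvr"].notna().sum() > 0
        },
        "notes": notes,
    }
    return _jsonable(report)


def _compare_groups(
    sa: pd.DataFrame, ta: pd.DataFrame, definition: str, config: RunConfig,
    notes: list[str],
) -> list[dict]:
    out: list[dict] = []

    def record(res: groupstats.GroupComparisonResult, model_tag: str) -> None:
        d = res.to_dict()
        d.update(group=definition, model=model_tag)
        out.append(d)

    # demographics: Welch t / chi-square as in a cohort characteristics table
    record(groupstats.welch_t_cohens_d(
        sa["age"].to_numpy(), ta["age"].to_numpy(), outcome="age"), "welch")
    record(groupstats.welch_t_cohens_d(
        sa["education_years"].to_numpy(), ta["education_years"].to_numpy(),
        outcome="education_years"), "welch")
    sex_table = np.array(
        [
            [int(sa["sex_f"].sum()), int((1 - sa["sex_f"]).sum())],
            [int(ta["sex_f"].sum()), int((1 - ta["sex_f"]).sum())],
        ]
    )
    try:
        record(groupstats.chisq_cramers_v(sex_table, outcome="sex"), "chisq")
    except ValueError as err:
        notes.append(f"sex chi-square skipped for {definition}: {err}")

    # ROI ANCOVAs, with education / without / with the scan-interval covariate
    both = pd.concat([sa.assign(_g=1), ta.assign(_g=0)], ignore_index=True)
    covar_cols = {"age": "age", "sex": "sex_f", "education_years": "education_years"}
    base = [covar_cols[c] for c in config.covariates if c in covar_cols]
    variants = {
        "ancova": base,
        "ancova_no_education": [c for c in base if c != "education_years"],
    }
    if config.extra_covariate:
        variants["ancova_extra_covariate"] = base + [config.extra_covariate]
    for outcome in ROI_OUTCOMES:
        for tag, cols in variants.items():
            sub = both[[outcome, "_g", *cols]].dropna()
            if sub["_g"].nunique() < 2 or len(sub) < len(cols) + 4:
                notes.append(f"{tag} skipped for {definition}/{outcome}: too few rows")
                continue
            try:
                res = groupstats.ancova_eta2(
                    sub[outcome].to_numpy(), sub["_g"].to_numpy(),
                    sub[cols], outcome_name=outcome,
                )
            except ValueError as err:
                notes.append(f"{tag} failed for {definition}/{outcome}: {err}")
                continue
            record(res, tag)
    return out
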