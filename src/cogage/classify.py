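"""Successful-aging (SA) classification rules on the 70+ pool.

Four rules, applied to one index session per participant:

- SA-CAG: bias-corrected cognitive age gap in the lowest 20th percentile
  (younger-than-expected cognition);
- SA-EM / SA-NM: age-regressed composite residual at or above the 80th
  percentile;
- SA-CVLT: CVLT Long Delay Free Recall of 14 or more (max 16), a normative
  young-adult level.

SA-ALL is the union; typical aging (TA) is its complement, so SA-ALL and TA
partition the pool.  Percentile cutoffs are linear-interpolation quantiles
computed once on the full pool; boundary ties are all selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SALabelSet", "percentile_cutoff", "classify", "matched_subsample",
           "SA_DEFINITIONS"]

SA_DEFINITIONS = ["sa_cag", "sa_em", "sa_nm", "sa_cvlt"]

#: score column feeding each definition and the extreme direction of its rule
_SCORE_FOR = {
    "sa_cag": ("cag", "low"),
    "sa_em": ("em_resid", "high"),
    "sa_nm": ("nm_resid", "high"),
    "sa_cvlt": ("cvlt_ldfr", "high"),
}


@dataclass
class SALabelSet:
    """Per-participant SA labels, the scores that drove them, and the cutoffs."""

    labels: pd.DataFrame  # participant_id, scores, sa_*, sa_all, ta
    cutoffs: dict[str, float] = field(default_factory=dict)

    def group(self, definition: str) -> pd.Index:
        return self.labels.loc[self.labels[definition], "participant_id"]

    def sizes(self) -> dict[str, int]:
        cols = SA_DEFINITIONS + ["sa_all", "ta"]
        return {c: int(self.labels[c].sum()) for c in cols}


def percentile_cutoff(scores: np.ndarray, q: float, tail: str) -> tuple[float, np.ndarray]:
    """Linear-interpolation percentile cutoff and the selected boolean mask.

    ``tail='low'`` selects scores <= the q-th percentile; ``tail='high'``
    selects scores >= the q-th percentile.  Ties at the cutoff are all selected.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    if tail not in {"low", "high"}:
        raise ValueError("tail must be 'low' or 'high'")
    cutoff = float(np.quantile(scores, q / 100.0, method="linear"))
    selected = scores <= cutoff if tail == "low" else scores >= cutoff
    return cutoff, selected


def classify(
    pool: pd.DataFrame,
    min_age: float = 70.0,
    sa_percentile: float = 20.0,
    cvlt_threshold: int = 14,
) -> SALabelSet:
    """Apply the four SA rules to the classification pool.

    ``pool`` needs columns participant_id, age, cag, em_resid, nm_resid,
    cvlt_ldfr — one row per participant (the index session).  Every pool member
    must be ``min_age`` or older; cutoffs are computed on the full pool and
    reused for all analyses.
    """
    required = ["participant_id", "age", "cag", "em_resid", "nm_resid", "cvlt_ldfr"]
    missing = [c for c in required if c not in pool.columns]
    if missing:
        raise ValueError(f"pool is missing column(s): {missing}")
    if (pool["age"] < min_age).any():
        bad = pool.loc[pool["age"] < min_age, "participant_id"].iloc[0]
        raise ValueError(f"participant {bad!r} is younger than {min_age}")

    out = pool[required].copy().reset_index(drop=True)
    cag_cut, sa_cag = percentile_cutoff(out["cag"].to_numpy(), sa_percentile, "low")
    em_cut, sa_em = percentile_cutoff(out["em_resid"].to_numpy(), 100 - sa_percentile, "high")
    nm_cut, sa_nm = percentile_cutoff(out["nm_resid"].to_numpy(), 100 - sa_percentile, "high")
    sa_cvlt = out["cvlt_ldfr"].to_numpy() >= cvlt_threshold

    out["sa_cag"] = sa_cag
    out["sa_em"] = sa_em
    out["sa_nm"] = sa_nm
    out["sa_cvlt"] = sa_cvlt
    out["sa_all"] = out[SA_DEFINITIONS].any(axis=1)
    out["ta"] = ~out["sa_all"]

    cutoffs = {
        "cag_p20": cag_cut,
        "em_p80": em_cut,
        "nm_p80": nm_cut,
        "cvlt_threshold": float(cvlt_threshold),
    }
    return SALabelSet(labels=out, cutoffs=cutoffs)


def matched_subsample(
    label_set: SALabelSet,
    target_n: int,
    mode: str = "rank",
    seed: int | None = None,
) -> SALabelSet:
    """Shrink every SA group to ``target_n`` members for matched reanalysis.

    ``mode='rank'`` keeps the target_n most extreme members by each
    definition's own score (deterministic); ``mode='random'`` subsamples with
    the given seed.  SA-ALL and TA are recomputed from the reduced groups.
    """
    if mode not in {"rank", "random"}:
        raise ValueError("mode must be 'rank' or 'random'")
    labels = label_set.labels.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    for definition in SA_DEFINITIONS:
        members = np.flatnonzero(labels[definition].to_numpy())
        if target_n > members.size:
            raise ValueError(
                f"target_n={target_n} exceeds {definition} group size {members.size}"
            )
        if target_n == members.size:
            continue
        if mode == "rank":
            score_col, tail = _SCORE_FOR[definition]
            scores = labels.loc[members, score_col].to_numpy(dtype=float)
            order = np.argsort(scores, kind="stable")
            keep = members[order[:target_n]] if tail == "low" else members[order[-target_n:]]
        else:
            keep = rng.choice(members, size=target_n, replace=False)
        new_col = np.zeros(len(labels), dtype=bool)
        new_col[keep] = True
        labels[definition] = new_col
    labels["sa_all"] = labels[SA_DEFINITIONS].any(axis=1)
    labels["ta"] = ~labels["sa_all"]
    return SALabelSet(labels=labels, cutoffs=dict(label_set.cutoffs))
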