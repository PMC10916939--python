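"""Agreement between SA definitions: Cohen's kappa and overlap counts."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .classify import SA_DEFINITIONS, SALabelSet, matched_subsample

__all__ = [
    "KappaResult",
    "cohens_kappa",
    "strength_label",
    "kappa_table",
    "overlap_matrix",
    "matched_kappa",
]

#: Landis–Koch-style strength-of-agreement bands.
_BANDS = [
    (0.0, "poor"),        # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]


@dataclass
class KappaResult:
    kappa: float
    po: float               # observed agreement
    pe: float               # chance agreement
    table: np.ndarray       # 2x2 counts [[both+, A+B-], [A-B+, both-]]
    n: int
    strength: str
    undefined: bool = False


def strength_label(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    for upper, label in _BANDS[1:]:
        if kappa <= upper:
            return label
    return "almost perfect"


def cohens_kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> KappaResult:
    """Cohen's kappa for two binary label vectors over the same participants.

    kappa = (po - pe) / (1 - pe).  When both raters are constant and identical
    (pe = 1), kappa is undefined and flagged rather than forced to a number.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    t11 = int(np.sum(a & b))
    t10 = int(np.sum(a & ~b))
    t01 = int(np.sum(~a & b))
    t00 = int(np.sum(~a & ~b))
    table = np.array([[t11, t10], [t01, t00]])
    po = (t11 + t00) / n
    pe = ((t11 + t10) * (t11 + t01) + (t01 + t00) * (t10 + t00)) / n**2
    if pe == 1.0:
        return KappaResult(kappa=np.nan, po=po, pe=pe, table=table, n=n,
                           strength="undefined", undefined=True)
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa=kappa, po=po, pe=pe, table=table, n=n,
                       strength=strength_label(kappa))


def kappa_table(label_set: SALabelSet) -> pd.DataFrame:
    """Pairwise kappa over the whole classification pool for all SA pairs."""
    rows = []
    labels = label_set.labels
    for a, b in combinations(SA_DEFINITIONS, 2):
        res = cohens_kappa(labels[a].to_numpy(), labels[b].to_numpy())
        rows.append(
            {
                "definition_a": a,
                "definition_b": b,
                "kappa": res.kappa,
                "po": res.po,
                "pe": res.pe,
                "n": res.n,
                "strength": res.strength,
            }
        )
    return pd.DataFrame(rows)


def overlap_matrix(label_set: SALabelSet) -> dict[str, int]:
    """Counts of every intersection of the four SA sets.

    Keys: '+'-joined definition names for each of the 2⁴−1 non-empty subsets
    (count of participants in *all* the named sets), 'only_<def>' exclusive
    counts, 'all_four', and 'sa_all'.
    """
    labels = label_set.labels
    masks = {d: labels[d].to_numpy(dtype=bool) for d in SA_DEFINITIONS}
    out: dict[str, int] = {}
    for r in range(1, len(SA_DEFINITIONS) + 1):
        for subset in combinations(SA_DEFINITIONS, r):
            inter = np.logical_and.reduce([masks[d] for d in subset])
            out["+".join(subset)] = int(inter.sum())
    for d in SA_DEFINITIONS:
        others = np.logical_or.reduce([masks[o] for o in SA_DEFINITIONS if o != d])
        out[f"only_{d}"] = int((masks[d] & ~others).sum())
    out["all_four"] = out["+".join(SA_DEFINITIONS)]
    out["sa_all"] = int(np.logical_or.reduce(list(masks.values())).sum())
    return out


def matched_kappa(
    label_set: SALabelSet,
    target_n: int,
    mode: str = "rank",
    seed: int | None = None,
) -> pd.DataFrame:
    """Kappa table after shrinking every SA group to the same size."""
    reduced = matched_subsample(label_set, target_n, mode=mode, seed=seed)
    return kappa_table(reduced)
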