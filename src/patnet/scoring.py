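"""PAT 2.0 scoring: subscale scores, total score, and risk level.

Each subscale score is the number of high-risk (``1``) responses divided by the
number of scored (non-missing) questions on that subscale, so it ranges from
0.00 to 1.00. The total score is the unweighted sum of the seven subscale
scores (range 0-7) and maps onto the three-tier Pediatric Psychosocial
Preventative Health Model risk partition:

* total < 1      → ``universal`` (low risk)
* 1 ≤ total < 2  → ``targeted`` (intermediate risk)
* total ≥ 2      → ``clinical`` (high risk)

The published partition prints the bands as "<1", "1.0-1.9" and ">2"; the
half-open bands above are the contiguous, exhaustive reading of the standard
1/2 cutpoints.

Families without siblings cannot answer the optional sibling scale; they
contribute 0 on ``sibling_problems`` and the score card carries an
``inapplicable`` flag, keeping every family on the common 0-7 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import SUBSCALES, ItemCatalog

RISK_LEVELS = ("universal", "targeted", "clinical")

#: response value used for missing answers in records
MISSING = None


@dataclass
class FamilyRecord:
    """Dichotomized PAT responses of one family.

    ``responses`` maps every catalog item id to 0, 1 or ``None`` (missing).
    """

    family_id: str
    disease: str
    responses: dict[str, Optional[int]]
    sibling_applicable: bool = True
    timepoint: str = "T0"

    def validate(self, catalog: ItemCatalog) -> None:
        missing_ids = [i for i in catalog.item_ids if i not in self.responses]
        if missing_ids:
            raise ValueError(
                f"family {self.family_id}: responses missing for items {missing_ids[:5]}"
            )
        extra = [i for i in self.responses if i not in catalog]
        if extra:
            raise ValueError(
                f"family {self.family_id}: unknown item ids {extra[:5]}"
            )
        bad = {
            i: v
            for i, v in self.responses.items()
            if v is not None and v not in (0, 1)
        }
        if bad:
            raise ValueError(
                f"family {self.family_id}: non-binary responses {bad}"
            )


@dataclass
class ScoreCard:
    """Per-family PAT scores."""

    family_id: str
    subscale_scores: dict[str, float]
    n_scored: dict[str, int]
    total_score: float
    risk_level: Optional[str]
    flags: dict[str, str] = field(default_factory=dict)


def classify_risk(total_score: float) -> str:
    """Map a total PAT score onto the universal/targeted/clinical partition."""
    if not math.isfinite(total_score) or not 0.0 <= total_score <= 7.0:
        raise ValueError(f"total score {total_score!r} outside the 0-7 scale")
    if total_score < 1.0:
        return "universal"
    if total_score < 2.0:
        return "targeted"
    return "clinical"


def score_subscale(
    record: FamilyRecord, subscale: str, catalog: ItemCatalog
) -> tuple[float, int]:
    """Adjusted score of one subscale: risk items / scored items.

    Returns ``(score, n_scored)``. A subscale with no scored (non-missing)
    response has an undefined score and returns ``(nan, 0)``; the inapplicable
    sibling scale returns ``(0.0, 0)`` so the family stays on the 0-7 scale.
    """
    items = catalog.subscale_items(subscale)
    if not items:
        raise KeyError(f"subscale {subscale!r} not present in catalog")
    if subscale == "sibling_problems" and not record.sibling_applicable:
        return 0.0, 0
    values = [record.responses.get(it.item_id) for it in items]
    scored = [v for v in values if v is not None]
    if not scored:
        return float("nan"), 0
    return sum(scored) / len(scored), len(scored)


def score_record(record: FamilyRecord, catalog: ItemCatalog) -> ScoreCard:
    """Score one family on every subscale present in the catalog.

    The total is the sum of the seven subscale scores. If a non-sibling
    subscale is entirely missing the total (and risk level) are undefined and
    the card is flagged.
    """
    subscale_scores: dict[str, float] = {}
    n_scored: dict[str, int] = {}
    flags: dict[str, str] = {}
    for sub in catalog.subscales_present():
        s, n = score_subscale(record, sub, catalog)
        subscale_scores[sub] = s
        n_scored[sub] = n
        if sub == "sibling_problems" and not record.sibling_applicable:
            flags[sub] = "inapplicable"
        elif math.isnan(s):
            flags[sub] = "all_missing"
    if any(math.isnan(v) for v in subscale_scores.values()):
        total = float("nan")
        risk = None
    else:
        total = float(sum(subscale_scores.values()))
        risk = classify_risk(total)
    return ScoreCard(
        family_id=record.family_id,
        subscale_scores=subscale_scores,
        n_scored=n_scored,
        total_score=total,
        risk_level=risk,
        flags=flags,
    )


def score_total(record: FamilyRecord, catalog: ItemCatalog) -> float:
    """Total PAT score (0-7) of one family."""
    return score_record(record, catalog).total_score


def score_cohort(frame: pd.DataFrame, catalog: ItemCatalog) -> pd.DataFrame:
    """Score every family of a cohort frame (see :mod:`patnet.cohort`).

    Vectorized equivalent of :func:`score_record` row by row. Returns a frame
    indexed like ``frame`` with one column per subscale, ``total``,
    ``risk_level`` and ``disease`` carried over.
    """
    out = pd.DataFrame(index=frame.index)
    for sub in catalog.subscales_present():
        ids = [it.item_id for it in catalog.subscale_items(sub)]
        block = frame[ids].astype(float)
        score = block.mean(axis=1, skipna=True)  # NaN if all missing
        if sub == "sibling_problems" and "sibling_applicable" in frame:
            applicable = frame["sibling_applicable"].astype(bool)
            score = score.where(applicable, 0.0)
        out[sub] = score
    out["total"] = out[list(catalog.subscales_present())].sum(axis=1, skipna=False)
    out["risk_level"] = [
        classify_risk(t) if math.isfinite(t) else None for t in out["total"]
    ]
    for col in ("family_id", "disease"):
        if col in frame:
            out[col] = frame[col]
    return out


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1))


def cohort_summary(scores: pd.DataFrame | Sequence[ScoreCard]) -> dict:
    """Cohort-level summary: subscale and total mean ± SD, risk proportions,
    and the proportional weight of each subscale within the total score.

    Weights are subscale mean / total mean; across fully scored subscales they
    sum to 1 up to rounding.
    """
    if not isinstance(scores, pd.DataFrame):
        if len(scores) == 0:
            raise ValueError("empty cohort")
        rows = {c.family_id: {**c.subscale_scores, "total": c.total_score,
                              "risk_level": c.risk_level} for c in scores}
        scores = pd.DataFrame.from_dict(rows, orient="index")
    if len(scores) == 0:
        raise ValueError("empty cohort")
    subscales = [s for s in SUBSCALES if s in scores.columns]
    summary: dict = {"n": int(len(scores)), "subscales": {}, "weights": {}}
    total_mean, total_sd = _mean_sd(scores["total"].to_numpy())
    summary["total"] = {"mean": total_mean, "sd": total_sd}
    for sub in subscales:
        m, sd = _mean_sd(scores[sub].to_numpy())
        summary["subscales"][sub] = {"mean": m, "sd": sd}
        summary["weights"][sub] = m / total_mean if total_mean else float("nan")
    counts = scores["risk_level"].value_counts(dropna=True)
    n_classified = int(counts.sum())
    summary["risk_proportions"] = {
        level: (int(counts.get(level, 0)) / n_classified if n_classified else float("nan"))
        for level in RISK_LEVELS
    }
    return summary


def summary_table(summary: Mapping) -> pd.DataFrame:
    """Tidy one-row-per-subscale view of :func:`cohort_summary` output."""
    rows = []
    for sub, ms in summary["subscales"].items():
        rows.append(
            {"subscale": sub, "mean": ms["mean"], "sd": ms["sd"],
             "weight": summary["weights"][sub]}
        )
    rows.append(
        {"subscale": "total", "mean": summary["total"]["mean"],
         "sd": summary["total"]["sd"], "weight": 1.0}
    )
    return pd.DataFrame(rows)
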