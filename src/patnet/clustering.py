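"""Data-driven risk-profile clustering on the seven PAT subscale scores.

Families (regardless of diagnosis) are clustered on their z-scored subscale
profiles with k-means (k = 2 by default, the published solution), using
multiple seeded restarts and keeping the lowest within-cluster sum of
squares. Because k-means labels are arbitrary, clusters are relabelled in
ascending order of their raw Family Beliefs mean, so for k = 2 "cluster 2" is
always the high-Family-Beliefs profile and "cluster 1" the high
structure/support-problems profile. Silhouette scores for k in {2, 3, 4} are
available as a model-selection diagnostic.

Exposed statsmodels-style: :class:`RiskProfileKMeans` built from a scorecard
frame; :meth:`fit` returns a :class:`ClusterResults` carrying assignments,
centroids, per-cluster raw profiles, disease and risk-level cross-tabulations,
and the silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .catalog import SUBSCALES


def _zscore(features: pd.DataFrame) -> pd.DataFrame:
    mu = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0)
    z = (features - mu) / sd.replace(0.0, np.nan)
    return z.fillna(0.0)  # zero-variance subscale carries no information


@dataclass
class ClusterResults:
    """A fitted k-cluster solution over family subscale profiles."""

    k: int
    assignment: pd.Series  # family_id -> cluster label (1..k)
    centroids_z: pd.DataFrame  # cluster x subscale, standardized space
    profile_table: pd.DataFrame  # cluster x subscale, raw score means
    cluster_sizes: pd.Series
    inertia: float
    silhouette: float
    seed: int
    restarts: int
    crosstab_disease: Optional[pd.DataFrame] = None
    crosstab_risk: Optional[pd.DataFrame] = None

    def share(self, cluster: int, disease: str) -> float:
        """Fraction of a disease group assigned to ``cluster``."""
        if self.crosstab_disease is None:
            raise ValueError("no disease labels were available at fit time")
        col = self.crosstab_disease[disease]
        return float(col.get(cluster, 0)) / float(col.sum())

    def long_profile(self) -> pd.DataFrame:
        """Figure-ready long format: cluster, subscale, mean score."""
        return (
            self.profile_table.reset_index()
            .melt(id_vars="cluster", var_name="subscale", value_name="mean_score")
        )

    def summary(self) -> str:
        lines = [
            f"Risk-profile k-means (k={self.k}, restarts={self.restarts}, seed={self.seed})",
            f"  sizes: {dict(self.cluster_sizes)}",
            f"  within-cluster SS: {self.inertia:.3f}",
            f"  silhouette: {self.silhouette:.3f}" if np.isfinite(self.silhouette)
            else "  silhouette: n/a",
            "  per-cluster raw subscale means:",
        ]
        lines.append(self.profile_table.round(3).to_string())
        if self.crosstab_disease is not None:
            lines.append("  cluster x disease counts:")
            lines.append(self.crosstab_disease.to_string())
        return "\n".join(lines)


class RiskProfileKMeans:
    """K-means model over per-family subscale scores.

    Parameters
    ----------
    scores
        Scorecard frame as produced by :func:`patnet.scoring.score_cohort`
        (one row per family; subscale columns, optionally ``family_id``,
        ``disease`` and ``risk_level``).
    k
        Number of clusters (default 2, the published solution).
    """

    def __init__(self, scores: pd.DataFrame, k: int = 2):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.subscales = [s for s in SUBSCALES if s in scores.columns]
        if not self.subscales:
            raise ValueError("scores frame has no subscale columns")
        if len(scores) < 2 * k:
            raise ValueError(f"need at least {2 * k} families for k={k}")
        scores = scores.reset_index(drop=True)
        if "family_id" not in scores.columns:
            scores = scores.assign(family_id=[f"fam{i:04d}" for i in range(len(scores))])
        features = scores[self.subscales].astype(float)
        if features.isna().any().any():
            raise ValueError("subscale scores must be complete (impute or drop first)")
        self.scores = scores
        self.k = k

    def fit(self, seed: int = 0, restarts: int = 20) -> ClusterResults:
        # sort by family_id so the solution is invariant to row order
        order = self.scores.sort_values("family_id", kind="stable").reset_index(drop=True)
        features = order[self.subscales].astype(float)
        if (features.nunique(axis=0) <= 1).all():
            raise ValueError("degenerate input: all families share one profile")
        z = _zscore(features)

        km = KMeans(n_clusters=self.k, n_init=restarts, random_state=seed)
        raw_labels = km.fit_predict(z.to_numpy())

        # canonical labels: ascending raw family_beliefs mean -> 1..k
        beliefs_col = (
            "family_beliefs" if "family_beliefs" in self.subscales else self.subscales[0]
        )
        means = {
            lab: features.loc[raw_labels == lab, beliefs_col].mean()
            for lab in np.unique(raw_labels)
        }
        ranked = sorted(means, key=lambda lab: (means[lab], lab))
        relabel = {lab: i + 1 for i, lab in enumerate(ranked)}
        labels = np.array([relabel[lab] for lab in raw_labels])

        assignment = pd.Series(labels, index=order["family_id"].to_numpy(), name="cluster")
        centroids_z = (
            z.assign(cluster=labels).groupby("cluster").mean().sort_index()
        )
        profile = (
            features.assign(cluster=labels).groupby("cluster").mean().sort_index()
        )
        profile.index.name = "cluster"
        sizes = pd.Series(labels, name="cluster").value_counts().sort_index()

        if self.k >= 2 and len(set(labels)) > 1:
            sil = float(silhouette_score(z.to_numpy(), labels))
        else:
            sil = float("nan")

        crosstab_disease = None
        if "disease" in order.columns:
            crosstab_disease = pd.crosstab(labels, order["disease"])
            crosstab_disease.index.name = "cluster"
        crosstab_risk = None
        if "risk_level" in order.columns:
            crosstab_risk = pd.crosstab(labels, order["risk_level"])
            crosstab_risk.index.name = "cluster"

        return ClusterResults(
            k=self.k,
            assignment=assignment,
            centroids_z=centroids_z,
            profile_table=profile,
            cluster_sizes=sizes,
            inertia=float(km.inertia_),
            silhouette=sil,
            seed=seed,
            restarts=restarts,
            crosstab_disease=crosstab_disease,
            crosstab_risk=crosstab_risk,
        )


def cluster_families(scores: pd.DataFrame, k: int = 2, seed: int = 0,
                     restarts: int = 20) -> ClusterResults:
    """Functional façade over :class:`RiskProfileKMeans`."""
    return RiskProfileKMeans(scores, k=k).fit(seed=seed, restarts=restarts)


def silhouette_diagnostic(scores: pd.DataFrame, ks=(2, 3, 4), seed: int = 0,
                          restarts: int = 20) -> dict[int, float]:
    """Silhouette score per candidate k (model-selection diagnostic)."""
    return {
        k: RiskProfileKMeans(scores, k=k).fit(seed=seed, restarts=restarts).silhouette
        for k in ks
    }
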