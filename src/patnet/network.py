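"""Psychosocial correlation networks over PAT items or subscales.

Nodes are the 38 scored in-network items (or the seven subscales); an edge's
weight is the pairwise correlation of the two columns across families. On
dichotomous items the Pearson correlation is the phi coefficient; a tetrachoric
estimator (latent-normal correlation) is available as an option. Edges can be
pruned by statistical thresholding (two-sided p < alpha from the t transform
``t = r * sqrt((m - 2) / (1 - r^2))`` with m complete pairs) and/or by
proportional thresholding (keep the fixed fraction of edges with the largest
absolute weight).

Negative correlations are kept: the sign is edge metadata, while thresholding,
node strength, and path lengths all use the magnitude — the usual convention
in symptom networks.

Estimation is exposed statsmodels-style: build a
:class:`PsychosocialNetworkModel` from a cohort, call :meth:`fit`, and work
with the returned :class:`NetworkResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import ItemCatalog
from .cohort import Cohort
from .scoring import score_cohort

__all__ = [
    "PsychosocialNetworkModel",
    "NetworkResults",
    "correlation_matrix",
    "threshold_significance",
    "threshold_proportional",
    "layout_fruchterman_reingold",
    "fruchterman_reingold",
]


def _phi_pvalue(r: float, m: int) -> float:
    """Two-sided p-value of a correlation via the t transform, df = m - 2."""
    if m < 3 or not math.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((m - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=m - 2))


def _tetrachoric(x: np.ndarray, y: np.ndarray) -> float:
    """Latent-normal correlation of two binary vectors (threshold identity).

    Solves ``Phi2(h, k; rho) = P(x=1, y=1)`` with thresholds matched to the
    marginal prevalences. Cells are continuity-corrected by 0.5 when empty.
    """
    a = float(np.sum((x == 1) & (y == 1)))
    b = float(np.sum((x == 1) & (y == 0)))
    c = float(np.sum((x == 0) & (y == 1)))
    d = float(np.sum((x == 0) & (y == 0)))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    p1, p2, p11 = (a + b) / n, (a + c) / n, a / n
    h, k = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)

    def objective(rho: float) -> float:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        upper = stats.multivariate_normal.cdf(
            [-h, -k], mean=[0.0, 0.0], cov=cov
        )  # P(z1 > h, z2 > k) by symmetry
        return upper - p11

    lo, hi = -0.999, 0.999
    if objective(lo) * objective(hi) > 0:
        return 1.0 if objective(hi) < 0 else -1.0
    return float(optimize.brentq(objective, lo, hi, xtol=1e-6))


@dataclass
class NetworkResults:
    """Fitted psychosocial network.

    ``weights``/``pvalues``/``pair_counts`` are symmetric frames over the
    retained node set (zero-variance nodes already excluded); ``retained``
    flags the edges surviving the thresholding recorded in
    ``threshold_spec``. Unestimable edges (fewer than 3 complete pairs) have
    NaN weight and are never retained.
    """

    level: str
    nodes: pd.DataFrame  # id, label, subscale
    weights: pd.DataFrame
    pvalues: pd.DataFrame
    pair_counts: pd.DataFrame
    retained: pd.DataFrame
    excluded: tuple[str, ...] = ()
    threshold_spec: tuple[dict, ...] = ()
    layout_: Optional[dict[str, tuple[float, float]]] = field(default=None, compare=False)

    @property
    def node_ids(self) -> list[str]:
        return list(self.weights.index)

    def edges(self, retained_only: bool = False) -> pd.DataFrame:
        """Tidy upper-triangle edge list in node order."""
        ids = self.node_ids
        rows = []
        for i, u in enumerate(ids):
            for v in ids[i + 1:]:
                w = self.weights.at[u, v]
                estimable = math.isfinite(w)
                rows.append(
                    {
                        "node_i": u,
                        "node_j": v,
                        "weight": w,
                        "abs_weight": abs(w) if estimable else float("nan"),
                        "sign": (0 if not estimable else (1 if w >= 0 else -1)),
                        "p_value": self.pvalues.at[u, v],
                        "n_pairs": int(self.pair_counts.at[u, v]),
                        "retained": bool(self.retained.at[u, v]),
                    }
                )
        frame = pd.DataFrame(
            rows, columns=["node_i", "node_j", "weight", "abs_weight", "sign",
                           "p_value", "n_pairs", "retained"]
        )
        if retained_only:
            frame = frame[frame["retained"]].reset_index(drop=True)
        return frame

    def threshold_significance(self, alpha: float = 0.05) -> "NetworkResults":
        """Keep edges with p < alpha (uncorrected). Never adds edges."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if alpha >= 1.0:  # vacuous threshold keeps every estimable edge
            return replace(
                self,
                threshold_spec=self.threshold_spec
                + ({"mode": "significance", "alpha": alpha},),
            )
        keep = self.retained & (self.pvalues < alpha) & self.weights.notna()
        np.fill_diagonal(keep.values, False)
        spec = self.threshold_spec + ({"mode": "significance", "alpha": alpha},)
        return replace(self, retained=keep, threshold_spec=spec, layout_=None)

    def threshold_proportional(self, keep_fraction: float) -> "NetworkResults":
        """Keep the ``ceil(keep_fraction * E)`` currently retained edges of
        largest absolute weight; ties broken by node-pair order."""
        if not 0.0 < keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        edges = self.edges(retained_only=True)
        n_keep = math.ceil(keep_fraction * len(edges))
        order = edges.sort_values("abs_weight", ascending=False, kind="stable")
        kept_pairs = set(
            zip(order["node_i"].iloc[:n_keep], order["node_j"].iloc[:n_keep])
        )
        keep = self.retained.copy()
        keep.loc[:, :] = False
        for u, v in kept_pairs:
            keep.at[u, v] = True
            keep.at[v, u] = True
        spec = self.threshold_spec + (
            {"mode": "proportional", "keep_fraction": keep_fraction},
        )
        return replace(self, retained=keep, threshold_spec=spec, layout_=None)

    def graph(self, retained_only: bool = True) -> nx.Graph:
        """networkx view: every node, retained edges with ``weight`` (signed),
        ``abs_weight`` and ``length`` = 1/|weight| attributes."""
        g = nx.Graph()
        node_meta = self.nodes.set_index("id")
        for node_id in self.node_ids:
            g.add_node(
                node_id,
                label=str(node_meta.at[node_id, "label"]),
                subscale=str(node_meta.at[node_id, "subscale"]),
            )
        edges = self.edges(retained_only=retained_only)
        for row in edges.itertuples(index=False):
            if not math.isfinite(row.weight):
                continue
            g.add_edge(
                row.node_i,
                row.node_j,
                weight=float(row.weight),
                abs_weight=float(row.abs_weight),
                length=(1.0 / row.abs_weight) if row.abs_weight > 0 else float("inf"),
                p_value=float(row.p_value) if math.isfinite(row.p_value) else float("nan"),
                retained=bool(row.retained),
            )
        return g

    def layout(self, seed: int = 0, iterations: int = 200,
               gravity: float = 10.0) -> dict[str, tuple[float, float]]:
        """Seeded Fruchterman-Reingold coordinates of the retained network."""
        g = self.graph(retained_only=True)
        pos = fruchterman_reingold(g, seed=seed, iterations=iterations, gravity=gravity)
        self.layout_ = pos
        return pos

    def summary(self) -> str:
        edges = self.edges()
        retained = int(edges["retained"].sum())
        lines = [
            f"Psychosocial network ({self.level} level)",
            f"  nodes: {len(self.node_ids)}"
            + (f" (excluded zero-variance: {', '.join(self.excluded)})" if self.excluded else ""),
            f"  estimable edges: {int(edges['weight'].notna().sum())} / {len(edges)}",
            f"  retained edges: {retained}",
            f"  thresholding: {list(self.threshold_spec) or 'none'}",
        ]
        return "\n".join(lines)

    def to_graphml(self, path) -> None:
        g = self.graph(retained_only=True)
        strengths = {
            node: sum(d["abs_weight"] for _, _, d in g.edges(node, data=True))
            for node in g.nodes
        }
        nx.set_node_attributes(g, strengths, "strength")
        if self.layout_:
            nx.set_node_attributes(g, {k: float(v[0]) for k, v in self.layout_.items()}, "x")
            nx.set_node_attributes(g, {k: float(v[1]) for k, v in self.layout_.items()}, "y")
        nx.write_graphml(g, path)

    def to_edge_csv(self, path) -> None:
        self.edges().to_csv(path, index=False)


class PsychosocialNetworkModel:
    """Correlation-network estimator for one cohort.

    Parameters
    ----------
    cohort
        A :class:`patnet.cohort.Cohort`.
    level
        ``"item"`` (38-node network over in-network items) or ``"subscale"``
        (7-node summary network over subscale scores).
    method
        ``"pearson"`` (phi on 0/1 items; default) or ``"tetrachoric"``
        (item level only).
    """

    def __init__(self, cohort: Cohort, level: str = "item", method: str = "pearson"):
        if level not in ("item", "subscale"):
            raise ValueError(f"level must be 'item' or 'subscale', got {level!r}")
        if method not in ("pearson", "tetrachoric"):
            raise ValueError(f"unknown correlation method {method!r}")
        if method == "tetrachoric" and level != "item":
            raise ValueError("tetrachoric correlations apply to binary items only")
        if len(cohort) < 3:
            raise ValueError("need at least 3 families to estimate correlations")
        self.cohort = cohort
        self.level = level
        self.method = method
        self.catalog: ItemCatalog = cohort.catalog

    def _data(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        if self.level == "item":
            items = self.catalog.network_items
            data = self.cohort.frame[[it.item_id for it in items]].astype(float)
            nodes = pd.DataFrame(
                {"id": [it.item_id for it in items],
                 "label": [it.label for it in items],
                 "subscale": [it.subscale for it in items]}
            )
        else:
            scores = score_cohort(self.cohort.frame, self.catalog)
            subs = list(self.catalog.subscales_present())
            data = scores[subs].astype(float)
            nodes = pd.DataFrame({"id": subs, "label": subs, "subscale": subs})
        return data, nodes

    def fit(self) -> NetworkResults:
        data, nodes = self._data()

        variances = data.var(axis=0, skipna=True)
        zero_var = [c for c in data.columns if not variances[c] > 0]
        if zero_var:
            data = data.drop(columns=zero_var)
            nodes = nodes[~nodes["id"].isin(zero_var)].reset_index(drop=True)
        ids = list(data.columns)
        k = len(ids)
        values = data.to_numpy(dtype=float)
        present = np.isfinite(values)

        weights = np.full((k, k), np.nan)
        pvals = np.full((k, k), np.nan)
        counts = np.zeros((k, k), dtype=int)
        np.fill_diagonal(weights, np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                mask = present[:, i] & present[:, j]
                m = int(mask.sum())
                counts[i, j] = counts[j, i] = m
                if m < 3:
                    continue
                x, y = values[mask, i], values[mask, j]
                if x.std() == 0 or y.std() == 0:
                    continue  # constant on complete pairs: unestimable
                if self.method == "pearson":
                    r = float(np.corrcoef(x, y)[0, 1])
                else:
                    r = _tetrachoric(x, y)
                weights[i, j] = weights[j, i] = r
                p = _phi_pvalue(r, m)
                pvals[i, j] = pvals[j, i] = p

        w = pd.DataFrame(weights, index=ids, columns=ids)
        p = pd.DataFrame(pvals, index=ids, columns=ids)
        m = pd.DataFrame(counts, index=ids, columns=ids)
        retained = w.notna()
        np.fill_diagonal(retained.values, False)
        return NetworkResults(
            level=self.level,
            nodes=nodes,
            weights=w,
            pvalues=p,
            pair_counts=m,
            retained=retained,
            excluded=tuple(zero_var),
        )


# -- functional façade ----------------------------------------------------


def correlation_matrix(cohort: Cohort, level: str = "item",
                       method: str = "pearson") -> NetworkResults:
    """Fit the correlation network (weights + p-values) for a cohort."""
    return PsychosocialNetworkModel(cohort, level=level, method=method).fit()


def threshold_significance(results: NetworkResults, alpha: float = 0.05) -> NetworkResults:
    return results.threshold_significance(alpha)


def threshold_proportional(results: NetworkResults, keep_fraction: float) -> NetworkResults:
    return results.threshold_proportional(keep_fraction)


def layout_fruchterman_reingold(results: NetworkResults, seed: int = 0,
                                iterations: int = 200,
                                gravity: float = 10.0) -> dict[str, tuple[float, float]]:
    return results.layout(seed=seed, iterations=iterations, gravity=gravity)


def fruchterman_reingold(
    graph: nx.Graph,
    seed: int = 0,
    iterations: int = 200,
    gravity: float = 10.0,
    weight: str = "abs_weight",
) -> dict[str, tuple[float, float]]:
    """Force-directed (Fruchterman-Reingold) layout with a central gravity pull.

    Strongly connected (high-strength) nodes end up near the centroid while
    weakly connected nodes are pushed to the periphery, mirroring the layout
    convention of desktop graph tools. Deterministic for a fixed seed.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    if n == 1:
        return {nodes[0]: (0.0, 0.0)}
    index = {node: i for i, node in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2))

    k = math.sqrt(1.0 / n)  # ideal pairwise distance for unit area
    edge_list = [
        (index[u], index[v], float(d.get(weight, 1.0)) or 1.0)
        for u, v, d in graph.edges(data=True)
    ]
    t0 = 0.1
    for it in range(iterations):
        temp = t0 * (1.0 - it / iterations) + 1e-6
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # pairwise repulsion k^2 / d
        disp = (delta / dist[..., None] * (k * k / dist ** 2)[..., None]).sum(axis=1)
        # attraction along edges, scaled by weight: w * d^2 / k
        for i, j, w_ij in edge_list:
            d_vec = pos[i] - pos[j]
            d = max(float(np.linalg.norm(d_vec)), 1e-9)
            f = w_ij * d * d / k
            shift = d_vec / d * f
            disp[i] -= shift
            disp[j] += shift
        # gravity toward the origin
        disp -= 0.01 * gravity * k * pos
        lengths = np.maximum(np.linalg.norm(disp, axis=1), 1e-9)
        pos += disp / lengths[:, None] * np.minimum(lengths, temp)[:, None]
    return {node: (float(pos[i, 0]), float(pos[i, 1])) for node, i in index.items()}
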