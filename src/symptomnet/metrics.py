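"""Node-level network indices and community detection.

Expected influence (EI) of a node is the plain sum of its signed edge
weights; bridge expected influence (BEI) restricts the sum to edges crossing
community boundaries — by default the two-instrument split (burnout items vs
depression items), optionally an empirical partition. Predictability is the
variance of a node explained by its network neighbors. Communities come from
the Walktrap algorithm: short random walks on the (absolute-) weighted graph
define node distances that are agglomerated and cut at maximum modularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .ggm import NetworkModel
from .preprocess import TransformedTable

__all__ = [
    "CommunityAssignment",
    "expected_influence",
    "bridge_expected_influence",
    "predictability",
    "walktrap",
    "centrality_table",
    "two_group_split",
]


def expected_influence(model: NetworkModel | np.ndarray) -> np.ndarray:
    """One-step expected influence: row sums of the weight matrix, diagonal excluded."""
    w = model.weights if isinstance(model, NetworkModel) else np.asarray(model, float)
    w = w - np.diag(np.diag(w))
    return w.sum(axis=1)


def two_group_split(labels) -> np.ndarray:
    """The two-instrument partition: burnout (MBI-*) vs depression (D*) items."""
    groups = []
    for lab in labels:
        s = str(lab)
        if s.startswith("MBI"):
            groups.append("burnout")
        elif s.startswith("D"):
            groups.append("depression")
        else:
            raise ValueError(
                f"cannot infer instrument for node {lab!r}; pass groups explicitly"
            )
    return np.asarray(groups, dtype=object)


def bridge_expected_influence(
    model: NetworkModel | np.ndarray, groups=None
) -> np.ndarray:
    """Sum of each node's edge weights to nodes outside its own group.

    ``groups`` is one label per node; when omitted and the model's node labels
    follow the MBI-*/D* convention, the two-instrument split is used. For any
    node, BEI plus the within-group weight sum equals EI exactly.
    """
    if isinstance(model, NetworkModel):
        w = model.weights
        if groups is None:
            groups = two_group_split(model.labels)
    else:
        w = np.asarray(model, float)
        if groups is None:
            raise ValueError("groups required when passing a bare matrix")
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != w.shape[0]:
        raise ValueError("groups must label every node exactly once")
    w = w - np.diag(np.diag(w))
    cross = groups[:, None] != groups[None, :]
    return (w * cross).sum(axis=1)


def predictability(
    table: TransformedTable | pd.DataFrame,
    model: NetworkModel,
    mode: str = "neighbors",
) -> np.ndarray:
    """Per-node explained variance (R^2, floored at 0).

    ``mode='neighbors'`` regresses each node on its network neighbors (the
    defining notion: variance explained by adjacent nodes); ``mode='all'``
    uses all remaining nodes as predictors (nodewise-regression flavor).
    Nodes with no neighbors score 0.
    """
    df = table.values if isinstance(table, TransformedTable) else pd.DataFrame(table)
    X = df.to_numpy(float)
    n, p = X.shape
    if list(df.columns) != list(model.labels):
        raise ValueError("table columns do not match network node labels")
    r2 = np.zeros(p)
    for i in range(p):
        if mode == "neighbors":
            idx = np.flatnonzero(model.weights[i] != 0)
        elif mode == "all":
            idx = np.array([j for j in range(p) if j != i])
        else:
            raise ValueError("mode must be 'neighbors' or 'all'")
        if idx.size == 0:
            continue
        if n <= idx.size + 1:
            raise ValueError(f"n = {n} too small to regress node {i} on {idx.size} neighbors")
        y = X[:, i]
        Z = np.column_stack([np.ones(n), X[:, idx]])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        sst = ((y - y.mean()) ** 2).sum()
        r2[i] = max(0.0, 1.0 - resid @ resid / sst) if sst > 0 else 0.0
    return r2


@dataclass
class CommunityAssignment:
    """A partition of network nodes into labeled communities."""

    membership: np.ndarray  # contiguous integer label per node
    n_communities: int
    modularity: float
    method: str = "walktrap"

    def as_dict(self, labels) -> dict:
        return {str(lab): int(c) for lab, c in zip(labels, self.membership)}


def walktrap(model: NetworkModel, steps: int = 4) -> CommunityAssignment:
    """Walktrap community detection on the estimated network.

    Random walks require nonnegative weights, so the walk runs on absolute
    edge weights (the convention for signed psychometric networks); the
    resulting dendrogram is cut at maximum modularity. Isolated nodes become
    singleton communities (with a warning).
    """
    w = np.abs(model.weights)
    p = w.shape[0]
    iu, ju = np.triu_indices(p, 1)
    mask = w[iu, ju] > 0
    if not mask.any():
        raise ValueError("walktrap needs at least one edge")
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    g = ig.Graph(n=p, edges=edges)
    g.es["weight"] = w[iu, ju][mask].tolist()
    if min(g.degree()) == 0:
        warnings.warn("isolated node(s) become singleton communities")
    dendrogram = g.community_walktrap(weights="weight", steps=steps)
    clustering = dendrogram.as_clustering()  # cut at maximum modularity
    membership = np.asarray(clustering.membership, dtype=int)
    # relabel contiguously in first-appearance order
    seen: dict[int, int] = {}
    for m in membership:
        if m not in seen:
            seen[m] = len(seen)
    membership = np.array([seen[m] for m in membership], dtype=int)
    q = g.modularity(clustering.membership, weights="weight")
    return CommunityAssignment(
        membership=membership,
        n_communities=len(seen),
        modularity=float(q),
        method=f"walktrap(steps={steps}, abs_weights=True)",
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(
    model: NetworkModel,
    table: TransformedTable | pd.DataFrame | None = None,
    groups=None,
    communities: CommunityAssignment | None = None,
    predictability_mode: str = "neighbors",
) -> pd.DataFrame:
    """Per-node index table: EI, BEI, predictability, z-scores, community.

    ``groups`` drives BEI (default two-instrument split); ``communities``
    (defaulting to a fresh Walktrap run when the network has edges) is
    reported alongside. Predictability requires ``table``; otherwise NaN.
    """
    ei = expected_influence(model)
    bei = bridge_expected_influence(model, groups)
    if communities is None and model.edge_count() > 0:
        communities = walktrap(model)
    comm = communities.membership if communities is not None else np.zeros(model.p, int)
    if table is not None:
        pred = predictability(table, model, mode=predictability_mode)
    else:
        pred = np.full(model.p, np.nan)
    return pd.DataFrame(
        {
            "node": model.labels,
            "expected_influence": ei,
            "bridge_expected_influence": bei,
            "predictability": pred,
            "z_expected_influence": _zscore(ei),
            "z_bridge_expected_influence": _zscore(bei),
            "community": comm,
        }
    )
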