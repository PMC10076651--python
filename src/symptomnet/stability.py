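"""Bootstrap accuracy and stability of the estimated network.

Edge-weight accuracy: nonparametric bootstrap over respondents with full
re-estimation (nonparanormal transform -> correlations -> EBIC glasso) per
resample, summarized by 95% percentile intervals. Bootstrapped difference
tests declare two edges (or two nodes' expected influence) different when
the percentile interval of their bootstrapped difference excludes zero.
Centrality stability: the case-dropping bootstrap drops growing fractions of
respondents, re-estimates, and correlates subset centralities with the
full-sample ones; the correlation-stability (CS) coefficient is the largest
drop fraction at which at least 95% of those correlations stay >= 0.70
(>= 0.25 is considered acceptable, >= 0.50 preferred).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ggm import estimate_network, estimate_weights
from .metrics import bridge_expected_influence, expected_influence, two_group_split
from .simulate import ItemResponseTable

__all__ = [
    "BootstrapSummary",
    "CSResult",
    "bootstrap_edges",
    "difference_test",
    "case_dropping_cs",
]

DEFAULT_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, ItemResponseTable):
        return table.keyed()
    return pd.DataFrame(table)


@dataclass
class BootstrapSummary:
    """Bootstrap replicates of edge weights and node expected influence."""

    labels: list[str]
    point_weights: np.ndarray          # p x p full-sample estimate
    edge_index: list[tuple[int, int]]  # upper-triangle (i, j) pairs
    edge_samples: np.ndarray           # nboot x n_edges
    ei_samples: np.ndarray             # nboot x p
    nboot: int
    seed: int
    n_redrawn: int = 0

    def point_edges(self) -> np.ndarray:
        iu = [i for i, _ in self.edge_index]
        ju = [j for _, j in self.edge_index]
        return self.point_weights[iu, ju]

    def edge_table(self, level: float = 0.95) -> pd.DataFrame:
        """Per-edge point estimate, bootstrap mean and percentile CI."""
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        q = np.percentile(self.edge_samples, [lo, hi], axis=0)
        return pd.DataFrame(
            {
                "node_i": [self.labels[i] for i, _ in self.edge_index],
                "node_j": [self.labels[j] for _, j in self.edge_index],
                "estimate": self.point_edges(),
                "boot_mean": self.edge_samples.mean(axis=0),
                "ci_lower": q[0],
                "ci_upper": q[1],
            }
        )


def bootstrap_edges(
    table,
    nboot: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    npn: bool = True,
    max_redraws: int = 100,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the whole estimation pipeline.

    Respondents are resampled with replacement; each resample is re-estimated
    from scratch. Resamples that produce a constant column are redrawn
    (counted; capped at ``max_redraws``).
    """
    if nboot < 100:
        raise ValueError("nboot must be at least 100")
    if nboot < 1000:
        warnings.warn(f"nboot = {nboot} is low; intervals will be rough")
    df = _as_frame(table)
    n, p = df.shape
    point = estimate_network(df, gamma=gamma, n_lambda=n_lambda, npn=npn)
    iu, ju = np.triu_indices(p, 1)
    edge_index = list(zip(iu.tolist(), ju.tolist()))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    edge_samples = np.empty((nboot, len(edge_index)))
    ei_samples = np.empty((nboot, p))
    redrawn = 0
    X = df.to_numpy()
    for b in range(nboot):
        while True:
            idx = rng.integers(0, n, size=n)
            sub = X[idx]
            if all(len(np.unique(sub[:, j])) > 1 for j in range(p)):
                break
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
        w = estimate_weights(sub, gamma=gamma, n_lambda=n_lambda, npn=npn)
        edge_samples[b] = w[iu, ju]
        ei_samples[b] = expected_influence(w)
    return BootstrapSummary(
        labels=list(df.columns),
        point_weights=point.weights,
        edge_index=edge_index,
        edge_samples=edge_samples,
        ei_samples=ei_samples,
        nboot=nboot,
        seed=seed,
        n_redrawn=redrawn,
    )


def _resolve_edge(summary: BootstrapSummary, edge) -> int:
    i, j = edge
    if isinstance(i, str):
        i = summary.labels.index(i)
    if isinstance(j, str):
        j = summary.labels.index(j)
    i, j = min(i, j), max(i, j)
    return summary.edge_index.index((i, j))


def difference_test(
    summary: BootstrapSummary, a, b, kind: str = "edge", level: float = 0.95
) -> dict:
    """Bootstrapped difference test between two edges or two nodes' EI.

    Significant iff the percentile CI of the bootstrapped difference excludes
    zero. Symmetric: (a, b) and (b, a) always agree.
    """
    if kind == "edge":
        xa = summary.edge_samples[:, _resolve_edge(summary, a)]
        xb = summary.edge_samples[:, _resolve_edge(summary, b)]
    elif kind == "ei":
        ia = summary.labels.index(a) if isinstance(a, str) else int(a)
        ib = summary.labels.index(b) if isinstance(b, str) else int(b)
        xa, xb = summary.ei_samples[:, ia], summary.ei_samples[:, ib]
    else:
        raise ValueError("kind must be 'edge' or 'ei'")
    diff = xa - xb
    lo, hi = np.percentile(diff, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    significant = bool(lo > 0 or hi < 0)
    return {"significant": significant, "ci": (float(lo), float(hi))}


@dataclass
class CSResult:
    """Case-dropping stability of a centrality index."""

    grid: tuple
    correlations: dict = field(default_factory=dict)  # drop fraction -> np.ndarray
    cs_coefficient: float = 0.0
    statistic: str = "ei"
    nboot: int = 0
    seed: int = 0

    def proportion_stable(self, drop: float, floor: float = 0.70) -> float:
        r = self.correlations[drop]
        return float((r >= floor).mean())


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    return float(np.corrcoef(x, y)[0, 1])


def case_dropping_cs(
    table,
    statistic: str = "ei",
    nboot: int = 2000,
    grid=DEFAULT_GRID,
    seed: int = 0,
    groups=None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    npn: bool = True,
    cor_method: str = "pearson",
    cor_floor: float = 0.70,
    coverage: float = 0.95,
) -> CSResult:
    """Case-dropping bootstrap and the correlation-stability coefficient.

    ``nboot`` re-estimations are split evenly over the drop-proportion grid.
    The CS coefficient is the largest grid proportion q such that, at q and
    at every smaller grid proportion, at least ``coverage`` of the subset vs
    full-sample centrality correlations reach ``cor_floor``; 0.0 when even
    the smallest proportion fails. Subsets smaller than the node count are
    skipped with a warning. A degenerate (constant) centrality vector counts
    as correlation 0.
    """
    grid = tuple(sorted(grid))
    if not all(0 < q < 1 for q in grid):
        raise ValueError("grid proportions must lie in (0, 1)")
    df = _as_frame(table)
    n, p = df.shape
    full = estimate_network(df, gamma=gamma, n_lambda=n_lambda, npn=npn)
    if statistic == "ei":
        ref = expected_influence(full)
    elif statistic == "bei":
        if groups is None:
            groups = two_group_split(df.columns)
        ref = bridge_expected_influence(full, groups)
    else:
        raise ValueError("statistic must be 'ei' or 'bei'")
    per_q = max(1, nboot // len(grid))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    X = df.to_numpy()
    result = CSResult(grid=grid, statistic=statistic, nboot=nboot, seed=seed)
    for q in grid:
        keep = int(round(n * (1 - q)))
        if keep < p:
            warnings.warn(f"drop proportion {q}: subsample {keep} < p = {p}, skipped")
            continue
        cors = np.empty(per_q)
        for b in range(per_q):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                w = estimate_weights(X[idx], gamma=gamma, n_lambda=n_lambda, npn=npn)
            except ValueError:  # constant column in subsample
                cors[b] = 0.0
                continue
            if statistic == "ei":
                stat = expected_influence(w)
            else:
                stat = bridge_expected_influence(w, groups)
            cors[b] = _safe_corr(stat, ref, cor_method)
        result.correlations[q] = cors
    cs = 0.0
    for q in grid:
        if q not in result.correlations:
            break
        if result.proportion_stable(q, cor_floor) >= coverage:
            cs = q
        else:
            break
    result.cs_coefficient = cs
    return result
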