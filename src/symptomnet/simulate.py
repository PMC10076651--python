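"""Synthetic ordinal questionnaire data from a known sparse Gaussian graphical model.

Latent responses follow a zero-mean multivariate Gaussian whose precision
matrix has a planted block (community) structure plus a small number of
cross-community "bridge" edges; observed item scores are obtained by
discretizing each latent margin at fixed normal quantiles (a Gaussian copula
with ordinal margins), optionally presenting some items reverse-keyed.

The default :func:`study_config` emulates a burnout + depression item pool:
15 MBI-GS items on a 0-6 scale in three subscale communities (emotional
exhaustion, depersonalization, reduced professional efficacy) and 20 SDS
items on a 1-4 scale in two depression communities, with right-skewed
margins and bridge edges of magnitude 0.07-0.10 connecting the constructs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GeneratorConfig",
    "PrecisionSpec",
    "ItemResponseTable",
    "build_precision",
    "sample_responses",
    "study_config",
    "simulate_dataset",
    "SDS_REVERSE_KEYED",
]

# SDS items worded positively and therefore presented reverse-keyed
# (0-based indices within the 20-item block: D2, D5, D6, D11, D12, D14,
# D16, D17, D18, D20).
SDS_REVERSE_KEYED = frozenset({1, 4, 5, 10, 11, 13, 15, 16, 17, 19})

# Right-skewed default category probabilities: most respondents endorse the
# low end of each item, as is typical for symptom inventories.
MBI_DEFAULT_PROBS = (0.30, 0.25, 0.17, 0.12, 0.08, 0.05, 0.03)
SDS_DEFAULT_PROBS = (0.35, 0.35, 0.20, 0.10)


@dataclass(frozen=True)
class GeneratorConfig:
    """Specification of a planted-network ordinal data generator.

    Parameters
    ----------
    n_respondents
        Number of rows to draw.
    blocks
        Sequence of ``(label, node_count, within_partial)`` triples. Nodes are
        laid out contiguously in block order; every within-block pair receives
        the block's partial correlation.
    bridge_edges
        ``(i, j, partial)`` triples with global node indices spanning two
        distinct blocks.
    item_levels
        Number of ordinal categories per item (length p, each >= 2).
    marginal_probs
        Optional per-item category probabilities (rows summing to 1). ``None``
        entries (or a ``None`` list) mean equiprobable categories.
    min_codes
        Lowest observed code per item (0 for MBI-style items, 1 for SDS-style).
    reverse_keyed
        Indices of items presented reverse-keyed: the observed code is
        ``min + max - latent_code``.
    node_names
        Item labels; defaults to ``X1..Xp``.
    seed
        Seed for all randomness in :func:`sample_responses`.
    """

    n_respondents: int
    blocks: Sequence[tuple[str, int, float]]
    bridge_edges: Sequence[tuple[int, int, float]] = ()
    item_levels: Sequence[int] = ()
    marginal_probs: Sequence[Sequence[float] | None] | None = None
    min_codes: Sequence[int] = ()
    reverse_keyed: frozenset[int] = frozenset()
    node_names: Sequence[str] = ()
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return sum(count for _, count, _ in self.blocks)

    def block_membership(self) -> np.ndarray:
        """Community label per node, in node order."""
        labels = []
        for name, count, _ in self.blocks:
            labels.extend([name] * count)
        return np.asarray(labels, dtype=object)

    def __post_init__(self):
        p = self.n_nodes
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if p == 0:
            raise ValueError("at least one block is required")
        for name, count, r in self.blocks:
            if count <= 0:
                raise ValueError(f"block {name!r} has non-positive node count")
            if not -1 < r < 1:
                raise ValueError(f"block {name!r} within-partial {r} outside (-1, 1)")
        levels = self.item_levels or [7] * p
        if len(levels) != p:
            raise ValueError(f"item_levels length {len(levels)} != p={p}")
        if any(k < 2 for k in levels):
            raise ValueError("every item needs at least 2 categories")
        object.__setattr__(self, "item_levels", tuple(levels))
        mins = self.min_codes or [0] * p
        if len(mins) != p:
            raise ValueError("min_codes length mismatch")
        object.__setattr__(self, "min_codes", tuple(mins))
        names = self.node_names or [f"X{i + 1}" for i in range(p)]
        if len(names) != p or len(set(names)) != p:
            raise ValueError("node_names must be p unique labels")
        object.__setattr__(self, "node_names", tuple(names))
        membership = self.block_membership()
        for i, j, r in self.bridge_edges:
            if not (0 <= i < p and 0 <= j < p) or i == j:
                raise ValueError(f"bridge edge ({i}, {j}) has invalid endpoints")
            if membership[i] == membership[j]:
                raise ValueError(
                    f"bridge edge ({i}, {j}) lies within block {membership[i]!r}"
                )
            if not -1 < r < 1:
                raise ValueError(f"bridge edge ({i}, {j}) partial {r} outside (-1, 1)")
        if self.marginal_probs is not None:
            if len(self.marginal_probs) != p:
                raise ValueError("marginal_probs length mismatch")
            for idx, probs in enumerate(self.marginal_probs):
                if probs is None:
                    continue
                if len(probs) != self.item_levels[idx]:
                    raise ValueError(
                        f"item {idx}: {len(probs)} probabilities for "
                        f"{self.item_levels[idx]} categories"
                    )
                arr = np.asarray(probs, float)
                if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-8):
                    raise ValueError(f"item {idx}: probabilities must sum to 1")
        if any(not 0 <= i < p for i in self.reverse_keyed):
            raise ValueError("reverse_keyed index out of range")


@dataclass(frozen=True)
class PrecisionSpec:
    """A precision matrix and the partial correlations it implies.

    ``true_partials[i, j] = -matrix[i, j] / sqrt(matrix[i, i] * matrix[j, j])``
    with a zero diagonal; these are the edge weights a perfectly estimated
    network would recover.
    """

    matrix: np.ndarray
    true_partials: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "precision": self.matrix.tolist(),
            "true_partials": self.true_partials.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrecisionSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            matrix=np.asarray(payload["precision"], float),
            true_partials=np.asarray(payload["true_partials"], float),
        )


@dataclass
class ItemResponseTable:
    """Respondents x items ordinal matrix with item metadata."""

    responses: pd.DataFrame
    items: pd.DataFrame  # columns: item, scale, community, levels, min_code, reverse

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def keyed(self) -> pd.DataFrame:
        """Responses with reverse-keyed items recoded to the symptom direction.

        The recode ``x -> min + max - x`` is an involution: keying a keyed
        table restores the original codes.
        """
        out = self.responses.copy()
        for _, row in self.items.iterrows():
            if row["reverse"]:
                lo = row["min_code"]
                hi = lo + row["levels"] - 1
                out[row["item"]] = lo + hi - out[row["item"]]
        return out

    def to_csv(self, path: str | Path) -> None:
        self.responses.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, items: pd.DataFrame | None = None
    ) -> "ItemResponseTable":
        df = pd.read_csv(path)
        if items is None:
            items = infer_item_metadata(df)
        return cls(responses=df, items=items)


def infer_item_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Item metadata from MBI-*/D* column-name conventions.

    MBI items: 7 levels coded 0-6, never reverse-keyed. D items: 4 levels
    coded 1-4, the 10 positively-worded ones reverse-keyed. Other columns are
    treated as generic items spanning their observed range.
    """
    rows = []
    for col in df.columns:
        if col.startswith("MBI-"):
            idx = int(col.split("-")[1])
            community = "EE" if idx <= 5 else ("DP" if idx <= 9 else "RPE")
            rows.append((col, "MBI", community, 7, 0, False))
        elif col.startswith("D") and col[1:].isdigit():
            idx = int(col[1:]) - 1
            rows.append((col, "SDS", "SDS", 4, 1, idx in SDS_REVERSE_KEYED))
        else:
            lo, hi = int(df[col].min()), int(df[col].max())
            rows.append((col, "GEN", "GEN", hi - lo + 1, lo, False))
    return pd.DataFrame(
        rows, columns=["item", "scale", "community", "levels", "min_code", "reverse"]
    )


def build_precision(config: GeneratorConfig) -> PrecisionSpec:
    """Assemble the block-plus-bridges precision matrix.

    Unit diagonal; within-block and bridge off-diagonals are the negated
    requested partial correlations (so the implied partials equal the request
    exactly); all other off-diagonals are exactly zero. Rejects constructions
    whose smallest eigenvalue is not positive, naming the most overloaded
    block or bridge endpoint in the diagnostic.
    """
    p = config.n_nodes
    theta = np.eye(p)
    start = 0
    for name, count, r in config.blocks:
        stop = start + count
        theta[start:stop, start:stop] = -r
        start = stop
    np.fill_diagonal(theta, 1.0)
    for i, j, r in config.bridge_edges:
        theta[i, j] = theta[j, i] = -r

    eigmin = float(np.linalg.eigvalsh(theta).min())
    if eigmin <= 0:
        # point at the row furthest from diagonal dominance
        loads = np.abs(theta).sum(axis=1) - 1.0
        worst = int(np.argmax(loads))
        membership = config.block_membership()
        raise ValueError(
            f"requested precision is not positive definite (min eigenvalue "
            f"{eigmin:.4g}); node {worst} in block {membership[worst]!r} carries "
            f"off-diagonal mass {loads[worst]:.3f} >= 1"
        )

    d = np.sqrt(np.diag(theta))
    partials = -theta / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return PrecisionSpec(matrix=theta, true_partials=partials)


def _thresholds(probs: np.ndarray) -> np.ndarray:
    """Standard-normal cut points partitioning the line per category mass."""
    cum = np.cumsum(probs)[:-1]
    if (np.diff(np.concatenate([[0.0], cum, [1.0]])) <= 0).any():
        warnings.warn(
            "degenerate thresholds: zero-probability category merged with its "
            "neighbor",
            stacklevel=3,
        )
    return norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def sample_responses(spec: PrecisionSpec, config: GeneratorConfig) -> ItemResponseTable:
    """Draw ordinal responses from the latent Gaussian copula.

    Latent vectors are N(0, Theta^-1) standardized to unit margins, each
    margin discretized at the normal quantiles of its cumulative category
    probabilities, shifted to the item's coding range, and reverse-keyed where
    flagged. Fully reproducible from ``config.seed``.
    """
    p = spec.n_nodes
    cov = spec.covariance()
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((config.n_respondents, p)) @ chol.T

    data = np.empty((config.n_respondents, p), dtype=np.int64)
    for idx in range(p):
        k = config.item_levels[idx]
        probs = None
        if config.marginal_probs is not None:
            probs = config.marginal_probs[idx]
        probs = np.full(k, 1.0 / k) if probs is None else np.asarray(probs, float)
        cuts = _thresholds(probs)
        codes = np.searchsorted(cuts, latent[:, idx]) + config.min_codes[idx]
        if idx in config.reverse_keyed:
            lo = config.min_codes[idx]
            hi = lo + k - 1
            codes = lo + hi - codes
        data[:, idx] = codes

    df = pd.DataFrame(data, columns=list(config.node_names))
    membership = config.block_membership()
    items = pd.DataFrame(
        {
            "item": list(config.node_names),
            "scale": [
                "MBI" if str(n).startswith("MBI") else ("SDS" if str(n).startswith("D") else "GEN")
                for n in config.node_names
            ],
            "community": membership,
            "levels": list(config.item_levels),
            "min_code": list(config.min_codes),
            "reverse": [i in config.reverse_keyed for i in range(p)],
        }
    )
    return ItemResponseTable(responses=df, items=items)


def study_config(
    n_respondents: int = 1322,
    seed: int = 0,
    within: Sequence[float] = (0.20, 0.22, 0.18, 0.10, 0.10),
    bridge_weights: Sequence[float] = (0.10, 0.07, 0.07),
) -> GeneratorConfig:
    """Default 35-node, 5-community burnout + depression generator.

    Blocks mirror the instrument structure: EE (MBI-1..5), DP (MBI-6..9),
    RPE (MBI-10..15), and two 10-item depression clusters (D1..D10, D11..D20).
    Within-block partial correlations are strong for the small MBI subscales
    and weaker for the 10-item depression clusters (any larger and the
    precision matrix could not stay positive definite, mirroring how dense
    real symptom clusters behave). Bridge edges connect a depression item to
    an MBI item in each of RPE, RPE and DP, with the cross-construct
    magnitudes seen in sparse empirical burnout-depression networks
    (0.07-0.10). Default sample size matches a large single-site survey
    (n = 1,322).
    """
    names = [f"MBI-{i}" for i in range(1, 16)] + [f"D{i}" for i in range(1, 21)]
    blocks = [
        ("EE", 5, within[0]),
        ("DP", 4, within[1]),
        ("RPE", 6, within[2]),
        ("DEP1", 10, within[3]),
        ("DEP2", 10, within[4]),
    ]
    # D17 (index 31) - MBI-14 (13); D14 (28) - MBI-13 (12); D1 (15) - MBI-7 (6)
    bridges = [
        (31, 13, bridge_weights[0]),
        (28, 12, bridge_weights[1]),
        (15, 6, bridge_weights[2]),
    ]
    levels = [7] * 15 + [4] * 20
    probs: list[Sequence[float] | None] = [MBI_DEFAULT_PROBS] * 15 + [SDS_DEFAULT_PROBS] * 20
    mins = [0] * 15 + [1] * 20
    reverse = frozenset(15 + i for i in SDS_REVERSE_KEYED)
    return GeneratorConfig(
        n_respondents=n_respondents,
        blocks=blocks,
        bridge_edges=bridges,
        item_levels=levels,
        marginal_probs=probs,
        min_codes=mins,
        reverse_keyed=reverse,
        node_names=names,
        seed=seed,
    )


def simulate_dataset(config: GeneratorConfig) -> tuple[ItemResponseTable, PrecisionSpec]:
    """Convenience: build the precision spec and sample a table in one call."""
    spec = build_precision(config)
    return sample_responses(spec, config), spec
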