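"""Normalization and redundancy screening ahead of network estimation.

Skewed ordinal items are mapped to approximately standard-normal margins by
the nonparanormal (Gaussian copula) transform: a winsorized empirical CDF
followed by the standard-normal quantile function. Redundant item pairs are
screened in the goldbricker style: two items are candidate duplicates when
they are strongly correlated yet their correlation profiles with every other
item are statistically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .simulate import ItemResponseTable

__all__ = [
    "TransformedTable",
    "RedundancyReport",
    "npn_transform",
    "find_redundant_pairs",
    "steiger_dependent_corr_test",
]


@dataclass
class TransformedTable:
    """Columns mapped to approximately standard-normal margins.

    Each column is a monotone (mid-rank) transform of its source column, so
    rank order — and equality of tied values — is preserved.
    """

    values: pd.DataFrame
    winsor_bound: float

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, ItemResponseTable):
        return table.keyed()
    if isinstance(table, TransformedTable):
        return table.values
    return pd.DataFrame(table)


def npn_transform(table) -> TransformedTable:
    """Nonparanormal transform with the shrunken (winsorized) ECDF.

    Mid-ranks give the ECDF value ``r_i / n``, winsorized into
    ``[delta_n, 1 - delta_n]`` with ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))``
    before applying the normal quantile function; each column is then
    standardized to mean 0, SD 1. Accepts an ItemResponseTable (reverse-keyed
    items are recoded to the symptom direction first) or any DataFrame/array.
    """
    df = _as_frame(table)
    n = len(df)
    if n < 10:
        raise ValueError(f"nonparanormal transform needs n >= 10, got {n}")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    z = npn_transform_array(df.to_numpy(float))
    return TransformedTable(
        values=pd.DataFrame(z, columns=df.columns), winsor_bound=float(delta)
    )


def npn_transform_array(X: np.ndarray) -> np.ndarray:
    """Array-level nonparanormal transform (same math as :func:`npn_transform`).

    Used inside resampling loops where DataFrame bookkeeping would dominate
    the runtime.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"nonparanormal transform needs n >= 10, got {n}")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant column")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    u = np.clip(rankdata(X, method="average", axis=0) / n, delta, 1.0 - delta)
    z = norm.ppf(u)
    return (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)


def steiger_dependent_corr_test(
    r_ik: float, r_jk: float, r_ij: float, n: int
) -> tuple[float, float]:
    """Two-sided test of H0: rho(i,k) = rho(j,k) for overlapping correlations.

    Steiger's z with the Hittner modification: both correlations are
    Fisher-transformed and their covariance term uses the back-transformed
    mean correlation. Returns (z, p).
    """
    if n < 4:
        raise ValueError("dependent-correlation test needs n >= 4")
    r_ik = float(np.clip(r_ik, -1 + 1e-12, 1 - 1e-12))
    r_jk = float(np.clip(r_jk, -1 + 1e-12, 1 - 1e-12))
    if r_ik == r_jk:
        return 0.0, 1.0
    z_ik, z_jk = np.arctanh(r_ik), np.arctanh(r_jk)
    rm = np.tanh((z_ik + z_jk) / 2.0)
    cov = (r_ij * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r_ij**2)) / (
        (1 - rm**2) ** 2
    )
    cov = min(cov, 1.0 - 1e-10)
    z = (z_ik - z_jk) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class RedundancyReport:
    """Item pairs whose correlation profiles are statistically interchangeable.

    ``flagged`` holds ``(item_i, item_j, proportion)`` where proportion is the
    share of third-party items k for which cor(i,k) and cor(j,k) differ
    significantly; a pair is flagged when that share falls below ``threshold``
    (and the pair itself correlates at least ``cor_min``).
    """

    flagged: list = field(default_factory=list)
    proportions: dict = field(default_factory=dict)
    threshold: float = 0.25
    alpha: float = 0.05
    cor_min: float = 0.5
    n: int = 0

    def flagged_pairs(self) -> list[tuple[str, str]]:
        return [(i, j) for i, j, _ in self.flagged]


def find_redundant_pairs(
    table,
    threshold: float = 0.25,
    alpha: float = 0.05,
    cor_min: float = 0.5,
) -> RedundancyReport:
    """Goldbricker-style redundancy screen.

    For every candidate pair (i, j) with |cor(i, j)| >= ``cor_min``, tests for
    each remaining item k whether cor(i, k) differs from cor(j, k)
    (Steiger/Hittner dependent-correlation z, two-sided at ``alpha``); the
    pair is reported as redundant when fewer than ``threshold`` of these
    comparisons are significant. Flagging is symmetric in (i, j) and
    unaffected by column order. Pairs are reported, never dropped.
    """
    df = _as_frame(table)
    p = df.shape[1]
    n = len(df)
    if p < 3:
        raise ValueError("redundancy screening needs at least 3 items")
    if n < 20:
        raise ValueError(f"n = {n} too small for dependent-correlation tests")
    cols = list(df.columns)
    R = np.corrcoef(df.to_numpy(float).T)
    report = RedundancyReport(
        threshold=threshold, alpha=alpha, cor_min=cor_min, n=n
    )
    for a, b in combinations(range(p), 2):
        if abs(R[a, b]) < cor_min:
            continue
        others = [k for k in range(p) if k not in (a, b)]
        n_sig = 0
        for k in others:
            _, pval = steiger_dependent_corr_test(R[a, k], R[b, k], R[a, b], n)
            if pval < alpha:
                n_sig += 1
        prop = n_sig / len(others)
        report.proportions[(cols[a], cols[b])] = prop
        if prop < threshold:
            report.flagged.append((cols[a], cols[b], prop))
    return report
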