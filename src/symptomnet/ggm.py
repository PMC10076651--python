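"""Sparse Gaussian graphical model estimation with EBIC penalty selection.

The network's nodes are questionnaire items; edges are regularized partial
correlations. Estimation follows the standard EBIC-glasso recipe: a
product-moment correlation matrix of the (nonparanormal-transformed) items is
fed to the graphical lasso along a descending penalty path, and the model
minimizing the extended BIC

    EBIC(Theta) = -2 loglik(Theta; S, n) + E log n + 4 gamma E log p

is retained, where E counts nonzero upper-triangle edges and gamma (default
0.5) penalizes dense solutions in high dimensions. The precision matrix Theta
converts to edge weights via w_ij = -Theta_ij / sqrt(Theta_ii Theta_jj).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.covariance._graph_lasso import _graphical_lasso as _sk_glasso_path_step

from .preprocess import TransformedTable, npn_transform

__all__ = [
    "CorrelationMatrix",
    "NetworkModel",
    "correlation",
    "glasso",
    "ebic",
    "ebic_select",
    "estimate_network",
    "precision_to_partials",
    "GlassoError",
]

#: magnitude below which a converted partial correlation counts as an absent edge
ZERO_EDGE_TOL = 1e-8


class GlassoError(RuntimeError):
    pass


class GlassoConvergenceWarning(UserWarning):
    """The coordinate-descent sweep limit was reached at a given penalty."""


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    n: int
    labels: list[str]
    eigenvalue_floored: bool = False

    @property
    def p(self) -> int:
        return self.values.shape[0]


def correlation(table: TransformedTable | pd.DataFrame) -> CorrelationMatrix:
    """Product-moment correlations of the (transformed) columns.

    The result is forced symmetric with an exact unit diagonal; if sampling
    noise leaves it indefinite, negative eigenvalues are floored at 1e-10 and
    the matrix rescaled back to unit diagonal (recorded in the output).
    """
    df = table.values if isinstance(table, TransformedTable) else pd.DataFrame(table)
    n, p = df.shape
    if n <= p:
        warnings.warn(f"n = {n} <= p = {p}: correlations are poorly determined")
    R = np.corrcoef(df.to_numpy(float).T)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    floored = False
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < 0:
        w, V = np.linalg.eigh(R)
        R = (V * np.clip(w, 1e-10, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        floored = True
    return CorrelationMatrix(values=R, n=n, labels=list(df.columns), eigenvalue_floored=floored)


def glasso(
    S: CorrelationMatrix | np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """L1-penalized precision estimate at a single penalty.

    Maximizes ``log det Theta - tr(S Theta) - lam * sum_{i != j} |Theta_ij|``
    (the diagonal is unpenalized). At ``lam = 0`` this is plain maximum
    likelihood, i.e. the inverse of S.
    """
    Sm = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0:
        return np.linalg.inv(Sm)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _, precision = _sk_glasso(Sm, alpha=float(lam), tol=tol, max_iter=max_iter)
    except FloatingPointError as err:  # pragma: no cover - pathological input
        raise GlassoError(f"graphical lasso failed to converge at lam={lam}: {err}")
    for w in caught:
        if "did not converge" in str(w.message):
            warnings.warn(
                f"glasso sweep limit ({max_iter}) reached at lam={lam:.4g}; "
                f"{w.message}",
                GlassoConvergenceWarning,
                stacklevel=2,
            )
        else:
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    return precision


def precision_to_partials(theta: np.ndarray, zero_tol: float = ZERO_EDGE_TOL) -> np.ndarray:
    """Partial correlations implied by a precision matrix.

    ``w_ij = -theta_ij / sqrt(theta_ii * theta_jj)``; the diagonal is zero and
    magnitudes below ``zero_tol`` are snapped to exact zeros so float noise
    cannot masquerade as edges. Signs of surviving entries mirror the (negated)
    precision pattern exactly.
    """
    d = np.sqrt(np.diag(theta))
    w = -theta / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) < zero_tol] = 0.0
    return (w + w.T) / 2.0


def ebic(theta: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a fitted precision matrix."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    loglik = (n / 2.0) * (logdet - np.trace(S @ theta))
    w = precision_to_partials(theta)
    E = int(np.count_nonzero(np.triu(w, 1)))
    p = theta.shape[0]
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


@dataclass
class NetworkModel:
    """An estimated partial-correlation network.

    ``weights`` is symmetric with a zero diagonal; exact zeros are absent
    edges. Fit metadata records the penalty path and EBIC values behind the
    selection.
    """

    weights: np.ndarray
    precision: np.ndarray
    labels: list[str]
    lambda_selected: float
    gamma: float
    lambda_path: np.ndarray
    ebic_path: np.ndarray
    n: int = 0

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_potential_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def density(self) -> float:
        return self.edge_count() / self.n_potential_edges

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges sorted by |weight| descending."""
        iu, ju = np.triu_indices(self.p, 1)
        mask = self.weights[iu, ju] != 0
        df = pd.DataFrame(
            {
                "node_i": [self.labels[i] for i in iu[mask]],
                "node_j": [self.labels[j] for j in ju[mask]],
                "weight": self.weights[iu, ju][mask],
            }
        )
        return df.reindex(df["weight"].abs().sort_values(ascending=False).index).reset_index(
            drop=True
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "weights": self.weights.tolist(),
            "precision": self.precision.tolist(),
            "lambda_selected": self.lambda_selected,
            "gamma": self.gamma,
            "lambda_path": np.asarray(self.lambda_path).tolist(),
            "ebic_path": np.asarray(self.ebic_path).tolist(),
            "n": self.n,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"], float),
            precision=np.asarray(d["precision"], float),
            labels=list(d["labels"]),
            lambda_selected=float(d["lambda_selected"]),
            gamma=float(d["gamma"]),
            lambda_path=np.asarray(d["lambda_path"], float),
            ebic_path=np.asarray(d["ebic_path"], float),
            n=int(d["n"]),
        )


def _glasso_warm_path(
    S: np.ndarray, lambdas: np.ndarray, tol: float = 1e-4, max_iter: int = 200
) -> list[np.ndarray]:
    """Precision estimates along a descending penalty path.

    Each fit is warm-started from the previous covariance estimate, which is
    what makes long paths affordable; solutions match cold starts to solver
    tolerance. Convergence shortfalls are aggregated into one warning.
    """
    precisions = []
    cov_init = None
    stalled: list[float] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for lam in lambdas:
            n_before = len(caught)
            cov, prec, *_ = _sk_glasso_path_step(
                S,
                alpha=float(lam),
                cov_init=cov_init,
                mode="cd",
                tol=tol,
                enet_tol=tol,
                max_iter=max_iter,
                verbose=False,
                eps=np.finfo(np.float64).eps,
            )
            if any("did not converge" in str(w.message) for w in caught[n_before:]):
                stalled.append(float(lam))
            cov_init = cov
            precisions.append(prec)
    if stalled:
        warnings.warn(
            f"glasso sweep limit ({max_iter}) reached at {len(stalled)} "
            f"penalties (smallest lam={min(stalled):.4g}); EBIC selection is "
            "unaffected unless the minimum sits there",
            GlassoConvergenceWarning,
            stacklevel=2,
        )
    return precisions


def lambda_path_for(S: np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down to min_ratio * lambda_max."""
    p = S.shape[0]
    lam_max = float(np.abs(S - np.diag(np.diag(S))).max())
    if lam_max <= 0:
        return np.array([])
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def ebic_select(
    S: CorrelationMatrix,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    labels: list[str] | None = None,
) -> NetworkModel:
    """Fit the glasso path and return the EBIC-minimizing network.

    A degenerate path (identity correlation matrix, hence lambda_max = 0)
    returns the empty network with a warning.
    """
    Sm = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    n = n if n is not None else (S.n if isinstance(S, CorrelationMatrix) else None)
    if n is None:
        raise ValueError("sample size n is required")
    labels = labels or (
        S.labels if isinstance(S, CorrelationMatrix) else [f"X{i+1}" for i in range(Sm.shape[0])]
    )
    path = lambda_path_for(Sm, n_lambda, lambda_min_ratio)
    if path.size == 0:
        warnings.warn("all off-diagonal correlations are zero: returning empty network")
        p = Sm.shape[0]
        return NetworkModel(
            weights=np.zeros((p, p)),
            precision=np.eye(p),
            labels=labels,
            lambda_selected=0.0,
            gamma=gamma,
            lambda_path=path,
            ebic_path=np.array([]),
            n=n,
        )
    if path.size < 2:
        raise ValueError("penalty path needs at least 2 values")
    thetas = _glasso_warm_path(Sm, path)
    ebics = np.array([ebic(theta, Sm, n, gamma) for theta in thetas])
    best = int(np.argmin(ebics))
    theta = thetas[best]
    return NetworkModel(
        weights=precision_to_partials(theta),
        precision=theta,
        labels=list(labels),
        lambda_selected=float(path[best]),
        gamma=gamma,
        lambda_path=path,
        ebic_path=ebics,
        n=n,
    )


def estimate_weights(
    X: np.ndarray,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    npn: bool = True,
) -> np.ndarray:
    """Array-level shortcut returning only the selected weight matrix.

    Same estimator as :func:`estimate_network` (nonparanormal transform,
    correlations, warm-started glasso path, EBIC selection) minus the
    metadata; intended for bootstrap and permutation loops.
    """
    from .preprocess import npn_transform_array

    X = np.asarray(X, float)
    if npn:
        X = npn_transform_array(X)
    n = n if n is not None else X.shape[0]
    R = np.corrcoef(X.T)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    path = lambda_path_for(R, n_lambda, lambda_min_ratio)
    if path.size == 0:
        return np.zeros_like(R)
    thetas = _glasso_warm_path(R, path)
    ebics = np.array([ebic(theta, R, n, gamma) for theta in thetas])
    return precision_to_partials(thetas[int(np.argmin(ebics))])


def estimate_network(
    table,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    npn: bool = True,
) -> NetworkModel:
    """One-call estimation: (optional) nonparanormal transform -> correlations
    -> EBIC-selected glasso. ``table`` may be an ItemResponseTable (keyed
    automatically), a raw DataFrame, or an already transformed table."""
    transformed = npn_transform(table) if npn else table
    S = correlation(transformed)
    return ebic_select(
        S, gamma=gamma, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio
    )
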