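"""Weighted undirected association matrices from cleaned node time series.

Two estimators are provided: full Pearson correlation and pairwise partial
correlation.  Partial correlations condition each node pair on all remaining
nodes via the precision (inverse covariance) matrix,

    rho_ij = -P_ij / sqrt(P_ii * P_jj),

which makes network topology less sensitive to global confounds such as
residual motion.  With many nodes and few volumes (e.g. 160 nodes, ~200
volumes) the sample covariance is near-singular, so the default regularises
it with Ledoit-Wolf analytic shrinkage toward a scaled-identity target; a
fixed shrinkage intensity toward the covariance diagonal is also available.
The chosen intensity is recorded on the returned matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.covariance import ledoit_wolf

from .preprocess import TimeSeriesMatrix

__all__ = ["ConnectivityMatrix", "pearson_matrix", "partial_correlation_matrix"]


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted node x node association matrix with zero diagonal.

    The diagonal is set to exactly 0 (not 1) so that proportional
    thresholding never selects self-connections.
    """

    values: np.ndarray
    method: str  # "partial" or "pearson"
    node_ids: Sequence[str]
    shrinkage: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 0):
            raise ValueError("diagonal must be exactly zero")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        self.values = v
        self.node_ids = list(map(str, self.node_ids))
        if len(self.node_ids) != v.shape[0]:
            raise ValueError("node_ids length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _check_variance(values: np.ndarray, node_ids: Sequence[str]) -> None:
    sd = values.std(axis=1)
    bad = np.where(sd <= 0)[0]
    if bad.size:
        names = ", ".join(str(node_ids[i]) for i in bad[:5])
        raise ValueError(f"zero-variance node series: {names}")


def pearson_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Full (marginal) product-moment correlation between all node pairs."""
    _check_variance(ts.values, ts.node_ids)
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, method="pearson", node_ids=ts.node_ids)


def partial_correlation_matrix(ts: TimeSeriesMatrix,
                               shrinkage: float | str = "auto",
                               ) -> ConnectivityMatrix:
    """Pairwise partial correlations conditioned on all remaining nodes.

    Parameters
    ----------
    shrinkage : "auto" or float in [0, 1]
        ``"auto"`` selects the Ledoit-Wolf analytic intensity toward a
        scaled-identity target (deterministic, parameter-free).  A float s
        shrinks toward the covariance diagonal:
        ``(1 - s) * S + s * diag(S)``.  ``0`` uses the raw sample covariance
        and fails with guidance if it is singular.
    """
    if ts.n_time <= 3:
        raise ValueError("need more than 3 time points for partial correlation")
    _check_variance(ts.values, ts.node_ids)
    X = ts.values.T  # samples x features
    if shrinkage == "auto":
        cov, s = ledoit_wolf(X, assume_centered=False)
        used = float(s)
    else:
        s = float(shrinkage)
        if not 0 <= s <= 1:
            raise ValueError("shrinkage must be in [0, 1] or 'auto'")
        sample = np.cov(ts.values)
        cov = (1 - s) * sample + s * np.diag(np.diag(sample))
        used = s
    if used == 0 and (ts.n_time <= ts.n_nodes
                      or np.linalg.cond(cov) > 1e12):
        raise np.linalg.LinAlgError(
            "covariance matrix is singular or near-singular; enable "
            "shrinkage (shrinkage='auto' or a value in (0, 1])")
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.abs(np.diag(prec)))
    rho = -prec / np.outer(d, d)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 0.0)
    return ConnectivityMatrix(rho, method="partial", node_ids=ts.node_ids,
                              shrinkage=used)
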