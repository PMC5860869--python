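"""Full and Tikhonov-regularised partial correlation network matrices.

A netmat summarises the temporal dependence between K node timeseries: the
full netmat is the Pearson correlation matrix; the partial netmat is obtained
by inverting the ridge-regularised correlation matrix ``R + rho*I`` and
normalising, which suppresses indirect (chained) dependence.  Applying the
ridge to the *correlation* (not covariance) matrix makes rho scale-free,
consistent with the small values (0.01-0.5) over which it is optimised.
Fisher z (atanh) is applied to edges before cross-subject comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import NodeTimeseries

__all__ = [
    "Netmat",
    "full_netmat",
    "partial_netmat",
    "optimise_rho",
    "fisher_z",
    "vectorise_edges",
]

RHO_GRID = np.round(np.arange(0.01, 0.501, 0.01), 2)


@dataclass
class Netmat:
    """K x K network matrix with estimation metadata."""

    values: np.ndarray
    kind: str  # "full" | "partial"
    z_transformed: bool = False
    rho: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("netmat must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("netmat must be symmetric")
        if not np.isfinite(V[~np.eye(V.shape[0], dtype=bool)]).all():
            raise ValueError("netmat off-diagonals must be finite")
        if self.kind not in ("full", "partial"):
            raise ValueError("kind must be 'full' or 'partial'")
        if self.kind == "full" and not self.z_transformed:
            if not np.allclose(np.diag(V), 1.0, atol=1e-8):
                raise ValueError("full correlation netmat must have unit diagonal")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def vectorise_edges(values: np.ndarray) -> np.ndarray:
    """Upper-triangle, row-major vectorisation of the off-diagonal edges."""
    values = np.asarray(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _corr_from_ts(ts: NodeTimeseries) -> np.ndarray:
    X = ts.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance timeseries for node {dead[0]}")
    return np.corrcoef(X, rowvar=False)


def full_netmat(ts: NodeTimeseries) -> Netmat:
    """Pearson full correlation netmat of the node timeseries."""
    return Netmat(values=_corr_from_ts(ts), kind="full")


def partial_netmat(ts: NodeTimeseries, rho: float = 0.01) -> Netmat:
    """Tikhonov-regularised partial correlation netmat.

    ``Omega = (R + rho*I)^-1``; edge ``p_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)``,
    diagonal set to 0.
    """
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    R = _corr_from_ts(ts)
    K = R.shape[0]
    try:
        Omega = np.linalg.inv(R + rho * np.eye(K))
    except np.linalg.LinAlgError as e:  # only possible at rho == 0
        raise ValueError("correlation matrix is singular; use rho > 0") from e
    d = np.sqrt(np.diag(Omega))
    P = -Omega / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return Netmat(values=0.5 * (P + P.T), kind="partial", rho=float(rho))


def fisher_z(net: Netmat, cap: float = 1.0 - 1e-12) -> Netmat:
    """Fisher r-to-z (atanh) transform of the off-diagonal edges; diagonal zeroed."""
    V = net.values.copy()
    off = ~np.eye(V.shape[0], dtype=bool)
    if np.any(np.abs(V[off]) >= 1.0):
        i, j = np.argwhere((np.abs(V) >= 1.0) & off)[0]
        raise ValueError(f"|r| >= 1 at edge ({i}, {j}); cannot z-transform")
    V[off] = np.arctanh(np.clip(V[off], -cap, cap))
    np.fill_diagonal(V, 0.0)
    return Netmat(values=V, kind=net.kind, z_transformed=True, rho=net.rho)


def optimise_rho(subject_ts: list[NodeTimeseries], grid: np.ndarray = RHO_GRID) -> float:
    """Pick the ridge rho maximising subject-to-group netmat similarity.

    The reference is the group-average z-transformed partial netmat at
    rho=0.01.  For each candidate rho the mean (over subjects) correlation
    between the vectorised subject netmat at that rho and the reference is
    computed; the argmax is returned, ties resolved towards the smallest rho.
    """
    if len(subject_ts) < 2:
        raise ValueError("need at least 2 subjects to optimise rho")
    ref_edges = np.mean(
        [vectorise_edges(fisher_z(partial_netmat(ts, 0.01)).values) for ts in subject_ts],
        axis=0,
    )
    best_rho, best_score = None, -np.inf
    for rho in np.asarray(grid, dtype=float):
        scores = []
        for ts in subject_ts:
            edges = vectorise_edges(fisher_z(partial_netmat(ts, rho)).values)
            scores.append(np.corrcoef(edges, ref_edges)[0, 1])
        score = float(np.mean(scores))
        if score > best_score + 1e-12:  # strict improvement; ties keep smaller rho
            best_rho, best_score = float(rho), score
    return best_rho
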