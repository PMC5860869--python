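"""Node timeseries, subject maps and amplitudes from voxelwise data.

Two extraction routes are supported, mirroring common practice with soft
(overlapping, weighted) versus hard (binary, non-overlapping) parcellations:

* dual regression — stage 1 spatially regresses a set of group maps into each
  timepoint of the data to obtain node timeseries; stage 2 temporally
  regresses those timeseries into each grayordinate's timecourse to obtain
  subject-specific spatial maps;
* parcel masking — the mean timeseries over all grayordinates in each binary
  parcel.

Node amplitudes are the temporal standard deviation of the stage-1 (or
parcel) timeseries.  A task-derived spatial basis is also provided: spatial
ICA on concatenated group-averaged task contrasts yields mixing weights that
are applied identically to every subject's contrasts, giving corresponding
group and subject basis maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_cohort import Parcellation

__all__ = [
    "NodeTimeseries",
    "SubjectMapSet",
    "dual_regression",
    "parcel_timeseries",
    "node_amplitudes",
    "task_basis_maps",
]


@dataclass
class NodeTimeseries:
    """T x K node timeseries (time-major) with run boundary offsets."""

    values: np.ndarray
    run_offsets: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("node timeseries must be 2-D (T x K)")
        if np.isnan(self.values).any():
            raise ValueError("node timeseries contain NaN")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectMapSet:
    """G x K subject spatial maps from dual-regression stage 2."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("subject maps must be 2-D (G x K)")


def dual_regression(
    data: np.ndarray,
    maps: np.ndarray,
    variance_normalise_stage1: bool = True,
) -> tuple[NodeTimeseries, SubjectMapSet]:
    """Two-stage least-squares mapping of group maps onto subject data.

    Stage 1 demeans each map column and each timepoint's data vector across
    grayordinates and solves ``data ~ maps`` for a T x K timeseries.  Stage 2
    (optionally variance-normalising the stage-1 series first) demeans across
    time and solves ``data.T ~ timeseries`` for G x K subject maps.
    """
    data = np.asarray(data, dtype=float)
    maps = np.asarray(maps, dtype=float)
    G, T = data.shape
    Gm, K = maps.shape
    if Gm != G:
        raise ValueError(f"maps have {Gm} grayordinates, data has {G}")
    if G <= K or T <= K:
        raise ValueError("need G > K and T > K for dual regression")
    X = maps - maps.mean(axis=0)
    rank = np.linalg.matrix_rank(X)
    if rank < K:
        # identify offending columns for the error message
        _, R = np.linalg.qr(X)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max())
        raise ValueError(f"group maps are rank deficient (collinear columns: {bad.tolist()})")
    Yd = data - data.mean(axis=0)
    ts = np.linalg.lstsq(X, Yd, rcond=None)[0].T  # (T, K)

    ts2 = ts.copy()
    if variance_normalise_stage1:
        sd = ts2.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        ts2 = ts2 / sd
    ts2 = ts2 - ts2.mean(axis=0)
    data_dm = data - data.mean(axis=1, keepdims=True)
    maps2 = np.linalg.lstsq(ts2, data_dm.T, rcond=None)[0].T  # (G, K)
    return NodeTimeseries(values=ts), SubjectMapSet(values=maps2)


def parcel_timeseries(data: np.ndarray, parcellation: Parcellation) -> NodeTimeseries:
    """Mean timeseries over the grayordinates of each binary parcel."""
    data = np.asarray(data, dtype=float)
    labels = parcellation.labels
    if labels.shape[0] != data.shape[0]:
        raise ValueError("parcellation length must match grayordinate count")
    K = parcellation.n_parcels
    out = np.empty((data.shape[1], K))
    for k in range(1, K + 1):
        idx = labels == k
        if not idx.any():
            raise ValueError(f"parcel {k} is empty")
        out[:, k - 1] = data[idx].mean(axis=0)
    return NodeTimeseries(values=out)


def node_amplitudes(ts: NodeTimeseries) -> np.ndarray:
    """Per-node temporal standard deviation (runs concatenated)."""
    if ts.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    return ts.values.std(axis=0, ddof=1)


def _fastica_weights(X: np.ndarray, d: int, seed: int = 0, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Symmetric fixed-point ICA (negentropy, tanh nonlinearity) unmixing.

    ``X`` is components-will-be-found-along-rows (n_c x G).  Returns the d x n_c
    matrix mapping the original rows to d independent components.  PCA
    whitening first; deterministic given the seed.
    """
    n_c, G = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-12 * s[0]
    U, s = U[:, keep][:, :d], s[keep][:d]
    if U.shape[1] < d:
        raise ValueError("contrast maps have rank below the requested dimensionality")
    Kw = (U / s).T * np.sqrt(G)  # (d, n_c) whitening
    Z = Kw @ Xc  # (d, G) white
    rng = np.random.default_rng(seed)
    W = np.linalg.qr(rng.standard_normal((d, d)))[0]
    for _ in range(max_iter):
        WZ = W @ Z
        gwz = np.tanh(WZ)
        g_prime = (1.0 - gwz**2).mean(axis=1)
        W_new = (gwz @ Z.T) / G - g_prime[:, None] * W
        # symmetric decorrelation
        u, _, vt = np.linalg.svd(W_new)
        W_new = u @ vt
        if np.max(np.abs(np.abs(np.sum(W_new * W, axis=1)) - 1.0)) < tol:
            W = W_new
            break
        W = W_new
    return W @ Kw  # (d, n_c)


def task_basis_maps(
    group_contrasts: np.ndarray,
    subject_contrasts: list[np.ndarray],
    d: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Task-derived spatial basis via spatial ICA on group-averaged contrasts.

    ICA on the group contrasts (n_c x G) yields d x n_c weights; applying the
    same weights to each subject's contrasts gives subject basis maps that
    correspond component-for-component with the group basis, sidestepping the
    correspondence problem of per-subject ICA.  Every returned map is rescaled
    to maximum 1.

    Returns ``(weights, group_basis, subject_bases)`` with bases d x G.
    """
    group_contrasts = np.asarray(group_contrasts, dtype=float)
    n_c = group_contrasts.shape[0]
    if not 1 <= d <= n_c:
        raise ValueError(f"need 1 <= d <= n_contrasts={n_c}, got d={d}")
    W = _fastica_weights(group_contrasts, d, seed=seed)

    def _norm_max1(B: np.ndarray) -> np.ndarray:
        # orient each map so its largest-magnitude value is positive, then scale to max 1
        signs = np.sign(B[np.arange(B.shape[0]), np.abs(B).argmax(axis=1)])
        signs[signs == 0] = 1.0
        B = B * signs[:, None]
        peaks = B.max(axis=1)
        peaks[peaks == 0] = 1.0
        return B / peaks[:, None]

    # fix component orientation on the group basis and reuse it for subjects
    raw_group = W @ group_contrasts
    signs = np.sign(raw_group[np.arange(d), np.abs(raw_group).argmax(axis=1)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    group_basis = _norm_max1(W @ group_contrasts)
    subject_bases = []
    for C in subject_contrasts:
        B = W @ np.asarray(C, dtype=float)
        peaks = B.max(axis=1)
        peaks[peaks == 0] = 1.0
        subject_bases.append(B / peaks[:, None])
    return W, group_basis, subject_bases
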