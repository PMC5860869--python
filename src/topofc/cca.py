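"""Brain-behaviour canonical correlation analysis with permutation inference.

The association stack used throughout: nuisance confounds are regressed out
of both feature blocks; subject-by-subject covariance matrices are built
(summed over maps for spatial features, with a pairwise-complete variant and
nearest-SPD repair when nodes are missing); their top eigenvectors (scaled by
the square root of the eigenvalue) form the CCA inputs; classical CCA finds
maximally correlated linear combinations ``U = X @ A`` and ``V = Y @ B``;
significance comes from permutations restricted to equal-size family blocks
(families shuffled as units, members shuffled within families, never across),
family-wise-error corrected across CCA modes via the max first-canonical-
correlation statistic; confidence intervals come from matrix-normal surrogate
data preserving row- and column-wise correlation structure.  Helpers
interpret a significant mode: correlations of V with the raw behaviour
variables, back-projection of U into the dense feature space for
visualisation, and grayordinate-wise correlation of subject weights with the
spatial maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureMatrix",
    "CCAResult",
    "deconfound",
    "subject_covariance",
    "pairwise_covariance_missing",
    "nearest_spd",
    "subject_eigenvectors",
    "cca_fit",
    "first_canonical_correlation",
    "permutation_pvalues",
    "restricted_permutation",
    "partial_cca",
    "MatrixNormalSurrogate",
    "surrogate_ci",
    "cross_mode_correlation",
    "behaviour_loadings",
    "backproject_mode",
    "weight_map_correlation",
    "bonferroni_threshold",
]


@dataclass
class FeatureMatrix:
    """N x Kc eigenvector scores entering the CCA, ordered by eigenvalue."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.isnan(self.scores).any():
            raise ValueError("scores contain NaN")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be in descending order")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class CCAResult:
    """Canonical weights, subject scores, correlations and permutation p-values."""

    x_weights: np.ndarray  # (Kx, n_modes)
    y_weights: np.ndarray  # (Ky, n_modes)
    U: np.ndarray  # (N, n_modes) imaging-side subject scores
    V: np.ndarray  # (N, n_modes) behaviour-side subject scores
    r: np.ndarray  # (n_modes,) canonical correlations
    p: np.ndarray | None = None  # permutation p-values, FWE-corrected across modes
    n_perm: int = 0


def deconfound(X: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """Residualise each column of X on [intercept, confounds].

    With no confounds this reduces to column demeaning.  Residual columns are
    orthogonal to the confounds (and to the intercept) by construction.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if confounds is None or np.size(confounds) == 0:
        return X - X.mean(axis=0)
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if N <= C.shape[1] + 1:
        raise ValueError("need N > n_confounds + 1")
    D = np.column_stack([np.ones(N), C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("confound matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return X - D @ beta


def subject_covariance(features: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Subject-by-subject covariance of a feature block.

    For a list of map blocks (one N x G array per map/mode) the per-map
    subject covariances are summed; for a single N x p array the plain
    covariance of the subject feature vectors is returned.
    """
    if isinstance(features, np.ndarray):
        blocks = [features]
    else:
        blocks = list(features)
    N = blocks[0].shape[0]
    cov = np.zeros((N, N))
    for B in blocks:
        B = np.asarray(B, dtype=float)
        if B.shape[0] != N:
            raise ValueError("feature blocks disagree on subject count")
        Bc = B - B.mean(axis=1, keepdims=True)
        cov += Bc @ Bc.T / (B.shape[1] - 1)
    return cov


def pairwise_covariance_missing(features: np.ndarray, missing_mask: np.ndarray) -> np.ndarray:
    """Subject covariance computed one element at a time over shared features.

    ``missing_mask`` is True where a feature is missing for a subject.  Entry
    (i, j) uses only features observed in both subjects; the result can be
    indefinite and should be repaired with :func:`nearest_spd` before
    eigendecomposition.
    """
    F = np.asarray(features, dtype=float)
    miss = np.asarray(missing_mask, dtype=bool)
    if F.shape != miss.shape:
        raise ValueError("features and missing_mask must share shape")
    N = F.shape[0]
    cov = np.empty((N, N))
    obs = ~miss
    for i in range(N):
        for j in range(i, N):
            shared = obs[i] & obs[j]
            n = int(shared.sum())
            if n < 2:
                raise ValueError(f"subject pair ({i}, {j}) shares fewer than 2 observed features")
            a = F[i, shared]
            b = F[j, shared]
            cov[i, j] = cov[j, i] = np.dot(a - a.mean(), b - b.mean()) / (n - 1)
    return cov


def nearest_spd(Mtx: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Project a square matrix to the nearest symmetric positive-definite matrix.

    Higham-style: symmetrise, clip eigenvalues at a small positive floor
    (scaled by the largest eigenvalue), reconstruct.  Idempotent on SPD input.
    """
    Mtx = np.asarray(Mtx, dtype=float)
    S = 0.5 * (Mtx + Mtx.T)
    w, V = np.linalg.eigh(S)
    eps = floor * max(abs(w[-1]), 1.0)
    if w[0] >= eps:
        return S
    w = np.clip(w, eps, None)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)


def subject_eigenvectors(cov: np.ndarray, Kc: int = 100, source: str = "") -> FeatureMatrix:
    """Top-Kc eigenvectors of the subject covariance, scaled by sqrt(eigenvalue).

    The scaling preserves the covariance geometry the CCA sees.  Sign
    convention: each component's largest-magnitude element is positive, so
    reruns give identical output.
    """
    cov = np.asarray(cov, dtype=float)
    N = cov.shape[0]
    if Kc > N:
        raise ValueError(f"Kc={Kc} exceeds the number of subjects N={N}")
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:Kc]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    signs = np.sign(V[np.abs(V).argmax(axis=0), np.arange(Kc)])
    signs[signs == 0] = 1.0
    scores = V * signs * np.sqrt(w)
    return FeatureMatrix(scores=scores, eigenvalues=w, source=source)


def _as_scores(X) -> np.ndarray:
    return X.scores if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _qr_demeaned(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        raise ValueError("feature matrix is rank deficient; reduce Kc")
    return Q, R


def cca_fit(X, Y) -> CCAResult:
    """Classical canonical correlation analysis of two feature blocks.

    Solved via QR of the demeaned blocks and SVD of ``Qx.T @ Qy``; canonical
    correlations are the singular values (non-increasing in [0, 1]); U and V
    columns are standardised to unit variance and mutually uncorrelated.
    """
    Xs, Ys = _as_scores(X), _as_scores(Y)
    N = Xs.shape[0]
    if Ys.shape[0] != N:
        raise ValueError("X and Y must share the subject count")
    if N <= max(Xs.shape[1], Ys.shape[1]):
        raise ValueError("need more subjects than feature columns")
    Qx, Rx = _qr_demeaned(Xs)
    Qy, Ry = _qr_demeaned(Ys)
    Uc, s, Vt = np.linalg.svd(Qx.T @ Qy)
    n_modes = min(Xs.shape[1], Ys.shape[1])
    Uc, s, Vc = Uc[:, :n_modes], np.clip(s[:n_modes], 0.0, 1.0), Vt[:n_modes].T
    scale = np.sqrt(N - 1)
    A = np.linalg.solve(Rx, Uc) * scale
    B = np.linalg.solve(Ry, Vc) * scale
    U = Qx @ Uc * scale
    V = Qy @ Vc * scale
    return CCAResult(x_weights=A, y_weights=B, U=U, V=V, r=s)


def first_canonical_correlation(X, Y) -> float:
    """First canonical correlation only (fast path for permutation nulls)."""
    Qx, _ = _qr_demeaned(_as_scores(X))
    Qy, _ = _qr_demeaned(_as_scores(Y))
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return float(min(s[0], 1.0))


def restricted_permutation(family_id: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One permutation respecting equal-size family blocks.

    Families are shuffled as units and members are shuffled within families;
    subjects never move across families except as part of a whole-family
    swap.  Requires contiguous equal-size blocks.
    """
    family_id = np.asarray(family_id)
    fams, counts = np.unique(family_id, return_counts=True)
    if counts.min() != counts.max():
        raise ValueError("family blocks must have equal size")
    size = int(counts[0])
    n_fam = fams.size
    members = np.argsort(family_id, kind="stable").reshape(n_fam, size)
    fam_order = rng.permutation(n_fam)
    out = np.empty(family_id.size, dtype=int)
    for slot, fam in enumerate(fam_order):
        perm_within = rng.permutation(size)
        out[members[slot]] = members[fam][perm_within]
    return out


def permutation_pvalues(
    X,
    Y,
    family_id: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    return_null: bool = False,
):
    """Family-restricted permutation p-values, FWE-corrected across CCA modes.

    The identity permutation counts as one of ``n_perm``.  The null statistic
    is the *first* canonical correlation of each permuted fit, so each mode's
    p-value ``p_k = #{first r of any permutation >= observed r_k} / n_perm``
    is corrected for selection across modes (max-statistic).  The smallest
    attainable p is ``1/n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xs, Ys = _as_scores(X), _as_scores(Y)
    res = cca_fit(Xs, Ys)
    rng = np.random.default_rng(seed)
    null_r1 = np.empty(n_perm)
    null_r1[0] = res.r[0]  # identity permutation
    Qx, _ = _qr_demeaned(Xs)
    Yc = Ys - Ys.mean(axis=0)
    Qy, _ = np.linalg.qr(Yc)
    for i in range(1, n_perm):
        perm = restricted_permutation(family_id, rng)
        # permuting rows of Y permutes rows of its (demeaned) orthonormal basis
        s = np.linalg.svd(Qx.T @ Qy[perm], compute_uv=False)
        null_r1[i] = min(s[0], 1.0)
    p = np.array([(null_r1 >= r - 1e-12).sum() / n_perm for r in res.r])
    if return_null:
        return p, null_r1
    return p


def partial_cca(X, Y, Z) -> CCAResult:
    """CCA after residualising X's columns on Z's columns (with intercept).

    Isolates the cross-subject information in X that is *not* explained by Z.
    If the residual collapses to (numerical) zero the degenerate contract is a
    result with all canonical correlations 0.
    """
    Xs, Ys, Zs = _as_scores(X), _as_scores(Y), _as_scores(Z)
    resid = deconfound(Xs, Zs)
    if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(Xs), 1.0):
        n_modes = min(Xs.shape[1], Ys.shape[1])
        N = Xs.shape[0]
        zeros = np.zeros((N, n_modes))
        return CCAResult(
            x_weights=np.zeros((Xs.shape[1], n_modes)),
            y_weights=np.zeros((Ys.shape[1], n_modes)),
            U=zeros,
            V=zeros,
            r=np.zeros(n_modes),
        )
    # drop residual directions that fell below numerical rank
    Uq, s, _ = np.linalg.svd(resid - resid.mean(axis=0), full_matrices=False)
    keep = s > 1e-8 * s[0]
    resid_reduced = Uq[:, keep] * s[keep]
    return cca_fit(resid_reduced, Ys)


def _psd_factor(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    return V * np.sqrt(np.clip(w, 0.0, None))


class MatrixNormalSurrogate:
    """Matrix-normal surrogate sampler preserving row and column structure.

    Draws ``scale * Lr @ Z @ Lc.T`` with ``Lr Lr.T`` the subject (row)
    covariance of the input, ``Lc Lc.T`` the feature (column) covariance, and
    the scale matched so the expected total variance equals the input's.
    """

    def __init__(self, M: np.ndarray):
        Mc = np.asarray(M, dtype=float)
        Mc = Mc - Mc.mean(axis=0)
        Sr = Mc @ Mc.T / max(Mc.shape[1] - 1, 1)
        Sc = Mc.T @ Mc / max(Mc.shape[0] - 1, 1)
        self.shape = Mc.shape
        self.Lr = _psd_factor(Sr)
        self.Lc = _psd_factor(Sc)
        self.scale = np.sqrt(np.sum(Mc**2) / max(np.trace(Sr) * np.trace(Sc), 1e-300))

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        Z = rng.standard_normal(self.shape)
        return self.scale * self.Lr @ Z @ self.Lc.T


def surrogate_ci(
    X,
    Y,
    n_surr: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float]:
    """Surrogate-data confidence interval for the first canonical correlation.

    Each surrogate block is drawn from a matrix-normal model whose row
    covariance is the subject covariance of the input and whose column
    covariance is the feature covariance, rescaled so the total variance
    matches the input; X and Y surrogates are drawn independently and a CCA is
    fitted to each pair.  Returns the empirical percentile interval of the
    first canonical correlation over surrogates.
    """
    if n_surr < 40:
        raise ValueError("need n_surr >= 40 for 2.5/97.5 percentiles")
    rng = np.random.default_rng(seed)
    sx = MatrixNormalSurrogate(_as_scores(X))
    sy = MatrixNormalSurrogate(_as_scores(Y))
    r1 = np.empty(n_surr)
    for i in range(n_surr):
        r1[i] = first_canonical_correlation(sx.draw(rng), sy.draw(rng))
    lo, hi = np.percentile(r1, percentiles)
    return float(lo), float(hi)


def cross_mode_correlation(U_ref_first: np.ndarray, U_other: np.ndarray) -> float:
    """Max |correlation| between a reference mode and any column of another U."""
    u = np.asarray(U_ref_first, dtype=float).ravel()
    Uo = np.asarray(U_other, dtype=float)
    if Uo.ndim == 1:
        Uo = Uo[:, None]
    uc = u - u.mean()
    Uc = Uo - Uo.mean(axis=0)
    denom = np.linalg.norm(uc) * np.linalg.norm(Uc, axis=0)
    denom[denom == 0] = np.inf
    return float(np.max(np.abs(uc @ Uc / denom)))


def behaviour_loadings(
    V1: np.ndarray, behaviour_raw: np.ndarray, report_threshold: float = 0.25
) -> tuple[np.ndarray, list[int]]:
    """Correlation of the behaviour-side subject scores with each raw variable.

    Returns the full loading vector (NaN for constant variables) and the
    indices of variables whose |loading| exceeds ``report_threshold``.
    """
    v = np.asarray(V1, dtype=float).ravel()
    B = np.asarray(behaviour_raw, dtype=float)
    vc = v - v.mean()
    Bc = B - B.mean(axis=0)
    sd = np.linalg.norm(Bc, axis=0)
    loadings = np.full(B.shape[1], np.nan)
    ok = sd > 0
    loadings[ok] = (vc @ Bc[:, ok]) / (np.linalg.norm(vc) * sd[ok])
    strong = [int(i) for i in np.flatnonzero(np.abs(loadings) > report_threshold)]
    return loadings, strong


def backproject_mode(
    U1: np.ndarray, dense_features: np.ndarray, n_frames: int = 5, extension: float = 0.10
) -> np.ndarray:
    """Rank-one back-projection of a CCA mode into the dense feature space.

    Fits each feature on the subject scores ``U1`` and evaluates the fitted
    line at ``n_frames`` positions spanning the score range extended by
    ``extension`` of the full range beyond both extremes — the frames of the
    population-continuum visualisation.
    """
    u = np.asarray(U1, dtype=float).ravel()
    F = np.asarray(dense_features, dtype=float)
    if np.ptp(u) == 0:
        raise ValueError("subject scores are constant; cannot back-project")
    uc = u - u.mean()
    slope = uc @ (F - F.mean(axis=0)) / (uc @ uc)
    lo = u.min() - extension * np.ptp(u)
    hi = u.max() + extension * np.ptp(u)
    positions = np.linspace(lo, hi, n_frames)
    return F.mean(axis=0) + (positions - u.mean())[:, None] * slope


def weight_map_correlation(weights: np.ndarray, subject_maps: list[np.ndarray]) -> np.ndarray:
    """Per-grayordinate max |correlation| of subject weights with any mode's map value.

    ``subject_maps`` is one G x M array per subject; for each grayordinate g
    and mode m the across-subject correlation of ``weights`` with
    ``maps[g, m]`` is computed, and the maximum absolute value over modes is
    returned.  Zero-variance map entries contribute correlation 0.
    """
    w = np.asarray(weights, dtype=float).ravel()
    stack = np.stack([np.asarray(P, dtype=float) for P in subject_maps])  # (N, G, M)
    wc = w - w.mean()
    Pc = stack - stack.mean(axis=0)
    num = np.einsum("n,ngm->gm", wc, Pc)
    denom = np.linalg.norm(wc) * np.sqrt((Pc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return np.abs(r).max(axis=1)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold under Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
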