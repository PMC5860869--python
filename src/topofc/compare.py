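"""Three-way evaluation of simulated against original network matrices.

* ``within_subject_similarity`` (Z_netmat): per subject, group-demeaned edges
  of the simulated netmat are correlated with the group-demeaned edges of the
  original netmat; the Fisher-z of these correlations is averaged.  This asks
  how well each subject's *deviation from the group* is regenerated.
* ``cross_subject_similarity`` (R_correlation): subject-by-subject similarity
  matrices are built from each set of netmats and their off-diagonals
  correlated.  This asks whether the *pattern of cross-subject variability*
  is regenerated — the quantity of primary interest.
* ``measure_similarity``: full and partial correlations between the
  similarity matrices of several measures (netmats, amplitudes, maps),
  showing which measures carry shared versus unique cross-subject structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netmats import Netmat, vectorise_edges

__all__ = [
    "SimilarityMatrix",
    "within_subject_similarity",
    "subject_similarity_matrix",
    "cross_subject_similarity",
    "measure_similarity",
]

_CAP = 1.0 - 1e-12


@dataclass
class SimilarityMatrix:
    """N x N subject-by-subject correlation matrix for one measure."""

    values: np.ndarray
    measure: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def within_subject_similarity(sim: list[Netmat], orig: list[Netmat]) -> float:
    """Mean Fisher-z within-subject correlation of group-demeaned edges (Z_netmat).

    Inputs should be z-transformed netmats.  The respective group-average
    netmat is subtracted from each subject's netmat before vectorising, so the
    correlation reflects unique subject variability rather than shared group
    structure.  Correlations are capped at ±(1 - 1e-12) before atanh.
    """
    if len(sim) != len(orig):
        raise ValueError("simulated and original subject counts differ")
    if len(sim) < 2:
        raise ValueError("need at least 2 subjects (group demeaning undefined)")
    E_sim = np.array([vectorise_edges(n.values) for n in sim])
    E_orig = np.array([vectorise_edges(n.values) for n in orig])
    if E_sim.shape[1] != E_orig.shape[1]:
        raise ValueError("node counts differ")
    E_sim = E_sim - E_sim.mean(axis=0)
    E_orig = E_orig - E_orig.mean(axis=0)
    zs = []
    for a, b in zip(E_sim, E_orig):
        r = np.corrcoef(a, b)[0, 1]
        zs.append(np.arctanh(np.clip(r, -_CAP, _CAP)))
    return float(np.mean(zs))


def subject_similarity_matrix(features: np.ndarray, measure: str = "") -> SimilarityMatrix:
    """N x N Pearson correlation of per-subject feature vectors.

    Features are netmat edge vectors, amplitude vectors, or concatenated map
    columns — one row per subject.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[0] < 3:
        raise ValueError("need a 2-D feature array with >= 3 subjects")
    sd = F.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant feature vector for subject {dead[0]}")
    return SimilarityMatrix(values=np.corrcoef(F), measure=measure)


def cross_subject_similarity(simN: SimilarityMatrix, origN: SimilarityMatrix) -> float:
    """Correlation of the off-diagonals of two similarity matrices (R_correlation)."""
    if simN.n_subjects != origN.n_subjects:
        raise ValueError("subject counts differ")
    if simN.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    a = vectorise_edges(simN.values)
    b = vectorise_edges(origN.values)
    return float(np.corrcoef(a, b)[0, 1])


def measure_similarity(mats: list[SimilarityMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Full and partial correlations between measures' cross-subject structure.

    Vectorises each similarity matrix's off-diagonal and returns the
    measure x measure full correlation matrix and the partial correlation
    matrix (via the inverse correlation matrix, no ridge).
    """
    if len(mats) < 2:
        raise ValueError("need at least 2 measures")
    N = mats[0].n_subjects
    if any(m.n_subjects != N for m in mats):
        raise ValueError("measures must share the subject count")
    E = np.array([vectorise_edges(m.values) for m in mats])
    full = np.corrcoef(E)
    # pinv keeps the partial computation defined for duplicated measures
    Omega = np.linalg.pinv(full)
    d = np.sqrt(np.diag(Omega))
    partial = -Omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return full, 0.5 * (partial + partial.T)
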