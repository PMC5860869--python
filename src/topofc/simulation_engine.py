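"""Outer-product simulation engine with exact correlation injection.

A subject's data is modelled as ``D = P @ diag(h) @ A + noise`` with spatial
maps ``P`` (G x M), amplitudes ``h`` (M,) and timecourses ``A`` (M x T).  The
engine rewrites the timecourses so their correlation matches a prescribed
target exactly — variance-normalise, ZCA-whiten, multiply by the symmetric
square root of the target correlation, restore variances — and selectively
fixes maps / amplitudes / netmats to their group averages ("pseudo-modes"),
optionally simplifying the maps by thresholding or binarisation before the
outer product is taken.

Orientation is fixed throughout: modes along rows, time along columns.
Whitening and injection matrices act on the left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import GroupModel, ModeDecomposition

__all__ = [
    "SimulationSpec",
    "ProcessedTimeseries",
    "variance_normalise",
    "zca_whiten",
    "apply_netmat",
    "restore_variance",
    "pseudo_modes",
    "modulate_maps",
    "reconstruct",
]

_MODULATIONS = ("none", "fixed_threshold_binary", "percentile_binary", "threshold_only")


@dataclass(frozen=True)
class SimulationSpec:
    """Which decomposition factors vary across subjects, and map simplification.

    ``vary_maps`` / ``vary_amplitudes`` / ``vary_netmats``: a False entry fixes
    that factor to its group average, eliminating the corresponding source of
    cross-subject variability from the simulated data.  ``map_modulation``
    optionally reduces maps to shape information: ``fixed_threshold_binary``
    signs-and-binarises at ``fixed_threshold`` (keeps size variability),
    ``percentile_binary`` binarises the top/bottom ``percentile`` of each
    column (fixes size too), ``threshold_only`` zeroes sub-threshold entries
    but keeps the surviving weights.
    """

    vary_maps: bool = True
    vary_amplitudes: bool = True
    vary_netmats: bool = True
    map_modulation: str = "none"
    fixed_threshold: float = 1.0
    percentile: float = 5.0
    noise_var: float | str = "matched"

    def __post_init__(self) -> None:
        if self.map_modulation not in _MODULATIONS:
            raise ValueError(
                f"map_modulation must be one of {_MODULATIONS}, got {self.map_modulation!r}"
            )
        if not 0.0 < self.percentile < 50.0:
            raise ValueError(f"percentile must lie in (0, 50), got {self.percentile!r}")
        if isinstance(self.noise_var, str):
            if self.noise_var != "matched":
                raise ValueError("noise_var must be a nonnegative real or 'matched'")
        elif self.noise_var < 0:
            raise ValueError("noise_var must be nonnegative")

    @property
    def label(self) -> str:
        parts = [
            "maps" if self.vary_maps else "",
            "amplitudes" if self.vary_amplitudes else "",
            "netmats" if self.vary_netmats else "",
        ]
        varying = "+".join(p for p in parts if p) or "nothing"
        if self.map_modulation != "none":
            varying += f"|{self.map_modulation}"
        return varying


@dataclass
class ProcessedTimeseries:
    """Intermediate products of the normalise-whiten-inject-restore chain."""

    Bs: np.ndarray  # unit-variance timecourses (M, T)
    vs: np.ndarray  # retained variances (M,)
    Zs: np.ndarray  # whitening transform (M, M)
    Cs: np.ndarray  # whitened timecourses (M, T)
    Es: np.ndarray  # final timecourses (M, T)


def variance_normalise(As: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each row to unit sample variance; return (Bs, vs).

    ``Bs * sqrt(vs)[:, None]`` recovers ``As`` exactly.
    """
    As = np.asarray(As, dtype=float)
    vs = As.var(axis=1, ddof=1)
    zero = np.flatnonzero(vs <= 0)
    if zero.size:
        raise ValueError(f"zero-variance timecourse for mode index {zero[0]}")
    Bs = As / np.sqrt(vs)[:, None]
    return Bs, vs


def zca_whiten(Bs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove correlations between timeseries with the symmetric (ZCA) transform.

    ``Zs = cov(Bs.T)^(-1/2)`` (unique symmetric positive-definite inverse
    square root) and ``Cs = Zs @ Bs``, so the sample covariance of ``Cs.T`` is
    the identity.  Of all whitening transforms, ZCA distorts the original
    signals least.
    """
    Bs = np.asarray(Bs, dtype=float)
    M, T = Bs.shape
    if T <= M:
        raise ValueError(f"need T > M to whiten (got M={M}, T={T})")
    C = np.cov(Bs)
    C = np.atleast_2d(C)
    w, V = np.linalg.eigh(C)
    if w.min() <= max(1e-12 * w.max(), 0.0):
        raise ValueError(
            "covariance is singular (perfectly correlated timeseries); "
            "need T > M and linearly independent rows, or regularise first"
        )
    Zs = (V / np.sqrt(w)) @ V.T
    Cs = Zs @ Bs
    return Cs, Zs


def apply_netmat(Cs: np.ndarray, R_target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inject a target correlation into white timeseries.

    Returns ``(Ds, alpha)`` where ``alpha`` is the symmetric PSD square root
    of ``R_target`` and ``Ds = alpha @ Cs``.  Because ``Cs`` is exactly white,
    the sample correlation of ``Ds.T`` equals ``R_target`` exactly.
    """
    Cs = np.asarray(Cs, dtype=float)
    R = np.asarray(R_target, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R_target must be symmetric")
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-10:
        raise ValueError(
            "R_target is not positive semidefinite; repair it first "
            "(e.g. topofc.synthetic_cohort.nearest_correlation)"
        )
    alpha = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    return alpha @ Cs, alpha


def restore_variance(Ds: np.ndarray, vs: np.ndarray) -> np.ndarray:
    """Rescale each unit-variance row back to its retained variance."""
    Ds = np.asarray(Ds, dtype=float)
    vs = np.asarray(vs, dtype=float)
    if Ds.shape[0] != vs.shape[0]:
        raise ValueError("row count of Ds must match length of vs")
    if np.any(vs <= 0):
        raise ValueError("variances must be positive")
    return Ds * np.sqrt(vs)[:, None]


def _inject_correlation(As: np.ndarray, R: np.ndarray, restore_vs: np.ndarray | None = None) -> np.ndarray:
    """normalise -> whiten -> apply R -> restore, on one run of timecourses."""
    Bs, vs = variance_normalise(As)
    Cs, _ = zca_whiten(Bs)
    Ds, _ = apply_netmat(Cs, R)
    return restore_variance(Ds, vs if restore_vs is None else restore_vs)


def pseudo_modes(
    subject: ModeDecomposition,
    group: GroupModel,
    spec: SimulationSpec,
    run_length: int | None = None,
) -> ModeDecomposition:
    """Build a subject's pseudo-mode decomposition under a simulation spec.

    Maps and amplitudes are taken from the subject or the group according to
    the vary flags; the timecourse correlation is rewritten to the subject's
    own correlation (``vary_netmats``) or the group netmat (fixed).  Amplitude
    fixing also swaps the restored timecourse variances for the group-average
    variances.  Map modulation is applied last.  Runs of ``run_length``
    timepoints are processed independently (default: one run spanning T).
    """
    G, M, T = subject.n_grayordinates, subject.n_modes, subject.n_timepoints
    if group.group_maps.shape != (G, M):
        raise ValueError("subject and group shapes disagree")
    run_length = T if run_length is None else run_length
    if T % run_length != 0:
        raise ValueError(f"run_length {run_length} must divide T={T}")

    maps = subject.maps if spec.vary_maps else group.group_maps
    if spec.vary_amplitudes:
        amps, restore_vs = subject.amplitudes, None
    else:
        amps, restore_vs = group.group_amplitudes, group.group_variances

    A_runs = []
    for start in range(0, T, run_length):
        A_run = subject.timecourses[:, start : start + run_length]
        R = np.corrcoef(A_run) if spec.vary_netmats else group.group_netmat
        A_runs.append(_inject_correlation(A_run, R, restore_vs))
    A_hat = np.concatenate(A_runs, axis=1)

    if spec.map_modulation != "none":
        maps = modulate_maps(
            maps, spec.map_modulation, threshold=spec.fixed_threshold, percentile=spec.percentile
        )
        # binarised maps can zero out a mode entirely for extreme thresholds;
        # the decomposition still needs valid shapes, so keep maps as-is
    return ModeDecomposition(maps=maps, amplitudes=np.asarray(amps, float).copy(), timecourses=A_hat)


def modulate_maps(
    Ps: np.ndarray, mode: str, threshold: float = 1.0, percentile: float = 5.0
) -> np.ndarray:
    """Simplify spatial maps to isolate shape from weight information.

    ``fixed_threshold_binary``: entries > tau -> +1, < -tau -> -1, else 0
    (retains cross-subject size variability).  ``threshold_only``: entries
    with \\|value\\| <= tau zeroed, others kept.  ``percentile_binary``: per
    column, exactly ``floor(p/100 * G)`` largest entries -> +1 and the same
    number of smallest -> -1, fixing network size across subjects.
    """
    Ps = np.asarray(Ps, dtype=float)
    if mode == "none":
        return Ps.copy()
    if mode == "fixed_threshold_binary":
        return np.where(Ps > threshold, 1.0, np.where(Ps < -threshold, -1.0, 0.0))
    if mode == "threshold_only":
        return np.where(np.abs(Ps) <= threshold, 0.0, Ps)
    if mode == "percentile_binary":
        G = Ps.shape[0]
        n_tail = int(np.floor(percentile / 100.0 * G))
        out = np.zeros_like(Ps)
        if n_tail:
            order = np.argsort(Ps, axis=0, kind="stable")
            rows_lo = order[:n_tail]
            rows_hi = order[-n_tail:]
            cols = np.arange(Ps.shape[1])
            out[rows_lo, cols] = -1.0
            out[rows_hi, cols] = 1.0
        return out
    raise ValueError(f"unknown map modulation mode {mode!r}")


def reconstruct(
    decomp: ModeDecomposition,
    noise_var: float | str = 0.0,
    reference_data: np.ndarray | None = None,
    reference_decomp: ModeDecomposition | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reconstruct voxelwise data ``P @ diag(h) @ A + noise`` (G x T).

    ``noise_var="matched"`` uses the mean residual variance of
    ``reference_data`` given its own decomposition (``reference_decomp``,
    defaulting to ``decomp``), so the simulated dataset keeps the reference's
    overall noise level — one global scalar, not per-grayordinate.
    """
    signal = decomp.maps @ (decomp.amplitudes[:, None] * decomp.timecourses)
    if noise_var == "matched":
        if reference_data is None:
            raise ValueError("noise_var='matched' requires reference_data")
        ref = reference_decomp if reference_decomp is not None else decomp
        ref_signal = ref.maps @ (ref.amplitudes[:, None] * ref.timecourses)
        resid = reference_data - ref_signal
        noise_var = float(np.mean(resid**2))
    elif isinstance(noise_var, str):
        raise ValueError("noise_var must be a nonnegative real or 'matched'")
    if noise_var < 0:
        raise ValueError("noise_var must be nonnegative")
    if noise_var == 0:
        return signal
    rng = np.random.default_rng() if rng is None else rng
    return signal + np.sqrt(noise_var) * rng.standard_normal(signal.shape)
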