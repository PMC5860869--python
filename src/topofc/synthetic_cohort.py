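"""Synthetic cohorts of functional-mode decompositions with known ground truth.

Each subject's resting-state signal subspace is described by a mode
decomposition: spatial maps ``Ps`` (G grayordinates x M modes), positive mode
amplitudes ``hs`` (M,) and timecourses ``As`` (M x T).  The generator builds a
group model (mean maps, amplitudes, mode-correlation matrix) and perturbs it
per subject with controlled variability:

* spatial maps — bump-centre displacement plus bump reweighting, so the shape
  *and* location of regions vary, partly driven by a latent behavioural trait;
* amplitudes — log-normal scatter around the group amplitudes;
* netmats — symmetric noise on the group mode-correlation matrix followed by
  a nearest-correlation repair, then injected *exactly* into the timecourses;
* behaviour — variables loading on the latent trait plus nuisance confound
  leakage, organised in equal-size family blocks for restricted permutation.

Everything is reproducible from a single seed, and the latent trait plus the
per-subject map-perturbation weights are stored so downstream recovery can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CohortSpec",
    "GroupModel",
    "ModeDecomposition",
    "Cohort",
    "Parcellation",
    "generate_cohort",
    "generate_parcellation",
    "generate_task_contrasts",
    "nearest_correlation",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters controlling cohort generation.

    Scales: ``spatial_sd`` multiplies a nominal map perturbation (bump-centre
    shifts of 0.3 x bump width and 20% bump reweighting at ``spatial_sd=1``);
    ``amplitude_sd`` is the log-scale SD of amplitude scatter; ``netmat_sd``
    is the SD of the symmetric perturbation added to the group correlation
    before repair.  ``latent_loading_maps`` / ``latent_loading_behaviour`` in
    [0, 1] set how strongly the latent trait drives map perturbations and
    behaviour columns.  ``noise_var`` is the variance of the white noise added
    at data reconstruction.
    """

    n_subjects: int = 50
    n_modes: int = 10
    n_grayordinates: int = 2000
    n_timepoints: int = 600
    n_runs: int = 1
    family_size: int = 2
    spatial_sd: float = 1.0
    amplitude_sd: float = 0.2
    netmat_sd: float = 0.15
    latent_loading_maps: float = 0.9
    latent_loading_behaviour: float = 0.9
    n_behaviour: int = 40
    n_confounds: int = 4
    noise_var: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_modes", "n_grayordinates", "n_timepoints", "n_runs", "family_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_behaviour", "n_confounds"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        for name in ("spatial_sd", "amplitude_sd", "netmat_sd", "noise_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        for name in ("latent_loading_maps", "latent_loading_behaviour"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_subjects % self.family_size != 0:
            raise ValueError(
                f"family_size ({self.family_size}) must divide n_subjects ({self.n_subjects})"
            )


@dataclass
class GroupModel:
    """Group-level model: mean maps, amplitudes, mode correlation, noise.

    ``group_variances`` is the group-average timecourse variance per mode; the
    simulation engine restores it in place of subject variances when amplitude
    variability is fixed to the group.
    """

    group_maps: np.ndarray  # (G, M)
    group_amplitudes: np.ndarray  # (M,)
    group_netmat: np.ndarray  # (M, M) correlation
    noise_var: float = 0.0
    group_variances: np.ndarray | None = None  # (M,)

    def __post_init__(self) -> None:
        self.group_maps = np.asarray(self.group_maps, dtype=float)
        self.group_amplitudes = np.asarray(self.group_amplitudes, dtype=float)
        self.group_netmat = np.asarray(self.group_netmat, dtype=float)
        if self.group_variances is None:
            self.group_variances = np.ones(self.group_maps.shape[1])
        else:
            self.group_variances = np.asarray(self.group_variances, dtype=float)
        if np.any(self.group_amplitudes <= 0):
            raise ValueError("group amplitudes must be positive")
        R = self.group_netmat
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("group netmat must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("group netmat must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("group netmat must be positive definite")


@dataclass
class ModeDecomposition:
    """One subject's spatial maps (G x M), amplitudes (M,) and timecourses (M x T)."""

    maps: np.ndarray
    amplitudes: np.ndarray
    timecourses: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.timecourses = np.asarray(self.timecourses, dtype=float)
        G, M = self.maps.shape
        if self.amplitudes.shape != (M,):
            raise ValueError(f"amplitudes shape {self.amplitudes.shape} != ({M},)")
        if self.timecourses.ndim != 2 or self.timecourses.shape[0] != M:
            raise ValueError("timecourses must be (M, T) with M matching maps")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any(np.all(self.timecourses == 0, axis=1)):
            raise ValueError("timecourses contain an all-zero row")

    @property
    def n_modes(self) -> int:
        return self.maps.shape[1]

    @property
    def n_grayordinates(self) -> int:
        return self.maps.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.timecourses.shape[1]


@dataclass
class Cohort:
    """Subjects plus behaviour table, confounds, family labels and ground truth."""

    subjects: list[ModeDecomposition]
    group: GroupModel
    behaviour: np.ndarray  # (N, n_behaviour)
    confounds: np.ndarray  # (N, n_confounds)
    family_id: np.ndarray  # (N,) int
    latent: np.ndarray  # (N,)
    spec: CohortSpec | None = None
    netmats: np.ndarray | None = None  # (N, M, M) subject mode correlations
    map_perturbation_weights: np.ndarray | None = None  # (N,) signed perturbation weight
    behaviour_loadings_true: np.ndarray | None = None  # (n_behaviour,)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class Parcellation:
    """Hard parcellation over the grayordinate axis: 0 = unassigned, 1..K parcels."""

    labels: np.ndarray  # (G,) int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        K = self.n_parcels
        present = np.unique(self.labels[self.labels > 0])
        if K and not np.array_equal(present, np.arange(1, K + 1)):
            raise ValueError("parcel ids must be exactly 1..K with every parcel non-empty")

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max(initial=0))


def nearest_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix into a valid correlation matrix.

    Symmetrises, clips eigenvalues at a small positive floor, reconstructs and
    rescales to unit diagonal.  Guarantees a symmetric positive-definite
    matrix suitable as a target for correlation injection.
    """
    R = np.asarray(R, dtype=float)
    S = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(S)
    w = np.clip(w, floor, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    return 0.5 * (S + S.T)


def _bump_profile(grid: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - centre) / width) ** 2)


def _make_group_bumps(spec: CohortSpec, rng: np.random.Generator):
    """Random smooth radial-bump layout for the group maps on a 1-D axis.

    Each mode is a sum of a few Gaussian bumps; adjacent modes overlap, giving
    the soft, partially overlapping character of functional mode maps.
    Returns (centres, widths, weights) with shape (M, n_bumps).
    """
    G, M = spec.n_grayordinates, spec.n_modes
    n_bumps = 3
    width = G / (4.0 * M)
    # mode anchor positions spread over the axis, bumps scattered around them
    anchors = (np.arange(M) + 0.5) * G / M
    centres = anchors[:, None] + rng.uniform(-1.5, 1.5, size=(M, n_bumps)) * width * 2
    widths = width * rng.uniform(0.7, 1.4, size=(M, n_bumps))
    weights = rng.uniform(1.0, 2.5, size=(M, n_bumps)) * rng.choice([1.0, 1.0, 1.0, -1.0], size=(M, n_bumps))
    return centres, widths, weights


def _render_maps(G: int, centres: np.ndarray, widths: np.ndarray, weights: np.ndarray) -> np.ndarray:
    grid = np.arange(G, dtype=float)
    M, n_bumps = centres.shape
    maps = np.zeros((G, M))
    for m in range(M):
        for b in range(n_bumps):
            maps[:, m] += weights[m, b] * _bump_profile(grid, centres[m, b], widths[m, b])
    return maps


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort with known ground truth.

    All randomness comes from one generator seeded with ``spec.seed``, drawn in
    a fixed documented order (group layout, latent trait, per-subject map
    weights, amplitudes, netmats, timecourses, behaviour, confounds), so equal
    specs give bit-identical cohorts.

    The subject map perturbation is a displacement + reweighting of the group
    bump layout with signed weight ``w_s = lam*latent_s + sqrt(1-lam^2)*eps_s``
    (``lam = latent_loading_maps``), scaled by ``spatial_sd``; ``w_s`` is
    stored in ``map_perturbation_weights``.  Timecourses are drawn white and
    passed through the engine's normalise-whiten-inject-restore chain so that
    ``corr(As.T)`` equals the subject netmat exactly.
    """
    from .simulation_engine import apply_netmat, zca_whiten

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G, M, T = spec.n_grayordinates, spec.n_modes, spec.n_timepoints
    N = spec.n_subjects
    T_total = T * spec.n_runs

    centres, widths, weights = _make_group_bumps(spec, rng)
    group_maps = _render_maps(G, centres, widths, weights)
    group_amplitudes = rng.uniform(0.8, 1.6, size=M)
    # group mode correlation: moderately coupled random structure
    B = rng.standard_normal((M, M + 3))
    Rg_raw = np.corrcoef(B)
    Rg = nearest_correlation(0.6 * np.eye(M) + 0.4 * Rg_raw)

    latent = rng.standard_normal(N)

    lam = spec.latent_loading_maps
    w = lam * latent + np.sqrt(1.0 - lam**2) * rng.standard_normal(N)

    # fixed perturbation directions per bump (shared basis across subjects)
    shift_dir = rng.standard_normal((M, centres.shape[1]))
    shift_dir /= np.linalg.norm(shift_dir) / np.sqrt(shift_dir.size)
    reweight_dir = rng.standard_normal((M, centres.shape[1]))
    reweight_dir /= np.linalg.norm(reweight_dir) / np.sqrt(reweight_dir.size)

    # per-mode spatial-strength direction: latent-driven scaling of whole map
    # columns; visible in subject maps but invisible to correlation netmats
    scale_dir = rng.standard_normal(M)
    # idiosyncratic (subject-unique, high-dimensional) perturbation draws
    idio_shift = rng.standard_normal((N,) + centres.shape)
    idio_reweight = rng.standard_normal((N,) + centres.shape)
    idio_scale = rng.standard_normal((N, M))
    log_amp = rng.standard_normal((N, M))
    netmat_noise = rng.standard_normal((N, M, M))
    ts_raw = rng.standard_normal((N, M, T_total))

    width_scale = G / (4.0 * M)  # nominal bump width
    subjects: list[ModeDecomposition] = []
    subject_netmats = np.empty((N, M, M))
    var_sum = np.zeros(M)
    for s in range(N):
        if spec.spatial_sd == 0:
            maps_s = group_maps.copy()
        else:
            dc = spec.spatial_sd * 0.3 * width_scale * (w[s] * shift_dir + idio_shift[s])
            dw = 1.0 + spec.spatial_sd * 0.2 * (w[s] * reweight_dir + idio_reweight[s])
            maps_s = _render_maps(G, centres + dc, widths, weights * dw)
            maps_s *= np.exp(spec.spatial_sd * 0.15 * (w[s] * scale_dir + 0.5 * idio_scale[s]))
        amps_s = group_amplitudes * np.exp(spec.amplitude_sd * log_amp[s])
        if spec.netmat_sd == 0:
            R_s = Rg.copy()
        else:
            E = netmat_noise[s]
            E = 0.5 * (E + E.T)
            np.fill_diagonal(E, 0.0)
            R_s = nearest_correlation(Rg + spec.netmat_sd * E)
        subject_netmats[s] = R_s
        # exact correlation injection, run by run
        A_runs = []
        for r in range(spec.n_runs):
            raw = ts_raw[s, :, r * T : (r + 1) * T]
            raw = raw - raw.mean(axis=1, keepdims=True)
            white, _ = zca_whiten(raw / raw.std(axis=1, ddof=1, keepdims=True))
            A_runs.append(apply_netmat(white, R_s)[0])
        A_s = np.concatenate(A_runs, axis=1)
        var_sum += A_s.var(axis=1, ddof=1)
        subjects.append(ModeDecomposition(maps=maps_s, amplitudes=amps_s, timecourses=A_s))

    group = GroupModel(
        group_maps=group_maps,
        group_amplitudes=group_amplitudes,
        group_netmat=Rg,
        noise_var=spec.noise_var,
        group_variances=var_sum / N,
    )

    confounds = rng.standard_normal((N, spec.n_confounds))
    lam_b = spec.latent_loading_behaviour
    n_loaded = (spec.n_behaviour + 1) // 2
    load = np.zeros(spec.n_behaviour)
    if spec.n_behaviour:
        load[:n_loaded] = rng.uniform(0.5, 1.0, size=n_loaded) * rng.choice([1.0, -1.0], size=n_loaded)
    noise_b = rng.standard_normal((N, spec.n_behaviour))
    gamma = 0.3 * rng.standard_normal((spec.n_confounds, spec.n_behaviour))
    behaviour = (
        lam_b * np.outer(latent, load)
        + np.sqrt(max(1.0 - lam_b**2, 0.0)) * noise_b
        + confounds @ gamma
    )
    # unloaded columns are pure noise + confound leakage
    if spec.n_behaviour:
        behaviour[:, n_loaded:] = noise_b[:, n_loaded:] + (confounds @ gamma)[:, n_loaded:]

    family_id = np.repeat(np.arange(N // spec.family_size), spec.family_size)

    return Cohort(
        subjects=subjects,
        group=group,
        behaviour=behaviour,
        confounds=confounds,
        family_id=family_id,
        latent=latent,
        spec=spec,
        netmats=subject_netmats,
        map_perturbation_weights=w,
        behaviour_loadings_true=load,
    )


def generate_parcellation(spec: CohortSpec, K: int) -> Parcellation:
    """Hard parcellation of the grayordinate axis into K contiguous parcels.

    Grayordinates are ranked by group-map energy (max |group map| across
    modes); the top portion is assigned and split, in axis order, into K
    near-equal contiguous chunks, so every parcel overlaps at least one mode's
    high-weight region.
    """
    spec.validate()
    G = spec.n_grayordinates
    if not 1 <= K <= G:
        raise ValueError(f"K must satisfy 1 <= K <= G={G}, got {K}")
    rng = np.random.default_rng(spec.seed)
    centres, widths, weights = _make_group_bumps(spec, rng)
    group_maps = _render_maps(G, centres, widths, weights)
    energy = np.abs(group_maps).max(axis=1)
    n_assigned = max(K, int(np.ceil(0.5 * G)))
    assigned = np.sort(np.argsort(energy)[::-1][:n_assigned])
    labels = np.zeros(G, dtype=int)
    chunks = np.array_split(assigned, K)
    for k, idx in enumerate(chunks, start=1):
        labels[idx] = k
    return Parcellation(labels=labels)


def generate_task_contrasts(
    cohort: Cohort, n_contrasts: int, noise_sd: float = 0.05, seed: int = 0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-subject task contrast maps plus group average.

    Each contrast is a nonnegative random mixture of that subject's mode maps
    (mixture weights shared across subjects so contrasts correspond) plus
    white noise.  Returns ``(subject_contrasts, group_average)`` with each
    element of shape ``(n_contrasts, G)``.
    """
    if n_contrasts < 2:
        raise ValueError("n_contrasts must be >= 2")
    rng = np.random.default_rng(seed)
    M = cohort.subjects[0].n_modes
    G = cohort.subjects[0].n_grayordinates
    W = rng.uniform(0.0, 1.0, size=(n_contrasts, M)) ** 2  # sparse-ish nonnegative
    subject_contrasts = []
    for s in cohort.subjects:
        C = W @ s.maps.T
        if noise_sd > 0:
            C = C + noise_sd * rng.standard_normal((n_contrasts, G))
        subject_contrasts.append(C)
    group_average = np.mean(subject_contrasts, axis=0)
    return subject_contrasts, group_average
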