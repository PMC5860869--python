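# Methods

This note documents the models, numerical choices and limitations of
`topofc` at the level of detail a maintainer or reviewer needs. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The outer-product data model

A subject's signal subspace is `D_s = P_s · diag(h_s) · A_s + ε` with maps
`P_s ∈ R^{G×M}`, amplitudes `h_s ∈ R^M_{>0}`, timecourses `A_s ∈ R^{M×T}`
and iid Gaussian noise. Orientation is fixed throughout the package: modes
along rows of `A_s`, time along columns; whitening and injection matrices
act on the left. (The transposed convention found in some treatments is
dimensionally ambiguous; fixing row-modes makes every product well defined.)

## Synthetic cohort generator

The generator is the test bed's definition of "truth"; everything downstream
is scored against quantities it stores.

**Group maps.** Each of the M modes is a sum of 3 Gaussian bumps on a 1-D
grayordinate axis, with anchor positions spread over the axis, widths of
order `G/(4M)`, and signed weights in ±[1, 2.5]. This reproduces the
overlapping, soft-parcellation character of functional modes without any
surface geometry.

**Subject maps.** Subject s perturbs the group bump layout in three ways,
all scaled by `spatial_sd`:

* bump-centre displacement — `0.3 × bump-width × (w_s · u + η_s)`;
* bump reweighting — multiplicative `1 + 0.2 (w_s · u' + η'_s)`;
* per-mode column scaling — `exp(0.15 (w_s · c + 0.5 η''_s))`.

Here `w_s = λ·latent_s + √(1−λ²)·ε_s` (λ = `latent_loading_maps`) is the
stored, signed perturbation weight; `u, u', c` are fixed directions shared
by all subjects; and the `η` terms are per-subject idiosyncratic draws.
The decomposition matters scientifically: the shared, latent-weighted part
carries the behaviourally relevant axis; the idiosyncratic part makes
subject spatial variability genuinely high-dimensional (as in real
cohorts); and the column-scaling channel encodes spatial *strength*
information that correlation-based netmats are invariant to — precisely the
kind of information that map binarisation removes and that distinguishes
"maps" from "coupling" in the partial-CCA analyses. Displacement and
reweighting change where regions sit and their internal balance, so
"shape and location", not only strength, vary across subjects.

**Amplitudes and netmats.** `h_s = h_g · exp(amplitude_sd · z)` (log-normal
scatter); the subject mode-correlation target is
`nearest_correlation(R_g + netmat_sd · symmetric noise)`, where the repair
clips eigenvalues at 1e-6 and rescales to unit diagonal. Timecourses are
drawn white and passed through the engine's injection chain, so
`corr(A_sᵀ)` equals the stored subject netmat *exactly* — ground truth is
exact, not approximate.

**Behaviour, confounds, families.** Half of the behaviour columns load on
the latent trait with strengths ±[0.5, 1] times `latent_loading_behaviour`;
all columns receive unit noise and a linear leakage (weights 0.3·N(0,1))
of the nuisance confounds. Families are contiguous equal-size blocks.

**Defaults.** `spatial_sd=1, amplitude_sd=0.2, netmat_sd=0.15,
noise_var=0.1, latent loadings 0.9, family_size=2`. The scales were chosen
so that (i) subject maps deviate visibly but recognisably from the group
(fractional-width displacements, tens-of-percent reweighting), matching
reports that region sizes vary by about twofold across people; (ii)
amplitude scatter is ~20% — typical of session-level BOLD amplitude
variability; (iii) netmat perturbations are small relative to the group
correlation structure. All randomness comes from one `default_rng(seed)`
stream drawn in a fixed documented order, so cohorts are bit-reproducible.

**What the generator does not emulate.** Surface geometry and CIFTI
spaces, haemodynamics, autocorrelated or physiological noise, unequal
family sizes, missing data, non-Gaussian behaviour distributions. Passing
tests therefore demonstrate the *logic* of the analyses under controlled
variability, not their calibration on real fMRI.

## Simulation engine

The injection chain is `B = A·diag(v)^{-1/2}` (unit row variances, `v`
retained), `C = cov(Bᵀ)^{-1/2} B` (ZCA: the unique symmetric SPD inverse
square root — the whitening that minimally distorts the input),
`D = α C` with `α = R^{1/2}` the symmetric PSD square root of the target
correlation, and `E = diag(v)^{1/2} D`. Because the sample covariance of
`C` is exactly the identity, the sample correlation of `D` equals `R`
exactly (to solver precision, ~1e-12); the round-trip with the original
correlation is the identity on variances and correlation within 1e-8
(property-tested). The symmetric choice of `α` (rather than Cholesky)
mirrors the ZCA choice and makes injection∘whitening self-inverse; for
white input the induced correlation is the same for any factor of `R`.

Pseudo-mode generation replaces `P_s → P_g` and/or `h_s → h_g` and/or the
injected `R → R_g` according to the simulation flags. Fixing amplitudes
also swaps the restored variances for the group-average variances (the
group model stores them), since in the outer product the effective mode
strength is `h_i √v_i`. Runs are processed independently when a run length
is given.

Map modulations: `fixed_threshold_binary` (entries > τ → +1, < −τ → −1,
else 0; retains size variability), `threshold_only` (zero sub-threshold
entries, keep surviving weights), `percentile_binary` (per column, exactly
`⌊p/100·G⌋` entries in each tail → ±1, fixing network size across
subjects; at G=91282 and p=5 this is 4564 per tail). The tail-count
convention is deliberate: `floor` of the tail mass, implemented by ranking,
so the count is exact regardless of ties.

Matched reconstruction noise is one global scalar — the mean squared
residual of the reference data under the reference decomposition — not a
per-grayordinate field.

## Extraction

Dual regression stage 1 demeans each map column and each timepoint's data
vector across grayordinates and solves the spatial least-squares problem;
stage 2 variance-normalises the stage-1 series (configurable, default on,
matching common tooling), demeans across time, and solves the temporal
problem per grayordinate. The stage-2 model excludes a grand-mean column —
the demeaned formulation makes it redundant; a consequence is that a
constant-only map set is degenerate (zero regressor after demeaning) and is
rejected rather than special-cased. Parcel extraction is the plain mean
over grayordinates per binary parcel; amplitudes are per-node temporal
standard deviations with runs concatenated.

The task basis is a symmetric fixed-point ICA (tanh negentropy contrast,
deterministic seed, PCA whitening to dimension d) on the group-averaged
contrast maps; the resulting d×n_contrasts weights are applied unchanged to
every subject's contrasts, guaranteeing component correspondence. All basis
maps are sign-fixed (largest-magnitude value positive, decided on the group
basis and reused for subjects) and rescaled to maximum 1.

## Netmats

Partial correlations use a ridge on the *correlation* matrix, `Ω = (R +
ρI)^{-1}`, which makes ρ scale-free and consistent with the small values
over which it is optimised. At ρ=0 this is the textbook partial correlation
(oracle-tested against explicit regression residuals). The ρ grid is
0.01:0.01:0.50; the optimisation reference is the group-average
z-transformed partial netmat at ρ=0.01, subject netmats are z-transformed
before comparison (comparing like with like), and ties resolve to the
smallest ρ. Fisher z is plain `atanh` with edges capped at ±(1−1e-12);
whether an empirically rescaled z would better match any particular
toolchain is left open — plain atanh is the documented choice.

Edge vectorisation is the upper triangle, row-major, diagonal excluded —
for symmetric matrices this is equivalent (up to duplication) to full
off-diagonal vectorisation under correlation.

## Evaluation metrics

`Z_netmat`: subject netmats (z-transformed first, then group-demeaned — the
ordering is fixed here since the source convention is implicit) are
vectorised and correlated within subject between simulation and original;
correlations are capped at ±(1−1e-12) before `atanh` (the mean is undefined
at exact ±1) and averaged. `R_correlation`: the off-diagonals of the two
subject-by-subject correlation matrices are Pearson-correlated.
`measure_similarity` computes full and partial (pseudo-inverse based, so
duplicated measures remain defined) correlations between the cross-subject
similarity structures of several measures.

## CCA stack

Inputs are built as: deconfound (least squares on [intercept, confounds]);
subject covariance (summed over map blocks for spatial features —
equivalently the covariance of concatenated maps); optional
pairwise-complete covariance under missingness followed by a Higham-style
nearest-SPD repair (symmetrise, clip eigenvalues at `1e-10·λ_max`,
reconstruct; idempotent); eigenvectors scaled by √eigenvalue (preserving
the covariance geometry the CCA sees — bare eigenvectors would whiten the
subjects' similarity structure) with a deterministic sign convention.

`cca_fit` is classical CCA via QR of the demeaned score blocks and SVD of
`Qxᵀ Qy`; canonical correlations are the singular values, U/V are
standardised and mutually uncorrelated, and the solution is invariant to
invertible re-mixing of either block's columns (tested against an
independent generalised-eigenvalue oracle).

**Permutation inference** shuffles equal-size family blocks as units and
members within blocks, never across; the identity permutation is one of the
`n_perm` draws, so `p = count/n_perm` with minimum `1/n_perm` (0.00001 at
100 000 permutations). Each permutation contributes only its *first*
canonical correlation, and every mode's observed r is compared against that
null — the max-statistic construction that gives family-wise-error control
across CCA modes without naming a per-mode scheme. Note one finite-group
caveat: with very few families the restricted-permutation group is small
(6 families of 2 → 46 080 elements) and duplicate draws inflate the
attainable minimum p; a dozen families of 2 already put the group size far
beyond any practical `n_perm`.

Partial CCA residualises one block's score columns on the other's (with
intercept), drops numerically null residual directions, and reports all
canonical correlations as 0 in the fully degenerate case.

Surrogate confidence intervals use a matrix-normal model: a surrogate block
is `s · L_r Z L_cᵀ` with `L_r L_rᵀ` the subject covariance, `L_c L_cᵀ` the
feature covariance, and `s` matching the expected total variance to the
input's (the joint row/column preservation is underdetermined; the total-
variance scaling is the package's convention). X and Y surrogates are drawn
independently — correlated perturbation of both is a plausible alternative
not implemented.

Interpretation helpers: behaviour loadings (per-variable correlation with
V₁, NaN for constant variables, report threshold |r|>0.25), rank-one
back-projection of U₁ over a score range extended 10% beyond both extremes
(5 frames by default), and grayordinate-wise max-|r| between subject
weights and subject map values.

## Experiment orchestration and problem sizes

`run_table_experiment` and `run_topography_vs_coupling` derive all
stage seeds from one master seed via `SeedSequence.spawn`, log stage
timings, continue past failing rows, and stamp outputs with a SHA-256
config hash. The number of CCA eigenvector scores defaults to
`min(100, N/8)` — the ratio the 100-of-819 design implies; pushing Kc
toward N/2 drives the null first canonical correlation toward 1 (the
Jacobi-ensemble support edge is `2√(c(1−c))` at `c = Kc/N`) and destroys
power, which is also why the partial-CCA experiment uses N=120 subjects
with Kc=10.

Desk-scale sizes used by the test suite: the selective-fixing table runs 50
subjects, G=2000, M=10, T=600; latent recovery runs 200 subjects, G=1000;
the partial-CCA comparison 120 subjects, G=800, T=250; permutation-validity
checks 200 null cohorts at 200 permutations. These sizes were chosen as the
smallest at which the respective effects have comfortable statistical
margin.

## Known limitations

* 1-D grayordinate geometry: no spatial autocorrelation structure beyond
  bump smoothness, no hemispheric or network topology.
* The latent trait is one-dimensional; real population covariation has
  many axes.
* Only equal-size family blocks are supported (no general exchangeability
  trees).
* The iid Monte-Carlo null for the first canonical correlation (the
  calibration quantity `scripts/acceptance.py` recomputes) concentrates at
  the Jacobi edge `2√(c(1−c))` ≈ 0.655 for c = 100/819; empirical
  permutation nulls on real, family-structured, deconfounded cohorts sit
  slightly higher because subjects are not exchangeable iid draws.
* Tikhonov z-transformed partials use plain `atanh`; toolchains that apply
  an empirical z-scaling will differ by a smooth monotone factor.
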