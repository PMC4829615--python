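# Methods

## Scope and model

`slowosc` analyses the spectral composition of intrinsic connectivity
network (ICN) oscillations in multi-subject resting-state fMRI. The
observation model underlying both the generator and the analysis is a
linear mixture: subject *i*'s scan is

    X_i(v, t) = Σ_c M_c(v) · s_{ic}(t) + ε_i(v, t),

with shared non-negative spatial maps `M_c`, subject-specific component
time courses `s_ic`, and white voxel noise ε. The analysis chain
estimates the maps and time courses by group spatial ICA and then
characterises each component's spectrum through band-limited
fractional ALFF (fALFF).

## Frequency bands

Infra-slow bands follow the standard decomposition: slow-5
0.01–0.027 Hz, slow-4 0.027–0.073 Hz, their union ("resting")
0.01–0.073 Hz, the robustness bands LF 0.01–0.1 Hz and HF
0.1 Hz–Nyquist, and the full acquired range 0–Nyquist. All intervals
are half-open `[lo, hi)` except those ending at Nyquist, which are
closed above; a Fourier frequency at exactly 0.027 Hz belongs to
slow-4. A Nyquist at or below 0.073 Hz (TR ≥ ~6.8 s) is rejected: the
slow-4 band would be truncated and band fALFF ill-defined. At the
default TR of 2.6 s and 220 retained volumes the Fourier resolution is
1/(220·2.6) ≈ 0.00175 Hz and the Nyquist 0.1923 Hz.

## Preprocessing

Temporal-only, by design: the first `n_discard` (default 10) volumes
are dropped, voxel series are despiked by clipping against a
running-median (window 7) baseline at ±k·MAD (k = 5, MAD scaled to
σ-equivalent), and linearly detrended. A constant series has MAD 0 and
passes through unchanged. Spatial registration stages (slice timing,
realignment, template normalisation, spatial smoothing) are not
implemented: synthetic cohorts are generated on a common grid, and
those stages are off-the-shelf image registration orthogonal to the
spectral analysis that is this package's subject.

Motion is represented as a 6-parameter rigid-body track (x, y, z in
mm; roll, pitch, yaw in degrees). Rotations are converted to arc
millimetres on a 50-mm-radius sphere (a common convention; the radius
is a module constant). Subjects are excluded when any single
parameter's peak-to-peak excursion strictly exceeds 2 mm; the per-frame
Euclidean norm (enorm) of backward differences is reported as a
summary. Peak-to-peak (rather than frame-wise) excursion was a
genuinely open choice; it is the stricter reading of a "greater than
2 mm in each direction" criterion and is flagged here.

## Group ICA

Two-stage reduction: each demeaned subject matrix (time × voxels) is
reduced to `subject_pca_dim` temporal principal components (default
1.5·k — a common heuristic; only "standard PCA" is prescribed by the
design), the reduced matrices are concatenated along the reduced-time
axis, and a group PCA yields k whitened rows over voxels (k default 28;
simulation tests use k = 8 on 12-subject cohorts, a deliberate
scale-down). Demeaning costs one rank; the rank check tolerates exactly
that and rejects genuinely degenerate subjects by name.

Spatial Infomax ICA maximises the entropy of logistic-transformed
sources with voxels as i.i.d. samples, via the natural-gradient update
`W += lr (I + (1 − 2σ(u)) uᵀ/B) W` on shuffled voxel batches (B = 256).
Convergence is declared when the largest per-batch weight change falls
below `tol` (1e-6, relative to the weight scale) or after `max_iter`
(512) epochs; on divergence the learning rate (default 0.01) is halved
and estimation restarts, and repeated failure raises. These
hyperparameters are this package's own choices. No bias term is used —
inputs are whitened and zero-mean. Output maps are normalised to unit
variance and oriented to positive skewness (network maps are sparse
and positive-tailed, making the sign convention stable); Infomax with
a logistic nonlinearity recovers super-Gaussian sources, which spatial
network maps are. Gaussian-only sources are unidentifiable; the
implementation still terminates and simply returns an arbitrary
rotation.

GICA back-reconstruction: writing the concatenated reduced data as
`G diag(s) Vᵀ` and the ICA maps as `S = W H`, the concatenated mixing
matrix is `M = G diag(s) W⁻¹ / √n_vox`; its per-subject block `M_i`
lifts through the subject's temporal basis `U_i` to give time courses
`TC_i = U_i M_i`, and subject maps are `pinv(M_i) · (U_iᵀ X_i)`. For a
cohort of identical subjects every back-reconstructed time course
equals the group time course up to scale.

**Stability (ICASSO-style).** The ICA is rerun `n_stability_runs`
(default 20) times under subject-level bootstrap and random
initialisation; all runs' maps are pooled with the reference fit and
clustered by average linkage on the 1 − |r| spatial distance. Clusters
are cut at |r| = 0.5 rather than at exactly k clusters: scattered
noise components otherwise consume the cluster budget and force
distinct stable clusters to merge. Each reference component scores
(mean intra-cluster |r|) − (mean |r| to non-members), clipped to
[0, 1]. On planted cohorts stable components score > 0.9 while
pure-noise ICA stays well below.

**Identification and robustness.** Components are assigned to named
templates greedily in descending |spatial r| (threshold 0.3, each
template and component used once, maps sign-flipped to positive
correlation). A component is retained as an ICN only if the mean over
subjects of its LF/HF spectral power ratio exceeds 50 (strictly); a
subject with zero HF power contributes an infinite ratio. Templates
come from the generator's ground truth in simulations; for real data
the CLI accepts user-supplied template maps — no atlas is bundled.

## Spectra and fALFF

Per-subject component spectra are computed from the GICA
back-reconstructed time courses (the basis of between-subject
statistics; the group-level alternative is exposed too, as the
convention is genuinely ambiguous in the field). The one-sided
magnitude spectrum |X(f_k)| (no windowing; amplitude = √power,
following the fALFF literature) is smoothed with a Gaussian kernel of
σ = 2 Fourier bins, reflect boundaries — σ is interpreted in bin units
as no unit is conventional, and smoothing conserves interior amplitude
mass to within 1%. fALFF is computed from the smoothed spectrum (a
flag allows raw-spectrum fALFF for sensitivity checks):
`fALFF(band) = Σ_band |X| / Σ_denominator |X|`, denominator the full
acquired range unless stated. Disjoint bands are exactly additive and
the measure is invariant to positive rescaling of the series. For the
discrete bin analysis the smoothed spectrum is linearly interpolated
onto 34 bins of 0.0015 Hz spanning 0.009–0.060 Hz — interpolation, not
aggregation, because the bin width is finer than the native Fourier
resolution. Composite components (DMN = pDMN + aDMN + vDMN;
visual–sensorimotor = visual + motor) are unweighted means of member
spectra.

## Group statistics

Per-bin comparisons use the pooled-variance two-sample Student t-test
(Welch available by flag), reported uncorrected at α = 0.05 — the
per-bin analysis is descriptive by design — with optional
Benjamini–Hochberg columns. Zero-variance bins are handled explicitly
(identical groups: t = 0, p = 1). Component fALFF is tested with
one-way fixed-effects ANOVA followed by Tukey HSD using the
studentized range with the Tukey–Kramer unequal-n correction (group
sizes 43/42/14/16 differ). One-tailed contrasts must be declared in
configuration; inferring the direction from the data would double the
nominal error rate, so an unstated direction raises. The contrast
report assembles every component × band × contrast cell with group
means, t, p and — on simulated data — the generative mean difference
and whether the detected sign matches it.

## Synthetic cohort generator

**Time courses.** A component time course is the sum of random-phase
sinusoids at every Fourier frequency inside slow-5, jointly scaled so
that the slow-5 part has standard deviation `slow5_amp` (each sinusoid
gets its own phase, avoiding phase-locked degeneracy), the same
construction for slow-4, and white noise of sd `broadband_amp`
(default 1, the amplitude unit). No hemodynamic convolution and no
cardiac/respiratory cycles are modelled — the study design this
emulates acquired no physiological recordings — and scanner noise is
white by default.

**Analytic oracle.** The expected smoothed amplitude spectrum is
available in closed form: a sinusoid of amplitude A contributes A·T/2
to its bin; noise makes each bin Rice-distributed with mean
σ√(πT/2)/√2 · ₁F₁(−½; 1; −A'²/(2σ'²)), and the σ = 2 smoothing kernel
is applied to the expectation (smoothing is linear, so this is exact).
Generative band fALFF computed this way matches the pipeline-measured
value within Monte-Carlo error and serves as the independent oracle in
tests.

**Group structure.** Effects are parameterised by target generative
slow-5 fALFF per component and group; the (slow5, slow4) amplitude
pair is solved by root-finding under a total low-frequency power
constraint (slow5² + slow4² fixed, default 30 noise-variance units).
The default targets are the published component means where available
(old → stroke-late: pDMN 0.383 → 0.329, aDMN 0.401 → 0.335, vDMN
0.349 → 0.305, visual 0.429 → 0.385, motor 0.437 → 0.376); stroke-early
equals old; young-group values are not published and default to
old + 0.05 in the DMN and old − 0.05 in visual/motor, following the
qualitative aging pattern. LF power is constant across old /
stroke-early / stroke-late (the stroke effect is a reallocation, not a
loss) while the young DMN gets 1.2× (aging depletes DMN resting
power). Group sizes default to the study cohort: 43 young, 42 old, 14
stroke-early, 16 stroke-late; 230 volumes at TR 2.6 s.

**Between-subject variability.** Each subject's slow-5 and slow-4
amplitudes are independently jittered by a factor
max(1 + N(0, 0.4), 0.05); 0.4 was calibrated once so the measured
per-subject fALFF standard deviation is ≈ 0.1, the scale implied by
the study's reported t statistics. The multiplicative jitter pulls the
*group-mean* measured fALFF a few percent below the nominal target
(Jensen's inequality on the concave amplitude→fALFF map); per-subject
analytic targets are recorded in the ground truth and the pipeline is
unbiased against those.

**Spatial maps and scans.** Maps are sums of one or two Gaussian blobs
on a 20×24×20 voxel grid (geometry scales with the grid), with centres
chosen so all pairwise map correlations stay below 0.3 — blob geometry
is this package's own choice, as no spatial extents are prescribed.
Scans are map ⊗ time-course mixtures plus white voxel noise (sd 1).
Motion tracks are smooth mean-reverting walks (reversion 0.9 per
frame) rescaled to a target mean frame-to-frame enorm (default
0.15 mm); a pure random walk at realistic per-frame motion drifts past
the 2-mm exclusion range for essentially all subjects, which would
empty every cohort. One seeded generator drives everything: a fixed
seed fixes every output byte.

**What the generator does not emulate.** Hemodynamic filtering,
physiological noise, spatial autocorrelation of scanner noise,
subject-specific map variability, lesions, and registration errors.
Passing tests therefore validate the estimation chain under the linear
mixing model, not robustness to those real-data complications.

## Numerical and design notes

- fALFF denominators with zero mass raise a degenerate-series error
  rather than returning NaN.
- The robustness threshold comparison is strict (> 50); a ratio equal
  to the threshold fails.
- Tukey mean differences follow the statsmodels pair ordering
  (second group minus first).
- The variance-explained diagnostic is the energy of the retained
  group singular values over the total demeaned data energy; it is
  monotone non-decreasing in k at fixed subject PCA dimension.
- Problem sizes in tests (12-subject cohorts, k = 8, reduced grids,
  1000-replicate null calibrations, 11-replicate effect-pattern runs)
  are deliberate scale-downs chosen to exercise every property at
  desk scale.

## Known limitations

- Infomax uses a fixed logistic nonlinearity; sub-Gaussian sources
  (e.g. artefactual slow drifts) would need extended-Infomax, which is
  not implemented.
- The ICASSO surrogate reports a similarity-contrast index, not the
  original cluster-quality index of the reference toolbox.
- Back-reconstruction is GICA only; dual regression is not offered.
- Composite components average spectra with equal weights; no
  variance-weighting is attempted.
- The per-bin analysis is reported uncorrected by design; treat
  isolated significant bins accordingly.
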