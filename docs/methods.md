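# Methods

## Pipeline

Per subject, in order: discard the first `n_discard` frames (default 10);
compute framewise displacement and apply the motion exclusion rule;
regress nuisance covariates; optionally band-pass; slide tapered windows;
evaluate the five indices per window; form variability maps (SD →
normalize → smooth) and the two concordance summaries. Group analysis
then contrasts the per-subject maps and scalars.

### Motion

Framewise displacement follows Power: FD_i = Σ|Δtranslation| +
r·Σ|Δrotation in radians| with r = 50 mm, FD_1 = 0. The formulation is a
deliberate choice — Jenkinson's RMS variant is equally defensible but the
two cannot both be matched; Power's is the more common default and the
one implemented. Subjects are excluded when any frame's absolute
translation exceeds 3 mm on any axis or any rotation exceeds 3°
(thresholds configurable). Motion files carry degrees on disk; radians
are used internally.

### Nuisance regression

Voxel-wise OLS against intercept, linear drift (0..t−1 rescaled to
[−0.5, 0.5] for conditioning), the Friston-24 expansion
[p, p², p_{t−1}, p_{t−1}²] (lagged first row zero-filled), and mean WM /
CSF signals when masks are supplied (mean series over the supplied
masks, not a component-based method). A rank-deficient design raises an
error naming the collinear columns. Residuals are exactly orthogonal to
the design, and the operation is idempotent.

### Band-pass

FFT-domain: bins strictly outside [0.01, 0.08] Hz (including DC) are
zeroed. Applied after nuisance regression and before ReHo/DC/VMHC/GSC —
never before ALFF, whose band selection happens in its own spectrum.
Controlled by `AnalysisConfig.bandpass` (default on): the
correlation/rank indices are conventionally computed on band-limited
data, while ALFF must see the unfiltered spectrum.

### Windows

Half-open 0-based ranges [start, start+L), starts {0, s, 2s, ...},
n = floor((t−L)/s)+1. Defaults L = 32 TR, s = 4 TR: 50 windows for a
230-frame series. Each segment is demeaned per voxel and then multiplied
by the classical hamming taper w(n) = 0.54 − 0.46·cos(2πn/(L−1));
demean-then-taper prevents the taper from leaking the segment mean into
the spectrum. The taper applies uniformly to all five indices (it is a
property of the windowing, not of any one index); `taper: none` is
available, and rank/correlation indices are only mildly affected by it.

### Indices

- ALFF: single-sided amplitudes a_k = 2|X_k|/L for k ≥ 1; mean over bins
  with f_lo ≤ k/(L·TR) ≤ f_hi. An empty band raises an error advising a
  longer window.
- ReHo: Kendall's W over the in-mask 27-voxel neighbourhood (centre + 26
  neighbours; 7/19 available) across the window's time points, tie
  corrections included.
- DC: binary degree over signed r > 0.25 ("exceeding" read literally, so
  negative correlations never count), z-scored across the mask per
  window. A zero-SD degree map yields zeros, not NaN.
- VMHC: reflection across the mid-plane of the first grid axis; even
  first dimension required (no symmetric-template resampling — upstream
  registration is out of scope). Unpaired voxels are NaN.
- GSC: correlation with the unweighted mask-mean of the same segment.
- Fisher z uses atanh with |r| clamped at 1 − 1e−7 so degenerate perfect
  correlations stay finite.
- A voxel with zero variance within a window gets NaN for all five
  indices in that window; NaN voxels are dropped pairwise downstream and
  counted in the log.

### Variability maps

Population SD (divide by n_windows) across windows — windows overlap, so
neither population nor sample SD is canonically "correct"; population is
fixed for determinism. Normalization across the mask is z-scoring with
ddof = 1 by default (`normalization: mean`, divide-by-mask-mean, is the
documented alternative since toolkits differ). Order is normalize THEN
smooth. Smoothing is a separable Gaussian with σ_axis =
FWHM/(2√(2 ln 2)·voxel_size_axis) (0.566 voxels for 4 mm FWHM at 3 mm
voxels), NaN-aware and mask-renormalized: the zero-filled map and the
valid-voxel indicator are smoothed with the same kernel and divided, so
edge voxels are unbiased.

### Concordance

W uses average ranks and the tie-corrected denominator
m²(n³−n) − m·ΣT_j; a judge with constant values contributes uniform
ranks; if every judge is constant the result is NaN (the statistic
carries no information). Voxel-wise concordance treats the five indices
as judges and windows as items, dropping (per voxel) windows where any
index is NaN; the map is computed on unsmoothed index stacks and only
the resulting map is smoothed. Volume-wise concordance ranks the fixed
intersection of voxels valid across all indices and windows, per window,
and averages W over windows — keeping the item set constant across
windows. Both summaries are invariant to per-index monotone transforms;
the volume-wise one is additionally invariant to per-window
standardization.

Note on baselines: for five mutually independent series E[W] = 1/m =
0.2, but the five indices of a real voxel are computed from the same
data and co-fluctuate through shared sampling variability, so empirical
voxel-wise W sits near 0.5 even without planted structure — consistent
with reported concordance levels in healthy cohorts.

### Group statistics

Voxel-wise: OLS GLM (intercept + group + optional covariates), t for the
group coefficient, df = N − p. Multiple comparisons use a permutation
max-statistic test instead of Gaussian-random-field correction: GRF needs
smoothness estimation machinery that is tangential here, while
permutation is exact under exchangeability and directly testable. The
cluster-forming threshold is |t| > t_df(1 − p/2) at p = 0.001
(two-tailed); supra-threshold voxels form 26-connected clusters;
positive and negative clusters are pooled against one null of the
largest |t|-cluster statistic per permutation; cluster
p = (1 + #{null ≥ observed})/(1 + n_perm). With covariates, permutation
follows Freedman–Lane (reduced-model residuals are permuted). When
n_perm reaches the number of distinct labelings a warning is logged.

The cluster statistic is extent with ties broken by supra-threshold
mass: stat = size + m/(1+m), m = Σ(|t| − threshold) over the cluster.
The tie-break term is < 1, so the extent ordering is preserved exactly;
its purpose is numerical: on desk-scale grids the integer extent
distribution is heavily tied, which makes the permutation test validly
but markedly conservative (measured type-I ≈ 0.015 instead of 0.05);
the continuous refinement restores exactness (measured ≈ 0.055 over 200
null cohorts) without changing which clusters are larger than which.

Scalar ANCOVA on volume-wise concordance is the same GLM applied to one
"voxel" (F = t²). Summary-statistic tests (pooled t, Welch t with
Satterthwaite df, Pearson χ² without continuity correction) operate on
printed group summaries; both t variants are provided because reports
rarely state which was used per row. Partial correlations residualize
both variables on the covariates (+intercept), rank-transforming first
for Spearman; p from t = r√((n−2−k)/(1−r²)). Gender enters covariate
sets as a 0/1 code.

Voxel-wise group maps are tested without covariates by default (the
covariate set for map contrasts is configurable); correlations control
for age, gender, IQ and mean FD by default.

## Synthetic data

The generator emulates the statistical structure the dynamic indices
assume, not BOLD biophysics. Defaults (the frozen study conditions):
24×24×16 voxels of 3 mm in an ellipsoidal, bilaterally symmetric mask
(~3600 voxels), 240 frames at TR = 2 s, two groups of 20.

Each voxel: AR(1) noise (φ = 0.4, unit SD) plus band-limited
(0.01–0.08 Hz) structured components:

- one global and two network components, each with a smooth, bilaterally
  symmetric, non-negative loading field (peak loadings 1.2 / 1.0) and an
  independent slow envelope 1 + d·e(t) (d = 1.2, e Gaussian smoothed at
  σ = 40 frames, standardized, product clipped at 0). Several
  independent sources of deep, slow co-fluctuation give the concordance
  maps stable spatial structure that is not hostage to a single envelope
  realization; the depths/loadings were calibrated so the mean voxel-wise
  W (~0.5) and its spatial contrast match levels reported for real
  cohorts;
- a dALFF region (3×3×3) sharing a carrier whose envelope depth differs
  by group (patient 0.8 vs control 0.4) — the planted dynamic-amplitude
  effect;
- a ReHo region mixing a common local carrier (coherence 0.6) with
  private carriers;
- homotopic pairs (3×3×3 per hemisphere) sharing per-pair carriers at
  coupling 0.9, amplitude 1.8;
- a hub voxel sharing a latent with 150 satellites (amplitude 1.5) —
  sized so the hub stands out over the degree spread the global
  component itself induces;
- motion traces: per-axis random walks (step SD 0.02) giving mean FD
  ≈ 0.09 mm; a designated violator fraction receives one frame beyond
  the 3 mm/3° rule;
- clinical scores: β·(planted per-subject concordance scalar) +
  covariate loadings + Gaussian noise, with β solvable for any target
  partial correlation (`partial_r_to_beta`).

Everything is bit-reproducible from (spec, seed).

What the generator does NOT emulate: hemodynamic nonlinearity, scanner
drift/spikes, physiological (cardiac/respiratory) aliasing, anatomical
tissue classes, or spatially varying noise. Passing tests therefore
demonstrate that the estimators and inference machinery behave correctly
on data with the assumed statistical structure — not that the pipeline
is robust to every artifact of real scanners.

## Calibration studies and problem sizes

The cluster-inference calibration and power studies run on subject-level
maps drawn directly as smoothed (FWHM 4 mm) unit-variance Gaussian noise
fields — the object the group stage actually consumes (variability maps
are smoothed and normalized) — rather than full BOLD cohorts, which
keeps hundreds of replicates at desk scale: type-I error over 200 null
cohorts of n = 10/group with 200 permutations each; power over 50
replicates of an 18-voxel region shifted by 1.5 SD at n = 20/group (the
region extent was fixed by an a-priori power analysis; real clusters
span tens to hundreds of voxels). The score-association study recovers a
true partial r = −0.4 at n = 50 with 4 covariates over 200 replicates.
Window-length robustness runs the full BOLD pipeline on one default
synthetic subject at 32/48/64 TR; pairwise map correlations land between
0.88 and 0.99 depending on the realization, reflecting the shrinking
number of effectively independent windows at 64 TR.

## Degenerate inputs and numerical choices

- Empty masks, < 2 frames, non-finite in-mask values, 5-column motion
  files, duplicate subject ids and unknown group labels are rejected at
  construction/read time.
- All-constant data: W → NaN; DC z-map → zeros; zero-spread
  normalization raises.
- z-scores across the mask use ddof = 1 throughout; SD across windows
  uses ddof = 0.
- Permutation p-values use the add-one estimator and never reach 0.
- Determinism: a single integer seed governs every random draw; rerunning
  a subject yields byte-identical output hashes (recorded per run in the
  manifest).

## Known limitations

- VMHC uses grid-plane mirroring; real data would need a symmetric
  template upstream.
- DC stores no weighted variant; fALFF and frequency sub-bands are out
  of scope.
- The permutation null is label exchangeability; heteroscedastic groups
  at very small n would call for sign-flipping or Welch-based statistics.
- The gray-matter mask is an input, never derived; scrubbing/censoring
  is not implemented.
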