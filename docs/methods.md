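# Methods

This document specifies the models, the analysis constants, the
synthetic generator, and the numerical choices made in `confield`. All
empirical numbers quoted here were computed with this package (seeds
stated); nothing is asserted that the code does not compute.

## Population receptive field (pRF) model

A source vertex's response to a binary stimulus aperture movie `A(t, x, y)`
is modeled as the overlap with an isotropic 2D Gaussian in visual space,

    p(t) = β · Σ_{x,y} A(t, x, y) · exp(−((x − x0)² + (y − y0)²) / 2σ²) + b,

with center `(x0, y0)` (degrees), size `σ > 0`, amplitude `β`, and
baseline `b`. Fitting is a grid search over candidate `(x0, y0, σ)`
with `β, b` solved per candidate by least squares, scored by R²;
optional L-BFGS-B refinement (`PRFConfig.iterative`) polishes the grid
optimum and never regresses R². Optional convolution with a
peak-normalized double-gamma hemodynamic response (`PRFConfig.hrf`) is
**off by default** because the bundled generator emits neural-level
signals; enable it for BOLD-like data.

Eligibility as a CF center requires R² > 0.2, pRF center inside the
stimulated field (eccentricity ≤ aperture radius), and positive
amplitude.

## Connective field (CF) model

A target time course is modeled as a Gaussian kernel on the source
surface, per hemisphere:

    CF(v; v0, σ) = exp(−d(v, v0)² / 2σ²),

where `d` is the geodesic distance in mm between source vertices. The
model prediction is the z-scored CF-weighted sum of all source-region
signals (all vertices participate in the weighting; eligibility
restricts only the candidate *centers*). No hemodynamic convolution is
applied at this stage: predictions and targets are compared as z-scored
series by Pearson correlation, and the best candidate maximizes the
*squared* correlation, with candidates from both hemispheres competing
(the winning hemisphere is the laterality proxy).

The σ ladder is fixed: 0.5, 1, 2, 3, 4, 5, 7, 10, 15, 20, 30, 40, 80 mm.
Exact score ties resolve to the smallest σ, then the lowest center
index (candidates are enumerated σ-major ascending).

### Cross-validation and the null model

Selection is leave-one-run-out (fourfold with the default four runs):
each fold selects the best candidate on the concatenated training runs
(each run preprocessed separately beforehand) and scores that fixed
candidate on the left-out run. The nontopographic **null model** — the
z-scored average of *all* source vertices, both hemispheres — is scored
on the same left-out runs, and

    corrected = mean_folds(cv_r) − mean_folds(null_r)

indexes topographic connectivity above the global-signal baseline.
Corrected values are differences of correlations and are not themselves
correlations.

Parameters are averaged across folds: the reported center `v0` is the
geodesic Fréchet mean of the fold-selected centers within the modal
hemisphere (the source vertex minimizing the summed squared geodesic
distance to the fold winners); `sigma_cf` reports the modal fold value
(always on the ladder) and `sigma_cf_mean` the arithmetic fold mean.

### State contrast

With CF fits per condition, each target's represented visual-field
position is the pRF of its CF center, and its represented hemifield is
contralateral to the CF hemisphere. Cross-state statistics:

- normalized preference ratio `ρ_RS / (ρ_RS + ρ_MW)` of corrected
  values; negative constituents are clamped to 0 and ratios with
  clamped denominator < 0.01 are undefined (NaN);
- weighted Pearson correlation and weighted paired t test
  (statsmodels `DescrStatsW`), weighted by corrected values, with
  degrees of freedom from the Kish effective sample size
  `n_eff = (Σw)² / Σw²`; under uniform weights both reduce *exactly* to
  their classical counterparts;
- contralaterality index `(n_contra − n_ipsi) / n`, tested against 0
  across units with a one-sample t test.

## Preprocessing

Each run is detrended by subtracting a Savitzky–Golay filter (third
order, 210-s window by default; the window length in samples is derived
from the sampling rate and forced odd) and then z-scored per vertex
(population SD; constant rows map to zeros). Runs are never
concatenated before preprocessing. Retinotopy runs are averaged across
runs after preprocessing, before pRF fitting.

## Geometry

Geodesic distances are computed with the heat method on the triangle
mesh (cotangent Laplacian, lumped mass matrix; diffuse, normalize the
gradient, solve the Poisson problem), then clamped into a certified
sandwich: from below by the Euclidean chord length (a true lower bound)
and from above by edge-graph Dijkstra shortest paths (a true upper
bound), with an additional unfolded face-strip shortcut graph
tightening the upper bound. Distance matrices are symmetrized. On
planar test grids the result is within 3% of the exact (Euclidean)
geodesic. Distances are computed per hemisphere and never mixed.

## Synthetic generator

The generator's defaults are the study conditions; they are fixed a
priori and are not adjusted to outcomes.

- **Sheets**: two hemispheres, 20 × 25 vertices at 1 mm spacing, planar
  regular triangulation (alternating diagonals), the whole sheet
  labeled V1. Planar sheets keep the geometry oracle exact.
- **Retinotopy**: eccentricity 0.25–7° linear along one axis, polar
  angle ±80° along the other; the left hemisphere maps the right
  hemifield and vice versa; pRF size = 0.15 + 0.15 · eccentricity.
- **Apertures**: bar sweeps (4 directions) and a rotating wedge for
  retinotopy; a "noise" kind (random smoothed binary patterns, default
  1° scale, 30% fill) emulates naturalistic clips for stimulated-mode
  conditions, one independent movie per run.
- **Sources**: stimulated runs are z-scored pRF-overlap series plus
  white noise (SD 1.5 in z units); resting runs are a latent field of
  white noise smoothed over the sheet (Gaussian, 2 mm correlation
  length) and mildly in time, plus white noise. Hemispheres' latents
  are independent.
- **Targets**: 200 targets, alternating hemispheres; planted CF centers
  drawn away from the sheet border; planted σ ∈ {2, 3, 5, 7} mm. Each
  target is `zscore(CF-weighted source sum) + 0.3 · zscore(global mean
  source signal) + noise`; pure-null targets (optional fraction)
  receive only the global mean plus noise. At these defaults the
  within-set target r² is ≈ 0.35.
- **Determinism**: all randomness descends from one root seed through
  named streams (crc32-hashed keys), so identical configs regenerate
  bit-identical data across processes.

Scope: the generator validates the *estimator*, not hemodynamics — no
HRF, no physiological confounds, no volumetric targets (surface targets
only; volumetric projection is an extension point), planar rather than
folded cortical geometry.

## Numerical choices

- GIFTI pointsets are stored float32 (the standard's only pointset
  type); mm-grid coordinates are float32-exact. Timecourse NPZ round
  trips are bit-exact.
- Correlations are computed from demeaned unit-norm rows (BLAS matrix
  products); zero-variance rows are flagged invalid and carry r = 0.
- Degenerate statistics follow fixed conventions: zero-SD samples
  centered on the null give (t = 0, p = 1), off-center give
  (±inf, p = 0).
- The pipeline writes its fully resolved config (YAML) and a sha256
  config hash into every output directory; reruns are byte-identical.

## Limitations

Measured with this package on the default configuration (ledger seeds;
"recovery" = fitted v0 within one vertex spacing of truth):

1. **Broad kernels are weakly localizable on a small sheet.** With
   planted σ = 7 mm on a 20 × 25 mm sheet, neighboring candidate
   predictions correlate > 0.995 and selection is noise-limited:
   full-data recovery at σ = 7 is ~0.59–0.77 across seeds 0–9 (σ = 2–3
   mm is ~1.0), giving joint v0+σ recovery 0.835–0.910 (mean 0.881,
   0.880 at seed 0) against a 0.90 release criterion. Exact distances
   instead of heat geodesics change nothing; this is an
   information-theoretic limit of the configuration, not a solver
   artifact.
2. **The null model strictly dominates on null targets.** Because the
   generator's resting latents are independent across hemispheres, the
   cross-hemispheric mean (the null model) cannot be matched by any
   single-hemisphere CF: pure-null targets get mean corrected ≈ −0.165
   rather than ≈ 0. The direction is conservative — mean-driven targets
   are penalized, never credited — but the ±0.02 release band assumes a
   hemisphere-shared global signal, as in real BOLD. Relatedly, focal
   targets' mean corrected is 0.187 (criterion > 0.2), since the
   correction subtracts a null_r of ≈ 0.40 driven by the planted global
   coupling.
3. **Cross-state agreement compounds per-state jitter.** Stimulated-mode
   (noise-movie) recovery is ~0.72–0.76; resting ~0.88; their center
   agreement is 0.65 at seed 0 (criterion ≥ 0.85), dominated by the
   same broad-σ ambiguity in both states.
4. The generator has no hemodynamics, motion, or physiological noise;
   preference-ratio behavior under such confounds is untested here.
5. Weighted-statistic p values rely on the Kish effective-n t
   approximation, which is inexact for highly concentrated weights.
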