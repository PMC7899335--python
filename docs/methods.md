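# Methods

This note documents the models, algorithms and parameter choices
implemented in glrkit, what the synthetic data does and does not
emulate, and the numerical decisions behind the code.

## 1. Line-scan puncta calling (`glrkit.puncta`)

**Input.** A 1-D intensity profile sampled on a uniform grid
(default pixel size 0.1 µm/px, a typical confocal sampling for
diffraction-limited puncta). `LineScan.from_csv` reads two columns,
`position_um` and `intensity`; positions must be uniformly spaced and
intensities finite and non-negative.

**Background.** Iterative sigma clipping: the estimate is seeded from
the median and 1.4826·MAD (the normal-consistent median absolute
deviation) and then iterated up to 10 times, each pass keeping pixels
within 3 SD of the current mean. Seeding from median/MAD rather than
mean/SD matters when puncta cover a large fraction of the scan: a
mean/SD seed is dragged upward by bright puncta and the clip can fail
to converge back to the true baseline. At least 20 pixels and at
least 10 surviving pixels are required (`DegenerateScanError`
otherwise).

**Detection.** The threshold is `bg_mean + k_sd * bg_sd` with
`k_sd = 4` by default. A punctum is a maximal run of consecutive
supra-threshold pixels whose width (run length × pixel size) is at
least `min_width_um = 0.3` µm; narrower runs are discarded as noise
spikes. The punctum center is the position of the maximum pixel in
the run (ties resolve toward the run midpoint). Runs are half-open
pixel spans `[start, stop)`.

**FWHM.** The half level is `bg + 0.5*(peak − bg)`. From the peak
pixel the algorithm walks outward in each direction to the first
pixel below the half level and linearly interpolates the crossing
position between the bracketing pixels; the FWHM is the distance
between the two crossings. If a crossing is not found before the scan
edge the punctum is flagged `edge=True` and its FWHM is reported from
the available side mirrored (consumers can exclude edge puncta). For
a noiseless Gaussian of width σ the recovered value matches the
analytic 2√(2 ln 2)·σ to < 0.1 px.

**Summary.** Density is `10 * n_puncta / length_um` (puncta per
10 µm). Peak normalization divides peak heights by a same-day
fluorescent-bead mean intensity; `summarize(...,
normalize=True)` requires the bead value and raises
`CalibrationError` if absent, even when zero puncta were found.
`extract_linescan` samples a 2-D image along an arbitrary polyline
with spline interpolation (`scipy.ndimage.map_coordinates`).

## 2. SEP/mCherry surface fraction (`glrkit.dualreporter`)

**Model.** With surface fraction *f*, quench efficiency *q* (fraction
of internal SEP fluorescence lost at endosomal pH; default 1, i.e.
complete quenching) and total receptor signal *T*:

    SEP     = T * (f + (1 − f)(1 − q))
    mCherry = T
    ratio   = SEP / mCherry = f + (1 − f)(1 − q)

Inversion: `f_hat = (ratio/cal − (1 − q)) / q`, where `cal` absorbs
channel gain differences (default 1; in practice the same-day control
ratio). `f_hat` is clamped to [0, 1] and the clamped flag returned;
`q <= 0` makes *f* non-identifiable and raises. The identity is exact
by construction; under noise the estimator is consistent because both
integrated densities are sums over the same ROI.

**Thresholds.** Per-channel thresholds are calibrated as the mean
over ≥ 3 control images of `bg + k_sd * sd` from sigma-clipped
background statistics. Integrated density is the sum of ROI pixels
strictly above the channel threshold; soma totals are unthresholded
(area and sum) since somatic signal is diffuse. Ratios are normalized
to the mean of same-day controls (per-day groupby; falls back to the
global control mean for days without controls, with a warning).

## 3. Dual-channel FRAP (`glrkit.frap`, forward model in `glrkit.synthdata`)

**Compartment model.** Four pools per fluorophore — surface/internal
× unbleached/bleached — with first-order exchange: exocytosis
`k_exo` (internal→surface), endocytosis `k_endo` (surface→internal),
and lateral influx `k_ext` of unbleached receptor from outside the
bleach region. Photobleaching at t = 0 moves a fraction β
(default 0.9) of unbleached mCherry to the bleached pool in *both*
compartments, but of SEP only at the surface: internal SEP is
pH-quenched, absorbs no light, and is bleach-protected. Signals are

    SEP(t)     = S_u(t) + (1 − q) I_u(t)
    mCherry(t) = S_u + S_b + I_u + I_b   (all pools fluoresce)

normalized to their pre-bleach values. With q = 1 and no influx,
mCherry is constant after the bleach while SEP recovers by insertion
of unbleached internal receptor — the mechanistic point of the assay.
The post-bleach SEP floor has the closed form
`1 − β f / (f + (1 − f)(1 − q))`, used as an analytic oracle.

Lateral influx is split across compartments in proportion to the
steady-state surface fraction (`k_ext*f_surf` into S_u,
`k_ext*(1−f_surf)` into I_u), so influx raises both normalized
channels at the same relative rate and mCherry recovery never lags
SEP. The ODE is solved with `solve_ivp` RK45 at `rtol=1e-8,
atol=1e-12`; tests verify it against a closed-form second-order
(Heun) recursion at dt = 1e-4 and against mass conservation.

**Geometry.** For an image of length L the bleach region is the
central half, `[L/4, 3L/4)`, and the quantification ROI the central
half of that, `[3L/8, 5L/8)` — strictly nested so lateral diffusion
into the bleach edges does not contaminate the measurement. For the
default 32 µm image: bleach 16 µm, ROI 8 µm.

**Quantification.** ROI totals at 0, 2.5, 5 and 10 min post-bleach
(the default schedule) divided by the pre-bleach total give the
recovery fraction. `fit_recovery` fits `n(t) = n0 + A(1 − e^{−kt})`
with n0 fixed at the t = 0 observation and `curve_fit` bounds
A ∈ [0, 1.5], k ≥ 0; a flat series returns A = 0 with no rate rather
than an unstable fit. Note four timepoints constrain a single
exponential weakly: on noisy single-worm series the rate estimate has
~15 % median error at 2 % multiplicative noise (measured in the
tests); group comparisons should use `compare_recovery`, which runs
the split-plot RM-ANOVA across worms plus per-timepoint Tukey HSD.

## 4. Behavior (`glrkit.behavior`)

Per-worm scores: nose-touch response fraction (at most 10 trials per
worm enforced), optogenetic response fraction (uncapped trials),
rates per stated observation period (thrashes/30 s,
reversals/5 min) with period consistency enforced per assay. Worms
with zero trials are excluded with a warning, not treated as zeros.
Aldicarb paralysis: fraction paralyzed per checkpoint pooled across
plates, with binomial standard errors; a non-monotone paralyzed count
within a plate (a paralyzed worm cannot recover) raises
`DataIntegrityError` naming the offending plate. `group_summary`
reports mean/SD/SEM/n per genotype.

## 5. Statistics (`glrkit.stats`)

All statistics are computed from sums of squares up; scipy supplies
only reference distributions (t, F, studentized range, χ²/normal
draws). Conventions for degenerate zero-variance inputs: t = 0, p = 1
for equal means; t = ∞, p = 0 otherwise.

- **t test**: pooled variance by default, Welch-Satterthwaite df on
  request.
- **One-way ANOVA**: SSB/SSW decomposition.
- **Tukey-Kramer HSD**: `q = |diff| / sqrt(MSW/2 (1/n_i + 1/n_j))`
  against the studentized-range distribution with the ANOVA
  within-group df.
- **Dunnett**: the joint null of the treatment-vs-control t
  statistics is multivariate t with correlation
  `sqrt(lambda_i lambda_j)`, `lambda = n/(n + n0)`. Critical values
  and adjusted p-values are Monte-Carlo estimates from 100 000 draws
  (`z = sqrt(lam) z0 + sqrt(1−lam) z_i`, scaled by `sqrt(W/df)`,
  W ~ χ²) with a fixed seed; MC error at the 95th percentile is
  ≈ 0.005 in the critical value.
- **Two-way RM-ANOVA** (split-plot): between factor = group, within
  factor = time, every unit observed at every timepoint (missing
  cells raise, no imputation). Group is tested against
  subjects-within-groups; time and group×time against the
  within-subject residual. Counts-weighted sums of squares handle
  unbalanced group sizes. No sphericity correction is applied (with
  the default 4-timepoint grids the liberality is mild; the measured
  type-I error is within [0.02, 0.08] at α = 0.05). Tiny sums of
  squares below `1e-12 * max(1, SS_total)` are zeroed so degenerate
  designs give exact F = 0 rather than floating-point noise ratios.

The test suite validates these against independent oracles: exact
permutation of the F statistic, `scipy.stats.tukey_hsd` and
`scipy.stats.dunnett`, `pingouin.mixed_anova`, and hand-derivable
textbook cases; family-wise error rates are measured by simulation
(2000 null replications, acceptance band [0.03, 0.07] at α = 0.05).

## 6. Synthetic data (`glrkit.synthdata`)

All generators take frozen truth dataclasses and a seed, use
`numpy.random.default_rng(seed)` exclusively, and are byte-identical
across runs for a fixed seed. Defaults: 60 µm scans at 0.1 µm/px,
background 100 ± 5 AU, bead mean 250 AU; reporter images 20×60 px,
total signal 200 AU; FRAP at 1000 AU scale with 2 % multiplicative
noise; behavior with 24 worms/genotype.

Noise is additive Gaussian by default with an optional Poisson
shot-noise mode; intensities are clipped at zero. For
characterization studies, puncta amplitudes are drawn from
300–3000 AU — the upper range of a 12-bit detector with the default
background, matching where real puncta are called — and puncta are
spaced at least `4(σ_prev + σ_next)` apart plus a random margin so
ground-truth puncta do not merge into a single supra-threshold run
(merged puncta are a genuine resolution limit of any thresholding
caller, not an implementation defect).

What the simulations do **not** emulate: optics (no PSF convolution
beyond the Gaussian punctum shape itself, no out-of-focus haze),
detector artifacts (no read-noise floor, gain nonlinearity, or
saturation), photobleaching during acquisition, animal movement, or
biological correlations between neighboring synapses. They are
designed to validate the estimators against known ground truth, not
to look like micrographs.

## 7. Numerical and interface choices

- Half-open pixel spans everywhere; µm lengths are pixel counts ×
  pixel size.
- `solve_ivp` RK45 `rtol=1e-8/atol=1e-12` for the FRAP forward model;
  closed-form oracles (SEP floor, steady-state invariance,
  conservation) guard against silent solver drift.
- `curve_fit` with explicit bounds and fixed n0 keeps the
  4-point exponential fit from wandering; failure modes return
  `fit_ok=False` instead of raising.
- CLI exit codes: 2 = configuration error, 3 = missing input,
  4 = data integrity; every run writes a JSON manifest recording
  inputs, parameters and seed. Failed runs leave no partial outputs.
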