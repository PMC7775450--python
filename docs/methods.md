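# Methods

## Counterion condensation (module `manning`)

A glycosaminoglycan chain is reduced to two numbers: contour length `L`
[nm] and charge count `P`, giving the mean inter-charge spacing `b = L/P`.
The dimensionless line charge density `xi = l_B / b` compares `b` with the
Bjerrum length `l_B = e² / (4π ε₀ ε k T)` (0.714 nm in water at 25 °C;
constants are CODATA 2018 at full double precision). Condensation occurs for
`xi > 1`. The theory itself only supplies the criterion; we complete it with
the standard Manning closure for monovalent counterions — condensed charge
fraction `1 − 1/xi`, effective charge fraction `1/xi` — because it is the
canonical limiting law and gives a testable renormalization contract
(`effective_fraction · xi = 1` above threshold). Temperatures may be given
in °C at the interface and are converted; no salt-dependent screening or
divalent counterions are modelled.

## Condensation-gated binding (module `binding`)

**Model.** Available binding sites are the effective (uncondensed) charge
fraction: `f(c) = 1/xi_eff(c)`. The release of condensed counterions around
the critical particle concentration `c*` is represented by a geometric
interpolation `xi_eff(c) = xi0^(1 − s(c))` with `s` a logistic in
log₁₀-concentration centred at `c*` (width 0.15 decades by default). The
geometric form keeps `xi_eff` positive, makes `f` monotone, and puts
`xi_eff(c*) = sqrt(xi0)` exactly at the transition midpoint; as the width
shrinks it reduces to the two-regime piecewise picture. Bound signal
accumulates over a finite site pool (Langmuir-like depletion),
`B(c) = b_max (1 − exp(−(1/b_max)∫₀ᶜ s_high f(u) du))`, so the low-dose
slope is `s_high/xi0`, the pre-saturation high-dose slope is `s_high`, and
saturation is smooth. The integral is evaluated by trapezoidal quadrature
on a log-spaced grid containing the dose points (≥400 points per decade);
a brute-force Euler accumulation agrees to <0.1% on the test grids.

**Fitting.** `fit_condensation_model` estimates `(xi0, c*, b_max, s_high)`
by bounded nonlinear least squares in log-parameter space with a
deterministic 5-start schedule. Residuals are taken on log-signal: the
fluorescence noise model is multiplicative log-normal, for which log
residuals are homoscedastic — i.e. exactly the inverse-variance weighting —
and this keeps the information-rich low-dose points from being swamped by
the large-signal doses. Convergence requires optimizer success away from
the parameter bounds; single-regime curves leave `c*` unidentified and are
flagged rather than silently accepted. Standard errors come from the
Gauss–Newton covariance via the delta method. Note that `xi0` and `c*` are
correlated along a likelihood ridge: a single nine-dose experiment at 5%
noise determines `c*` only to roughly ±30% for weakly condensed chains
(ξ₀ ≈ 1.5), so medians over many repeats converge much faster than any
individual fit.

**Cooperativity index.** Ratio of the steepest dose-to-dose incremental
slope to the zero-intercept OLS slope through the lowest three doses. In
the sharp-transition, pre-saturation limit this ratio equals `xi0`; site
depletion near saturation attenuates the incremental slopes, so on strongly
saturating curves (including the normalized study grid) the index
*under*-states `xi0` — it is a classifier (threshold 1.5, placing the
weak-condensation scenario at the boundary) rather than an estimator there.

**Initial slope.** Zero-intercept OLS over all doses ≤ `c*/2` when `c*` is
known, else the lowest three doses; the intercept is pinned at zero because
unbound controls define zero background. On saturating curves the window
must stay in the truly linear regime (depletion <2%) for the generator
slope to be recovered within a few percent.

**Chain length.** The critical concentration is converted to a chain length
by charge bookkeeping,
`L = c* · charges_per_particle / (cells_per_ml · chains_per_cell ·
charges_per_nm)`, with `charges_per_nm = 4` as the only default; the other
geometry factors must be supplied. Only length *ratios* between conditions
measured with shared geometry are meaningful, and the ratio property
`L₁/L₂ = c*₁/c*₂` is exact by construction.

## Vacuole kinetics (module `kinetics`)

`N_v(t) = N_v,max tⁿ/(k_halfⁿ + tⁿ)` is fitted in log-parameter space with
bounds; initialization uses the observed maximum, the earliest
half-maximum crossing, and `n₀ = 2`. A fit is "reasonable" — `converged =
True` — only when the optimizer succeeds, the plateau's standard error is
smaller than the plateau, and `k_half` lies inside the observed time span.
Flat or zero series short-circuit to `converged = False` (no detectable
vacuole formation is a result, not an error). The inverse half-time
`k_inv = 1/k_half` is the deposition-ability metric used for comparisons
between conditions; absolute parameter values are validated only against
synthetic ground truth, since the source study reports the metric
graphically.

## Impedance decomposition (module `ecis`)

Raw impedance series are normalized by the mean over a pre-treatment
baseline window (default 2 h) and re-referenced so treatment is `t = 0`;
normalization is scale-invariant and idempotent. Measured traces rise for
~30 min after treatment as particles settle before the modelled decay
takes over, so the model `Z(t) = z₀ + z_max e^(−t/a) − N_v(t)` is fitted
from the post-treatment maximum onward while keeping the time origin at
treatment (parameters keep their meaning; the noiseless generator is exact
over that window). Pre-treatment samples are included in the residuals as
a `z₀` anchor: `z₀` remains a free parameter but is identified by the data
that define it. Five parameters (`z₀, z_max, a, nv_max, k_half`) are free;
the Hill exponent is held at 2 by default because a free exponent makes
the decaying binding term and the sigmoid vacuole term nearly collinear
over a single trace (correlation ≈ −0.97 between `a` and `k_half`,
tripling their uncertainties); pass `n_hill_fixed=None` to free it.
`converged = False` on optimizer failure or a non-positive fitted `z_max`;
a separate `hill_identified` flag reports whether the vacuole component is
resolvable (plateau above three residual SDs and above its own SE).
Component segregation returns `z_max e^(−t/a)` and `N_v(t)`, whose sum
with `z₀` reproduces the model pointwise by construction.

## Image quantification (module `imaging`)

Frames are linearly rescaled to 8 bits (min → 0, max → 255) before
thresholding, matching the 8-bit conversion used for phase-contrast
processing. `mean_dark` thresholds at the histogram mean; `triangle_dark`
uses the Zack triangle algorithm (scikit-image implementation; the test
suite checks it against an exhaustive search over all 256 candidate
thresholds). "Dark" polarity means foreground is above threshold.

The motility index binarizes consecutive frames with `mean_dark` and takes
the mean of the per-pixel *population* standard-deviation image of each
pair — for two binary frames, `|m₁ − m₂|/2`, so a full flip scores 0.5 and
identical frames score 0.

Vacuole area per cell applies one triangle threshold computed on the
pooled stack histogram to every frame (a single threshold per experiment,
as a macro would set it), converts mask area to µm² via the pixel size and
divides by the cell count. Thresholding each frame independently would
re-threshold pre-vacuole frames into their own noise floor and fabricate
early-time area.

Cluster detection band-passes the image with a difference-of-Gaussians
slightly undersized relative to the PSF (0.7 σ_psf, sharpening close
pairs), finds local maxima above `median + 5·MAD` of the filtered image
with minimum separation one pixel, and reports: raw density
(count/area), mean nearest-neighbour spacing, and a CSR-corrected density
that inverts the expected loss of sub-resolution pairs. Two equal Gaussians
merge into a single maximum below a separation of 2σ_psf; for a Poisson
field of intensity λ the expected observed density is then
`λ(1 − ½(1 − e^(−λπr²)))`, which is solved for λ by bisection. The raw
density satisfies the count/area identity and is accurate to ~10% at
22 spots/µm²; the corrected density is accurate to ~5% across
5–40 spots/µm² at 20 nm pixels and 60 nm PSF. Detection parameters are
exposed, since the original macro settings are not recorded.

## Synthetic data (module `synthetic`)

Generators emulate the statistical structure of each measurement, not the
instrument physics:

* **Binding**: model mean on the nine-dose assay grid
  (4.97 × 10¹⁰…1.27 × 10¹² particles/mL), multiplicative log-normal noise
  (CV 5% default — replicate scatter is only shown graphically in the
  source, so the CV is a fixture choice), 4 replicates. Presets: control
  (ξ₀ = 4.2, c\* = 2.6 × 10¹¹), heparinase (ξ₀ = 1.5, c\* = 1.2 × 10¹¹),
  non-condensing cells (ξ₀ < 1, slope 17.0 × 10⁻¹¹ %·mL/particle), and a
  salt-free condition with condensation disabled. The intrinsic slope of
  the condensing presets is the printed low-dose slope times ξ₀
  (6.6 × 10⁻¹¹ × 4.2), since the model ties the two together.
* **Impedance**: normalized model mean with a sin² rise that saturates
  exactly at the 30-min binding peak (so the post-peak segment is exactly
  the model), additive Gaussian noise (SD 0.02 normalized units), scaled
  to an absolute 900 Ω baseline with treatment at 2 h; 5-min sampling over
  24 h. Scenario parameters (a = 2 h vs 4 h, plateaus 0.2 vs 0.08) encode
  the qualitative cell-line contrast at realistic magnitudes, as the source
  reports these only graphically.
* **Vacuole time-courses**: Hill mean with dose-scaled plateau; the lowest
  dose generates a zero plateau to exercise the non-convergence path.
* **Cluster fields**: homogeneous Poisson points at the target density
  (default 22 µm⁻²), Gaussian PSF rendering (60 nm FWHM), Poisson shot
  noise, 20 nm pixels, 4 µm² fields.
* **Image stacks**: textured blobs with per-frame Gaussian jitter following
  a configurable step profile (motility), and disks growing on the Hill
  schedule with the plateau re-expressed as 4 µm² of vacuole per cell so
  the disks are resolvable at 0.5 µm pixels (vacuole channel).

Everything is driven by one integer seed through `numpy`'s Generator;
identical seeds give byte-identical output. What passing recovery tests on
these generators shows is that the estimators are correct and stable under
the declared noise models; they say nothing about detector nonlinearity,
bleaching, segmentation of touching cells, or biological replicate
variability, none of which are emulated.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use medians over 20 simulated
experiments per condition — enough for stable medians at the declared noise
levels while keeping the whole suite fast. Optimizers are
`scipy.optimize.least_squares` (trust-region reflective) with bounded
log-parametrizations and deterministic multi-starts; tie-breaks and bound
contacts are reported through `converged` flags rather than exceptions.
Degenerate inputs (constant images, flat series, all-zero signals,
single-regime curves) are either defined results (zero slope, zero area)
or flagged outcomes, as documented per function.

## Known limitations

* The c\*→chain-length conversion is a proportionality stand-in; absolute
  lengths require a geometry calibration that is not part of the package.
* The cooperativity index is conservative on saturating curves.
* The CSR pair-merging correction assumes spatial randomness; clustered or
  inhibited point patterns would need a different correction.
* Single-trace impedance fits with a free Hill exponent are ill-conditioned;
  the default fixes the exponent at 2.
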