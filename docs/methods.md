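# Methods

## Model and assumptions

The input morphogen is a noisy linear gradient over a one-dimensional cell
array: mean `(x/L)·c_max`, additive Gaussian fluctuations of constant SD `σ₀`,
uncorrelated between cells. Readout is composed of three operations — a noisy
*access* (adds Gaussian input noise `η₀`), a deterministic *amplify* (linear
gain λ, or an integer-gain triangle-wave "zigzag" that preserves dynamic
range), and *average* over `N_eff` effective independent measurements
(fluctuation SD shrinks by `1/√N_eff`, mean shape untouched). Averaging is
modelled as purely temporal — the mean of independent realizations — so the
smoothing that spatial averaging would apply to the mean profile near domain
boundaries is deliberately absent; `N_eff` absorbs both mechanisms. Noise is
uncorrelated between genes and cells throughout; correlated fluctuations are
out of scope.

The *direct* strategy averages the input itself
(`ĉ⁽⁰⁾ = G_Neff[ĉ]`, fluctuation `σ₀/√N_eff`); the *two-tier* strategy
averages an amplified noisy readout
(`ĉ^(λ) = G_Neff[F_λ(ĉ + η̂)]`, fluctuation `ξ_λ = λ√((σ₀²+η₀²)/N_eff)`).
Raw information is the mutual information between profile and position for a
uniform position prior; accessible information is the same quantity after one
more access operation corrupts the profile with fresh noise `η₀`.

## Information quantities

All internal computation is in nats (`value_bits = value/ln 2`). Three routes:

1. **Closed forms.** Everything for linear profiles reduces to
   `I(φ) = ln φ − ½ln(2πe)` with the effective signal-to-noise ratios listed
   in the README. These expressions hold in the small-noise, many-cell limit
   and neglect domain-boundary terms.

2. **Small-noise functional** (`info_small_noise`). For arbitrary
   differentiable channels the positional error aggregates Fisher information,
   `σ_x(x)⁻² = Σᵢ (dḡᵢ/dx)²/(σᵢ(x)² + η₀²)`, and
   `I = ln L − ⟨ln(√(2πe)·σ_x(x))⟩` under the uniform prior. For one linear
   channel this reproduces `I(φ)` exactly. Isolated zeros of the total Fisher
   information (e.g. the trough bottom of a stripe profile) give integrable
   `ln` singularities and are handled by midpoint quadrature (default 2001
   points); a zero on a whole subinterval raises an error, as the
   approximation is undefined there. Note that for a *single* non-monotonic
   channel this expression ignores the fold degeneracy (positions sharing an
   expression level) and therefore overestimates; for the multi-channel sets
   used here the monotone gap-like channels break the degeneracy, and the
   explicit `zigzag_info` correction (`−ln λ`) covers the folded case.

3. **Numeric oracle** (`mi_numeric`). `I = H(g) − H(g|x)` with the
   conditional entropy computed exactly by quadrature (Gaussian noise) and the
   marginal entropy by Monte Carlo over draws of `(x, g)`, evaluating the
   mixture density `p(g) = ⟨p(g|x)⟩_x` by midpoint quadrature on an `n_grid`
   position grid (defaults: 512 grid points, 20 000 draws; the grid must
   resolve the posterior width, `n_grid ≳ 1.5·L/min σ_x`). The standard error
   comes from batching the draws (20 batches). No small-noise assumption is
   made, so the estimator is valid for zigzag/stripe profiles and joint
   multi-channel information; it is the independent cross-check for every
   closed form.

**Finite-domain boundary terms.** The exact mutual information of a
finite-domain linear channel exceeds `I(φ)` by ≈ `1.81/φ` nats (edge pile-up
of the mixture density), and a zigzag channel similarly carries an
`O(ξ/c_max)` fold term. These are real properties of the finite channel that
the small-noise formulas neglect. Where a test validates a closed form
against the oracle, the oracle is therefore run on a K-fold tiled domain and
`ln K` subtracted — the bulk information rate, which converges to the closed
form as `K → ∞` (K = ⌈400/φ⌉ keeps the residual below ~0.005 nats) — and
zigzag difference checks use relative noise ≤ 10⁻³. Comparisons are made at
tolerance `max(3·MC SE, 0.02 nats)`: the Monte-Carlo SE of the tiled oracle
(~5·10⁻⁴ nats) is far below the residual deterministic bias, so the 0.02-nat
scale is the meaningful agreement target.

## Synthetic embryo generator

`default_embryo_spec()` emulates the mid-body AP geometry the analysis
assumes, on a regular grid of 200 AP rows × 20 DV columns (~4000 nuclei per
embryo, comparable to a blastoderm surface), with 8 replicate embryos as the
default study size. Expression is in units of each gene's idealized maximum:

- `hb`: decreasing logistic boundary, midpoint 0.42, width 0.025, range
  0.2–1.0, constant SD 0.05;
- `kr`: the mirror-image increasing boundary (same parameters), so the two
  gap-like genes form opposing boundaries across the ROI (0.37, 0.47);
- `eve`: two Gaussian stripes (centers 0.36/0.48, width 0.015, amplitude 0.6)
  on a 0.4 basal level — a trough centered in the ROI, maximum ROI slope
  ≈ 3× the gap-gene slope — with constant SD 0.10, twice the gap noise.

The noise magnitudes (5% and 10% of maximum) are in the range typical of
nucleus-resolved immunofluorescence after background subtraction; the
steeper-but-noisier Eve-like channel is the regime in which the crossing-point
analysis is informative. Basal offsets keep every mean ≥ 4 SD above zero so
that the additive Gaussian noise essentially never produces negative
expression; the rare negative draws are clipped at 0 (≈10⁻⁵ of nuclei),
preserving the non-negativity expected of intensity data without distorting
the noise statistics. Noise models can be constant, affine in `x`, or
fractional (SD ∝ mean); shapes and noise are configurable via YAML.

What the generator does **not** emulate: embryo curvature and projection
distortion (coordinates are already projected AP fractions), spatially
correlated noise, cross-gene noise correlations, cell-cycle or staining
variability between replicates (replicates differ only by noise draws), and
the full seven-stripe pair-rule pattern (two stripes suffice for the ROI
analysis). Passing tests therefore demonstrate the estimators' correctness
under the stated noise model, not robustness to those real-data features.

## Empirical pipeline

- **Neighbor noise**: for every pair of nuclei sharing an AP row with
  adjacent DV indices, the expression difference is binned by AP position
  (default 50 bins over the data domain); per-bin RMS difference and
  per-nucleus SD = RMS/√2 (difference of two iid measurements) are reported,
  pooled over replicates, with the across-replicate spread alongside. Bins
  with fewer than two pairs are flagged missing. Both RMS and SD are stored;
  information calculations use the SD.
- **Idealized profiles**: smoothing splines (generalized cross-validation by
  default, penalty overridable) fit to per-row mean expression and to the
  binned SD estimates; mean and SD are then divided by the fitted mean's
  maximum over the data domain, so every gene's idealized maximum is 1 and a
  single η₀ is meaningful across genes. Fitted SDs are clipped at zero.
- **ROI restriction** truncates the domain and re-uniformizes the prior
  (default ROI 0.37–0.47).
- **Curves**: accessible information (small-noise functional) versus η₀ for
  the triplet, and for the gap pair with expression noise forced to zero (the
  best case for any strategy lacking the downstream gene). At η₀ = 0 the
  bound is infinite and stored as an explicit sentinel, never interpolated.
  A `fractional` switch replaces the absolute readout noise η₀ by
  `η₀·ḡ(x)` per channel.
- **Crossing point**: first grid interval where the triplet meets the bound,
  refined by root bisection on the two curve evaluators.

The default η₀ grid is 25 logarithmic points over 3·10⁻³–3 (units of
normalized maximum expression), bracketing the expression-noise scale of the
default embryo (0.05–0.1) by more than an order of magnitude on either side.

## Numerical and design choices

- Zigzag inputs are clamped to `[0, c_max]` before folding (the map models a
  bounded dynamic range); at exactly the top of the range the last segment's
  value is used. Noise equivalence between zigzag and linear amplification
  holds away from fold points; tests exclude cells within 3 total-noise SDs
  of a fold.
- Non-integer `N_eff` is implemented by rescaling a single realization's
  fluctuation around the known mean by `1/√N_eff`; integer `N_eff` averages
  that many independent realizations.
- All randomness flows from one integer seed per entry point via
  `SeedSequence` spawning; equal config + seed gives byte-identical outputs
  (TSV floats use shortest round-trip representation, JSON floats 12
  significant digits, non-finite values as explicit string sentinels). The
  run manifest omits wall-clock timestamps by default for the same reason.
- Problem sizes (20 000 MC draws, ≤ 12 000 quadrature points, 10⁵-cell
  simulations, 8 × 4000-nucleus embryos) keep the full test suite and the
  acceptance script at a few minutes on one CPU while leaving Monte-Carlo
  errors well below the tolerances tested.

## Known limitations

- Closed forms and the small-noise functional are asymptotic: they degrade
  when `σ_x` approaches the domain length (they can then even go negative),
  and they ignore the finite-domain boundary terms quantified above.
- The accessible-information curves use the small-noise functional
  throughout; at the largest η₀ values on the default grid the absolute
  values are outside its regime, but the monotone-decay and crossing
  structure — the quantities of interest — are governed by the Fisher-ratio
  asymptotics, which the numeric oracle confirms at spot checks.
- The neighbor-noise estimator assumes iid noise between DV neighbors; any
  shared (row-level) noise component would be invisible to it.
- No general-purpose MI estimation from raw samples (k-NN, binning): only
  model-based Gaussian-noise profile sets.
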