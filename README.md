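# accinfo — accessible positional information in gradient-mediated patterning

Developmental patterning systems read graded morphogen signals through
cascades of noisy gene-expression steps. Measured by Shannon information
alone, every extra tier looks wasteful: each transcription/translation cycle
adds noise, so a multi-tiered readout always carries less *raw* positional
information than a direct one. Yet multi-tiered architectures are the norm —
in the fly segmentation cascade, vertebrate neural patterning, somitogenesis
and elsewhere.

`accinfo` implements the resolution of this apparent paradox: distinguish the
raw information in a signal from the information *accessible* to an
intrinsically noisy downstream readout. It is aimed at quantitative/systems
biologists who want to compute these quantities for model gradients or for
(real or synthetic) nucleus-resolved expression data.

## The model

Cells at positions `0 < x < L` see a noisy linear gradient
`ĉ = (x/L)·c_max + σ̂` with iid Gaussian noise of SD `σ₀`. A readout is
composed of three elementary operations:

- **access** — every readout sees only a noisy estimate `ĉ + η̂`, with
  Gaussian input noise of SD `η₀`;
- **amplify** — a deterministic gain `F_λ` (pure linear, or a triangle-wave
  "zigzag" `F_λ^z` that folds the profile λ times while preserving dynamic
  range);
- **average** — temporal/spatial averaging over `N_eff` effective independent
  measurements, dividing fluctuation variance by `N_eff`.

For a linear profile with dynamic-range-to-noise ratio φ, the small-noise
positional information is `I(φ) = ln(φ/√(2πe))` nats. The package provides
the four closed forms that follow:

| quantity | value |
|---|---|
| raw, direct | `I(c_max·√N_eff/σ₀)` |
| raw, two-tier | `I(c_max·√N_eff/√(σ₀²+η₀²))` — gain-independent |
| accessible, direct | `I(c_max/√(σ₀²/N_eff + η₀²))` |
| accessible, two-tier | `I(c_max/√((σ₀²+η₀²)/N_eff + η₀²/λ²))` |

The extra noisy tier is beneficial iff `η₀²(1 − 1/N_eff − 1/λ²) > 0`: never
without averaging (`N_eff = 1`) or amplification (`λ = 1`), but generically
beneficial once both are present — precisely because the readout is noisy.
A zigzag profile on its own loses exactly `ln λ` nats to the fold degeneracy,
but jointly with its input it is as informative as the linear amplifier.

Beyond the closed forms, `accinfo.information` provides a general small-noise
(Fisher-information) expression for arbitrary multi-channel profiles and an
independent numeric mutual-information estimator (quadrature over position,
Monte Carlo over expression) valid for non-monotonic profiles and joint
multi-gene information.

`accinfo.empirical_pipeline` applies all of this to nucleus tables emulating
the *Drosophila* blastoderm: expression noise estimated from immediate
dorsal/ventral neighbor differences, idealized Gaussian-noise profiles from
smoothing-spline fits, and accessible information of the gap-gene pair versus
the (Hb, Kr, Eve) triplet as a function of the readout noise `η₀`, including
the noiseless-pair upper bound and its crossing point `η₀*`.

## Worked example

```python
from accinfo import acc_info_direct, acc_info_two_tier, benefit_condition

direct = acc_info_direct(c_max=1.0, sigma0=0.1, eta0=0.1, n_eff=4)
two_tier = acc_info_two_tier(c_max=1.0, sigma0=0.1, eta0=0.1, n_eff=4, gain=2)
beneficial, margin = benefit_condition(eta0=0.1, n_eff=4, gain=2)
print(f"direct:   {direct.value_bits:.3f} bits")
print(f"two-tier: {two_tier.value_bits:.3f} bits")
print(f"margin:   {margin:.4f} (beneficial: {beneficial})")
```

prints

```
direct:   1.114 bits
two-tier: 1.482 bits
margin:   0.0050 (beneficial: True)
```

With readout noise as large as the input noise and four-fold averaging, a
two-fold amplifying intermediate tier gains ~0.37 bits of accessible
information even though it strictly *loses* raw information (the margin
`η₀²(1 − 1/4 − 1/4) = 0.005 > 0` predicts the sign of the gain).

The embryo analysis runs end-to-end from the command line; without `--tables`
it generates the default synthetic replicate set (8 embryos, 200×20 nuclei):

```
$ accinfo analyze-embryo --seed 3 --out-dir out
crossing at eta0* = 0.06108 | ROI info (bits): hb=1.52, kr=1.54, eve=0.63
```

The Eve-like channel carries the *least* information over the region of
interest (it is twice as noisy as the gap-like genes), yet above
`η₀* ≈ 0.061` (in units of each gene's idealized maximum) the triplet's
accessible information exceeds what perfectly noiseless Hb and Kr could ever
deliver — the steeper Eve profile re-encodes the same information in a
noise-tolerant format. `out/report.json` and `out/curves.tsv` hold the full
curves; `--plot` adds a PNG.

Other subcommands: `accinfo simulate-gradient`, `accinfo sweep` (direct vs
two-tier benefit maps over a parameter grid), `accinfo make-embryo`,
`accinfo info` (closed forms for one parameter set). All accept `--seed`;
equal seed and config give byte-identical outputs.

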