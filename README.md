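# glycobind

Quantitative models of how cationic nanocapsules interact with the
carbohydrate coat (glycocalyx) of urothelial cells, for biophysicists and
image analysts who want the full simulate → fit → report chain as a tested
Python library.

The glycocalyx is dominated by strongly anionic glycosaminoglycans such as
heparan sulphate. When the dimensionless line charge density

```
xi = l_B / b,      l_B = e^2 / (4 pi eps0 eps k T),      b = L / P
```

exceeds 1, mobile counterions condense onto the chain (Manning condensation)
and screen a fraction `1 - 1/xi` of its charge. For heparan sulphate
(`b = 0.25 nm`, water at 25 °C) this gives `xi ≈ 2.9`: most binding sites for
a cationic particle are electrostatically hidden. The package models the
consequence for dose–binding curves — a suppressed low-dose regime, a
critical particle concentration `c*` at which the condensed counterions are
released, and a steep cooperative regime above it:

```
B(c) = b_max (1 - exp(-(1/b_max) ∫₀ᶜ s · f(u) du)),   f(c) = 1 / xi_eff(c)
```

where `xi_eff` slides from `xi0` to 1 through a logistic switch in
log-concentration centred at `c*`, and `s` is the intrinsic (uncondensed)
binding slope. Fitting this model to a measured curve recovers `xi0` and
`c*`.

Downstream of binding, the package implements:

* **Vacuole kinetics** — Hill-type growth
  `N_v(t) = N_v,max · tⁿ / (kⁿ + tⁿ)` of drug-induced vacuole area per cell;
  `1/k` is the deposition-ability metric.
* **Impedance decomposition** — cell-substrate impedance traces modelled as
  `Z(t) = Z₀ + Z_max e^(−t/a) − N_v(t)`; `1/a` is the binding-ability
  metric, and fitted traces segregate into pure binding and vacuole curves.
* **Image quantification** — ImageJ-macro-style mean/triangle auto
  thresholds, a frame-difference motility index, vacuole area per cell from
  fluorescence stacks, and spot detection for glycan-cluster density on
  STED-like images.
* **Synthetic data** — seeded generators for every stage, with scenario
  presets carrying the study parameter sets (control ξ₀ = 4.2,
  c\* = 2.6 × 10¹¹ mL⁻¹; heparinase ξ₀ = 1.5, c\* = 1.2 × 10¹¹ mL⁻¹; the
  nine- and five-dose assay grids; 22 clusters µm⁻² fields).

## Worked example

`examples/02_cooperative_binding.py` simulates a noisy control-scenario
dose–binding experiment and fits it back:

```
fitted xi0      : 3.47  (+- 0.55; generator 4.2)
fitted c*       : 2.48e+11 particles/mL (generator 2.6e11)
converged       : True
cooperativity   : ratio 1.94 -> cooperative
chain-length ratio control/heparinase (from c*): 2.17
```

The fitted `xi0` says the chain charge density before any particle binds is
about 3.5–4 times critical (a single noisy experiment scatters around the
generating 4.2; the median over many repeats is within a few percent). The
critical concentration lands on the generating 2.6 × 10¹¹ particles/mL. The
cooperativity ratio > 1.5 classifies the curve as cooperative, and because
the inferred chain length is proportional to `c*`, the ratio of critical
concentrations (2.6/1.2 ≈ 2.17) is also the inferred ratio of heparan
sulphate chain lengths between untreated and heparinase-digested cells.

The other examples cover the condensation calculation itself
(`01`), vacuole kinetics including the non-converging zero-dose scenario
(`03`), impedance decomposition (`04`) and the three image quantifiers
(`05`). A thin CLI mirrors the library (`glycobind --help`), e.g.

```
glycobind manning --contour-length-nm 1 --n-charges 4
glycobind simulate-binding --scenario t24_control --seed 2 -o curve.csv
glycobind fit-binding curve.csv --normalize -o fit.json
```

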