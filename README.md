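# episcade

Sign epistasis in transcriptional signalling cascades: mechanistic
landscape analysis and an empirical calling pipeline.

## The problem

When two regulatory genes sit in the same signalling cascade — say an
upstream repressor *tetR* and a downstream repressor *lacI* relaying an
arabinose signal to a fluorescent readout — a mutation in one gene can be
beneficial in one genetic background and deleterious in another.  This
*sign epistasis* constrains which mutational paths evolution can take, and
it can arise purely from the functional hierarchy of the cascade, without
any physical contact between the proteins.  `episcade` provides the
computational toolkit for studying this phenomenon:

- an equilibrium Hill-stage model of multi-layer cascades
  (repressors/activators in any order), with the **response range**
  R = |Out(in_min) − Out(in_max)| over an input window as the performance
  proxy;
- geometric landscape analysis on 2D phenotype planes: restricted-optimum
  lines (where the optimum of one trait depends on the other),
  colour-coded epistasis-domain maps (magnitude / upstream sign /
  downstream sign / reciprocal), and the rotated-Gaussian reference family
  F(X,Y) = exp(−(X,Y)·M·(X,Y)ᵗ)/(2π det M) with
  m11 = cos²a/2 + 2sin²a, m12 = m21 = (3/4)sin 2a,
  m22 = sin²a/2 + 2cos²a;
- an angular coordinate θ that straightens the curved optimum lines onto
  {0, π/2, π, 3π/2} and a one-tailed binomial test, B(N_θ, f_E), for the
  radial clustering of epistasis classes;
- a statistical pipeline that calls epistasis classes from combinatorial
  mutant dose-response panels: smooth-response fits
  a·[ara]^d/(b^d + [ara]^d) + c, noise Δ (RMS deviation of replicate means
  from the curve), one-sided positivity tests of R, and two-sided Welch
  t-tests (df = 44 per genotype leg) on every single-mutation step of all
  C(n_up,2)·C(n_down,2) pairwise squares;
- a synthetic-data generator for the reference design (5 × 7 variants,
  16 inputs spanning 0–100 µM, 3 replicates, additive Gaussian noise) with
  full ground truth for recovery tests.

The scientific background, default parameter calibration and all numerical
conventions are documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate the reference 5 × 7 panel and call epistasis classes:

```python
import episcade as ep

variants, truth = ep.sample_variant_panel(ep.VariantPanelSpec(), seed=1)
data, curves = ep.simulate_panel_measurements(
    variants, ep.default_cascade(),
    ep.MeasurementSpec(noise_sigma=2.0, seed=1))

res = ep.PanelEpistasisModel.from_dataframe(data).fit()
print(res.summary())
```

```
Combinatorial cascade panel — epistasis summary
=======================================================
panel:            5 upstream × 7 downstream variants (35 genotypes)
pairwise squares: 210
input window:     0–100 µM
responding genotypes (p < 0.05): 32/35
-------------------------------------------------------
class fractions over all squares:
  magnitude         75.2%
  downstream_sign   20.5%
  upstream_sign      0.0%
  reciprocal         0.0%
  NS                 4.3%
-------------------------------------------------------
median fitted Hill slope d: 3.81; median noise Δ: 1.04
```

Each of the 210 squares pairs two *tetR* and two *lacI* variants; a square
is `downstream_sign` when the *lacI* mutation's effect on the response
range flips sign between the two *tetR* backgrounds (both flips significant
at p < 10⁻³), `reciprocal` when both mutations flip, and `NS` when no step
within the square is statistically resolvable.  Downstream sign epistasis
being the modal sign class is the hierarchy signature: the optimal
downstream binding constant depends on the upstream one, but much less the
other way around.

The mechanistic side of the same statement:

```python
L = ep.default_plane()                      # R over (log10 K_LacI, log10 K_TetR)
m = ep.epistasis_map(L, grid=201)
print({k: round(v, 3) for k, v in m.class_fractions().items()})
m.plot()                                    # the colour-coded domain map
```

```
{'magnitude': 0.927, 'downstream_sign': 0.066, 'upstream_sign': 0.007,
 'reciprocal': 0.0, 'neutral': 0.0}
```

Over the full 0–100 µM window the map contains a downstream-sign domain
only; restricting the window (`ep.default_plane(w=ep.RESTRICTED_WINDOW)`)
adds upstream and reciprocal domains — the environment (input range)
reshapes the epistasis structure without any mutation.

A thin CLI wraps the same functionality:

```bash
episcade simulate --panel 5x7 --sigma 2 --seed 1 -o panel.csv
episcade call --data panel.csv --window 0:100
episcade map --window 50:100 -o map.csv
episcade angles --window 50:100 -o angles.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes the quantitative acceptance target from
scratch — the pairwise-interaction count of the complete 5 × 7 variant
design, obtained from the package's combinatorics and cross-checked by
exhaustive enumeration of deduplicated 2×2 squares — and writes it as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
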