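# groupedkde

Nonparametric estimation for **interval-grouped data**: kernel density and
distribution (emergence-curve) estimation when observations are only
available as counts between inspection points, with plug-in and exact
multinomial-bootstrap bandwidth selection, bootstrap confidence bands, a
k-group Cramér–von Mises factor test, grouped maximum-likelihood parametric
fits, and moment/density-based emergence indices.

The package is aimed at weed scientists and ecologists modelling seedling
emergence against cumulative hydrothermal time (CHTT), but applies to any
variable recorded as interval counts.  Given grouping points
`e_0 < ... < e_k`, counts `n_i` and proportions `w_i = n_i/n`, the core
estimators place each interval's mass at its midpoint `t_i` and smooth:

```
fhat_h(x) = (1/h) Σ_i w_i K((x − t_i)/h)          (density)
Fhat_h(x) = Σ_i w_i 𝒦((x − t_i)/h)                (distribution)
```

with a Gaussian kernel `K` and its antiderivative `𝒦`.  The bandwidth `h`
is selected either by plug-in rules that solve a binning-aware AMISE
equation, or by minimizing the *exact* (closed-form, draw-free) bootstrap
MISE under multinomial resampling of the bin counts.  See
`docs/methods.md` for the statistical details.

## Worked example: wild-oat emergence

A season of *Avena sterilis* emergence counts from four replicate soil
cylinders ships with the package, with CHTT grids for three candidate
measuring depths (10, 20, 50 mm); pooled over cylinders, n = 278 seedlings.

```python
from groupedkde import (
    load_wild_oat, load_wild_oat_pooled, bootstrap_test,
    plugin_bandwidth_density, bootstrap_bandwidth_density,
    plugin_bandwidth_distribution, bootstrap_bandwidth_distribution,
)

# Is there a cylinder effect at 10 mm?  (k-group CvM bootstrap test)
res = bootstrap_test(load_wild_oat(10), B=1000, seed=0)
print(f"D = {res.D:.3f}, p = {res.p_raw:.3f}")

# Bandwidths for the pooled 10 mm sample
pooled = load_wild_oat_pooled(10)
print(f"density:      plug-in {plugin_bandwidth_density(pooled).h:.2f}, "
      f"bootstrap {bootstrap_bandwidth_density(pooled).h:.2f}")
print(f"distribution: plug-in {plugin_bandwidth_distribution(pooled).h:.2f}, "
      f"bootstrap {bootstrap_bandwidth_distribution(pooled).h:.2f}")
```

prints

```
D = 0.890, p = 0.013
density:      plug-in 14.48, bootstrap 19.90
distribution: plug-in 10.03, bootstrap 13.94
```

The test finds a cylinder effect that is significant at the 5% level but
not at 1%; with identically handled replicates a 1% level is the sensible
bar, so the cylinders are pooled.  The four bandwidths (in CHTT units)
then smooth the pooled density and emergence curve; the bootstrap
selectors smooth more than the plug-ins, and the two distribution
estimates are nearly indistinguishable (sup-distance ≈ 0.05), showing how
insensitive the smoothed CDF is to moderate bandwidth changes.

The same workflow runs from the shell:

```bash
groupedkde reproduce-example -B 1000 --seed 0 -o report.json
groupedkde density my_sample.csv --bands -o density.json
groupedkde treatment-test edges.csv counts.csv --sizes 53,61,90,74 --abs-values
groupedkde simulate --family weibull --params shape=2,scale=300 --n 5000 \
    --bins 12 --range 0 800
```

Grouped samples are CSVs with a `lower,upper,count` header; raw inspection
records (`value,count`) can be aggregated with the left-edge convention via
`groupedkde.read_inspection_csv`.

## Emergence indices

`moment_indices` and `density_indices` estimate I1 (coefficient of
variation, larger better), I2 (kurtosis), J1 (σ³∫f′²) and J2 (σ⁵∫f″²)
(all three smaller better) — shape summaries used to pick the measuring
depth with the most predictive power.  `rank_depths` compares several
depths and reports the per-index winners and a majority winner, with
bootstrap confidence intervals available via
`indices_confidence_intervals`.

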