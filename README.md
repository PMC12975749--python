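# cwmitv

Trait–environment analysis for understory plant communities: how much of the
variation in community-level functional traits is due to **species turnover**
(replacement of species along gradients) versus **intraspecific trait
variation** (ITV — plastic or genetic trait shifts within species), and which
environmental factor groups drive it.

The package is aimed at community ecologists working with the classic
three-table design — a plot × species cover matrix, an individual-level trait
table, and a per-plot environment table — at local scales where spatial
autocorrelation cannot be ignored (e.g. a grid of 10 m × 10 m quadrats in a
forest plot).

## The model

For each plot, three community-weighted means (CWM) are computed per trait,
weighted by relative species cover *p&#7522;*:

- **CWM_fixed** = Σ *p&#7522; x&#7522;*, with *x&#7522;* the species-wide fixed mean trait
  (its plot-specific means averaged over all plots where the species occurs).
  Varies among plots only through turnover.
- **CWM_specific** = Σ *p&#7522; x&#7522;&#8344;*, with *x&#7522;&#8344;* the plot-specific species
  mean. Varies through turnover *and* ITV.
- **CWM_intravar** = CWM_specific − CWM_fixed, the trait shift due to ITV
  alone.

The across-plot sum of squares of CWM_specific decomposes as

    SS_specific = SS_fixed + SS_intraspecific + SS_cov

giving percentage contributions of turnover, ITV and their covariation
(negative covariation lets turnover + ITV exceed 100%).

Trait–environment relationships are then modelled per response (six leaf
traits plus two trait-PCA axes, under each CWM variant) with **generalized
least squares** whose errors carry a distance-decay spatial correlation
(exponential by default, range estimated by maximum likelihood).  Explanatory
power is Nagelkerke's pseudo-R²,

    R² = [1 − exp(2(ll₀ − ll_m)/n)] / [1 − exp(2 ll₀/n)],

against an intercept-only GLS null, and the full model's R² is partitioned by
inclusion–exclusion into the unique and shared fractions of the topographic,
soil and biotic predictor groups (a three-set Venn diagram in numbers).

A seeded synthetic generator (grid of quadrats, deterministic elevation,
Gaussian-random-field soil variables, Gaussian-niche community assembly,
individual trait sampling with controllable plasticity and idiosyncratic ITV)
provides inputs with known ground truth for every stage.

## Worked example

```python
import cwmitv as cv

sc = cv.Scenario(n_plots_x=8, n_plots_y=8, n_species=20, seed=1)
env = cv.generate_environment(sc)
community = cv.generate_community(env, sc)
traits = cv.generate_traits(env, community, sc)

means = cv.compute_species_means(traits)
triple = cv.cwm_triple(community, means)
dec = cv.decompose_cwm_variance(triple)
print(dec[["pct_turnover", "pct_itv", "pct_cov"]].round(1))
```

```
         pct_turnover  pct_itv  pct_cov
trait
FH               42.2     55.5      2.2
LA               52.0     63.4    -15.3
SLA              55.7     40.9      3.4
LDMC             63.3     27.7      9.0
SPAD             56.1     38.7      5.2
PhiPSII          45.4     51.5      3.1
```

Each row splits the community-level variance of one trait: e.g. 42.2% of the
across-plot variance in CWM height (FH) is attributable to species turnover,
55.5% to ITV, and a small positive covariation makes up the rest.  For LA the
covariation is negative, so turnover and ITV shares sum past 100% —
compositional shifts and within-species shifts partially offset each other.

Fitting the spatial GLS models for height against the eight standard
predictors:

```python
e = env.set_index("plot_id")
pred = e[["elevation", "convexity", "pH", "TP",
          "density", "basal_area", "comp1", "comp2"]]
for variant in ("fixed", "specific", "intravar"):
    y = getattr(triple, variant)["FH"]
    fit, null, r2 = cv.fit_gls_r2(y, pred, e[["x", "y"]], cv.CorrelationModel())
    print(f"FH {variant:9s} pseudo-R2 = {r2:.3f}")
```

```
FH fixed     pseudo-R2 = 0.706
FH specific  pseudo-R2 = 0.279
FH intravar  pseudo-R2 = 0.113
```

The turnover-only model explains far more than the ITV-inclusive one, and the
ITV component itself is nearly unpredictable from the environment — the
default scenario generates ITV that is large but environmentally
idiosyncratic, and the models recover exactly that structure.

The same workflow runs from the shell:

```sh
cwmitv simulate --seed 1 --out data/
cwmitv run-all --config config.yaml --seed 1 --out results/
```

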