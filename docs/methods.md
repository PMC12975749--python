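# Methods

This note documents the models and procedures implemented in `cwmitv`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Community-weighted means and their decomposition

For plot *m* and a trait, the three CWM variants are weighted means over the
species present, with weights *p&#7522;* equal to each species' cover divided by
the total cover of species **with trait data in that plot**.  Renormalizing
over the measured species (rather than all species) keeps the fixed and
specific variants comparable when a rare species lacks measurements, and
makes the identity CWM_intravar = CWM_specific − CWM_fixed hold exactly per
plot because all three variants share one weight vector.  Plots in which no
measured species occurs get a missing value and are dropped listwise, per
response, with counts logged.

Species means are computed in two stages: the plot-specific mean *x&#7522;&#8344;* is
the arithmetic mean over that plot's individuals, and the fixed mean *x&#7522;* is
the **unweighted** mean of *x&#7522;&#8344;* over the plots where the species occurs.
Plots, not individuals, are the averaging unit, so heavily sampled plots do
not dominate a species' fixed mean.  An individual-weighted alternative
would be defensible; the unweighted convention is the stricter reading of
"averaged across plots" and is flagged here as a deliberate choice.

The variance decomposition uses centered (variance-style) sums of squares of
the fixed, intravar and specific CWM series across plots:
SS_cov = SS_specific − SS_fixed − SS_intra, algebraically twice the centered
cross-product of the fixed and intravar series.  Percentages are relative to
SS_specific; a negative covariation therefore lets the turnover and ITV
shares sum past 100%.  An ANOVA-style explained-variation variant was not
implemented; total SS is the only mode offered.  The decomposition is run on
the six traits and additionally on the two trait-PCA axis scores, treated as
two extra "traits".

Numerical detail: group means of *identical* values are forced to that exact
value (pairwise summation can otherwise be one ulp off), so a dataset with
no ITV yields CWM_intravar of exactly zero, not 1e-14.

## Ordination

PCA is an eigendecomposition of the correlation matrix by default (all
variable blocks mix units); the covariance matrix is available via
`scale=False`.  Sign convention: every loading column is flipped so its
largest-magnitude entry is positive, which makes axis interpretation
reproducible.  The trait PCA is fitted at species level on fixed means (one
point per species, so occupancy does not weight the functional space); both
the fixed and the plot-specific species means are then projected onto the
same loadings to obtain axis scores for the CWM machinery.

Overstory composition is ordinated by non-metric multidimensional scaling of
Bray–Curtis dissimilarities, k = 2, with a classical-scaling start plus
random restarts (50 by default in the library, fewer in the pipeline default
for speed), convergence at stress improvement < 1e-6.  The reported stress
is Kruskal stress-1 recomputed from the final configuration by isotonic
regression.  The final configuration is rotated to its principal axes and
centered — the rotation target of the field-standard post-rotation step is
not prescribed anywhere, so principal-axis rotation (axis 1 = maximal score
variance) is used and documented as such.  Wisconsin double standardization
and square-root pre-transforms are available behind flags but off by
default: the input is treated as an already-composite abundance index.

## Spatial GLS models

The trait–environment model is y = Xβ + ε, ε ~ N(0, σ²Σ(θ)), with
Σ built from corr(d) = (1 − nugget)·ρ(d/range) over Euclidean plot-center
distances in meters; ρ is exponential by default (gaussian and spherical are
available; `family="none"` reduces exactly to OLS).  β and σ² are profiled
out analytically; the range (log scale, initialized at the median inter-plot
distance, bounded optimization) and optionally the nugget (logit scale,
Nelder–Mead) are estimated by **maximum likelihood**, not REML — pseudo-R²
and variance partitioning compare likelihoods across different fixed-effects
structures, which REML does not permit.  The default of no nugget keeps the
model minimal; among-family selection by AIC is possible by refitting with
each family.

Predictors are standardized to mean 0, SD 1 inside the fit, so coefficients
are comparable and rescaling a raw column leaves the fit unchanged.
Coefficient tests are two-sided t-tests with n − k degrees of freedom using
the (n − k)-denominator residual variance, as in standard GLS software; the
ML variance (n denominator) enters only the likelihood.  No multiple-testing
correction is applied across the 8 predictors × 24 responses; users should
treat marginal p-values accordingly.

Nagelkerke's pseudo-R² is computed against an intercept-only GLS null that
re-estimates its own correlation parameters.  With continuous likelihoods
the null log-likelihood can be positive, making the Nagelkerke denominator
non-positive; the Cox–Snell numerator is then returned with a logged
warning.  Because the null can absorb smooth spatial trend through its
correlation structure, responses driven by a perfectly smooth gradient
(e.g. a planar elevation effect) show systematically lower pseudo-R² than
the same signal carried by a patchy field — an inherent property of
likelihood-ratio R² under spatial models, not a bug; the synthetic defaults
use a patchy soil gradient partly for this reason.

Partial-effect curves evaluate the fitted line over a grid of one
standardized predictor with all others held at 0 (their mean).  Per-species
models refit the same GLS to each retained species' plot-specific means
(default: present in ≥ 10 plots); under the null these slope tests are
calibrated to the nominal 5% rate (verified by simulation in the acceptance
suite).

## Variance partitioning

Seven subset models (T, S, B, TS, TB, SB, TSB) are fitted against one shared
intercept-only null and the inclusion–exclusion system is solved for the
seven disjoint fractions; the triple-shared fraction is defined as the
remainder, so closure (fractions sum to the full-model R²) is exact by
construction.  Correlation parameters are re-estimated independently in each
subset model, so small negative fractions can occur; they are reported as
computed, with a floor-at-zero display option.  No adjusted-R² correction is
applied for the differing numbers of predictors per subset — this biases
shared fractions slightly upward and is flagged as a known limitation.
Exactly duplicated predictor columns within a subset are fitted once (they
span the same space), which keeps degenerate constructions non-singular.

## The synthetic generator

The generator emulates a 121-quadrat (11 × 11 grid of 10 m cells) understory
survey of 45 species with five measured individuals per species per plot:

- **Environment.** Elevation is a deterministic tilted plane (~400 ± 40 m);
  slope, aspect and convexity add seeded variation.  The nine soil variables
  are built from two latent Gaussian random fields — a fertility axis
  (moisture, SOC, TN positively; pH negatively) and a phosphorus-richness
  axis (TP, Ca) — plus variable-specific fields, all with exponential
  covariance exp(−d/range), range 30 m by default, realized by dense
  Cholesky factorization over plot centers.  Biotic variables are stand
  density, basal area and two latent composition axes; an overstory
  composition matrix whose gradients align with those axes is generated for
  the NMDS stage.
- **Community.** Expected cover follows a Gaussian niche on the standardized
  turnover gradient (soil TP by default), times mean-one lognormal noise
  (CV 1.0 by default — covers are positive and right-skewed), with covers
  under 1% of `max_cover` set to 0 to mimic field non-detection.
- **Traits.** Each (plot, species) occurrence draws `n_individuals` = 5
  records: species baseline + plastic response (slope × standardized
  gradient, zero by default) + a plot-level species deviation independent of
  the environment (`plot_itv_sd`) + individual noise, noise SDs expressed in
  units of each trait's between-species SD.  LDMC and Φ_PSII are clipped to
  their physical ranges with a log message.

Default magnitudes (`niche_breadth` 0.5, `cover_noise_cv` 1.0,
`turnover_coupling` 0.6, `plot_itv_sd` 1.2, `individual_sd` 0.25) were
chosen once so the default study reproduces the qualitative regime reported
for this kind of system: ITV shares of roughly 25–45% of community trait
variance alongside turnover shares of 50–70%, ITV that is large but
environmentally idiosyncratic, and consequently turnover-only models with
substantially higher pseudo-R² than ITV-inclusive ones.

What the generator does **not** emulate: visual cover binning, kriging of
soil point samples (per-plot values are emitted directly), Importance-Value
computation from tree censuses, taxonomic identity of real species, and
fine-scale within-plot microhabitat structure.  Passing tests therefore show
that the estimators recover known structure under Gaussian niches,
stationary random fields and additive trait noise — not that real fern
communities obey those assumptions.

## Problem sizes and tolerances

Simulation-based checks use the sizes that make them sharp but quick: the
decomposition closure runs 1,000 random 10-plot instances (closure asserted
at 1e-8 relative); range recovery uses 100 replicates of an 11 × 11 grid
with true range 20 m (median within [10, 40] m); the directional ITV pattern
uses 20 full-study replicates; type-I calibration accumulates 500 species ×
trait fits on 8 × 8-plot studies (rate 0.05 ± 0.02); partition closure is
asserted at 1e-10 on every run.  The per-plot CWM identity is asserted at
1e-10 relative; GLS/OLS equivalence at 1e-8.

## Known limitations

- The exponential-without-nugget default is a modeling choice, not an
  inference from any particular dataset; with strong fine-scale noise a
  nugget model (available via `estimate_nugget=True`) fits better.
- Pseudo-R² values from different responses are comparable only loosely;
  the Cox–Snell fallback (logged) changes the ceiling for affected fits.
- Negative partition fractions are genuine outputs of independently
  optimized subset models and should be reported, not silently floored.
- The CLI's `decompose` stage infers trait names from `<trait>_<variant>`
  column labels and therefore requires trait names without underscores.
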