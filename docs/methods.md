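# Methods

## Model and assumptions

Each gene's expression over the brain is treated as a realization of a
second-order-stationary random field observed at sparse wells.  Spatial
dependence is summarized by the semivariogram γ(h) = nugget + partial
sill · g(h/range), with g the exponential (default), gaussian or
spherical unit structure.  Ordinary kriging then gives the best linear
unbiased predictor under that model, with weights constrained to sum to
one so that the (unknown, constant) mean cancels.  The approach assumes
isotropy and stationarity within the analysis domain; anisotropic or
nonstationary structure is absorbed into, and degrades, the fitted
nugget.

Downstream statistics deliberately use ranks (Spearman's ρ against the
target map), so any monotone distortion between expression intensity and
the imaging measure is irrelevant; the validity filter uses Pearson's r
between observed and held-out well values, where the linear scale *is*
meaningful.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| variogram family | exponential | gstat-style standard; config-selectable, recorded in outputs |
| variogram bins | 15 | equal-width lag bins |
| max lag | half max pairwise distance | customary rule of thumb |
| LOOCV refit | per fold | honest validation; full-data-model reuse is opt-in and logged |
| ρ threshold | 0.7, comparison ≥ | coexpression screen |
| r threshold | 0.3, comparison > (strict) | prediction-validity screen |
| prioritization percentile | 90 | keep the decile of screened genes with smallest \|SD − SD_target\| |
| SD divisor | n − 1 (sample) | population divisor selectable |
| enrichment sidedness | one-sided overrepresentation | two-sided selectable |
| enrichment α | 0.05, q < α strict | BH-adjusted |

Where the screen's comparison conventions are stated ambiguously in the
field (ρ ≥ 0.7 vs ρ > 0.7 appear interchangeably), the inclusive ≥ is
the default and both are configurable; r > 0.3 is strict.

## The synthetic generator

`synthetic.SyntheticConfig` defaults define the standard study: a
10×10×10 voxel grid at 2.5 mm spacing (≈39 mm diameter), 50 genes, 2
drivers, exponential fields with nugget 0.02 / partial sill 1.0 / range
20 mm (ground-truth RSV ≈ 98%), 180 wells, and target noise SD 0.3
(≈15% of the target's SD).  Wells are a uniform random site subset by
default; a clustered mode mimicking slab-style sampling is available.

Two design choices deserve explanation:

- **Driver coherence.**  The target map is a weighted sum of the driver
  fields plus noise.  If the drivers were mutually independent, no
  single driver could rank-correlate with a two-driver target above
  ≈0.69 (for two equal weights the population Spearman is
  (6/π)·asin(√2/4)), so a ρ ≥ 0.7 screen could never recover a planted
  independent pair — and biologically, genes that jointly shape one
  receptor's distribution are themselves coexpressed.  Driver genes
  therefore share a latent structured field (default coherence 0.95 of
  structured variance); non-drivers are fully independent.
- **Well density and smoothness.**  An exponential covariance is not
  mean-square differentiable: prediction error at a held-out well decays
  only like the well spacing over the range.  The defaults put the mean
  nearest-well spacing (~1.6 mm) far inside the correlation length
  (20 mm), the regime in which kriging prediction is informative —
  mirroring real atlas sampling relative to centimetre-scale cortical
  expression gradients.  The `gaussian` field family generates genuinely
  smooth fields (LOOCV r ≈ 0.99 at the same density) and is used where a
  "smooth gene" is meant literally.

What the generator does **not** emulate: donor-to-donor variability and
probe-level noise structure, hemispheric asymmetry, anatomically
realistic cortical meshes and geodesic distances, and anisotropy.
Passing tests on synthetic studies therefore demonstrate correctness of
the estimator chain and its screening behaviour under the stated model,
not performance on real atlas data.

## Numerical choices

- **Variogram fitting** is a variable projection: the range is profiled
  over a 30-point deterministic log-spaced grid (sub-bin to 6× the lag
  window); at each candidate the nugget and partial sill solve a
  2-parameter weighted least squares in closed form with nonnegativity
  repaired on the active boundary; the best candidate is polished by
  bounded trust-region least squares.  The polished range is capped at
  6× the lag window: beyond the observed window, range and sill are
  jointly unidentifiable and runaway ranges produce numerically
  degenerate kriging systems.
- **Kriging solves** apply an escalating diagonal jitter
  (0, 1e-10, 1e-7, 1e-4 × sill) and accept a solution only if the
  weight-sum constraint holds to 1e-8 — a built-in conditioning check.
  Unsolvable sites are set missing and masked out.
- **LOOCV fold refits** reuse the full-data bin edges (the held-out
  well's pairs are subtracted from the binned sums) and the grid-profile
  fit without polish, with the full-data model as an extra candidate;
  this makes per-fold refitting exact and cheap.
- **Degenerate LOOCV predictions.**  Leaving well i out shifts every
  prediction by about −z_i/(n−1); an (almost) constant predictor
  therefore acquires a spurious correlation of magnitude up to 1 that
  reflects resampling, not skill.  r is defined as 0 when the predicted
  values' SD is below 0.2× the observed SD (and when either vector is
  exactly constant).  A calibrated predictor at that spread would have
  r ≈ 0.2, below the r > 0.3 screen, so the convention cannot suppress
  a gene with usable signal.
- **Ties** in Spearman use mid-ranks; prioritization percentiles use
  linear interpolation between order statistics with ties at the cutoff
  all kept; screened output sorts by ρ descending then gene id,
  prioritized output by SD descending then gene id.
- **Duplicate well coordinates** are averaged at load with a warning;
  genes with fewer than 3 wells are loaded but flagged unfittable.

## Open design points, resolved

- Surface analyses use 3D chordal distances between vertex coordinates
  (geodesic distance is not computed); this underestimates along-surface
  separation across sulci and is flagged in output metadata.
- Annotation catalogues are taken as given (plain term→gene TSV): no
  ontology-hierarchy propagation is performed, and the reference
  population is the catalogue's own gene list (a flag switches to the
  analysis universe).
- No multiple-testing correction is applied to the ρ screen: it is an
  effect-size filter, not an inference; the enrichment stage is the
  inferential step and is FDR-controlled.
- Cortical (surface) and subcortical (volume) screens run independently
  on their own geometries and are intersected only for reporting
  both-region genes.

## Problem sizes in tests and the acceptance script

Synthetic studies use 1000 sites / 50 genes / 180 wells for full-pipeline
checks (noiseless plus 10–20 noisy seeds), 125-site / 50-well single-gene
studies for LOOCV behaviour (100 null repeats), 5 random ≤10-well
instances for the dense-solver oracle, and 500 simulated null studies
over a 120-gene, 40-term catalogue for FDR control — sizes chosen so the
chain's statistical claims are testable with comfortable margins on a
single CPU.

## Known limitations

Kriging quality — and hence everything downstream — degrades when wells
are sparse relative to the field's correlation length; with rough
(exponential) fields the LOOCV r of a well-specified model rarely exceeds
~0.85 at realistic densities, which is precisely why a validity screen is
needed.  RSV estimates are unreliable when the analysis domain is small
relative to the range (the sill is never observed); the fitted RSV then
saturates toward 100%.  The enrichment test inherits the usual caveats of
overrepresentation analysis: term overlap is ignored and the choice of
reference population materially changes p-values.
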