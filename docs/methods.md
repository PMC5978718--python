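# Methods

This note records the models implemented in `nicheshift`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer should know
about.

## Niche-shift model

**Background sample.** "Potential habitat" is the set of centers of
1°×1° half-open grid cells (`[lon, lon+1) × [lat, lat+1)`) intersected
by any coastline polyline. Cell membership is computed by exact segment
traversal (cutting segments at gridline crossings), not point sampling,
so the result is deterministic and resolution-exact. Polylines crossing
the antimeridian are split first; longitudes are normalized to
[−180, 180).

**Buffered climate extraction.** Satellite marine layers and
terrestrial layers rarely cover the same coastal pixel, so each
location's climate vector is the per-variable mean over 50 random
points inside a 50-km great-circle disk (area-uniform: √u radial
transform, longitude offsets compressed by cos lat; haversine sphere
radius 6371.0088 km). Layer values are bilinear interpolations of cell
centers; samples landing on missing data are dropped, and only if *all*
samples miss for a variable is an error raised naming the variable and
point.

**Variable filtering.** Pairs with |Pearson r| ≥ .9 are removed
greedily: find the worst remaining pair, drop its member with the
larger mean |r| against all remaining variables, repeat; ties drop the
alphabetically later name. Deterministic and order-independent.

**Ordination.** Correlation PCA (center + unit-scale) over background
and occurrence rows jointly. Scaling is required because the variables
mix °C, mm and salinity units; fitting jointly keeps one coordinate
system for both clouds. The alternative (background-only fit) is
available through the function arguments. No kernel density weighting
of occurrences is applied. Sign convention: each component's
largest-magnitude loading is made positive.

**99% regions and O/E/U labels.** Each range's 2-D score cloud gets a
Gaussian KDE (Scott's rule with the full sample covariance, the scipy
default; the bandwidth matrix is recorded in the output). The region is
the highest-density set of evaluation-grid cells whose cumulative
normalized mass first reaches the coverage (0.99): a highest-density
region, not a pointwise quantile, hence deterministic given grid and
bandwidth. The default grid is 200×200 spanning the data padded by 3
marginal bandwidths; comparing two regions requires a shared grid
(`shared_grid(...)`), otherwise classification refuses. Labels follow
set algebra on the masks (O = both, E = invaded only, U = native only);
populations are labeled by the cell containing their population-mean
score, and populations outside both regions are reported as `outside`.
Degenerate score clouds (singular sample covariance) fall back to a
diagonal bandwidth floored at 1e-3 of the data scale, so identical
points still yield a compact region.

## Clone and ploidy filter

Ploidy: diploid iff ≥ 1 heterozygous locus. This is applied verbatim,
which means a diploid homozygous at every typed locus is misclassified
haploid — a known property of the rule, not of this implementation.

`p_gen` is the Hardy–Weinberg probability of an MLG (p² / 2pq per
locus, missing loci skipped); `Psex` is the binomial upper tail for
observing the MLG ≥ n times among N sampled thalli under independent
sexual reproduction. No F_is correction is applied, and the default
significance threshold is α = 0.05; both are exposed as arguments.
Allele frequencies are computed per population after provisionally
collapsing exact-duplicate MLGs once (switchable), to limit clonal
inflation. MLG matching ignores loci missing in either thallus and
refuses to merge thalli sharing fewer than 5 scored loci — conservative
toward retaining genets. Within a matched group with Psex < α, every
ramet after the first (input order) is dropped; haploids are always
dropped.

## Ordinal phenotype models

`SBS = BS_treatment − BS_control` per thallus (one control apex per
thallus and stressor), giving ordered values in −2..2. Models fit the
categories actually observed in each data subset; negative values enter
as the lowest categories when present rather than being collapsed.

The proportional-odds likelihood uses the logit link. Cutpoints are
optimized through `θ₁ = ζ₁, θ_j = θ_{j−1} + exp(ζ_j)`, which enforces
ordering without constraints. Fixed-effect fits (`fit_clm`) use BFGS
with an analytic gradient, gradient tolerance 1e-8, and starting values
from cumulative empirical logits; fits whose coefficients run past
|β| > 30 raise a separation error rather than returning garbage.

The mixed model (`fit_clmm`) adds a normal population intercept and
maximizes the marginal likelihood with **adaptive** Gauss–Hermite
quadrature: each group's integrand is Newton-maximized (the integrand
is log-concave, so this is safe), and the 15 default nodes are centered
at the mode and scaled by the curvature. Adaptivity matters — with ~50
observations per group the integrand is far narrower than the random
intercept prior, and non-adaptive quadrature at any practical node
count would be badly biased. Increasing nodes 15→25 moves the
log-likelihood by < 1e-4 on the test fixtures. σ is optimized on the
log scale with bounds [1e-4, 50]; a fit at the lower bound reports a
numerically-zero variance and collapses to the fixed-effects fit.

p-values come from likelihood-ratio χ² tests of nested fits. The
random-intercept test (mixed vs fixed full model, 1 df) is
anti-conservative at the boundary; this matches common practice and is
flagged here. The analysis-of-deviance battery compares the native
*source* populations against non-native ones (other native populations
do not share the invasion's history and are excluded); main effects are
dropped from the full region × treatment interaction model, and post
hoc tests refit region within each treatment level (with the random
intercept where ≥ 2 populations remain), without multiplicity
correction. If a region contains a single population the
random-intercept row is reported not-estimable and fixed-effect rows
are still returned. The SST cline model (SBS ~ SST + region +
SST×region + (1|pop)) instead contrasts the *whole* native coastline
with the invaded one, because the native cline spans source and
nonsource latitudes; SST is centered before fitting, prediction curves
report P(SBS > 0) across the observed SST range per region, and the
R² of SSTmax against |latitude| per coastline is attached as a
diagnostic.

## Darwin rates

`rate = |ln(x₂/x₁)| / (t/10⁶ yr)` with t defaulting to 100 years (the
invasion's approximate age). The trait entering the ratio is pluggable;
the default is the group-mean proportion of bleached thalli
(SBS > 0) at a treatment level, floored at ε = 0.01 so a fully tolerant
group does not produce ln 0. Rates are computed per invaded coastline ×
treatment level against the native-source mean and averaged per
stressor. The published per-stressor estimates for the real system
depend on the deposited assay data and are not recomputable from
synthetic worlds; this module reproduces the formula and the averaging
convention.

## Synthetic world

The generator emulates the *structure* of the study system, not its
geography:

* Coastlines are meridional polylines — one native (populations at
  25–46°N, source subset restricted to 38–46°N) and one to three
  invaded (25–50°N). Occurrences are snapped to coastal cell centers.
* Climate layers are latitudinal ramps (temperatures fall ~0.4–0.6 °C
  per degree of |latitude|; ranges rise) plus a longitudinal
  seasonality term (the native coast is more seasonal), a +1.5 °C
  offset on all six temperature-level layers on the invaded side, a
  smooth seeded anomaly field per variable, and white cell noise. The
  smooth anomalies (sinusoid mixtures, 4–12° wavelengths) represent
  regional climate structure independent of latitude; they keep
  cross-variable correlations realistic (below the .9 filter threshold)
  and survive the 50-km disk averaging. With all stochastic amplitudes
  zero, every layer equals its analytic formula exactly.
* The warm offset plus the cold source band produce the planted
  geometry: high-latitude invaded sites fall inside the source niche
  (O) and low-latitude ones beyond its warm edge (E). Against the
  *whole* native range the same invaded populations read as conserved —
  the contrast the method exists to expose.
* Genotypes: per population and locus, allele frequencies are Dirichlet
  draws (10 loci, 8 alleles, concentration 1); planted clones are exact
  MLG copies of a diploid progenitor, haploids carry one allele per
  locus, and a truth table records every planted genet for recovery
  tests.
* Phenotypes follow the latent-logistic cumulative-link model the
  analysis fits: latent propensity = treatment severity + region effect
  + SST-linked cline + population intercept (+ optional per-population
  offsets, used to plant tolerance advantages for expansion
  populations); scores are drawn from the implied multinomial. Controls
  are drawn at zero severity; the default cutpoints (2.2, 4.0) put
  ~10% bleaching in controls, so negative SBS occurs but is uncommon.
  The distribution of control bleaching is a free parameter of the
  generator, not a claim about any real assay.

What passing tests on this generator do **not** show: robustness to
real-world features it omits — non-linear coastlines and shared ocean
circulation, spatially autocorrelated sampling of occurrences,
genotyping error and null alleles, assay-plate effects, or deviations
from proportional odds in real bleaching scores.

## Problem sizes and seeds

All randomness flows from explicit seeds through numpy Generators; the
pipeline derives one child seed per stage from the global seed, so
stages are individually reproducible and a rerun is byte-identical.
The analysis scripts and the acceptance script use a 45-population
world (three invaded coastlines, 16 thalli per population). Simulation
studies in the test suite use 20 populations × 50 observations for
mixed-model recovery (50 replicates), 1,000 null replicates for LRT
calibration, and 100 seeded replicates of the full
world→niche→phenotype chain; these sizes give Monte-Carlo error
comfortably below the asserted tolerances.

## Known limitations

* The KDE coverage is grid-mass coverage, so the point coverage of the
  data can fall slightly under the nominal 99% (the tests bound it at
  97% for well-behaved clouds).
* The random-intercept LRT ignores the boundary correction (p-values
  for σ = 0 are conservative by about a factor of two).
* `Psex` uses the plain binomial formulation; inbred populations would
  need an F_is-corrected variant.
* Mixed-model standard errors come from a finite-difference Hessian of
  the quadrature likelihood; they are adequate for z-screening but the
  LRT is the authoritative test throughout.
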