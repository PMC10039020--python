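# Methods

This note records the models, defaults, and design choices behind
`sedanet`, and what the synthetic tests do and do not demonstrate.

## Data model

A record is a `CountMatrix`: non-negative integer read counts per sample
and family, with a strictly increasing calibrated age per sample (kyr
BP; larger = older). All stratigraphic ordering keys on age, never on
file order. Families carry a `TaxonAnnotation` (habitat
pelagic/benthic/excluded, functional group, trophic mode); taxonomic
curation — e.g. dropping contaminant or parasite families — is expressed
entirely through the annotation's `excluded` label, not through special
cases in code. Proxies are age–value series on their own grids.
Kraken2 report parsing uses clade-level counts at rank code `F` by
default (a `clade_counts=False` option switches to direct assignments;
the choice matters only when reads are classified below family level).

## Filtering and rarefaction

The retention rule is two conjunctive conditions — present (count > 0)
in ≥ `min_samples` (3) samples *and* column total ≥ `min_total` (10).
The alternative reading (≥ 10 reads in each of ≥ 3 samples) would
eliminate genuinely rare but consistently present families and is not
used.

Rarefaction draws exactly `depth` reads per sample per iteration,
without replacement (multivariate hypergeometric) by default; a
with-replacement multinomial option exists because classical rarefaction
is not the only defensible reading of "resampling to a fixed sample
effort". The 500 iterations are aggregated by the arithmetic mean and
kept as real numbers: every downstream correlation is rank-based, so
rounding would only discard information. Samples whose total is below
the target depth raise an error naming the sample — silent dropping
would bias the stratigraphy. The pelagic and benthic branches are
filtered and rarefied independently, each with its own depth; only the
pelagic branch feeds the networks.

Because the two branches are rarefied to *fixed* depths, a
pelagic:benthic ratio of rarefied totals would be a constant; the ratio
is therefore computed on the raw filtered counts (it is invariant to
uniform per-sample rescaling, so library-size effects cancel).

## Proxy alignment and tagging

Interpolation is piecewise linear and refuses to extrapolate: query ages
outside the proxy span come back missing. Only a missing run at the
*young* end has a defined repair — each value is replaced by the mean of
the three youngest interpolated values (the situation of a sea-ice
biomarker record that stops before the core top); gaps anywhere else are
an error. Environmental association uses Spearman ρ of each family's
aggregate rarefied abundance against the aligned proxy, with BH
adjustment applied within each proxy's battery of family tests (not
pooled across proxies, since each proxy answers a separate question).
Tags require ρ > 0.4 and adjusted p < 0.1. Tag sets for the two proxies
are not forced to be disjoint; with anticorrelated proxies they rarely
overlap in practice.

## Spearman network

ρ is the Pearson correlation of average ranks; two-sided p values use
the t approximation with n − 2 degrees of freedom (the behaviour of the
usual correlation-test routines). BH runs over the full upper triangle
of tested pairs; constant columns are excluded from the battery rather
than contributing undefined tests. Edges require ρ > 0.4 and adjusted
p < 0.1, positive sign only (a negative-edge variant exists as a
diagnostic); isolated nodes are pruned, so every surviving node has
degree ≥ 1. Modules default to connected components labelled by
decreasing size; greedy modularity is available behind a flag but never
the default, because component structure is the weakest assumption
consistent with "two visually separate clusters". The degree comparison
between tagged and untagged families uses the Welch (unequal-variance)
t-test, appropriate for the very unequal group sizes involved.

**Known limitation.** Component-based modules are brittle by
construction: among thousands of simultaneous tests controlled at FDR
0.1, a single false-positive edge chain can merge two otherwise separate
blocks. On synthetic data this happens on some seeds and not others;
when it does, the module Rand index against truth drops sharply while
tagging, edge recovery and the network-overlap statistics are
unaffected. A community-detection method is the remedy when component
merging is observed.

## Gaussian copula graphical model

Marginals are negative-binomial (NB2) regressions of each family's
(rounded) aggregate counts on the covariates IP25 and SST with
intercept; families whose NB fit fails to converge or whose dispersion
collapses fall back to Poisson with a warning. Dunn–Smyth residuals map
each count to a normal score: u ~ Uniform(F(y−1), F(y)) under the
fitted marginal, z = Φ⁻¹(u), clamped to [10⁻⁶, 1 − 10⁻⁶]. The
randomisation is seeded; one draw is used by default (averaging edges
over several draws is available, as the appropriate handling of this
randomness is a genuinely open choice).

The graphical lasso maximises
`log det Θ − tr(SΘ) − λ‖Θ‖₁,offdiag` on the score correlation matrix by
ADMM: an eigendecomposition-based Θ-update, off-diagonal
soft-thresholding for the split variable Z (which therefore carries
exact zeros), and dual update, iterated to 10⁻⁶ element-wise residuals
(2000-iteration cap; non-convergence raises). The reported precision is
the smooth iterate masked by Z's support, which keeps positive
definiteness in practice while giving a clean edge set; edge weights are
partial correlations −Θ_ij/√(Θ_ii Θ_jj). At λ = 0 the solver reproduces
direct inversion of S; at λ ≥ max |off-diagonal of S| the edge set is
empty. The solution is cross-checked in the tests against
scikit-learn's independent coordinate-descent implementation. Edge
counts along the default grid (0.1–1.0 step 0.1, plus the headline
λ = 0.51) are checked for monotone shrinkage and a warning is emitted on
violations, since glasso paths are not strictly monotone in general.

## Network agreement

Agreement per λ is the Jaccard index of the positive copula edges and
the (positive) Spearman edges, restricted to the shared node universe.
The null rewires the *copula* graph by double-edge swaps — the
model-based network whose degree structure is conditioned on — with
10 × |E| swaps per replicate (enough to approach configuration-model
mixing) and 10 replicates per λ. Graphs admitting no valid swap are
returned unchanged with a warning. `exceedance` is the fraction of null
replicates ≥ the observed value; an exceedance of 0 means the observed
overlap exceeds the whole null distribution.

## Stratigraphic diagnostics

The ACF screen flags families whose sample autocorrelation exceeds the
±z·n^(−1/2) white-noise band at any lag up to `max_lag`; with ~25
samples the band is approximate, so this is a screen for serial
dependence, not a formal test. CONISS merges only stratigraphically
adjacent clusters, choosing at each step the merge with the smallest
increase in within-cluster sum of squares,
`Δ(A,B) = |A||B|/(|A|+|B|) · ‖c_A − c_B‖²`; cumulative heights therefore
sum exactly to the total within-group sum of squares, which the tests
verify against a brute-force recomputation oracle. Clustering runs on
proportion-transformed data by default (the convention for percentage
diagrams) and, in the pipeline, on the displayed-family subset (present
in ≥ 3 samples, reaching ≥ 1.5% in at least one sample — "reaches" being
the stratigraphic-diagram reading of the display threshold).

## Synthetic communities

The generator emulates the features the statistics rely on: log
abundance of family f at time t is
`intercept_f + β_f·driver(t) + module factor + noise`, squashed through
a softmax into per-sample proportions and drawn multinomially at a depth
uniform on `depth_range` — so compositional coupling is real and sample
totals equal their drawn depths exactly. Structural zeros are injected
into the proportions *before* the draw, preserving that identity. Two
smooth drivers (sea-ice-like and SST-like) are anticorrelated by
construction (default −0.7). Defaults: 25 samples, 160 families, depths
10⁴–4·10⁴, 5% zero inflation, loadings β = 1.5, module factor sd 0.5,
noise sd 0.3; 25% of families load on the ice driver, 65% on the warm
driver and 10% are neutral, matching a strongly environmentally
structured pelagic community in which the two modules hold ~90% of
retained families. Proxies are noisy observations of the drivers on a
knot grid offset from the sample ages and refined two-fold (biomarker
records typically resolve finer than the sedaDNA sampling); an optional
truncation removes the knots covering the youngest three samples to
exercise the tail-fill rule.

What the generator does **not** emulate: DNA damage and taphonomy,
read-level noise, taxonomic misclassification, age-model uncertainty,
and non-stationary driver–taxon relationships. Passing tests therefore
demonstrate that the statistical machinery recovers structure *of the
assumed form*; they say nothing about classification quality or
preservation biases in real sedaDNA.

## Problem sizes and determinism

Simulation-based tests run at the generator's default scale (25 × 160)
or smaller; the rarefaction-expectation and BH-oracle checks use 10⁴
iterations and 10³ random vectors respectively; support-recovery and
solver-limit checks use n = 400 Gaussian samples. Every stochastic
component — generation, rarefaction, residual draws, swaps, layout —
takes an explicit integer seed, and the pipeline derives per-stage seeds
from one master seed recorded in the run manifest, so tabular outputs
are byte-reproducible.
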