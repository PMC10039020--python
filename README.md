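# sedanet

Co-occurrence network analysis for sedimentary ancient DNA (sedaDNA)
records.

Shotgun-sequenced marine sediment cores yield a family-level read count
table over time-ordered samples — a compositional snapshot of past
pelagic and benthic communities. `sedanet` implements the statistical
toolchain for relating that record to paleo-environmental proxies such
as the sea-ice biomarker IP25 and alkenone-based sea-surface
temperatures (SST):

- **Normalisation** — prevalence/abundance filtering (families present in
  ≥ 3 samples with ≥ 10 reads) and repeated fixed-depth rarefaction
  (default 500 iterations, multivariate hypergeometric), aggregated by
  the mean.
- **Proxy alignment** — piecewise-linear interpolation of proxy series to
  the sample ages, with the young-end gap of a truncated record filled by
  the mean of the three youngest interpolated values.
- **Environmental tagging** — per-family Spearman correlation against each
  aligned proxy, Benjamini–Hochberg adjusted within the proxy's test
  battery; families with ρ > 0.4 and adjusted p < 0.1 are tagged *ice*
  or *warm*.
- **Spearman network** — edges between families with pairwise ρ > 0.4 at
  BH-adjusted p < 0.1 (positive correlations only, no self-loops,
  isolated nodes pruned), modules as connected components, plus
  neighbour-composition contingency tables and Welch t-tests on node
  degrees.
- **Gaussian copula graphical model** — per-family negative-binomial
  regressions on the covariates (IP25, SST), Dunn–Smyth randomised
  quantile residuals, and an L1-penalised precision estimate of the
  residual scores (graphical lasso, ADMM solver). For scores **z** with
  correlation matrix *S* it maximises
  `log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|`; nonzero off-diagonals of Θ are
  conditional (direct) associations with environmental effects removed.
  Default shrinkage grid 0.1–1.0 plus the headline λ = 0.51.
- **Network agreement** — Jaccard index of the two edge sets per λ,
  against a degree-preserving double-edge-swap null (10 replicates per λ).
- **Stratigraphic diagnostics** — pelagic:benthic read ratio, functional
  group ratios, autocorrelation screen, and CONISS (constrained
  incremental sum-of-squares) zonation.

A synthetic-community generator with known ground truth (two
anticorrelated environmental drivers, block module structure,
compositional multinomial counts, zero inflation, uneven depths) makes
every stage testable end to end without any external data.

## Worked example

```python
import sedanet as sn

cm, ann, truth = sn.generate_community(seed=7)      # 25 samples x 160 families
pelagic, _ = sn.split_by_habitat(cm, ann)
filtered = sn.filter_families(pelagic)              # >=3 samples, >=10 reads
rs = sn.rarefy(filtered, int(filtered.sample_totals().min()), seed=9)

cr = sn.pairwise_spearman(rs.aggregate)
net = sn.build_network(cr, rho_min=0.4, alpha=0.1)
modules = sn.find_modules(net)
print(net.number_of_nodes(), net.number_of_edges(), len(set(modules.values())))
```

prints `120 3339 2`: all 120 pelagic families pass the filter, the
thresholded network keeps 3339 positive edges, and it splits into two
modules — the sea-ice-driven and the warm-water-driven block of the
generator. Running the full comparison (`examples/03_networks_and_overlap.py`)
adds the copula side:

```
Spearman network: 120 nodes, 3339 edges, 2 modules
 lambda  observed_jaccard  null_mean  null_min  null_max  exceedance
  0.100             0.194      0.129     0.124     0.134       0.000
  0.510             0.152      0.089     0.087     0.091       0.000
  1.000             0.000      0.000     0.000     0.000       1.000
```

At moderate shrinkage the observed edge overlap between the two network
methods sits far above the entire swap-null distribution (exceedance 0):
the methods agree on far more shared structure than their degree
sequences alone would produce. The `examples/` directory holds one short
narrative script per capability; the same stages are exposed as a thin
CLI (`sedanet simulate | filter | rarefy | net | copula | compare |
diagnostics | run`) driven by a YAML config with full seed control.

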