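# phycosplit

Statistical machinery to separate **biotic** (phototroph-driven) from
**abiotic** (dilution-frequency-driven) effects on bacterial community
assembly in serial-dilution enrichment experiments.

The motivating setting: complex soil-derived bacterial consortia are grown
with ("hybrid") or without ("control") the alga *Chlamydomonas reinhardtii*,
under serial 64-fold dilutions every τ ∈ {3, 6, 9, 12} days, with 16S
amplicon sequencing after every other round (2, 4, …, 10). When nutrients
are supplied infrequently (long τ), the alga dominates assembly and drives
initially distinct communities to converge; when dilutions are frequent,
abiotic nutrient supply dominates. `phycosplit` implements the compositional
statistics that make this separation, for microbial-ecology researchers with
taxa × samples count tables from comparable designs.

## What it computes

All analyses operate on centered log-ratio (CLR) transformed relative
abundances: for counts *c* with pseudocount 1,
x_i = ln((c_i + 1)/g), with g the geometric mean — after discarding taxa
whose maximum relative abundance never reaches exp(−8.2) ≈ 0.00027.

* **Diversity** — Shannon H = −Σ p_i ln p_i per community (on unfiltered
  counts), compared across treatments with two-sample Kolmogorov–Smirnov
  tests.
* **Ordination** — a single PCA fit jointly over all communities; the number
  of components exceeding sequencing noise is estimated by permuting taxon
  identities within each sample and comparing eigenvalue spectra. Aitchison
  distance (Euclidean on CLR) with metric MDS is provided as a cross-check.
* **Attribution** — the displacement of a community group along a principal
  axis between rounds 2 and 10 is decomposed into per-taxon contributions
  o_k = |x_2,k − x_10,k| · p_k (p_k the loading); taxa above the 97.5th
  percentile of the pooled contribution distribution are the axis "drivers".
  Driver sets from hybrid and control communities are compared per taxon
  with Fisher's exact test under Bonferroni correction — drivers that are
  treatment-independent mark the abiotic (dilution) axis.
* **Enrichment quadrants** — per-taxon mean CLR change per sequenced-round
  step with (r_h) and without (r_c) the alga; the sign pair places each
  taxon in a quadrant (e.g. r_c > 0 ∧ r_h < 0: enriched alone, suppressed
  with algae), and r_h < r_c marks net algal suppression.
* **Divergence testing** — Jensen–Shannon divergence
  J(X,Y) = H(½X + ½Y) − ½H(X) − ½H(Y) (natural log, bounded by ln 2) between
  communities; hybrid–control separation is tested by bootstrapping the
  difference of medians between inter (hybrid vs control) and intra
  (hybrid vs hybrid) divergence sets.
* **Trait models** — growth-curve AUC ratios (co-culture/monoculture) with
  propagated errors, spline-based growth features, carbon-utilization
  binarization at max OD600 ≥ 0.05, a positive-slope screen for secreted
  exudate compounds, and a LASSO regression
  r_s = β₀ + Σ_j β_j g_js + ε under cost (1/N)‖r − r̂‖² + λ‖β‖₁, with the
  penalty chosen by repeated 4-fold cross-validation and the held-out R²
  validated against response-shuffled null fits by a bootstrap
  median-difference test.
* **Synthetic data** — a generator that plants this exact structure (a
  shared dilution drift axis, a set of algae-suppressed soil-B taxa acting
  only at long τ, a linear utilization→enrichment map) with known ground
  truth, so every stage has a recovery test.

## Worked example

```python
import phycosplit as ps

design = ps.DesignSpec(seed=1)          # 400 taxa, 2 soils, tau in {3,6,9,12}
truth = ps.make_ground_truth(design)    # plants drift + 8 algae-suppressed taxa
table = ps.simulate_counts(design, truth)

config = ps.PipelineConfig(seed=1, n_perm=200, n_boot=1000)
report = ps.analyze(table, config)
```

Printing the headline results of `report` for this seed gives:

```
PC1 23.1% / PC2 13.0% of variance, 2 significant components
PC2 drivers (tau12, soil B): 10 taxa, 100% of planted suppressed taxa recovered
S_tau9 vs S_tau12 overlap: 100% in common
enrichment quadrants (tau12 drivers): {'II': 5, 'III': 3, 'I': 2}, 80% on the suppression side
hybrid-control JSD separation, soil B: p = 0.000 (tau12), p = 0.391 (tau3)
converged growth periods: [9, 12]
```

Read this as: the permutation test finds exactly the two planted gradients;
the drivers of the convergence axis (PC2) are the planted algae-suppressed
taxa; those taxa sit in quadrants II/III above the diagonal (suppressed in
the presence of the alga); hybrid communities separate from controls only at
long growth periods; and only the long-τ hybrid communities converge across
soils. A null dataset (no planted structure) reports zero significant
components, no drivers, and non-significant separation.

There is also a CLI mirroring the stages:

```bash
phycosplit simulate --seed 1 --out-prefix demo
phycosplit run-full --counts demo_counts.tsv --samples demo_samples.csv --seed 1
phycosplit ordinate --counts demo_counts.tsv --samples demo_samples.csv --nperm 200 --seed 1
```

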