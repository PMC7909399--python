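# aquassembly

Diversity, constrained ordination, spatial variation partitioning and
null-model community-assembly analysis for aquatic microbiomes sampled
along salinity/nutrient gradients.

The package is aimed at microbial ecologists asking a classic question
about inland waters: **is bacterial community composition assembled
deterministically (environmental filtering, e.g. by salinity) or
stochastically (dispersal, drift, shared regional pools)?** It provides
the complete statistical toolchain for answering it from a sample × OTU
count table plus per-sample environmental and geographic metadata, and a
synthetic-data generator that emulates a four-habitat salinity gradient
(rivers ≈ 0.21 ‰, freshwater lakes ≈ 0.44 ‰, a low-brackish lake ≈ 6.22 ‰
and a high-brackish lake ≈ 11.36 ‰, with TDN correlated to salinity at
*r* ≈ 0.70) with a tunable niche/neutral assembly mixture ν ∈ [0, 1].

## What it computes

* **Preprocessing** — low-abundance OTU filtering (< 10 total reads),
  taxonomy-based exclusion (chloroplasts), seeded rarefaction to the
  smallest sequencing depth.
* **α/β-diversity** — bias-corrected Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)),
  Shannon H = −Σ pᵢ ln pᵢ, inverse Simpson 1/Σ pᵢ²; Bray–Curtis
  d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); UPGMA clustering; group OTU overlap and
  within-group dissimilarity summaries.
* **Constrained ordination** — Hellinger transform, RDA with a
  permutation global test, Monte-Carlo forward selection (999
  permutations, accept while partial *p* < 0.05), iterative VIF pruning
  (threshold 10), adjusted R² by the Ezekiel formula
  1 − (1−R²)(n−1)/(n−m−1).
* **Spatial analysis** — planar projection of coordinates, PCNM spatial
  eigenfunctions (minimum-spanning-tree truncation, Gower double
  centering), three-set variation partitioning (environment / PCNM /
  linear trend) by partial RDA with permutation tests of pure fractions,
  and distance–decay regression of community similarity on geographic
  distance.
* **Permutation tests** — Mantel (Spearman/Pearson, 9999 permutations),
  ANOSIM, PERMANOVA (999 permutations), Kruskal–Wallis with
  compact-letter displays, a two-sided non-parametric permutation test on
  group mean proportions (exhaustive when feasible), Benjamini–Hochberg
  FDR.
* **Assembly null model** — randomized tables preserving each sample's
  richness and read total (occupancy-weighted species draw,
  abundance-weighted read fill); per-pair stochasticity
  ST = min(C,E)/max(C,E) comparing observed similarity C with the null
  expectation E; the **stochasticity ratio** SR = 100 × mean within-group
  ST; and significance from observed PERMANOVA F against 1000 randomized
  datasets.
* **Function profiles** — FAPROTAX-style taxon→function rule mapping and
  between-group comparison.

Everything is seeded and deterministic: the pipeline writes a manifest of
every stage seed, and re-running with the same master seed reproduces all
outputs byte for byte.

## Worked example

Estimate the stochasticity ratio on synthetic gradients with known
assembly regimes (`examples/06_stochasticity_ratio.py`):

```text
nu = 0.0: SR overall =  41.7%  per group = {'Group I': 74.2, 'Group II': 43.8, 'Group III': 44.0, 'Group IV': 30.4}  ...
nu = 0.5: SR overall =  77.1%  per group = {'Group I': 88.9, 'Group II': 78.0, 'Group III': 77.6, 'Group IV': 73.4}  ...
nu = 1.0: SR overall =  86.1%  per group = {'Group I': 84.9, 'Group II': 86.6, 'Group III': 86.2, 'Group IV': 85.9}  ...

null-model PERMANOVA: observed F = 67.8, p = 0.0050
```

Under pure niche filtering (ν = 0) the observed similarities depart
strongly from the null expectation — SR is low, and lowest in the
high-salinity groups where filtering is strongest.  As ν rises toward a
purely neutral shared pool, SR climbs toward 100% and the per-group
differences vanish.  The null-model PERMANOVA confirms that the ν = 0
group structure is far stronger than any of the 200 randomized datasets
(minimum attainable p).

The other scripts in `examples/` walk through each capability one at a
time (simulation, diversity, RDA forward selection, variation
partitioning, permutation tests, function profiles, the full pipeline);
each prints the numbers it computes and a one-line interpretation.

A thin CLI covers the two shell-level entry points:

```bash
aquassembly simulate --seed 1 --out-dir data/
aquassembly run --config cfg.yaml
```

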