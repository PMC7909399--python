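# Methods

This note documents the models, numerical conventions and design choices
behind `aquassembly`, and what the synthetic-data generator does and does
not emulate.

## Data model and preprocessing

The central object is a sample × OTU integer count table with optional
semicolon-delimited taxonomy strings per OTU; per-sample metadata
(coordinates, environmental variables, habitat group) is a pandas
DataFrame aligned by sample id. Preprocessing removes OTUs whose **total
reads across all samples** fall below a threshold (default 10 — the
standard rare-noise filter; the per-OTU-total reading is the usual
semantics when filtering "from the OTU table") and OTUs whose lineage
contains an exclusion substring (default "Chloroplast",
case-insensitive). Rarefaction draws one multivariate-hypergeometric
subsample per sample (sampling without replacement) at an explicit seed;
replicate-averaged rarefying is available for rarefaction curves but α
diversity uses a single seeded draw by default — averaging would shrink
the variance of the indices in a way most published tables do not.

Habitat rules are half-open salinity intervals per ecosystem type:
rivers → Group I; lakes split at 1 ‰ and 8 ‰ into freshwater (II),
low-brackish (III) and high-brackish (IV). The bin edges are
configurable; the defaults place lakes at 0.44 / 6.22 / 11.36 ‰ into
groups II/III/IV.

## Diversity

Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) and
therefore requires integer counts. Shannon entropy uses the natural
log (the dominant ecology convention). Within-group β summaries use the
sample (n−1) standard deviation, configurable via `ddof`. Cluster
dendrograms default to average linkage (UPGMA); complete and Ward are
available through the same call since the linkage choice is a
convention, not a result.

## Constrained ordination

RDA is computed directly from its definition: the column-centred
response Y is regressed on the standardized predictors X by least
squares; R² = SS_fit/SS_total; canonical axes are the principal axes of
the fitted values; adjusted R² uses the Ezekiel formula with the rank of
X as m. The global test permutes rows of Y; pseudo-F =
(SS_fit/m)/(SS_res/(n−m−1)). Agreement with the vegan reference
implementation (R², adjusted R², PCNM eigenstructure) is asserted in
the test suite via an Rscript oracle.

Forward selection is greedy on added R². The candidate's partial test
permutes rows of Y at the first step and **residuals of the reduced
model** afterwards — the standard scheme for partial ordination tests,
because permuting raw rows under a non-empty conditioning set does not
respect the null. The stop rule is partial p ≥ α (default 0.05); an
optional second stop (cumulative adjusted R² exceeding the full-model
adjusted R²) is off by default. VIF pruning runs *after* selection,
dropping the worst variable iteratively until all VIF ≤ 10; exact
collinearity reports +∞. All permutation p-values use the add-one
convention (b+1)/(m+1), which can never be zero.

## Spatial methods

Coordinates are projected to planar km by an azimuthal-equidistant
projection about the sample centroid. A plain equirectangular projection
was considered and rejected: over a multi-degree latitude span its
east–west scale error (cos φ varying across the domain) exceeds 1% of
the great-circle distance for extreme pairs, while AEQD keeps regional
(few-hundred-km) pairwise errors well below that.

PCNM follows the classic recipe: truncation threshold t = the longest
minimum-spanning-tree edge, distances > t replaced by 4t, Gower double
centering of −d²/2, eigendecomposition, retention of positive-eigenvalue
axes scaled by √λ. When no distance exceeds t this reduces exactly to
metric PCoA (asserted against scikit-bio). An optional flag restricts
axes to positive Moran's I (computed with the within-threshold adjacency
as weights) since conventions differ between implementations.

Variation partitioning computes the Ezekiel-adjusted R² of the RDA on
every nonempty subset of {environment, PCNM axes, linear trend} and
solves the inclusion–exclusion system exactly for the 7 region
fractions, so the fractions sum to the full-model adjusted R² to
numerical precision. Shared fractions can be negative — adjusted R²
arithmetic is not additive. Note a practical bias: the Ezekiel
adjustment is unbiased only near the null, so with a strong signal in
one set a spurious negative shared fraction of order m/(n−1) × signal
fraction appears even for exactly orthogonal predictor sets. Pure
fractions are tested by permutation of residuals of the reduced model
(the pRDA conditioning set). The "linear trend" set is the pair of
centred projected coordinates.

Distance decay is an OLS of pairwise community similarity on pairwise
geographic distance over the upper triangle, with a two-sided
Mantel-style significance test (simultaneous row/column permutation of
the similarity matrix), because pair entries are not independent and an
ordinary regression test would be anticonservative.

## Permutation tests

Mantel correlates condensed upper triangles (Spearman by default; ranks
are computed once since rank transformation commutes with relabelling
samples). ANOSIM uses averaged ranks and R = (mean between − mean
within)/(M/2). PERMANOVA uses the direct sums-of-squares identities on
squared distances; on univariate Euclidean data the pseudo-F equals the
classical ANOVA F to machine precision (asserted). The two-group
proportion test is a permutation test on the difference of group mean
proportions — two-sided, exhaustive over all C(n, n₁) reassignments when
there are ≤ 10 000 of them (then the p-value is exact, counting the
observed arrangement), sampled with the add-one correction otherwise;
zero pooled variance yields p = 1 by convention. Compact letter displays
use the insert-and-absorb algorithm on the BH-corrected pairwise
significance graph. All tests are deterministic given (inputs, n_perm,
seed), and type-I calibration of Mantel/ANOSIM/PERMANOVA/RDA at α = 0.05
is asserted over 500 null simulations each.

## Null model and stochasticity ratio

The randomizer preserves what the sampling design fixes — each sample's
observed richness s and read total N — while scrambling species
identity: s species are drawn without replacement with probability
proportional to **occupancy** (the number of samples a species occurs
in), each receives one read, and the remaining N − s reads are
distributed multinomially with probability proportional to the regional
relative abundance of the drawn species. This is the standard
abundance-based null for Bray–Curtis-based assembly inference; an
equiprobable-draw variant is available behind a flag for sensitivity
analysis.

The null expectation E is the mean similarity (1 − Bray–Curtis) over
n_rand randomizations (default 1000; per-pair Monte-Carlo standard
errors are stored so users can judge adequacy). Per pair the
stochasticity is the similarity ratio

    ST = E/C  if C ≥ E   (observed co-occurrence stronger than null)
    ST = C/E  if C < E   (observed divergence stronger than null)

with ST = 1 when C = E = 0 and ST = 0 when exactly one of them is zero.
ST is symmetric in (C, E) and lies in [0, 1]. The group stochasticity
ratio SR is 100 × the mean within-group ST; a pooled SR over all
within-group pairs is also exposed as the scalar summary of a dataset.
Group contrasts use pairwise two-sided Wilcoxon rank-sum tests on the
within-group ST values with BH correction and compact letters at
α = 0.01 — within-group pairs share samples and are not independent, so
these letters are descriptive, a limitation this convention shares with
common practice. Assembly significance compares the observed PERMANOVA
pseudo-F with the F recomputed on each randomized table.

## Synthetic-data generator

The generator emulates the statistical structure of a 40-sample inland
water survey, not its sequences: four habitat groups with 6/9/13/12
samples and group salinity means 0.21/0.44/6.22/11.36 ‰ (group draws are
moment-matched so the realized group mean and SD equal the design values
exactly — the printed group statistics are the thing being emulated);
TDN built from the salinity z-scores plus an exactly orthogonalized
noise component so the realized Pearson correlation equals the target
ρ = 0.70 by construction (up to a rarely-binding detection floor);
auxiliary environmental variables (TDP, WT, pH, DO, Chl-a) with simple
dependence structures; and site coordinates in four planar clusters with
the river cluster adjacent to the freshwater-lake cluster (connected
basins) and the brackish lakes isolated, spanning a few hundred km.

Species abundances mix two components at the probability level:

* niche: w_ik ∝ a_k exp(−(log₁₀(s_i + 0.01) − μ_k)² / (2σ_k²)), a
  Gaussian response on log₁₀ salinity (the gradient spans two orders of
  magnitude, so a response on raw salinity would collapse the freshwater
  end); optima μ_k ~ Normal(−0.3, 0.8) on log₁₀ salinity, concentrated
  toward fresh water so richness declines along the gradient;
* neutral: a regional pool r_k shared by all samples.

Counts are multinomial(N, (1−ν)w_i + νr) with N = 17 629 reads by
default, so ν interpolates continuously from pure environmental
filtering (ν = 0) to pure shared-pool sampling (ν = 1), and row sums are
exact.

Three calibration choices matter and were fixed at design time:

* **SAD steepness.** Both r_k and the niche amplitudes a_k are lognormal
  with σ = 2: microbial species-abundance distributions span several
  orders of magnitude. A flatter SAD (σ = 1) makes per-sample richness
  saturate a small species pool, which degenerates the null model — the
  randomized communities then overlap almost completely and E ≈ C
  regardless of assembly regime.
* **Niche breadth.** σ_k = 0.2 log₁₀-salinity units (salinity
  specialists). The deterministic regime must actually be deterministic:
  with broad niches, samples from different groups share most taxa and
  the ν = 0 end of the mixture would not produce the low SR that defines
  environmental filtering.
* **Decoupled amplitudes.** a_k is drawn independently of r_k. Coupling
  them makes the ν = 0.5 mixture nearly indistinguishable from ν = 1,
  because both components are then dominated by the same species.

With σ_k → ∞ the niche weights lose all salinity dependence (w ∝ a_k),
making the generator neutral/exchangeable regardless of ν.

What the generator does **not** emulate: sequence-level noise (errors,
chimeras), phylogenetic structure, real lake geography, seasonal or
depth structure, and taxon-specific environmental responses beyond the
single salinity axis. Passing tests therefore demonstrate that the
estimators recover known structure of this class — a salinity-filtered
niche/neutral mixture — not that they are robust to every feature of
real survey data.

## Problem sizes and defaults

Library defaults match field conventions: 999 permutations for
group/ordination tests, 9999 for Mantel, 1000 null randomizations.
Tests and the acceptance script run the generator at a scaled size
chosen as the package's own standard desk-scale configuration —
40 samples, 300 species, 2000 reads per sample, 100–200 randomizations
and 99–199 permutations — which keeps every Monte-Carlo check
well-resolved while the entire suite completes in a few minutes.

## Known limitations

* The null-model randomizer is one member of a family; published
  analyses differ in whether species draws are occupancy-weighted and
  how reads are refilled. The variant here preserves richness and
  totals exactly and is pluggable (`species_weighting`).
* Forward selection inherits the usual selection biases; the double-stop
  rule mitigates overfitting but is off by default to match the
  single-criterion (p < 0.05) procedure.
* Compact letters on SR group contrasts treat within-group pairs as
  replicates (see above).
* The function-profile module ships only a small synthetic rule file;
  real analyses must supply their own taxon→function database in the
  2-column format (the full FAPROTAX syntax — elimination rules,
  cross-references — is out of scope).
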