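"""Abundance-based null model for beta-diversity and the stochasticity ratio.

The null model asks: how similar would two communities be if species
identities were assembled at random from the regional pool, while keeping
what is fixed by sampling design — each sample's richness and read total?
The randomizer draws each sample's species without replacement with
probability proportional to occupancy (how many samples a species occurs
in), seeds each drawn species with one read, and distributes the remaining
reads multinomially in proportion to regional relative abundance.

The stochasticity ratio (SR) compares observed pairwise Bray-Curtis
similarity C with the null expectation E: per pair,

    ST = E/C if C >= E else C/E          (ST in [0, 1])

and SR for a habitat group is 100 x the mean ST over within-group pairs.
ST near 1 means the observed similarity is indistinguishable from the null
(stochastic assembly); ST near 0 means strong departure (deterministic
assembly, e.g. environmental filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import CommunityMatrix
from .diversity import DistanceMatrix, bray_curtis_matrix
from .permtests import bh_adjust, permanova_from_condensed, _group_codes, \
    _compact_letters
from scipy import stats as _stats

__all__ = [
    "NullEnsemble",
    "StochasticityResult",
    "null_randomize",
    "expected_similarity",
    "stochasticity_ratio",
    "assembly_significance",
]


@dataclass
class NullEnsemble:
    """Mean (and variance) of pairwise similarity over null randomizations."""

    ids: list[str]
    expected: np.ndarray            # mean similarity, unit diagonal
    variance: np.ndarray            # per-pair variance over randomizations
    n_randomizations: int
    seed: int

    def monte_carlo_se(self) -> np.ndarray:
        return np.sqrt(self.variance / self.n_randomizations)


def _null_randomize_counts(
    counts: np.ndarray,
    occupancy: np.ndarray,
    regional: np.ndarray,
    rng: np.random.Generator,
    species_weighting: str = "occupancy",
) -> np.ndarray:
    n_samples, n_species = counts.shape
    out = np.zeros_like(counts)
    pool = np.flatnonzero(occupancy > 0)
    if species_weighting == "occupancy":
        draw_p = occupancy[pool] / occupancy[pool].sum()
    elif species_weighting == "equiprobable":
        draw_p = np.full(pool.size, 1.0 / pool.size)
    else:
        raise ValueError("species_weighting must be 'occupancy' or 'equiprobable'")
    for i in range(n_samples):
        s_i = int((counts[i] > 0).sum())
        n_i = int(counts[i].sum())
        if s_i > pool.size:
            raise ValueError(
                f"sample richness {s_i} exceeds species pool {pool.size}")
        chosen = rng.choice(pool, size=s_i, replace=False, p=draw_p)
        out[i, chosen] = 1
        remaining = n_i - s_i
        if remaining > 0:
            fill_p = regional[chosen]
            if fill_p.sum() <= 0:
                fill_p = np.full(s_i, 1.0 / s_i)
            else:
                fill_p = fill_p / fill_p.sum()
            out[i, chosen] += rng.multinomial(remaining, fill_p)
    return out


def null_randomize(
    cm: CommunityMatrix,
    seed: int | np.random.Generator,
    species_weighting: str = "occupancy",
) -> CommunityMatrix:
    """One null randomization of a (preprocessed, rarefied) community table.

    Per-sample richness and read totals are preserved exactly by
    construction.  ``species_weighting`` selects the species-draw law:
    ``occupancy`` (default; common species are drawn more often) or
    ``equiprobable`` (sensitivity variant).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counts = cm.counts
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    regional = regional / regional.sum()
    out = _null_randomize_counts(counts, occupancy, regional, rng,
                                 species_weighting)
    data = pd.DataFrame(out, index=cm.data.index, columns=cm.data.columns)
    return CommunityMatrix(data, cm.taxonomy)


def _similarity_condensed(counts: np.ndarray) -> np.ndarray:
    return 1.0 - pdist(counts.astype(float), metric="braycurtis")


def expected_similarity(
    cm: CommunityMatrix,
    n_rand: int = 1000,
    seed: int = 0,
    species_weighting: str = "occupancy",
) -> NullEnsemble:
    """Null expectation E_ij: mean of (1 - Bray-Curtis) over ``n_rand``
    randomized tables; per-pair variance is stored so the Monte-Carlo
    standard error can be reported."""
    if n_rand < 2:
        raise ValueError("need at least 2 randomizations")
    rng = np.random.default_rng(seed)
    counts = cm.counts
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    regional = regional / regional.sum()
    n = counts.shape[0]
    m = n * (n - 1) // 2
    mean = np.zeros(m)
    m2 = np.zeros(m)
    for k in range(n_rand):
        rand = _null_randomize_counts(counts, occupancy, regional, rng,
                                      species_weighting)
        sim = _similarity_condensed(rand)
        delta = sim - mean
        mean += delta / (k + 1)
        m2 += delta * (sim - mean)
    var = m2 / (n_rand - 1)
    E = squareform(mean)
    np.fill_diagonal(E, 1.0)
    V = squareform(var)
    return NullEnsemble(cm.sample_ids, E, V,
                        n_rand, seed if isinstance(seed, int) else -1)


@dataclass
class StochasticityResult:
    pair_table: pd.DataFrame        # within-group pairs: C, E, ST, group
    sr_per_group: pd.Series         # percent
    letters: dict
    pairwise_q: dict
    alpha: float

    @property
    def sr_overall(self) -> float:
        """Pooled SR: 100 x mean ST over all within-group pairs."""
        return float(self.pair_table["st"].mean() * 100.0)


def _st_value(c: float, e: float) -> float:
    if c <= 0.0 and e <= 0.0:
        return 1.0
    if c <= 0.0 or e <= 0.0:
        return 0.0
    return e / c if c >= e else c / e


def stochasticity_ratio(
    C: DistanceMatrix,
    ens: NullEnsemble,
    groups,
    alpha: float = 0.01,
) -> StochasticityResult:
    """Per-pair stochasticity ST and per-group stochasticity ratio SR.

    ST_ij = E_ij/C_ij when observed similarity exceeds the null
    expectation (deterministic co-occurrence) and C_ij/E_ij otherwise
    (deterministic divergence); SR_g = 100 x mean within-group ST.
    Group differences are assessed by pairwise two-sided Wilcoxon
    rank-sum tests on the within-group ST values with BH correction and
    a compact-letter display (default alpha = 0.01).  Within-group pairs
    are not independent; the letters are descriptive.
    """
    if C.kind != "similarity":
        C = C.to_similarity()
    if C.ids != ens.ids:
        raise ValueError("similarity matrix and ensemble must share ids")
    groups = pd.Series(groups).reindex(C.ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = np.asarray(groups)
    rows = []
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                c = float(C.values[i, j])
                e = float(ens.expected[i, j])
                rows.append({"sample_i": C.ids[i], "sample_j": C.ids[j],
                             "group": g, "observed_similarity": c,
                             "expected_similarity": e,
                             "st": _st_value(c, e)})
    pair_table = pd.DataFrame(rows)
    sr = pair_table.groupby("group")["st"].mean() * 100.0

    group_names = list(pd.unique(labels))
    st_by_group = {g: pair_table.loc[pair_table["group"] == g, "st"].to_numpy()
                   for g in group_names}
    significant, pairwise_q = set(), {}
    testable = [g for g in group_names if st_by_group[g].size >= 2]
    if len(testable) >= 2:
        pairs = [(a, b) for i, a in enumerate(testable)
                 for b in testable[i + 1:]]
        raw = [_stats.ranksums(st_by_group[a], st_by_group[b]).pvalue
               for a, b in pairs]
        q = bh_adjust(raw)
        for (a, b), qv in zip(pairs, q):
            pairwise_q[(a, b)] = float(qv)
            if qv < alpha:
                significant.add((a, b))
    letters = _compact_letters(group_names, significant)
    return StochasticityResult(pair_table, sr, letters, pairwise_q, alpha)


def assembly_significance(
    cm: CommunityMatrix,
    groups,
    n_rand: int = 1000,
    seed: int = 0,
    species_weighting: str = "occupancy",
) -> dict:
    """Is the observed group structure stronger than the null model allows?

    The observed PERMANOVA pseudo-F on Bray-Curtis distances is compared
    with pseudo-F values recomputed on ``n_rand`` randomized tables;
    p = (#{F_null >= F_obs} + 1)/(n_rand + 1).
    """
    codes = _group_codes(groups, cm.sample_ids)
    sizes = np.bincount(codes)
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = len(cm.sample_ids)
    d_obs = pdist(cm.counts.astype(float), metric="braycurtis")
    f_obs, r2 = permanova_from_condensed(d_obs ** 2, codes, n)

    rng = np.random.default_rng(seed)
    counts = cm.counts
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    regional = regional / regional.sum()
    null_f = np.empty(n_rand)
    for k in range(n_rand):
        rand = _null_randomize_counts(counts, occupancy, regional, rng,
                                      species_weighting)
        d = pdist(rand.astype(float), metric="braycurtis")
        null_f[k], _ = permanova_from_condensed(d ** 2, codes, n)
    p = (np.sum(null_f >= f_obs - 1e-12) + 1) / (n_rand + 1)
    return {"observed_f": float(f_obs), "r2": float(r2),
            "null_f": null_f, "p_value": float(p), "n_rand": n_rand}
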