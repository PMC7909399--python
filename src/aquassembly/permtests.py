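"""Permutation tests on distance matrices and group comparisons.

Mantel (Spearman/Pearson), ANOSIM, PERMANOVA, Kruskal-Wallis with a
compact-letter display, White's non-parametric two-group test on
proportions, and Benjamini-Hochberg FDR adjustment.

All permutation nulls are generated from an explicit integer seed via
``numpy.random.default_rng`` so that every result is reproducible given
(inputs, n_perm, seed).  Permutation p-values use the add-one convention
p = (#{null >= observed} + 1) / (n_perm + 1), which cannot be zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import DistanceMatrix

__all__ = [
    "TestResult",
    "mantel",
    "anosim",
    "permanova",
    "permanova_from_condensed",
    "kruskal_letters",
    "whites_test",
    "bh_adjust",
]


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    n_perm: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, for report logs
        return (f"TestResult({self.statistic_name}={self.statistic:.4g}, "
                f"p={self.p_value:.4g}, n_perm={self.n_perm})")


def _check_same_ids(D1: DistanceMatrix, D2: DistanceMatrix) -> None:
    if D1.ids != D2.ids:
        raise ValueError("distance matrices must share the same sample ids "
                         "in the same order")


def _perm_pvalue(null: np.ndarray, observed: float) -> float:
    return (np.sum(null >= observed - 1e-12) + 1) / (null.size + 1)


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int = 0,
) -> TestResult:
    """Mantel test: correlation between the upper triangles of two
    distance matrices, with a null built by simultaneously permuting the
    rows and columns of ``D2``.  One-sided (upper-tail) p.

    ``method='spearman'`` correlates average ranks of the condensed
    entries (rank-transforming the matrix commutes with permuting sample
    labels, so ranks are computed once).
    """
    _check_same_ids(D1, D2)
    n = D1.n
    iu, ju = np.triu_indices(n, k=1)

    def prepare(values: np.ndarray) -> np.ndarray:
        if method == "spearman":
            ranked = np.zeros_like(values)
            r = stats.rankdata(values[iu, ju])
            ranked[iu, ju] = r
            ranked[ju, iu] = r
            return ranked
        if method == "pearson":
            return values
        raise ValueError("method must be 'spearman' or 'pearson'")

    M1 = prepare(D1.values)
    M2 = prepare(D2.values)
    x = M1[iu, ju]
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())

    def corr_with(values: np.ndarray) -> float:
        y = values[iu, ju]
        yc = y - y.mean()
        denom = xs * np.sqrt((yc ** 2).sum())
        if denom == 0:
            return 0.0
        return float((xc * yc).sum() / denom)

    r_obs = corr_with(M2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        null[k] = corr_with(M2[np.ix_(p, p)])
    return TestResult("mantel_r", r_obs, _perm_pvalue(null, r_obs),
                      n_perm, seed, {"method": method})


def _group_codes(groups, ids) -> np.ndarray:
    groups = pd.Series(groups)
    if not groups.index.equals(pd.Index(range(len(groups)))):
        groups = groups.reindex(ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    return pd.Categorical(groups).codes.astype(np.int64)


def anosim(
    D: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (M/2)
    over the ranked condensed dissimilarities (average ranks on ties),
    M = n(n-1)/2.  R = 1 means complete separation, 0 none.  One-sided
    upper-tail p by permuting group labels.
    """
    codes = _group_codes(groups, D.ids)
    sizes = np.bincount(codes)
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = D.n
    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(D.values[iu, ju])
    m = ranks.size
    denom = m / 2.0
    total = ranks.sum()

    def r_stat(c: np.ndarray) -> float:
        within = c[iu] == c[ju]
        n_within = within.sum()
        if n_within == 0 or n_within == m:
            raise ValueError("degenerate grouping")
        mean_within = ranks[within].mean()
        mean_between = (total - ranks[within].sum()) / (m - n_within)
        return (mean_between - mean_within) / denom

    r_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = r_stat(rng.permutation(codes))
    return TestResult("anosim_R", r_obs, _perm_pvalue(null, r_obs), n_perm, seed)


def permanova_from_condensed(
    d2_condensed: np.ndarray, codes: np.ndarray, n: int
) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared condensed distances and group codes."""
    iu, ju = np.triu_indices(n, k=1)
    sizes = np.bincount(codes)
    a = len(sizes)
    ss_total = d2_condensed.sum() / n
    within = codes[iu] == codes[ju]
    ss_within = 0.0
    for g in range(a):
        mask = within & (codes[iu] == g)
        ss_within += d2_condensed[mask].sum() / sizes[g]
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        raise ValueError("degenerate distances: within-group SS is zero")
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = 1.0 - ss_within / ss_total
    return float(f), float(r2)


def permanova(
    D: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = (1/n) sum_{i<j} d_ij^2, SS_within pools (1/n_g)-scaled
    within-group squared distances; pseudo-F = (SS_between/(a-1)) /
    (SS_within/(n-a)).  Upper-tail p by permuting group labels.
    """
    codes = _group_codes(groups, D.ids)
    sizes = np.bincount(codes)
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = D.n
    if np.allclose(D.condensed(), 0.0):
        raise ValueError("degenerate distances: all pairwise distances are zero")
    d2 = D.condensed() ** 2
    f_obs, r2 = permanova_from_condensed(d2, codes, n)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k], _ = permanova_from_condensed(d2, rng.permutation(codes), n)
    return TestResult("permanova_F", f_obs, _perm_pvalue(null, f_obs),
                      n_perm, seed, {"R2": r2})


def _compact_letters(groups: list, significant: set[tuple]) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are NOT significantly different; every
    significant pair ends up with disjoint letter sets.
    """
    letter_sets: list[set] = [set(groups)]
    for a, b in significant:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                # absorb duplicates/subsets
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets = [s for s in letter_sets if s]
    # stable ordering: by smallest group position
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def kruskal_letters(values, groups, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis H (tie-corrected) across groups; if significant,
    pairwise two-sided Wilcoxon rank-sum tests with BH correction feed a
    compact-letter display (groups sharing a letter do not differ).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return {"H": 0.0, "p": 1.0,
                "letters": {g: "a" for g in labels}, "pairwise": {}}
    H, p = stats.kruskal(*samples)
    pairwise: dict[tuple, float] = {}
    significant: set[tuple] = set()
    if p < alpha and len(labels) > 1:
        pairs = list(itertools.combinations(range(len(labels)), 2))
        raw = [stats.ranksums(samples[i], samples[j]).pvalue for i, j in pairs]
        q = bh_adjust(raw)
        for (i, j), qv in zip(pairs, q):
            pairwise[(labels[i], labels[j])] = float(qv)
            if qv < alpha:
                significant.add((labels[i], labels[j]))
    letters = _compact_letters(labels, significant)
    return {"H": float(H), "p": float(p), "letters": letters,
            "pairwise": pairwise}


def whites_test(
    group1,
    group2,
    n_perm: int = 9999,
    seed: int = 0,
) -> TestResult:
    """Two-sided permutation test on the difference of group mean
    proportions (non-parametric two-group comparison for relative
    abundances).

    All C(n1+n2, n1) label reassignments are enumerated when there are at
    most 10,000 of them (exact p = fraction of arrangements at least as
    extreme, including the observed one); otherwise ``n_perm`` random
    reassignments with the add-one correction.  Zero pooled variance
    yields p = 1 by convention.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("both groups need >= 2 samples")
    obs = float(g1.mean() - g2.mean())
    pooled = np.concatenate([g1, g2])
    if np.ptp(pooled) == 0:
        return TestResult("mean_difference", obs, 1.0, 0, seed,
                          {"exhaustive": True})
    n1, n = g1.size, pooled.size
    n_arr = comb(n, n1)
    if n_arr <= 10_000:
        total_sum = pooled.sum()
        count = 0
        for idx in itertools.combinations(range(n), n1):
            s1 = pooled[list(idx)].sum()
            diff = s1 / n1 - (total_sum - s1) / (n - n1)
            if abs(diff) >= abs(obs) - 1e-12:
                count += 1
        p = count / n_arr
        return TestResult("mean_difference", obs, p, n_arr, seed,
                          {"exhaustive": True})
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:n1].mean() - perm[n1:].mean()
        if abs(diff) >= abs(obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return TestResult("mean_difference", obs, p, n_perm, seed,
                      {"exhaustive": False})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
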