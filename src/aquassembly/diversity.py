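"""Alpha and beta diversity: Chao1/Shannon/inverse-Simpson, rarefaction
curves, Bray-Curtis matrices, group OTU overlap, within-group dissimilarity
summaries and average-linkage (UPGMA) dendrograms."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .core import CommunityMatrix

__all__ = [
    "DistanceMatrix",
    "alpha_diversity",
    "rarefaction_curve",
    "bray_curtis_matrix",
    "group_overlap",
    "within_group_beta",
    "upgma_tree",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with a semantic kind.

    kind is one of ``dissimilarity`` (zero diagonal, Bray-Curtis in [0,1]),
    ``similarity`` (unit diagonal) or ``geographic`` (zero diagonal, km).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "dissimilarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if np.isnan(self.values).any():
            raise ValueError("NaN entries in distance matrix")
        if self.kind not in {"dissimilarity", "similarity", "geographic"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        diag = np.diag(self.values)
        target = 1.0 if self.kind == "similarity" else 0.0
        if not np.allclose(diag, target, atol=1e-10):
            raise ValueError(f"diagonal must be {target} for kind={self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]

    def to_similarity(self) -> "DistanceMatrix":
        if self.kind == "similarity":
            return self
        if self.kind != "dissimilarity":
            raise ValueError("cannot convert geographic distances to similarity")
        return DistanceMatrix(self.ids, 1.0 - self.values, "similarity")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "dissimilarity"):
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


def _alpha_one(row: np.ndarray) -> dict[str, float]:
    row = row[row > 0]
    if row.size == 0:
        raise ValueError("empty sample: no reads")
    s_obs = row.size
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    # bias-corrected Chao1
    chao1 = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    p = row / row.sum()
    shannon = float(-(p * np.log(p)).sum())
    inv_simpson = float(1.0 / (p ** 2).sum())
    return {
        "richness": s_obs,
        "singletons": f1,
        "doubletons": f2,
        "chao1": chao1,
        "shannon": shannon,
        "inv_simpson": inv_simpson,
    }


def alpha_diversity(cm: CommunityMatrix) -> pd.DataFrame:
    """Per-sample observed richness, F1/F2, bias-corrected Chao1,
    Shannon H (natural log) and inverse Simpson.

    Chao1 = S_obs + F1(F1-1) / (2(F2+1)); requires integer counts.
    """
    records = {sid: _alpha_one(np.asarray(row, dtype=np.int64))
               for sid, row in cm.data.iterrows()}
    return pd.DataFrame.from_dict(records, orient="index").loc[cm.sample_ids]


def rarefaction_curve(
    cm: CommunityMatrix,
    depths: Sequence[int],
    reps: int = 10,
    seed: int = 0,
    metric: str = "chao1",
) -> pd.DataFrame:
    """Mean Chao1 (or observed richness) over ``reps`` seeded subsamples at
    each depth; depths exceeding a sample's total are truncated to it.

    Returns a samples x depths DataFrame.
    """
    if metric not in {"chao1", "richness"}:
        raise ValueError("metric must be 'chao1' or 'richness'")
    depths = sorted(int(d) for d in depths)
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=cm.sample_ids, columns=depths, dtype=float)
    for sid, row in cm.data.iterrows():
        counts = row.to_numpy(dtype=np.int64)
        total = counts.sum()
        for depth in depths:
            d = min(depth, int(total))
            vals = []
            for _ in range(reps):
                sub = rng.multivariate_hypergeometric(counts, d)
                vals.append(_alpha_one(sub)[metric])
            out.loc[sid, depth] = float(np.mean(vals))
    return out


def bray_curtis_matrix(cm: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y)."""
    totals = cm.data.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total reads: {bad}")
    if cm.data.shape[0] < 2:
        raise ValueError("need at least two samples")
    condensed = pdist(cm.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(cm.sample_ids, squareform(condensed), "dissimilarity")


def group_overlap(cm: CommunityMatrix, groups: pd.Series) -> dict:
    """Presence-based OTU overlap among habitat groups.

    An OTU belongs to a group if any sample of the group has a positive
    count.  Returns per-group totals, the shared-by-all-groups count and
    per-group exclusive counts with percentages of the total OTU pool.
    """
    groups = groups.reindex(cm.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample must have a group label")
    presence = {}
    for g, sub in cm.data.groupby(groups, sort=True):
        presence[g] = set(cm.data.columns[(sub > 0).any(axis=0)])
    total_otus = cm.data.shape[1]
    shared_all = set.intersection(*presence.values()) if presence else set()
    result = {
        "total_otus": total_otus,
        "shared_by_all": len(shared_all),
        "shared_by_all_pct": 100.0 * len(shared_all) / total_otus,
        "per_group": {},
    }
    for g, members in presence.items():
        others = set().union(*(m for h, m in presence.items() if h != g))
        exclusive = members - others
        result["per_group"][g] = {
            "otus": len(members),
            "exclusive": len(exclusive),
            "exclusive_pct": 100.0 * len(exclusive) / total_otus,
        }
    return result


def within_group_beta(
    D: DistanceMatrix, groups: pd.Series, ddof: int = 1
) -> pd.DataFrame:
    """Mean +/- SD of within-group pairwise dissimilarities.

    Only upper-triangle entries between members of the same group enter;
    groups with fewer than two samples are reported as NaN.  ``ddof=1``
    (sample SD) by default.
    """
    groups = groups.reindex(D.ids)
    if groups.isna().any():
        raise ValueError("every sample must have a group label")
    rows = {}
    labels = np.asarray(groups)
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            rows[g] = {"mean": np.nan, "sd": np.nan, "n_pairs": 0}
            continue
        sub = D.values[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(idx.size, k=1)
        vals = sub[iu, ju]
        rows[g] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=ddof)) if vals.size > ddof else np.nan,
            "n_pairs": int(vals.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def upgma_tree(D: DistanceMatrix, method: str = "average") -> str:
    """Agglomerative clustering of samples; returns a newick string with
    branch lengths.  ``method`` may be ``average`` (UPGMA, default),
    ``complete`` or ``ward``."""
    if D.kind == "similarity":
        raise ValueError("clustering expects a dissimilarity matrix")
    Z = linkage(D.condensed(), method=method)
    tree = TreeNode.from_linkage_matrix(Z, D.ids)
    return str(tree).strip()
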