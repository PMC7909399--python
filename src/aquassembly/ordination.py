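"""Constrained ordination and spatial analysis.

Hellinger transform, redundancy analysis (RDA) with a permutation global
test, permutation-gated forward selection with VIF pruning, a local planar
projection of geographic coordinates, PCNM spatial eigenfunctions, three-set
variation partitioning by partial RDA, and distance-decay regression.

RDA here is the classical linear constrained ordination: the (column-
centred) response matrix Y is regressed on the standardized predictor
matrix X by least squares, the canonical axes are the principal axes of the
fitted values, and explained variance is R^2 = SS_fit / SS_total with the
Ezekiel adjustment adjR^2 = 1 - (1 - R^2)(n-1)/(n-m-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .core import CommunityMatrix
from .diversity import DistanceMatrix

__all__ = [
    "OrdinationResult",
    "SelectionTrace",
    "PcnmBasis",
    "PartitionFractions",
    "hellinger_transform",
    "adjusted_r2",
    "rda_fit",
    "forward_select",
    "vif",
    "project_coordinates",
    "pcnm_axes",
    "variation_partition",
    "distance_decay",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------- transforms

def hellinger_transform(cm: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Square root of relative abundances: y'_ij = sqrt(y_ij / rowsum_i).

    Each transformed row has unit sum of squares, which makes Euclidean
    distances between rows equal to Hellinger distances — the standard
    way to make abundance data suitable for linear ordination.
    """
    df = cm.data if isinstance(cm, CommunityMatrix) else pd.DataFrame(cm)
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("zero-total row: Hellinger transform undefined")
    return np.sqrt(df.div(totals, axis=0).astype(float))


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant predictor column cannot be standardized")
    return (X - mu) / sd


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


# ----------------------------------------------------------------------- RDA

@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    predictor_scores: np.ndarray | None
    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: float
    n_perm: int
    rank: int


def _rda_r2(Yc: np.ndarray, Xs: np.ndarray) -> tuple[float, np.ndarray]:
    """R^2 of the least-squares fit of centred Y on X; returns fitted Y."""
    coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    fitted = Xs @ coef
    ss_total = (Yc ** 2).sum()
    if ss_total == 0:
        raise ValueError("response matrix has zero variance")
    return float((fitted ** 2).sum() / ss_total), fitted


def rda_fit(
    Y: np.ndarray | pd.DataFrame,
    X: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> OrdinationResult:
    """Redundancy analysis of response matrix Y on predictors X.

    Y is column-centred and X standardized internally (unit-variance
    predictors, matching the convention of normalising environmental
    variables before ordination).  The global permutation test permutes
    the rows of Y; pseudo-F = (SS_fit/m) / (SS_res/(n-m-1)).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if n != Y.shape[0]:
        raise ValueError("Y and X must have the same number of rows")
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m})")
    Yc = Y - Y.mean(axis=0)
    Xs = _standardize(X) if standardize else X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xs)

    r2, fitted = _rda_r2(Yc, Xs)
    ss_total = (Yc ** 2).sum()
    ss_fit = r2 * ss_total
    ss_res = ss_total - ss_fit
    dof_res = n - rank - 1
    f_obs = (ss_fit / rank) / (ss_res / dof_res) if ss_res > 1e-300 else np.inf

    # canonical axes: principal axes of the fitted values
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > 1e-10 * (s[0] if s.size else 1.0)
    eigenvalues = (s[keep] ** 2) / (n - 1)
    site_scores = U[:, keep] * s[keep]
    if site_scores.size:
        with np.errstate(invalid="ignore"):
            pred_scores = np.corrcoef(Xs, site_scores, rowvar=False)[
                :m, m:
            ]
    else:
        pred_scores = None

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2_p, _ = _rda_r2(Yc[perm], Xs)
        ss_fit_p = r2_p * ss_total
        f_p = (ss_fit_p / rank) / ((ss_total - ss_fit_p) / dof_res)
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return OrdinationResult(eigenvalues, site_scores, pred_scores,
                            r2, adjusted_r2(r2, n, rank), f_obs, p,
                            n_perm, rank)


def vif(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) where R^2_j is
    from regressing predictor j on the remaining predictors.  Exactly
    collinear predictors report +inf."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("VIF needs at least two predictors")
    Xc = X - X.mean(axis=0)
    out = np.empty(m)
    for j in range(m):
        y = Xc[:, j]
        ss_y = (y ** 2).sum()
        if ss_y == 0:
            raise ValueError("constant predictor has undefined VIF")
        others = np.delete(Xc, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2_j = 1.0 - (resid ** 2).sum() / ss_y
        out[j] = np.inf if r2_j > 1 - 1e-12 else 1.0 / (1.0 - r2_j)
    if names is not None:
        return pd.Series(out, index=names)
    return out


# ---------------------------------------------------------- forward selection

@dataclass
class SelectionTrace:
    """Record of a permutation-gated forward selection."""

    selected: list[str] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)
    dropped_for_vif: list[str] = field(default_factory=list)
    vif_final: dict = field(default_factory=dict)


def _partial_f_test(
    Yc: np.ndarray,
    X_sel: np.ndarray | None,
    x_new: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation test for the added contribution of ``x_new`` given the
    already-selected predictors.

    With no prior predictors the rows of Y are permuted; otherwise the
    residuals of Y under the reduced model are permuted (permutation of
    residuals under the reduced model — the standard scheme for partial
    ordination tests).  Returns (added R^2, p).
    """
    n = Yc.shape[0]
    if X_sel is None or X_sel.shape[1] == 0:
        base_fit = np.zeros_like(Yc)
        m_red = 0
        resid_red = Yc
    else:
        coef, *_ = np.linalg.lstsq(X_sel, Yc, rcond=None)
        base_fit = X_sel @ coef
        m_red = X_sel.shape[1]
        resid_red = Yc - base_fit
    X_full = x_new[:, None] if X_sel is None or X_sel.shape[1] == 0 \
        else np.hstack([X_sel, x_new[:, None]])
    ss_total = (Yc ** 2).sum()

    def added_stats(Ymat: np.ndarray) -> tuple[float, float]:
        coef_f, *_ = np.linalg.lstsq(X_full, Ymat, rcond=None)
        fit_f = X_full @ coef_f
        ss_fit_f = (fit_f ** 2).sum()
        if m_red:
            coef_r, *_ = np.linalg.lstsq(X_sel, Ymat, rcond=None)
            ss_fit_r = ((X_sel @ coef_r) ** 2).sum()
        else:
            ss_fit_r = 0.0
        ss_tot = (Ymat ** 2).sum()
        ss_res = ss_tot - ss_fit_f
        dof = n - (m_red + 1) - 1
        f = (ss_fit_f - ss_fit_r) / (ss_res / dof) if ss_res > 1e-300 else np.inf
        return (ss_fit_f - ss_fit_r) / ss_total, f

    added_r2, f_obs = added_stats(Yc)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Y_perm = base_fit + resid_red[perm]
        Y_perm = Y_perm - Y_perm.mean(axis=0)
        _, f_p = added_stats(Y_perm)
        if f_p >= f_obs - 1e-12:
            exceed += 1
    return added_r2, (exceed + 1) / (n_perm + 1)


def forward_select(
    Y: np.ndarray | pd.DataFrame,
    X_all: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    double_stop: bool = False,
    vif_threshold: float = 10.0,
    seed: int = 0,
) -> SelectionTrace:
    """Greedy forward selection of predictors for RDA.

    At every step the candidate adding the most R^2 is tested with a
    Monte-Carlo permutation test; it enters while its partial p < alpha
    (and, with ``double_stop``, while the cumulative adjusted R^2 stays at
    or below the full-model adjusted R^2).  Afterwards the predictor with
    the worst VIF is dropped repeatedly until all VIF <= ``vif_threshold``.
    An empty selection is a valid outcome.
    """
    if X_all.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    Xs = pd.DataFrame(_standardize(X_all.to_numpy(dtype=float)),
                      columns=X_all.columns, index=X_all.index)
    n = Yc.shape[0]
    rng = np.random.default_rng(seed)

    adj_r2_global = np.nan
    if double_stop:
        r2_g, _ = _rda_r2(Yc, Xs.to_numpy())
        adj_r2_global = adjusted_r2(r2_g, n, Xs.shape[1])

    trace = SelectionTrace()
    remaining = list(Xs.columns)
    cum_r2 = 0.0
    while remaining and len(trace.selected) < n - 2:
        X_sel = Xs[trace.selected].to_numpy() if trace.selected else None
        best_var, best_gain = None, -np.inf
        for var in remaining:
            X_try = Xs[trace.selected + [var]].to_numpy()
            r2_try, _ = _rda_r2(Yc, X_try)
            gain = r2_try - cum_r2
            if gain > best_gain:
                best_var, best_gain = var, gain
        added_r2, p = _partial_f_test(Yc, X_sel, Xs[best_var].to_numpy(),
                                      n_perm, rng)
        if p >= alpha:
            break
        cand_adj = adjusted_r2(cum_r2 + best_gain, n, len(trace.selected) + 1)
        if double_stop and cand_adj > adj_r2_global:
            break
        trace.selected.append(best_var)
        remaining.remove(best_var)
        cum_r2 += best_gain
        trace.steps.append({"variable": best_var, "added_r2": best_gain,
                            "cumulative_r2": cum_r2, "p": p})

    # iterative worst-first VIF pruning of the selected set
    while len(trace.selected) >= 2:
        v = vif(Xs[trace.selected])
        worst = v.idxmax()
        if v[worst] <= vif_threshold:
            break
        trace.selected.remove(worst)
        trace.dropped_for_vif.append(worst)
    if len(trace.selected) >= 2:
        trace.vif_final = vif(Xs[trace.selected]).to_dict()
    elif len(trace.selected) == 1:
        trace.vif_final = {trace.selected[0]: 1.0}
    return trace


# ------------------------------------------------------------------- spatial

def project_coordinates(md: pd.DataFrame) -> pd.DataFrame:
    """Azimuthal-equidistant projection of lat/lon to planar km about the
    sample centroid (spherical Earth, R = 6371 km).

    Great-circle distances from the centroid are preserved exactly and
    pairwise Euclidean distances track great-circle distances to well
    under 1% over regional (few-hundred-km) extents.
    """
    lat = np.radians(md["latitude"].to_numpy(dtype=float))
    lon = np.radians(md["longitude"].to_numpy(dtype=float))
    lat0, lon0 = lat.mean(), lon.mean()
    dlon = lon - lon0
    # great-circle distance c (haversine form: stable near zero) and
    # forward azimuth from the centroid
    a = (np.sin((lat - lat0) / 2) ** 2
         + np.cos(lat0) * np.cos(lat) * np.sin(dlon / 2) ** 2)
    c = 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    az_y = np.sin(dlon) * np.cos(lat)
    az_x = np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon)
    az = np.arctan2(az_y, az_x)
    r = EARTH_RADIUS_KM * c
    return pd.DataFrame({"x_km": r * np.sin(az), "y_km": r * np.cos(az)},
                        index=md.index)


def geographic_distance_matrix(md: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances (km) between projected coordinates."""
    xy = project_coordinates(md).to_numpy()
    return DistanceMatrix(list(md.index.astype(str)),
                          squareform(pdist(xy)), "geographic")


@dataclass
class PcnmBasis:
    """PCNM spatial eigenfunctions: centred, mutually orthogonal columns
    (samples x axes), one per positive eigenvalue, scaled by sqrt(eigenvalue)."""

    vectors: pd.DataFrame
    eigenvalues: np.ndarray
    threshold: float


def pcnm_axes(
    geo: DistanceMatrix,
    threshold: float | None = None,
    positive_moran_only: bool = False,
) -> PcnmBasis:
    """Principal coordinates of neighbour matrices.

    The truncation threshold t defaults to the longest edge of the minimum
    spanning tree of the distance matrix; distances above t are replaced
    by 4t.  The truncated matrix is Gower-centred (-d^2/2, double-centred)
    and eigen-decomposed; axes with positive eigenvalues are retained and
    scaled by the square root of their eigenvalue.  With
    ``positive_moran_only`` only axes whose Moran's I (computed with the
    within-threshold adjacency as weights) exceeds the expectation
    -1/(n-1) are kept.
    """
    n = geo.n
    if n < 3:
        raise ValueError("PCNM needs at least 3 samples")
    D = geo.values.copy()
    if threshold is None:
        mst = minimum_spanning_tree(D).toarray()
        threshold = float(mst.max())
    Dt = np.where(D > threshold, 4.0 * threshold, D)
    np.fill_diagonal(Dt, 0.0)

    A = -0.5 * Dt ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-8 * abs(eigval[0]), 1e-12)
    keep = eigval > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    vectors = eigvec * np.sqrt(eigval)

    if positive_moran_only and vectors.shape[1]:
        W = ((D <= threshold) & (D > 0)).astype(float)
        w_sum = W.sum()
        keep_m = []
        for j in range(vectors.shape[1]):
            z = vectors[:, j] - vectors[:, j].mean()
            moran = (n / w_sum) * (z @ W @ z) / (z @ z)
            keep_m.append(moran > -1.0 / (n - 1))
        vectors = vectors[:, keep_m]
        eigval = eigval[keep_m]

    cols = [f"PCNM{j + 1}" for j in range(vectors.shape[1])]
    return PcnmBasis(pd.DataFrame(vectors, index=geo.ids, columns=cols),
                     eigval, threshold)


# -------------------------------------------------------- variation partition

@dataclass
class PartitionFractions:
    """Adjusted-R^2 decomposition of community variation among up to three
    explanatory sets: E (environment), S (spatial PCNM), T (linear trend).

    ``fractions`` holds the 7 unique regions keyed by frozenset subsets of
    {"E","S","T"} (pure fractions under singleton keys); shared fractions
    may be negative because adjusted R^2 is not additive."""

    fractions: dict
    subset_adj_r2: dict
    total_explained: float
    residual: float
    pure_p_values: dict


def _subset_matrix(blocks: dict, key: tuple) -> np.ndarray:
    return np.hstack([blocks[k] for k in key])


def variation_partition(
    Y: np.ndarray | pd.DataFrame,
    E: pd.DataFrame | np.ndarray | None,
    S: PcnmBasis | pd.DataFrame | np.ndarray | None = None,
    T: pd.DataFrame | np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PartitionFractions:
    """Three-set variation partitioning via (partial) RDA.

    Adjusted R^2 is computed for the RDA on each nonempty subset of the
    provided explanatory sets; the 7 pure/shared region fractions follow
    by inclusion-exclusion (solved exactly as a linear system).  Pure
    fractions are tested by permutation of residuals of the reduced model
    (the pRDA conditioning set).
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    n = Yc.shape[0]

    blocks: dict[str, np.ndarray] = {}
    for name, mat in (("E", E), ("S", S), ("T", T)):
        if mat is None:
            continue
        if isinstance(mat, PcnmBasis):
            mat = mat.vectors
        arr = np.asarray(mat, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            raise ValueError(f"set {name} is not row-aligned with Y")
        blocks[name] = _standardize(arr)
    if not blocks:
        raise ValueError("at least one explanatory set is required")
    m_total = sum(b.shape[1] for b in blocks.values())
    if m_total >= n - 1:
        raise ValueError(
            f"overfitted partition: {m_total} predictors for {n} samples")

    names = sorted(blocks)  # e.g. ["E", "S", "T"]
    subsets = [tuple(c) for r in range(1, len(names) + 1)
               for c in combinations(names, r)]
    adj: dict[tuple, float] = {}
    for sub in subsets:
        X = _subset_matrix(blocks, sub)
        r2, _ = _rda_r2(Yc, X)
        adj[sub] = adjusted_r2(r2, n, np.linalg.matrix_rank(X))

    # regions = nonempty subsets of names; adj[A] = sum of regions meeting A
    regions = subsets
    M = np.zeros((len(subsets), len(regions)))
    for i, sub in enumerate(subsets):
        for j, reg in enumerate(regions):
            if set(sub) & set(reg):
                M[i, j] = 1.0
    frac_vals = np.linalg.solve(M, np.array([adj[s] for s in subsets]))
    fractions = {frozenset(reg): float(v) for reg, v in zip(regions, frac_vals)}

    full = tuple(names)
    total_explained = adj[full]
    residual = 1.0 - total_explained

    pure_p: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    if len(names) > 1:
        for name in names:
            others = tuple(x for x in names if x != name)
            Z = _subset_matrix(blocks, others)
            p = _prda_permutation_test(Yc, blocks[name], Z, n_perm, rng)
            pure_p[name] = p
    return PartitionFractions(fractions, {"".join(k): v for k, v in adj.items()},
                              total_explained, residual, pure_p)


def _prda_permutation_test(
    Yc: np.ndarray, X: np.ndarray, Z: np.ndarray,
    n_perm: int, rng: np.random.Generator,
) -> float:
    """Partial RDA test of X given conditioning set Z by permutation of
    residuals under the reduced model."""
    n = Yc.shape[0]
    coef_z, *_ = np.linalg.lstsq(Z, Yc, rcond=None)
    fit_z = Z @ coef_z
    resid_z = Yc - fit_z
    XZ = np.hstack([Z, X])
    m_full = np.linalg.matrix_rank(XZ)
    m_red = np.linalg.matrix_rank(Z)

    def partial_f(Ymat: np.ndarray) -> float:
        cf, *_ = np.linalg.lstsq(XZ, Ymat, rcond=None)
        ss_full = ((XZ @ cf) ** 2).sum()
        cr, *_ = np.linalg.lstsq(Z, Ymat, rcond=None)
        ss_red = ((Z @ cr) ** 2).sum()
        ss_res = (Ymat ** 2).sum() - ss_full
        dof = n - m_full - 1
        if ss_res <= 1e-300:
            return np.inf
        return ((ss_full - ss_red) / (m_full - m_red)) / (ss_res / dof)

    f_obs = partial_f(Yc)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Y_perm = fit_z + resid_z[perm]
        Y_perm = Y_perm - Y_perm.mean(axis=0)
        if partial_f(Y_perm) >= f_obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


# --------------------------------------------------------------- distance decay

def distance_decay(
    comm_similarity: DistanceMatrix,
    geo: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Ordinary least squares of community similarity on geographic
    distance over sample pairs; two-sided significance by Mantel-style
    row/column permutation of the similarity matrix."""
    if comm_similarity.ids != geo.ids:
        raise ValueError("matrices must share sample ids and order")
    if comm_similarity.kind != "similarity":
        raise ValueError("first argument must be a similarity matrix")
    n = geo.n
    iu, ju = np.triu_indices(n, k=1)
    x = geo.values[iu, ju]
    if np.ptp(x) == 0:
        raise ValueError("constant geographic distances: slope undefined")
    S = comm_similarity.values
    y = S[iu, ju]

    xc = x - x.mean()
    ss_x = (xc ** 2).sum()

    def fit(yvec: np.ndarray) -> tuple[float, float, float]:
        slope = (xc * (yvec - yvec.mean())).sum() / ss_x
        intercept = yvec.mean() - slope * x.mean()
        resid = yvec - (intercept + slope * x)
        ss_y = ((yvec - yvec.mean()) ** 2).sum()
        r2 = 0.0 if ss_y == 0 else 1.0 - (resid ** 2).sum() / ss_y
        return slope, intercept, r2

    slope_obs, intercept, r2 = fit(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        y_p = S[np.ix_(p, p)][iu, ju]
        s_p, _, _ = fit(y_p)
        if abs(s_p) >= abs(slope_obs) - 1e-15:
            exceed += 1
    return {
        "slope": float(slope_obs),
        "intercept": float(intercept),
        "r2": float(r2),
        "p_value": (exceed + 1) / (n_perm + 1),
        "n_pairs": int(x.size),
        "n_perm": n_perm,
    }
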