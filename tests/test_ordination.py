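"""Hellinger transform, RDA, forward selection, VIF, PCNM, variation
partitioning and distance decay."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa

from aquassembly import (adjusted_r2, distance_decay, forward_select,
                         hellinger_transform, pcnm_axes, project_coordinates,
                         rda_fit, variation_partition, vif)
from aquassembly.core import CommunityMatrix
from aquassembly.diversity import DistanceMatrix
from aquassembly.ordination import geographic_distance_matrix


def dm_from_points(X):
    X = np.asarray(X, dtype=float)
    ids = [f"s{i}" for i in range(X.shape[0])]
    return DistanceMatrix(ids, squareform(pdist(X)), "geographic")


class TestHellinger:
    def test_closed_form_row(self):
        df = pd.DataFrame([[1, 1, 2]], index=["s"], columns=list("abc"))
        out = hellinger_transform(CommunityMatrix(df))
        assert np.allclose(out.to_numpy(),
                           [[0.5, 0.5, np.sqrt(0.5)]], atol=1e-10)

    def test_unit_row_norm(self, small_dataset):
        cm, _, _ = small_dataset
        out = hellinger_transform(cm)
        assert np.allclose((out ** 2).sum(axis=1), 1.0, atol=1e-12)

    def test_compositional_invariance(self):
        df = pd.DataFrame([[1, 2, 3], [10, 20, 30]], columns=list("abc"))
        out = hellinger_transform(df)
        assert np.allclose(out.iloc[0], out.iloc[1], atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            hellinger_transform(pd.DataFrame([[0, 0]]))


class TestRda:
    def test_perfect_predictor_r2_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        res = rda_fit(x[:, None], x[:, None], n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_fitted_values_equal_columnwise_ols(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(25, 6))
        X = rng.normal(size=(25, 3))
        Yc = Y - Y.mean(axis=0)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        # oracle: independent per-column least squares
        ss_fit = 0.0
        for j in range(Y.shape[1]):
            coef, *_ = np.linalg.lstsq(Xs, Yc[:, j], rcond=None)
            ss_fit += ((Xs @ coef) ** 2).sum()
        res = rda_fit(Y, X, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(ss_fit / (Yc ** 2).sum(), abs=1e-10)

    def test_r2_invariant_to_linear_recombination(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 4))
        X = rng.normal(size=(20, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        r1 = rda_fit(Y, X, n_perm=99, seed=0).r2
        r2 = rda_fit(Y, X @ A, n_perm=99, seed=0).r2
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_eigenvalues_nonincreasing(self):
        rng = np.random.default_rng(3)
        res = rda_fit(rng.normal(size=(30, 8)), rng.normal(size=(30, 4)),
                      n_perm=99, seed=0)
        ev = res.eigenvalues
        assert (np.diff(ev) <= 1e-12).all() and (ev >= 0).all()

    def test_ezekiel_adjustment_closed_form(self):
        assert adjusted_r2(0.5, 40, 7) == pytest.approx(1 - 0.5 * 39 / 32,
                                                        abs=1e-12)


class TestVif:
    def test_orthogonal_predictors(self):
        X = np.eye(4)[:, :2] - 0.25
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        assert np.allclose(vif(X), [1.0, 1.0], atol=1e-10)

    def test_known_correlation(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=50_000)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.normal(size=50_000)
        v = vif(np.column_stack([x1, x2]))
        assert np.allclose(v, 1 / (1 - 0.81), rtol=0.02)

    def test_exact_duplicate_is_infinite(self):
        x = np.random.default_rng(1).normal(size=30)
        v = vif(np.column_stack([x, x]))
        assert np.isinf(v).all()


class TestForwardSelect:
    def test_recovers_true_predictor(self):
        exact, false_inclusions = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x1 = rng.normal(size=30)
            noise = rng.normal(size=30)
            Y = np.column_stack([2 * x1 + 0.3 * rng.normal(size=30),
                                 -x1 + 0.3 * rng.normal(size=30)])
            X = pd.DataFrame({"x1": x1, "noise": noise})
            trace = forward_select(Y, X, alpha=0.05, n_perm=199, seed=seed)
            assert trace.selected[0] == "x1"  # true driver enters first
            if trace.selected == ["x1"]:
                exact += 1
            if "noise" in trace.selected:
                false_inclusions += 1
        # the second step falsely admits noise at ~ the nominal 5% rate
        assert exact >= 17
        assert false_inclusions <= 3

    def test_duplicate_predictor_pruned_by_vif(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        Y = (3 * x + 0.1 * rng.normal(size=25))[:, None]
        X = pd.DataFrame({"a": x, "b": x + 1e-9 * rng.normal(size=25)})
        trace = forward_select(Y, X, alpha=1.0, n_perm=99, seed=0)
        assert len(trace.selected) == 1
        assert len(trace.dropped_for_vif) == 1

    def test_alpha_one_admits_all_in_gain_order(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        Y = rng.normal(size=(30, 2))
        trace = forward_select(Y, X, alpha=1.0000001, n_perm=99, seed=0)
        assert sorted(trace.selected) == ["a", "b", "c"]
        gains = [s["added_r2"] for s in trace.steps]
        assert all(g > 0 for g in gains)

    def test_pure_noise_usually_selects_nothing(self):
        empties = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            Y = rng.normal(size=(25, 4))
            X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
            trace = forward_select(Y, X, alpha=0.05, n_perm=199, seed=seed)
            if not trace.selected:
                empties += 1
        assert empties >= 7  # ~ binomial(10, 0.95) minus selection bias


class TestCoordinates:
    def test_single_point_maps_to_origin(self):
        md = pd.DataFrame({"latitude": [43.0] * 3, "longitude": [116.0] * 3})
        xy = project_coordinates(md)
        assert np.allclose(xy.to_numpy(), 0.0)

    def test_one_degree_latitude(self):
        md = pd.DataFrame({"latitude": [43.0, 44.0],
                           "longitude": [116.0, 116.0]})
        xy = project_coordinates(md).to_numpy()
        d = np.linalg.norm(xy[0] - xy[1])
        assert d == pytest.approx(6371.0 * np.pi / 180, abs=0.01)

    def test_projection_close_to_haversine(self):
        rng = np.random.default_rng(2)
        lat = 43.0 + rng.uniform(-2, 2, 12)
        lon = 115.0 + rng.uniform(-3, 3, 12)
        md = pd.DataFrame({"latitude": lat, "longitude": lon})
        proj = squareform(pdist(project_coordinates(md).to_numpy()))

        def haversine(i, j):
            p1, p2 = np.radians([lat[i], lon[i]]), np.radians([lat[j], lon[j]])
            dlat, dlon = p2[0] - p1[0], p2[1] - p1[1]
            a = np.sin(dlat / 2) ** 2 + np.cos(p1[0]) * np.cos(p2[0]) * \
                np.sin(dlon / 2) ** 2
            return 2 * 6371.0 * np.arcsin(np.sqrt(a))

        for i in range(12):
            for j in range(i + 1, 12):
                assert proj[i, j] == pytest.approx(haversine(i, j), rel=0.01)


class TestPcnm:
    def test_equals_pcoa_without_truncation(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(10, 2))
        D = dm_from_points(X)
        # threshold above max distance -> no replacement happens
        basis = pcnm_axes(D, threshold=float(D.values.max() + 1))
        ref = pcoa(D.values, number_of_dimensions=basis.vectors.shape[1])
        ours = np.abs(basis.vectors.to_numpy())
        theirs = np.abs(ref.samples.to_numpy()[:, :ours.shape[1]])
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_transect_first_axis_half_wave(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        basis = pcnm_axes(dm_from_points(pts))
        v = basis.vectors.to_numpy()[:, 0]
        sign_changes = int((np.diff(np.sign(v[np.abs(v) > 1e-9])) != 0).sum())
        assert sign_changes == 1

    def test_columns_centered_and_orthogonal(self):
        rng = np.random.default_rng(1)
        D = dm_from_points(rng.uniform(0, 100, size=(15, 2)))
        V = pcnm_axes(D).vectors.to_numpy()
        assert np.allclose(V.mean(axis=0), 0.0, atol=1e-8)
        G = V.T @ V
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pcnm_axes(dm_from_points([[0, 0], [1, 1]]))


class TestVariationPartition:
    def test_single_set_collapse(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 3))
        Y = X @ rng.normal(size=(3, 5)) + 0.5 * rng.normal(size=(25, 5))
        part = variation_partition(Y, pd.DataFrame(X), None, None, n_perm=99)
        pure_e = part.fractions[frozenset({"E"})]
        assert pure_e == pytest.approx(part.total_explained, abs=1e-12)
        assert part.residual == pytest.approx(1 - pure_e, abs=1e-12)

    def test_inclusion_exclusion_identity(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(30, 6))
        E = pd.DataFrame(rng.normal(size=(30, 3)))
        S = pd.DataFrame(rng.normal(size=(30, 4)))
        T = pd.DataFrame(rng.normal(size=(30, 2)))
        part = variation_partition(Y, E, S, T, n_perm=99)
        assert sum(part.fractions.values()) == pytest.approx(
            part.total_explained, abs=1e-10)

    def test_orthogonal_sets_no_shared_fraction(self):
        shared, pure_s = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            E = rng.normal(size=(n, 2))
            S = rng.normal(size=(n, 2))
            # make S exactly orthogonal to E (and both centred)
            E = E - E.mean(0)
            S = S - S.mean(0)
            S = S - E @ np.linalg.lstsq(E, S, rcond=None)[0]
            # noise-dominated response: the Ezekiel adjustment is only
            # unbiased near the null, so a strong signal would leak a
            # systematic negative shared fraction
            Y = E @ rng.normal(size=(2, 5)) + 3.0 * rng.normal(size=(n, 5))
            part = variation_partition(Y, pd.DataFrame(E), pd.DataFrame(S),
                                       None, n_perm=99, seed=seed)
            shared.append(part.fractions[frozenset({"E", "S"})])
            pure_s.append(part.fractions[frozenset({"S"})])
        assert abs(np.mean(shared)) < 0.02
        assert abs(np.mean(pure_s)) < 0.02

    def test_overfit_rejected(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(10, 3))
        E = pd.DataFrame(rng.normal(size=(10, 9)))
        with pytest.raises(ValueError, match="overfitted"):
            variation_partition(Y, E, None, None)


class TestDistanceDecay:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(12, 2))
        geo = dm_from_points(pts)
        sim_vals = 0.9 - 0.004 * geo.values
        np.fill_diagonal(sim_vals, 1.0)
        sim = DistanceMatrix(geo.ids, sim_vals, "similarity")
        res = distance_decay(sim, geo, n_perm=99, seed=0)
        assert res["slope"] == pytest.approx(-0.004, abs=1e-10)
        assert res["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, size=(10, 2))
        geo = dm_from_points(pts)
        sim_vals = np.clip(1 - geo.values / 100 +
                           0.05 * rng.normal(size=geo.values.shape), 0, None)
        sim_vals = (sim_vals + sim_vals.T) / 2
        np.fill_diagonal(sim_vals, 1.0)
        sim = DistanceMatrix(geo.ids, sim_vals, "similarity")
        res1 = distance_decay(sim, geo, n_perm=99, seed=0)
        order = rng.permutation(10)
        sim2 = DistanceMatrix([geo.ids[i] for i in order],
                              sim_vals[np.ix_(order, order)], "similarity")
        geo2 = DistanceMatrix([geo.ids[i] for i in order],
                              geo.values[np.ix_(order, order)], "geographic")
        res2 = distance_decay(sim2, geo2, n_perm=99, seed=0)
        assert res1["slope"] == pytest.approx(res2["slope"], abs=1e-12)

    def test_constant_distance_rejected(self):
        vals = np.ones((4, 4)) - np.eye(4)
        geo = DistanceMatrix(list("abcd"), vals, "geographic")
        sim = DistanceMatrix(list("abcd"), np.eye(4), "similarity")
        with pytest.raises(ValueError, match="constant"):
            distance_decay(sim, geo)
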