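import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from smoltfate import classify
from smoltfate.classify import (
    LabelHeuristic,
    choose_k,
    classifier_agreement,
    cluster_and_label,
    fit_random_forest,
    label_clusters,
    mds_projection,
    predict_fates,
    sensitivity_analysis,
    standardize_matrix,
    ward_cluster,
)


def _frame(X, prefix="v"):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(
        X, columns=[f"{prefix}{j}" for j in range(X.shape[1])],
        index=[f"t{i}" for i in range(X.shape[0])],
    )


# ---------------------------------------------------------------------------
# standardization


class TestStandardize:
    def test_unit_columns(self):
        m = standardize_matrix(_frame([[1.0], [2.0], [3.0]]))
        assert m.mean().iloc[0] == pytest.approx(0.0)
        assert m.std(ddof=1).iloc[0] == pytest.approx(1.0)

    def test_constant_column_zeroed(self):
        m = standardize_matrix(_frame([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert (m.iloc[:, 0] == 0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = _frame(rng.normal(size=(12, 4)))
        once = standardize_matrix(m)
        twice = standardize_matrix(once)
        pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# Ward clustering vs. brute-force minimum-variance agglomeration


def brute_force_ward(X):
    """Greedy minimum-variance-increase agglomeration; heights on the
    Euclidean scale (sqrt of twice the ESS increase)."""
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(len(X))]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = X[clusters[i]], X[clusters[j]]
                na, nb = len(a), len(b)
                d = na * nb / (na + nb) * np.sum((a.mean(0) - b.mean(0)) ** 2)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(np.sqrt(2 * d))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        partitions.append([frozenset(c) for c in clusters])
    return np.array(heights), partitions


def _partition_sets(Z, X, k):
    labels = fcluster(Z, t=k, criterion="maxclust")
    return {frozenset(np.flatnonzero(labels == c)) for c in np.unique(labels)}


class TestWard:
    def test_two_points_merge_at_euclidean_distance(self):
        Z = ward_cluster(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert Z[0, 2] == pytest.approx(5.0)

    def test_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.01, (20, 2)), rng.normal(10, 0.01, (20, 2))]
        )
        Z = ward_cluster(X)
        labels = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    @pytest.mark.parametrize("n,p,seed", [(4, 2, 0), (5, 3, 1), (6, 2, 2), (7, 4, 3)])
    def test_matches_brute_force_oracle(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        Z = ward_cluster(X)
        bf_heights, bf_partitions = brute_force_ward(X)
        assert np.allclose(np.sort(Z[:, 2]), np.sort(bf_heights), rtol=1e-10)
        for step, parts in enumerate(bf_partitions):
            k = n - step - 1
            if k >= 1:
                assert _partition_sets(Z, X, k) == set(parts)

    def test_merge_heights_monotone_and_partitions_nested(self, default_run):
        Z = default_run["cls"]["cluster"].merge_tree
        assert (np.diff(Z[:, 2]) >= -1e-9).all()
        X = standardize_matrix(default_run["matrix"]).to_numpy()
        for k in range(2, 6):
            coarse = fcluster(Z, t=k, criterion="maxclust")
            fine = fcluster(Z, t=k + 1, criterion="maxclust")
            # every fine cluster maps into exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1


# ---------------------------------------------------------------------------
# cluster-count selection


def brute_force_silhouette(X, labels):
    X = np.asarray(X, dtype=float)
    D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    vals = []
    for i in range(len(X)):
        own = labels == labels[i]
        if own.sum() == 1:
            vals.append(0.0)
            continue
        a = D[i, own & (np.arange(len(X)) != i)].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestChooseK:
    def _blobs(self, centers, n=15, sd=0.05, seed=0):
        rng = np.random.default_rng(seed)
        return np.vstack([rng.normal(c, sd, (n, 2)) for c in centers])

    def test_three_blobs(self):
        X = self._blobs([(0, 0), (5, 5), (10, 0)])
        k, _, wss = choose_k(ward_cluster(X), X)
        assert k == 3
        assert wss[3] < wss[2]

    def test_two_blobs(self):
        X = self._blobs([(0, 0), (8, 8)])
        k, _, _ = choose_k(ward_cluster(X), X)
        assert k == 2

    def test_silhouette_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(6, 1, (5, 2))])
        Z = ward_cluster(X)
        k, sil, _ = choose_k(Z, X, k_max=5)
        brute = {
            kk: brute_force_silhouette(X, fcluster(Z, t=kk, criterion="maxclust"))
            for kk in range(2, 6)
        }
        for kk in brute:
            assert sil[kk] == pytest.approx(brute[kk], abs=1e-10)
        assert k == max(brute, key=lambda kk: (brute[kk], -kk))


# ---------------------------------------------------------------------------
# cluster labelling


class TestLabelClusters:
    def test_anchored_cluster_is_predator(self):
        assignments = pd.Series({"a": 1, "b": 1, "c": 2})
        fates = label_clusters(
            assignments,
            {"a": "predator"},
            metrics=pd.DataFrame(
                {
                    "n_reversals": [0, 0, 0],
                    "mean_up_speed_ms": [0.0, 0.0, 0.0],
                    "residency_lake_h": [10.0, 10.0, 10.0],
                    "residency_estuary_h": [1.0, 1.0, 1.0],
                },
                index=["a", "b", "c"],
            ),
        )
        assert fates[1] == "predator" and fates[2] == "smolt"

    def test_quiet_anchor_free_cluster_is_smolt(self):
        m = pd.DataFrame(
            {
                "n_reversals": [0, 1],
                "mean_up_speed_ms": [0.0, 0.1],
                "residency_lake_h": [40.0, 50.0],
                "residency_estuary_h": [2.0, 2.0],
            },
            index=["a", "b"],
        )
        fates = label_clusters(pd.Series({"a": 1, "b": 1}), None, metrics=m)
        assert fates[1] == "smolt"

    def test_prolonged_residency_cluster_is_predator(self):
        # one long-resident group against an ordinary cohort
        m = pd.DataFrame(
            {
                "n_reversals": [0] * 6,
                "mean_up_speed_ms": [0.0] * 6,
                "residency_lake_h": [40, 45, 50, 42, 254, 254],
                "residency_estuary_h": [2, 2, 3, 2, 23, 23],
            },
            index=list("abcdef"),
        )
        fates = label_clusters(
            pd.Series({"a": 1, "b": 1, "c": 1, "d": 1, "e": 2, "f": 2}), None, metrics=m
        )
        assert fates[2] == "predator" and fates[1] == "smolt"

    def test_no_anchors_no_heuristic_raises(self):
        with pytest.raises(ValueError):
            label_clusters(pd.Series({"a": 1}), None, metrics=None, heuristic=None)

    def test_invariant_to_row_order(self, default_run):
        m = default_run["matrix"]
        anchors = default_run["anchors"]
        base = cluster_and_label(m, anchors, k=2).fates
        shuffled = cluster_and_label(m.sample(frac=1.0, random_state=0), anchors, k=2).fates
        assert (base.sort_index() == shuffled.sort_index()).all()


# ---------------------------------------------------------------------------
# sensitivity trials


class TestSensitivity:
    def test_removing_uninformative_variable_changes_nothing(self, default_run):
        m = default_run["matrix"].copy()
        m["padding"] = 0.0
        out = sensitivity_analysis(
            m, {"drop_pad": ["padding"]}, default_run["anchors"], k=2
        )
        assert out["drop_pad"] == 0

    def test_speed_variables_carry_most_signal(self, default_run):
        m = default_run["matrix"]
        out = sensitivity_analysis(
            m,
            {
                "no_up": ["mean_up_speed_ms", "max_up_speed_ms"],
                "no_speeds": [
                    "mean_up_speed_ms",
                    "max_up_speed_ms",
                    "mean_down_speed_ms",
                    "max_down_speed_ms",
                ],
            },
            default_run["anchors"],
            k=2,
        )
        assert out["no_speeds"] >= out["no_up"]

    def test_counts_match_independent_rerun(self, default_run):
        m = default_run["matrix"].iloc[:12]
        anchors = {t: f for t, f in default_run["anchors"].items() if t in m.index}
        if not anchors:
            anchors = {m.index[0]: "predator"}
        removed = ["n_reversals"]
        out = sensitivity_analysis(m, {"trial": removed}, anchors, k=2)
        base = cluster_and_label(m, anchors, k=2).fates
        trial = cluster_and_label(m.drop(columns=removed), anchors, k=2).fates
        assert out["trial"] == int((base != trial).sum())

    def test_too_few_variables_rejected(self, default_run):
        m = default_run["matrix"].iloc[:, :3]
        with pytest.raises(ValueError):
            sensitivity_analysis(
                m, {"bad": list(m.columns[:2])}, default_run["anchors"], k=2
            )


# ---------------------------------------------------------------------------
# random forest


def _separable_fixture(n=40, seed=0):
    rng = np.random.default_rng(seed)
    preds = pd.DataFrame(
        {
            "n_reversals": rng.integers(10, 30, n // 2),
            "mean_up_speed_ms": rng.uniform(0.6, 1.5, n // 2),
            "residency_estuary_h": rng.uniform(50, 200, n // 2),
        }
    )
    smolts = pd.DataFrame(
        {
            "n_reversals": np.zeros(n // 2, dtype=int),
            "mean_up_speed_ms": np.zeros(n // 2),
            "residency_estuary_h": rng.uniform(1, 5, n // 2),
        }
    )
    X = pd.concat([preds, smolts], ignore_index=True)
    X.index = [f"t{i}" for i in range(len(X))]
    y = pd.Series(["predator"] * (n // 2) + ["smolt"] * (n // 2), index=X.index)
    return X, y


class TestForest:
    def test_separable_fixture_zero_oob_error(self):
        X, y = _separable_fixture()
        res = fit_random_forest(X, y, n_tree_grid=(25, 50, 100), seed=0)
        assert res.oob_error == 0.0
        assert res.class_errors == {"predator": 0.0, "smolt": 0.0}
        assert res.auroc == 1.0 and res.f1 == 1.0

    def test_class_weights_do_not_change_separable_predictions(self):
        X, y = _separable_fixture()
        a = fit_random_forest(X, y, n_tree_grid=(50,), seed=0)
        b = fit_random_forest(X, y, n_tree_grid=(50,), class_weights="balanced", seed=0)
        pd.testing.assert_series_equal(
            predict_fates(a, X)["fate"], predict_fates(b, X)["fate"]
        )

    def test_deterministic_under_seed(self):
        X, y = _separable_fixture()
        a = fit_random_forest(X, y, seed=5)
        b = fit_random_forest(X, y, seed=5)
        assert a.n_trees == b.n_trees and a.mtry == b.mtry
        pd.testing.assert_frame_equal(a.importance, b.importance)

    def test_single_class_rejected(self):
        X, y = _separable_fixture()
        with pytest.raises(ValueError):
            fit_random_forest(X, y[y == "smolt"], seed=0)

    def test_trigger_variable_flips_unidirectional_triggered_tag(self):
        """A triggered tag with smolt-like movement is recovered as a
        predator only while the hours-to-trigger variable is present.

        The fixture includes predators whose movement is indistinguishable
        from smolts, so the digestion trigger is the only variable that
        separates the classes perfectly."""
        X, y = _separable_fixture()
        X = X.copy()
        X["time_to_trigger_h"] = 0.0
        n_pred = int((y == "predator").sum())
        X.loc[y == "predator", "time_to_trigger_h"] = np.linspace(12, 60, n_pred)
        # two triggered tags moved like smolts: movement alone cannot split
        quiet = y[y == "predator"].index[:2]
        X.loc[quiet, ["n_reversals", "mean_up_speed_ms"]] = 0
        X.loc[quiet, "residency_estuary_h"] = 3.0
        odd = pd.DataFrame(
            {
                "n_reversals": [0],
                "mean_up_speed_ms": [0.0],
                "residency_estuary_h": [2.0],
                "time_to_trigger_h": [20.0],
            },
            index=["odd"],
        )
        with_var = fit_random_forest(
            X, y, n_tree_grid=(100,), mtry_grid=(X.shape[1],), seed=0
        )
        assert predict_fates(with_var, odd)["fate"].iloc[0] == "predator"
        without = fit_random_forest(
            X.drop(columns="time_to_trigger_h"),
            y,
            n_tree_grid=(100,),
            mtry_grid=(3,),
            seed=0,
        )
        assert (
            predict_fates(without, odd.drop(columns="time_to_trigger_h"))["fate"].iloc[0]
            == "smolt"
        )

    def test_predict_column_mismatch_rejected(self):
        X, y = _separable_fixture()
        res = fit_random_forest(X, y, n_tree_grid=(25,), seed=0)
        with pytest.raises(ValueError):
            predict_fates(res, X[list(X.columns[:2])])

    def test_predict_empty_matrix(self):
        X, y = _separable_fixture()
        res = fit_random_forest(X, y, n_tree_grid=(25,), seed=0)
        assert predict_fates(res, X.iloc[:0]).empty


class TestAgreement:
    def test_identical_maps(self):
        f = pd.Series({"a": "smolt", "b": "predator"})
        assert classifier_agreement(f, f) == 1.0

    def test_one_disagreement_in_fifty(self):
        a = pd.Series({f"t{i}": "smolt" for i in range(50)})
        b = a.copy()
        b.iloc[0] = "predator"
        assert classifier_agreement(a, b) == pytest.approx(0.98)

    def test_mismatched_tag_sets_rejected(self):
        with pytest.raises(ValueError):
            classifier_agreement(
                pd.Series({"a": "smolt"}), pd.Series({"b": "smolt"})
            )


class TestMDS:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        Y = mds_projection(D)
        d01 = np.linalg.norm(Y[0] - Y[1])
        d02 = np.linalg.norm(Y[0] - Y[2])
        d12 = np.linalg.norm(Y[1] - Y[2])
        assert d01 == pytest.approx(1.0, abs=1e-9)
        assert d02 == pytest.approx(1.0, abs=1e-9)
        assert d12 == pytest.approx(1.0, abs=1e-9)

    def test_distances_recovered_up_to_rigid_motion(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(9, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        Y = mds_projection(D, dims=2)
        D2 = np.sqrt(((Y[:, None] - Y[None, :]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)

    def test_single_point_at_origin(self):
        Y = mds_projection(np.zeros((1, 1)))
        assert np.allclose(Y, 0.0)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            mds_projection(D)
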