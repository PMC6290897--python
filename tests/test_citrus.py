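"""Pooled clustering, cluster features, PAMR, and SAM selection."""
import numpy as np
import pandas as pd
import pytest

from irsigflow.citrus import (
    CitrusError,
    cluster_features,
    pamr_fit_cv,
    pool_and_cluster,
    sam_select,
)
from irsigflow.citrus import _nsc_predict, _nsc_stats  # oracle access
from irsigflow.events import LINEAGE_CHANNELS, default_channel_roles, EventMatrix


def _blob_samples(rng, n_per_blob=300, sep=6.0, n_samples=2):
    """Two well-separated Gaussian blobs in lineage space, split over samples."""
    roles = default_channel_roles()
    centers = np.zeros((2, 7))
    centers[1, :] = sep  # 6 SD apart per axis, unit SD
    samples, truth = [], []
    for s in range(n_samples):
        labels = np.repeat([0, 1], n_per_blob // n_samples * np.ones(2, int))
        X = rng.normal(centers[labels], 1.0)
        values = pd.DataFrame(X, columns=list(LINEAGE_CHANNELS))
        for extra in set(roles) - set(values.columns):
            values[extra] = 0.0
        samples.append(EventMatrix(f"S{s}", values, roles, "arcsinh"))
        truth.append(labels)
    return samples, np.concatenate(truth)


class TestClustering:
    def test_two_blobs_recovered(self, rng):
        samples, truth = _blob_samples(rng)
        tree = pool_and_cluster(samples, min_cluster_frac=0.4,
                                max_pooled_events=None, seed=0)
        non_root = [i for i in tree.qualifying if i != tree.root]
        # exactly the two half-pool blob nodes clear a 40% size floor
        assert len(non_root) == 2
        for nid in non_root:
            members = tree.node_members(nid)
            frac_blob1 = truth[members].mean()
            assert max(frac_blob1, 1 - frac_blob1) > 0.99
            assert tree.nodes[nid].size_fraction == pytest.approx(0.5, abs=0.05)

    def test_min_frac_one_keeps_only_root(self, rng):
        samples, _ = _blob_samples(rng, n_per_blob=100)
        tree = pool_and_cluster(samples, min_cluster_frac=1.0,
                                max_pooled_events=None, seed=0)
        assert tree.qualifying == [tree.root]

    def test_children_subsets_of_parent(self, rng):
        samples, _ = _blob_samples(rng)
        tree = pool_and_cluster(samples, min_cluster_frac=0.2,
                                max_pooled_events=None, seed=0)
        for nid in tree.qualifying:
            node = tree.nodes[nid]
            if node.children is None:
                continue
            parent = set(tree.node_members(nid))
            for child in node.children:
                if child in tree.members:
                    assert set(tree.node_members(child)) <= parent

    def test_invariant_to_sample_order(self, rng):
        samples, _ = _blob_samples(rng, n_per_blob=100)
        t1 = pool_and_cluster(samples, min_cluster_frac=0.3,
                              max_pooled_events=None, seed=0)
        t2 = pool_and_cluster(samples[::-1], min_cluster_frac=0.3,
                              max_pooled_events=None, seed=0)

        def membership_sets(tree):
            keyed = tree.data.apply(tuple, axis=1).to_numpy()
            return {frozenset(keyed[tree.node_members(i)]) for i in tree.qualifying}

        assert membership_sets(t1) == membership_sets(t2)

    def test_bad_min_frac_rejected(self, rng):
        samples, _ = _blob_samples(rng, n_per_blob=50)
        with pytest.raises(CitrusError):
            pool_and_cluster(samples, min_cluster_frac=0.0)


class TestClusterFeatures:
    def test_single_sample_equals_pooled_medians(self, rng):
        samples, _ = _blob_samples(rng, n_samples=1)
        tree = pool_and_cluster(samples, min_cluster_frac=1.0,
                                max_pooled_events=None, seed=0)
        feats = cluster_features(tree, ("TIGIT",))
        pooled_median = np.median(tree.data["TIGIT"])
        assert feats.values.iloc[0, 0] == pytest.approx(pooled_median)
        assert not feats.mask.to_numpy().any()

    def test_missing_sample_imputed_and_masked(self, rng):
        samples, truth = _blob_samples(rng, n_per_blob=200)
        # sample S0 gets only blob-0 events: blob-1 node has no S0 members
        keep = np.flatnonzero(truth[:200] == 0)
        samples[0] = samples[0].take(keep)
        tree = pool_and_cluster(samples, min_cluster_frac=0.25,
                                max_pooled_events=None, seed=0)
        feats = cluster_features(tree, ("TIGIT",))
        assert feats.mask.to_numpy().any()


def _planted_features(rng, n=40, p=20, gap=4.0):
    X = rng.normal(size=(n, p))
    y = np.repeat([0, 1], n // 2)
    X[y == 1, 0] += gap  # planted feature 0
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


class TestPAMR:
    def test_delta_zero_keeps_all_features(self, rng):
        X, y = _planted_features(rng)
        res = pamr_fit_cv(X, y, n_folds=5, delta_grid=np.array([0.0]), seed=1)
        assert res.selected_features == list(X.columns)

    def test_delta_zero_equals_nearest_centroid_oracle(self, rng):
        """Unshrunk prediction must match an explicit per-sample loop over
        standardized distances to class centroids with log-prior offsets."""
        X, y = _planted_features(rng, n=30, p=8)
        Xa = X.to_numpy()
        stats = _nsc_stats(Xa, y)
        pred = _nsc_predict(Xa, stats, 0.0)
        classes, _, _, centroids, nk, si, s0, _, _ = stats
        for i in range(len(Xa)):
            scores = []
            for k, cls in enumerate(classes):
                dist = np.sum((Xa[i] - centroids[k]) ** 2 / (si + s0) ** 2)
                scores.append(dist - 2 * np.log(nk[k] / nk.sum()))
            assert pred[i] == classes[int(np.argmin(scores))]

    def test_full_shrinkage_predicts_majority(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        y = np.array([0] * 20 + [1] * 10)
        stats = _nsc_stats(X.to_numpy(), y)
        big = np.abs(stats[8]).max() + 1.0
        pred = _nsc_predict(X.to_numpy(), stats, big)
        assert (pred == 0).all()
        res = pamr_fit_cv(X, y, n_folds=5, delta_grid=np.array([big]), seed=1)
        assert res.cv_error[0] == pytest.approx(10 / 30, abs=1e-9)

    def test_planted_feature_recovered_with_zero_cv_error(self, rng):
        # 6 pooled-SD gap: the classes are fully separable on one feature
        X, y = _planted_features(rng, gap=6.0)
        res = pamr_fit_cv(X, y, n_folds=5, seed=3)
        assert res.cv_error.min() == 0.0
        assert res.selected_features == ["f0"]
        assert res.cv_accuracy == 1.0

    def test_cv_error_invariant_to_column_permutation(self, rng):
        X, y = _planted_features(rng)
        res1 = pamr_fit_cv(X, y, n_folds=5, seed=7)
        perm = rng.permutation(X.shape[1])
        res2 = pamr_fit_cv(X.iloc[:, perm], y, n_folds=5, seed=7)
        np.testing.assert_allclose(res1.cv_error, res2.cv_error, atol=1e-12)

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(CitrusError):
            pamr_fit_cv(X, np.zeros(10), seed=0)


class TestSAM:
    def test_nesting_across_fdr_levels(self, rng):
        X = rng.normal(size=(40, 60))
        y = np.repeat([0, 1], 20)
        X[y == 1, :3] += 1.5
        Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(60)])
        strict = sam_select(Xdf, y, fdr_target=0.01, n_perm=100, seed=4)
        loose = sam_select(Xdf, y, fdr_target=0.05, n_perm=100, seed=4)
        assert set(strict.selected_features) <= set(loose.selected_features)

    def test_null_calibration(self):
        """Under a global null the 1%-FDR set is almost always empty."""
        sizes = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            X = pd.DataFrame(rng.normal(size=(40, 60)))
            y = np.repeat([0, 1], 20)
            res = sam_select(X, y, fdr_target=0.01, n_perm=100, seed=rep)
            sizes.append(len(res.selected_features))
        assert np.mean(sizes) <= 0.6

    def test_planted_effects_recovered(self):
        hits, false = [], []
        for rep in range(50):
            rng = np.random.default_rng(500 + rep)
            X = rng.normal(size=(40, 60))
            y = np.repeat([0, 1], 20)
            X[y == 1, :3] += 2.5
            Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(60)])
            res = sam_select(Xdf, y, fdr_target=0.01, n_perm=100, seed=rep)
            sel = set(res.selected_features)
            hits.append({"f0", "f1", "f2"} <= sel)
            false.append(len(sel - {"f0", "f1", "f2"}))
        ok = [h and f <= 1 for h, f in zip(hits, false)]
        assert np.mean(ok) >= 0.9

    def test_degenerate_labels_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 5)))
        with pytest.raises(CitrusError):
            sam_select(X, np.zeros(10), n_perm=100)


class TestEndToEnd:
    def test_planted_tigit_effect_selects_gd_node(self, effect_tree):
        """A +1.5-logit HIV effect on gamma-delta TIGIT should be found as
        TIGIT features of gamma-delta-dominated nodes."""
        design, tree, feats = effect_tree
        labels = design.set_index("subject_id").loc[feats.values.index, "hiv"].to_numpy()
        res = pamr_fit_cv(feats, labels, seed=2)
        gd_frac = {
            nid: (tree.meta["subset"].to_numpy()[tree.node_members(nid)] == "gdT").mean()
            for nid in tree.qualifying
        }

        def is_gd_tigit(feature):
            nid = int(feature.split("_")[0][len("node"):])
            channel = feature.split("_", 1)[1]
            return gd_frac[nid] >= 0.5 and channel == "TIGIT"

        assert res.selected_features
        precision = np.mean([is_gd_tigit(f) for f in res.selected_features])
        assert precision >= 0.8
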