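import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cpgboost as cb
from cpgboost.model import expected_n_features

from conftest import make_profile


def toy_matrix(n=200, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    if separable:
        x1 = y + 0.01 * rng.random(n)
        x2 = -y + 0.01 * rng.random(n)
    else:
        x1, x2 = rng.random(n), rng.random(n)
    idx = pd.MultiIndex.from_tuples(
        [("c", "chr1", i + 1) for i in range(n)], names=["cell_id", "chrom", "pos"])
    X = pd.DataFrame({"f_a": x1, "f_b": x2}, index=idx)
    return cb.FeatureMatrix(X, pd.Series(y, index=idx, name="label"))


class TestBuildMatrix:
    @given(m=st.integers(1, 30))
    def test_column_count_formula(self, m):
        assert expected_n_features(m) == 259 + 4 * m + 8 * (m - 1)

    def test_expected_totals(self):
        assert expected_n_features(25) == 551
        assert expected_n_features(1) == 263

    def test_blocks_and_shape(self, sim_small):
        ds, gs, tracks = sim_small["dataset"], sim_small["gs"], sim_small["tracks"]
        fm = cb.build_matrix(ds, gs, tracks, "cell00", ["chr1"])
        m = ds.m
        assert fm.n_features == 259 + 4 * m + 8 * (m - 1)
        blocks = pd.Series(fm.blocks)
        assert (blocks == "seq").sum() == 84
        assert (blocks == "str").sum() == 175
        assert (blocks == "pos").sum() == 4 * m + 8 * (m - 1)
        # labels match the profile's binarized states
        pos_arr, states = ds.cell("cell00").labeled("chr1")
        assert len(fm.X) == len(pos_arr)
        np.testing.assert_array_equal(fm.y.to_numpy(), states)

    def test_positional_block_equals_per_site_vectors(self, sim_small):
        ds = sim_small["dataset"]
        fm = cb.build_matrix(ds, None, None, "cell01", ["chr2"], blocks=("pos",))
        pos_arr, _ = ds.cell("cell01").labeled("chr2")
        for take in (0, len(pos_arr) // 2, len(pos_arr) - 1):
            np.testing.assert_array_equal(
                fm.X.iloc[take].to_numpy(),
                cb.positional_vector(ds, "cell01", "chr2", int(pos_arr[take])))

    def test_empty_partition_errors(self, sim_small):
        with pytest.raises(ValueError):
            cb.build_matrix(sim_small["dataset"], None, None, "cell00",
                            ["chr99"], blocks=("pos",))

    def test_matrix_tsv_round_trip(self, sim_small, tmp_path):
        fm = cb.build_matrix(sim_small["dataset"], None, None, "cell00",
                             ["chr1"], blocks=("pos",))
        fm.to_tsv(tmp_path / "m.tsv", manifest_path=tmp_path / "man.tsv")
        back = cb.FeatureMatrix.from_tsv(tmp_path / "m.tsv", tmp_path / "man.tsv")
        pd.testing.assert_frame_equal(back.X, fm.X)
        assert back.blocks == fm.blocks
        assert back.origins == fm.origins


class TestGoss:
    def test_keep_everything(self):
        idx, w = cb.goss_select(np.arange(10.0), cb.GossConfig(a_frac=1.0, b_frac=0.0))
        assert sorted(idx.tolist()) == list(range(10))
        assert (w == 1).all()

    def test_uniform_keep_all(self):
        idx, w = cb.goss_select(np.arange(10.0), cb.GossConfig(a_frac=0.0, b_frac=1.0))
        assert sorted(idx.tolist()) == list(range(10))
        assert w == pytest.approx([1.0] * 10)

    def test_top_plus_random_remainder(self):
        grads = np.arange(1.0, 11.0)
        cfg = cb.GossConfig(a_frac=0.2, b_frac=0.25, seed=3)
        idx, w = cb.goss_select(grads, cfg)
        # top ceil(0.2*10)=2 by |gradient|, then ceil(0.25*10)=3 from the rest
        assert set(idx[:2].tolist()) == {9, 8}
        assert len(idx) == 5 and len(set(idx.tolist())) == 5
        assert set(idx[2:]).isdisjoint({9, 8})
        assert (w[:2] == 1).all()
        assert w[2:] == pytest.approx([(1 - 0.2) / 0.25] * 3)

    def test_no_amplification_weights(self):
        idx, w = cb.goss_select(
            np.arange(10.0), cb.GossConfig(a_frac=0.2, b_frac=0.3, amplify=False))
        assert (w == 1).all()

    def test_b_zero_with_amplify_no_division(self):
        idx, w = cb.goss_select(
            np.arange(10.0), cb.GossConfig(a_frac=0.5, b_frac=0.0, amplify=True))
        assert (w == 1).all() and len(idx) == 5

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            cb.GossConfig(a_frac=0.8, b_frac=0.4)

    def test_deterministic_per_seed(self):
        g = np.random.default_rng(0).random(50)
        i1, _ = cb.goss_select(g, cb.GossConfig(seed=11))
        i2, _ = cb.goss_select(g, cb.GossConfig(seed=11))
        i3, _ = cb.goss_select(g, cb.GossConfig(seed=12))
        assert i1.tolist() == i2.tolist()
        assert i1.tolist() != i3.tolist()

    def test_amplified_sum_is_unbiased(self):
        """With amplification the weighted |gradient| sum is unbiased for
        the full-sample sum (Monte Carlo over seeds)."""
        g = np.random.default_rng(1).random(10)
        target = np.abs(g).sum()
        cfgs = [cb.GossConfig(a_frac=0.2, b_frac=0.3, seed=s) for s in range(1000)]
        sums = []
        for cfg in cfgs:
            idx, w = cb.goss_select(g, cfg)
            sums.append((np.abs(g[idx]) * w).sum())
        assert np.mean(sums) == pytest.approx(target, rel=0.02)


class TestEfb:
    def test_conflict_disjoint_supports(self):
        a = np.array([1, 1, 0, 0, 0.0])
        b = np.array([0, 0, 2, 0, 0.0])
        assert cb.efb_conflict(a, b) == 0.0

    def test_conflict_identical_support(self):
        a = np.array([0, 3, 4, 0, 0.0])
        assert cb.efb_conflict(a, a) == pytest.approx(2 / 5)

    def test_conflict_hand_example(self):
        # L=10, supports {1,2,3} and {3,4}: one shared row
        a = np.zeros(10); a[[1, 2, 3]] = 1
        b = np.zeros(10); b[[3, 4]] = 1
        assert cb.efb_conflict(a, b) == pytest.approx(0.1)

    def test_conflict_empty_columns_error(self):
        with pytest.raises(ValueError):
            cb.efb_conflict(np.array([]), np.array([]))

    def test_bundle_d0_overlapping_all_singletons(self):
        X = np.ones((6, 4))  # every pair conflicts on every row
        plan = cb.efb_bundle(X, d=0.0)
        assert sorted(plan.sets) == [(0,), (1,), (2,), (3,)]

    def test_bundle_one_hot_single_set(self):
        X = np.eye(5)[:, :4]  # mutually exclusive one-hot columns
        for d in (0.0, 0.05, 0.5):
            plan = cb.efb_bundle(X, d=d)
            assert len(plan.sets) == 1 and plan.sets[0] == (0, 1, 2, 3)

    def test_bundle_respects_threshold_posthoc(self, rng):
        """Every within-set pair re-checked against the conflict bound."""
        X = (rng.random((60, 12)) < 0.15).astype(float) * rng.integers(1, 5, (60, 12))
        d = 0.2
        plan = cb.efb_bundle(X, d=d)
        assert sorted(i for s in plan.sets for i in s) == list(range(12))
        for members in plan.sets:
            for a in members:
                for b in members:
                    if a < b:
                        assert cb.efb_conflict(X[:, a], X[:, b]) <= d

    def test_merge_two_exclusive_binaries(self):
        X = np.array([[0, 0], [1, 0], [0, 1.0]])
        plan = cb.BundlePlan(sets=((0, 1),), d=0.0)
        res = cb.merge_bundles(X, plan)
        assert res.matrix[:, 0].tolist() == [0, 1, 2]

    def test_merge_singleton_sets_is_identity(self, rng):
        X = rng.random((20, 3))
        plan = cb.BundlePlan(sets=((0,), (1,), (2,)), d=0.0)
        res = cb.merge_bundles(X, plan)
        np.testing.assert_allclose(res.matrix, X)

    def test_merge_rejects_negative_values(self):
        X = np.array([[-1.0, 0], [0, 1]])
        with pytest.raises(ValueError):
            cb.merge_bundles(X, cb.BundlePlan(sets=((0, 1),), d=0.0))

    def test_merge_then_unmerge_recovers_columns(self, rng):
        """Histogram-offset bundling is information-preserving on
        exclusive columns."""
        n = 80
        X = np.zeros((n, 6))
        owner = rng.integers(0, 6, size=n)
        active = rng.random(n) < 0.7
        X[np.arange(n)[active], owner[active]] = rng.integers(1, 9, active.sum())
        plan = cb.efb_bundle(X, d=0.0)
        res = cb.merge_bundles(X, plan)
        np.testing.assert_allclose(cb.unmerge_bundles(res, 6), X)


class TestTrainPredict:
    def test_separable_toy_auc_one(self):
        fm = toy_matrix(separable=True)
        model = cb.train(fm, cb.ModelConfig(threads=1))
        assert cb.auc_roc(fm.y.to_numpy(), cb.predict(model, fm)) == 1.0

    def test_single_class_errors(self):
        fm = toy_matrix()
        fm = cb.FeatureMatrix(fm.X, pd.Series(np.ones(len(fm.X), dtype=int),
                                              index=fm.X.index))
        with pytest.raises(ValueError, match="single class"):
            cb.train(fm)

    def test_column_permutation_invariance(self):
        fm = toy_matrix(seed=2)
        model = cb.train(fm, cb.ModelConfig(threads=1))
        p1 = cb.predict(model, fm)
        shuffled = fm.X[["f_b", "f_a"]]
        p2 = cb.predict(model, shuffled)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_column_rejected(self):
        fm = toy_matrix()
        model = cb.train(fm, cb.ModelConfig(threads=1))
        with pytest.raises(ValueError, match="lacks training columns"):
            cb.predict(model, fm.X[["f_a"]])

    def test_deterministic_given_seed_single_thread(self, sim_small):
        ds = sim_small["dataset"]
        fm = cb.build_matrix(ds, None, None, "cell00", ["chr1"], blocks=("pos",))
        cfg = cb.ModelConfig(threads=1, seed=5)
        p1 = cb.predict(cb.train(fm, cfg), fm)
        p2 = cb.predict(cb.train(fm, cfg), fm)
        np.testing.assert_array_equal(p1, p2)

    def test_neighbor_signal_beats_permuted_labels(self, sim_small):
        """Held-out AUC on real labels exceeds a label-permuted control."""
        ds = sim_small["dataset"]
        fm_tr = cb.build_matrix(ds, None, None, "cell00", ["chr1"], blocks=("pos",))
        fm_te = cb.build_matrix(ds, None, None, "cell00", ["chr2"], blocks=("pos",))
        cfg = cb.ModelConfig(threads=1, seed=0)
        auc_real = cb.auc_roc(fm_te.y.to_numpy(),
                              cb.predict(cb.train(fm_tr, cfg), fm_te))
        rng = np.random.default_rng(0)
        y_perm = pd.Series(rng.permutation(fm_tr.y.to_numpy()), index=fm_tr.X.index)
        fm_perm = cb.FeatureMatrix(fm_tr.X, y_perm, fm_tr.blocks)
        auc_null = cb.auc_roc(fm_te.y.to_numpy(),
                              cb.predict(cb.train(fm_perm, cfg), fm_te))
        assert auc_real > auc_null + 0.2

    def test_predict_states_threshold(self):
        fm = toy_matrix(separable=True)
        model = cb.train(fm, cb.ModelConfig(threads=1))
        states = cb.predict_states(model, fm)
        np.testing.assert_array_equal(states, fm.y.to_numpy())

    def test_serialization_round_trip(self, tmp_path):
        fm = toy_matrix(seed=4)
        model = cb.train(fm, cb.ModelConfig(threads=1, seed=1))
        model.save(tmp_path / "m.txt", tmp_path / "m.json")
        back = cb.TrainedModel.load(tmp_path / "m.txt", tmp_path / "m.json")
        np.testing.assert_allclose(cb.predict(back, fm), cb.predict(model, fm))
        assert back.feature_names == model.feature_names


class TestImportance:
    def test_single_model_identity(self):
        fm = toy_matrix(seed=3)
        model = cb.train(fm, cb.ModelConfig(threads=1))
        agg = cb.aggregate_importance([model])
        assert sorted(agg.index) == sorted(model.feature_names)
        assert agg.sum() == model.split_counts.sum()

    def test_sum_equals_loop_oracle(self):
        models = [cb.train(toy_matrix(seed=s), cb.ModelConfig(threads=1, seed=s))
                  for s in range(3)]
        agg = cb.aggregate_importance(models)
        for name in agg.index:
            assert agg[name] == sum(m.split_counts[name] for m in models)
        assert list(agg.values) == sorted(agg.values, reverse=True)

    def test_mismatched_manifests_rejected(self):
        m1 = cb.train(toy_matrix(), cb.ModelConfig(threads=1))
        fm2 = toy_matrix()
        fm2 = cb.FeatureMatrix(fm2.X.rename(columns={"f_a": "other"}), fm2.y)
        m2 = cb.train(fm2, cb.ModelConfig(threads=1))
        with pytest.raises(ValueError):
            cb.aggregate_importance([m1, m2])
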