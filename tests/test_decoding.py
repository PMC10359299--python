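import itertools

import numpy as np
import pytest

from blockmvpa._fastsvm import batch_svc_decision, svc_train_predict
from blockmvpa.decoding import (BetaPatternSet, PatternDecoder,
                                cross_sample_decode, decode_patterns,
                                group_roi_discovery, leave_two_blocks_out_folds,
                                searchlight_decode, sphere_offsets)


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(0, 1), (1, 7), (2, 33), (4, 257)])
    def test_lattice_counts(self, radius, count):
        off = sphere_offsets(radius)
        assert off.shape == (count, 3)
        assert (np.sum(off ** 2, axis=1) <= radius ** 2).all()

    def test_deterministic_lexicographic_order(self):
        off = sphere_offsets(3)
        assert np.array_equal(off, np.array(sorted(map(tuple, off))))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_offsets(-1)


class TestFolds:
    @pytest.mark.parametrize("n_why,n_how,expected", [(4, 4, 16), (6, 6, 36), (2, 3, 6)])
    def test_all_pairs_enumerated(self, n_why, n_how, expected):
        labels = np.array(["why"] * n_why + ["how"] * n_how)
        folds = leave_two_blocks_out_folds(labels)
        assert len(folds) == expected
        for train, test in folds:
            assert len(test) == 2
            assert {labels[t] for t in test} == {"why", "how"}
            assert len(np.intersect1d(train, test)) == 0

    def test_single_block_class_rejected(self):
        with pytest.raises(ValueError):
            leave_two_blocks_out_folds(np.array(["why", "how", "how"]))


def _margin_oracle(X, y_pm, X_test):
    """Brute-force hard-margin linear separator for tiny 2-D problems.

    Enumerates active sets of <=3 points (the support set of a 2-D
    max-margin hyperplane), solves the equality-constrained KKT system
    for each, keeps feasible candidates and returns the max-margin
    separator's predictions.
    """
    n = len(y_pm)
    best = None
    for k in (2, 3):
        for subset in itertools.combinations(range(n), k):
            A = np.array([[X[i] @ X[j] * y_pm[i] * y_pm[j] for j in subset]
                          for i in subset])
            A = np.block([[A, y_pm[list(subset)][:, None]],
                          [y_pm[list(subset)][None, :], np.zeros((1, 1))]])
            rhs = np.concatenate([np.ones(k), [0.0]])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            alpha, b = sol[:k], sol[k]
            if (alpha < -1e-9).any():
                continue
            w = sum(a * y_pm[i] * X[i] for a, i in zip(alpha, subset))
            margins = y_pm * (X @ w + b)
            if margins.min() < 1 - 1e-6:
                continue
            norm = np.linalg.norm(w)
            if best is None or norm < best[0] - 1e-12:
                best = (norm, w, b)
    assert best is not None, "oracle found no feasible separator"
    return np.sign(best[1] @ X_test.T + best[2])


class TestDecodePatterns:
    def test_large_margin_problem_reaches_100(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 5)) * 0.1
        X[:4, 0] += 10.0
        X[4:, 0] -= 10.0
        y = np.array(["why"] * 4 + ["how"] * 4)
        assert decode_patterns(X, y) == 100.0

    def test_agrees_with_bruteforce_margin_oracle(self):
        rng = np.random.default_rng(1)
        n_checked = 0
        for trial in range(40):
            X = rng.normal(size=(6, 2))
            y_pm = np.array([1.0, 1, 1, -1, -1, -1])
            rng.shuffle(y_pm)
            X += y_pm[:, None] * 4.0  # separable with margin
            X *= 3.0  # keep optimal alphas below the cost bound
            X_test = rng.normal(size=(4, 2)) + \
                np.sign(rng.normal(size=4))[:, None] * 4.0 * 3.0
            oracle = _margin_oracle(X, y_pm, X_test / 3.0 * 3.0)
            y = np.where(y_pm > 0, "why", "how")
            pred = PatternDecoder(cost=1.0).fit(X, y).predict(X_test)
            got = np.where(pred == "why", 1.0, -1.0)
            keep = np.abs(oracle) > 0  # skip exact-boundary ties
            assert np.array_equal(got[keep], oracle[keep])
            n_checked += keep.sum()
        assert n_checked > 100

    def test_shuffled_labels_hover_at_chance(self):
        rng = np.random.default_rng(2)
        accs = []
        for _ in range(60):
            X = rng.normal(size=(8, 30))
            y = np.array(["why"] * 4 + ["how"] * 4)
            rng.shuffle(y)
            accs.append(decode_patterns(X, y))
        assert abs(np.mean(accs) - 50.0) < 5.0

    def test_full_label_flip_preserves_accuracy_and_scoring_flip_complements(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 10))
        y = np.array(["why", "how"] * 4)
        a = decode_patterns(X, y)
        flipped = np.where(y == "why", "how", "why")
        assert decode_patterns(X, flipped) == a
        # scoring the same predictions against complemented labels
        folds = leave_two_blocks_out_folds(y)
        correct = 0
        total = 0
        for train, test in folds:
            pred = PatternDecoder().fit(X[train], y[train]).predict(X[test])
            correct += (pred == flipped[test]).sum()
            total += len(test)
        assert a + 100.0 * correct / total == pytest.approx(100.0)

    def test_affine_rescaling_of_voxels_preserves_accuracy(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 12))
        y = np.array(["why"] * 4 + ["how"] * 4)
        rng.shuffle(y)
        a = decode_patterns(X, y)
        assert decode_patterns(X * 3.0, y) == a

    def test_constant_patterns_warn_but_return(self):
        X = np.ones((8, 5))
        y = np.array(["why"] * 4 + ["how"] * 4)
        with pytest.warns(UserWarning, match="degenerate"):
            acc = decode_patterns(X, y)
        assert 0.0 <= acc <= 100.0

    def test_fast_route_matches_public_sklearn_svc(self):
        from sklearn.svm import SVC
        rng = np.random.default_rng(5)
        for _ in range(50):
            X = rng.normal(size=(10, 6))
            y = np.array([0] * 5 + [1] * 5)
            rng.shuffle(y)
            Xt = rng.normal(size=(4, 6))
            fast = svc_train_predict(X @ X.T, y, Xt @ X.T, cost=1.0)
            ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(Xt)
            assert np.array_equal(fast, ref)


class TestSearchlight:
    def test_radius_zero_equals_single_voxel_decoding(self):
        rng = np.random.default_rng(6)
        grid = (4, 4, 4)
        b4 = rng.normal(size=(*grid, 8))
        y = np.array(["why", "how"] * 4)
        mask = np.ones(grid, dtype=bool)
        amap = searchlight_decode(b4, y, mask, radius=0)
        for flat in [0, 13, 37, 63]:
            idx = np.unravel_index(flat, grid)
            assert amap[idx] == pytest.approx(
                decode_patterns(b4[idx][:, None], y), abs=1e-9)

    def test_batched_solver_matches_per_voxel_svc(self):
        from sklearn.svm import SVC
        rng = np.random.default_rng(7)
        V, n = 300, 8
        y_pm = np.array([-1.0] * 4 + [1.0] * 4)
        Xf = rng.normal(size=(n, V, 17))
        K = np.ascontiguousarray(np.einsum("ivk,jvk->ijv", Xf, Xf))
        tr = [0, 1, 2, 4, 5, 6]
        te = [3, 7]
        Kt = np.ascontiguousarray(K[np.ix_(tr, tr)])
        Kc = np.ascontiguousarray(K[np.ix_(te, tr)])
        dec = batch_svc_decision(Kt, y_pm[tr], Kc)
        for v in range(V):
            m = SVC(kernel="precomputed", C=1.0).fit(
                np.ascontiguousarray(Kt[:, :, v]), (y_pm[tr] > 0).astype(int))
            ref = m.decision_function(Kc[:, :, v])
            assert np.array_equal(dec[:, v] > 0, ref > 0)

    def test_map_bounds_and_mask_handling(self):
        rng = np.random.default_rng(8)
        grid = (6, 6, 6)
        mask = np.zeros(grid, dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        b4 = rng.normal(size=(*grid, 8))
        y = np.array(["why"] * 4 + ["how"] * 4)
        amap = searchlight_decode(b4, y, mask, radius=2)
        assert np.isnan(amap[~mask]).all()
        vals = amap[mask]
        assert ((vals >= 0) & (vals <= 100)).all()

    def test_planted_effect_localizes_map_maxima(self):
        rng = np.random.default_rng(9)
        grid = (10, 10, 10)
        region = np.zeros(grid, dtype=bool)
        region[2:5, 2:5, 2:5] = True
        mask = np.ones(grid, dtype=bool)
        hits = 0
        n_runs = 12
        from scipy import ndimage
        dilated = ndimage.binary_dilation(region, iterations=2)
        for _ in range(n_runs):
            pattern = rng.normal(size=region.sum())
            pattern /= np.linalg.norm(pattern)
            b4 = rng.normal(size=(*grid, 8))
            signs = np.array([1.0] * 4 + [-1.0] * 4)
            b4[region] += 5.0 * np.outer(pattern, signs)
            y = np.array(["why"] * 4 + ["how"] * 4)
            amap = searchlight_decode(b4, y, mask, radius=2)
            # the global maximum is attained inside the dilated region
            hits += bool(np.nanmax(amap[dilated]) == np.nanmax(amap))
        assert hits >= int(0.95 * n_runs)


class TestGroupDiscovery:
    def _maps(self, rng, effect_mask=None, n_subj=12, grid=(8, 8, 8), shift=0.0):
        stack = 50.0 + rng.normal(0, 5.0, size=(n_subj, *grid))
        if effect_mask is not None:
            stack[:, effect_mask] += shift
        return stack

    def test_small_cluster_excluded_by_cluster_threshold(self):
        rng = np.random.default_rng(10)
        grid = (8, 8, 8)
        mask = np.ones(grid, dtype=bool)
        small = np.zeros(grid, dtype=bool)
        small[2, 2:6, 2] = True  # 4-voxel line, 6-connected
        assert small.sum() == 4
        maps = {"faces": self._maps(rng, small, shift=40.0),
                "hands": self._maps(rng, small, shift=40.0)}
        rois = group_roi_discovery(maps, mask, cluster_k=5, n_perm=500, seed=0)
        assert len(rois) == 0
        rois2 = group_roi_discovery(maps, mask, cluster_k=4, n_perm=500, seed=0)
        assert len(rois2) == 1

    def test_conjunction_requires_both_targets(self):
        rng = np.random.default_rng(11)
        grid = (8, 8, 8)
        mask = np.ones(grid, dtype=bool)
        region = np.zeros(grid, dtype=bool)
        region[1:4, 1:4, 1:4] = True
        maps = {"faces": self._maps(rng, region, shift=40.0),
                "hands": self._maps(rng, None)}
        rois = group_roi_discovery(maps, mask, n_perm=500, seed=1)
        assert len(rois) == 0

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(12)
        maps = {"faces": self._maps(rng, n_subj=8)}
        with pytest.raises(ValueError):
            group_roi_discovery(maps, np.ones((8, 8, 8), dtype=bool))


class TestCrossSample:
    def _sets(self, rng, n_subj, signal=0.0, pattern=None):
        out = []
        for _ in range(n_subj):
            X = rng.normal(size=(8, 20))
            if pattern is not None:
                signs = np.array([1.0] * 4 + [-1.0] * 4)
                X += signal * np.outer(signs, pattern)
            y = np.array(["why"] * 4 + ["how"] * 4)
            out.append(BetaPatternSet(patterns=X, inference=y,
                                      target=np.array(["faces"] * 8)))
        return out

    def test_shared_pattern_transfers(self):
        rng = np.random.default_rng(13)
        pattern = rng.normal(size=20)
        pattern /= np.linalg.norm(pattern)
        a = self._sets(rng, 5, signal=3.0, pattern=pattern)
        b = self._sets(rng, 5, signal=3.0, pattern=pattern)
        ab, ba = cross_sample_decode(a, b)
        assert ab > 90.0 and ba > 90.0

    def test_self_transfer_equals_training_accuracy(self):
        rng = np.random.default_rng(14)
        a = self._sets(rng, 4, signal=1.0, pattern=rng.normal(size=20))
        ab, ba = cross_sample_decode(a, a)
        assert ab == ba

    def test_voxel_space_mismatch_rejected(self):
        rng = np.random.default_rng(15)
        a = self._sets(rng, 3)
        b = [BetaPatternSet(patterns=rng.normal(size=(8, 21)),
                            inference=np.array(["why"] * 4 + ["how"] * 4),
                            target=np.array(["faces"] * 8))]
        with pytest.raises(ValueError):
            cross_sample_decode(a, b)
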