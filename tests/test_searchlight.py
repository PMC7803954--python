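"""Sphere geometry, OvO voting, cross-validation schemes, searchlight."""

import itertools

import numpy as np
import pandas as pd
import pytest

import voicelight as vl
from voicelight.searchlight import FoldError, SearchlightError

from conftest import synthetic_beta_series


def brute_force_sphere_count(radius, inclusive):
    n = 0
    r = int(np.ceil(radius))
    for x, y, z in itertools.product(range(-r, r + 1), repeat=3):
        d2 = x * x + y * y + z * z
        if (d2 <= radius**2) if inclusive else (d2 < radius**2):
            n += 1
    return n


class TestSphereGeometry:
    def test_r6_member_counts_match_enumeration(self):
        # 12 mm at 2 mm voxels = 6-voxel radius; ~900 voxels per sphere
        assert vl.sphere_offsets(12.0).shape[0] == \
            brute_force_sphere_count(6, inclusive=False) == 895
        assert vl.sphere_offsets(12.0, boundary="inclusive").shape[0] == \
            brute_force_sphere_count(6, inclusive=True) == 925

    def test_radius_zero_is_center_only(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        members = vl.sphere_members(mask, (1, 1, 1), radius_voxels=0,
                                    boundary="inclusive")
        assert len(members[0]) == 1
        assert (members[0][0], members[1][0], members[2][0]) == (1, 1, 1)

    def test_mask_clipping(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        members = vl.sphere_members(mask, (2, 2, 2), radius_voxels=2)
        assert len(members[0]) == 1  # everything else is outside the mask

    def test_center_outside_mask_raises(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        with pytest.raises(SearchlightError):
            vl.sphere_members(mask, (1, 1, 1))

    def test_anisotropic_voxels(self):
        offs = vl.sphere_offsets(4.0, voxel_size_mm=(4.0, 2.0, 2.0),
                                 boundary="inclusive")
        assert np.abs(offs[:, 0]).max() == 1  # 4 mm voxels along x
        assert np.abs(offs[:, 1]).max() == 2


class TestOvOVoting:
    def test_unanimous_vote(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [10.0], [10.1], [0.05]])
        y = np.array(["a", "a", "b", "b", "c", "c", "a"])
        pred = vl.ovo_predict(X[:-1], y[:-1], X[[-1]])
        assert pred[0] == "a"

    def test_three_cycle_tie_breaks_lexicographically(self):
        # 2D prototypes whose pairwise SVM boundaries form a triangle;
        # at the probe every pairwise classifier votes for a different
        # class (verified by inspecting the votes), so the majority is a
        # 3-way tie and the smallest label must win
        prototypes = np.array(
            [[1.37, -2.30], [-4.59, -4.83], [3.13, 4.13]]
        )
        train = np.vstack(
            [np.vstack([p + [0, 0.3], p - [0, 0.3]]) for p in prototypes]
        )
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        clf = vl.OvOVotingSVC().fit(train, labels)
        probe = np.array([[-3.8, 2.6]])
        votes = clf.vote_counts(probe)[0]
        assert np.all(votes == 1), f"expected a 3-cycle, got votes {votes}"
        assert clf.predict(probe)[0] == "a"  # smallest label wins

    def test_separable_clouds_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        centers = {"a": (0, 0), "b": (50, 0), "c": (0, 50)}
        Xtr, ytr, Xte, yte = [], [], [], []
        for lab, c in centers.items():
            pts = rng.normal(c, 1.0, size=(30, 2))
            Xtr += list(pts[:20]); ytr += [lab] * 20
            Xte += list(pts[20:]); yte += [lab] * 10
        pred = vl.ovo_predict(np.array(Xtr), np.array(ytr), np.array(Xte))
        assert (pred == np.array(yte)).all()

    def test_single_sample_class_raises(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b"])
        with pytest.raises(SearchlightError):
            vl.OvOVotingSVC().fit(X, y)

    def test_duplicated_features_leave_predictions_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        y = np.repeat(["a", "b", "c"], 20)
        X[y == "b", :] += 4.0
        X[y == "c", :] -= 4.0
        Xt = rng.normal(size=(30, 5))
        base = vl.ovo_predict(X, y, Xt)
        dup = vl.ovo_predict(np.hstack([X, X]), y, np.hstack([Xt, Xt]))
        assert (base == dup).all()


class TestCrossValidation:
    def test_fold_counts(self):
        bs = synthetic_beta_series(grid_shape=(2, 2, 2))
        feats = bs.betas.reshape(bs.betas.shape[0], -1)
        folds_loro = list(
            vl.searchlight._cv_folds(bs.meta, "loro"))
        folds_lowo = list(
            vl.searchlight._cv_folds(bs.meta, "lowo"))
        assert len(folds_loro) == 4
        assert len(folds_lowo) == 12
        # every fold's test group absent from training
        for g, train, test in folds_loro:
            assert not set(bs.meta.loc[train, "run"]) & {g}
        for g, train, test in folds_lowo:
            assert not set(bs.meta.loc[train, "word"]) & {g}

    def test_perfectly_informative_voxel(self):
        roi = np.zeros((2, 2, 2), dtype=bool)
        roi[0, 0, 0] = True
        bs = synthetic_beta_series(grid_shape=(2, 2, 2), noise=0.01,
                                   signal=10.0, informative=roi, seed=5)
        acc, cm = vl.roi_accuracy(bs, roi)
        assert acc == 1.0
        assert np.isclose(np.trace(cm.cells), 100.0)

    def test_shuffled_labels_near_chance(self):
        # balance-preserving null: labels permuted within each run so
        # every fold stays class-balanced (a global permutation would
        # unbalance training folds and bias CV accuracy below chance)
        rng = np.random.default_rng(7)
        accs = []
        for rep in range(200):
            bs = synthetic_beta_series(grid_shape=(1, 1, 2), n_words=3,
                                       seed=1000 + rep)
            meta = bs.meta.copy()
            for _, g in meta.groupby("run"):
                meta.loc[g.index, "speaker"] = rng.permutation(
                    g["speaker"].to_numpy()
                )
            feats = bs.betas.reshape(bs.betas.shape[0], -1)
            a, _ = vl.cross_validated_accuracy(feats, meta)
            accs.append(a)
        mean = np.mean(accs)
        sem = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 1.0 / 3.0) < 2 * sem + 0.01

    def test_accuracy_equals_confusion_trace(self):
        bs = synthetic_beta_series(grid_shape=(2, 2, 2), seed=9)
        feats = bs.betas.reshape(bs.betas.shape[0], -1)
        acc, cm = vl.cross_validated_accuracy(feats, bs.meta)
        assert np.isclose(acc, np.trace(cm.cells) / 100.0)
        assert np.isclose(cm.cells.sum(), 100.0)

    def test_missing_class_in_training_raises_fold_error(self):
        bs = synthetic_beta_series(grid_shape=(1, 1, 2), n_words=2)
        meta = bs.meta.copy()
        # put all of speaker anne into run 1: LORO fold 1 lacks anne
        meta.loc[meta["speaker"] == "anne", "run"] = 1
        feats = bs.betas.reshape(bs.betas.shape[0], -1)
        with pytest.raises(FoldError):
            vl.cross_validated_accuracy(feats, meta)


class TestSearchlight:
    def test_trial_order_shuffle_invariance(self):
        roi = np.zeros((3, 3, 1), dtype=bool)
        roi[1, 1, 0] = True
        bs = synthetic_beta_series(grid_shape=(3, 3, 1), signal=2.0,
                                   informative=roi, seed=21)
        base = vl.run_searchlight(bs, radius_mm=4.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(bs.meta))
        shuffled = vl.TrialBetaSeries(
            betas=bs.betas[perm],
            meta=bs.meta.iloc[perm].reset_index(drop=True),
            voxel_size=bs.voxel_size,
        )
        redo = vl.run_searchlight(shuffled, radius_mm=4.0)
        assert np.allclose(base, redo, equal_nan=True)

    def test_informative_roi_beats_surround(self):
        grid = (7, 7, 3)
        roi = np.zeros(grid, dtype=bool)
        roi[2:5, 2:5, 1] = True
        bs = synthetic_beta_series(grid_shape=grid, signal=2.0,
                                   informative=roi, seed=22)
        amap = vl.run_searchlight(bs, radius_mm=4.0)
        inside = np.nanmedian(amap[roi])
        outside = np.nanmedian(amap[~roi])
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(amap[roi].ravel(), amap[~roi].ravel(),
                            alternative="greater")
        assert inside > outside
        assert stat.pvalue < 0.01

    def test_against_nilearn_searchlight(self):
        """Independent cross-check: nilearn's SearchLight with an sklearn
        OvO SVC should agree with our implementation on LORO accuracy."""
        nilearn = pytest.importorskip("nilearn")
        import nibabel as nib
        from nilearn.decoding import SearchLight
        from sklearn.model_selection import LeaveOneGroupOut
        from sklearn.svm import SVC

        grid = (5, 5, 3)
        roi = np.zeros(grid, dtype=bool)
        roi[1:4, 1:4, 1] = True
        bs = synthetic_beta_series(grid_shape=grid, signal=1.5,
                                   informative=roi, seed=23, n_words=6)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        img = nib.Nifti1Image(
            np.moveaxis(bs.betas, 0, -1).astype(np.float32), affine
        )
        mask_img = nib.Nifti1Image(
            np.ones(grid, dtype=np.uint8), affine
        )
        y = bs.meta["speaker"].to_numpy()
        groups = bs.meta["run"].to_numpy()
        slight = SearchLight(
            mask_img, radius=6.0,
            estimator=SVC(kernel="linear", C=1.0,
                          decision_function_shape="ovo"),
            cv=LeaveOneGroupOut(), n_jobs=1,
        )
        slight.fit(img, y, groups=groups)
        ours = vl.run_searchlight(bs, radius_mm=6.0, boundary="inclusive")
        # nilearn averages per-fold scores; folds are balanced (36 trials
        # each) so pooled accuracy equals the fold average
        diff = np.abs(slight.scores_ - np.nan_to_num(ours))
        # tie-breaking may differ on vote cycles; demand near-exact match
        assert np.nanmean(diff) < 0.02
        assert np.nanmax(diff) < 0.06


class TestGroupLevelTTests:
    def test_identical_vectors_paired_t_zero(self):
        t, p = vl.scheme_comparison([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        assert t == 0.0 and p == 1.0

    def test_accuracies_at_chance_t_zero(self):
        t, _ = vl.one_sample_vs_chance(
            np.full(5, 100.0 / 3.0), chance=100.0 / 3.0
        )
        assert t == 0.0

    def test_hand_computed_one_sample_t(self):
        acc = np.array([40.0, 30.0, 50.0, 40.0])
        t, p = vl.one_sample_vs_chance(acc, chance=100.0 / 3.0)
        # mean 40, sd 8.165: t = 6.67 / (8.165 / 2) = 1.633
        assert np.isclose(t, 1.633, atol=1e-3)
        assert 0 < p < 1
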