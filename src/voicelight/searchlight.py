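"""Searchlight decoding of speaker identity from trial beta patterns.

A sphere (12 mm radius by default, ~900 voxels at 2 mm isotropic in an
unbounded mask) is centred at every voxel of the analysis mask; the betas
of all voxels in the sphere are the features of a one-vs-one soft-margin
SVM (C = 1) classifying the three speakers, evaluated under
leave-one-run-out (4 folds) or leave-one-word-out (12 folds)
cross-validation. The accuracy of each sphere is written to its centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .glm import TrialBetaSeries

CHANCE_LEVEL = 1.0 / 3.0

SCHEME_GROUP_KEY = {"loro": "run", "lowo": "word"}


class SearchlightError(ValueError):
    pass


class FoldError(SearchlightError):
    """A cross-validation fold lacks a class in its training set."""


@dataclass
class ConfusionMatrix3:
    """Presented x answered percentage table normalised to sum 100."""

    cells: np.ndarray  # (n_classes, n_classes) percentages
    n_trials: int
    labels: tuple = ()

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        if self.n_trials > 0 and not np.isclose(self.cells.sum(), 100.0):
            raise SearchlightError("confusion cells must sum to 100")
        if np.any(self.cells < 0):
            raise SearchlightError("confusion cells must be non-negative")

    @property
    def accuracy(self):
        return float(np.trace(self.cells)) / 100.0


class OvOVotingSVC(BaseEstimator, ClassifierMixin):
    """Multiclass SVM by one-vs-one reduction with majority voting.

    One binary soft-margin SVM is trained per class pair; at prediction
    each binary classifier votes and the class with most votes wins.
    Vote ties (e.g. a 3-cycle) are broken deterministically to the
    lexicographically smallest class label.

    Parameters
    ----------
    kernel : {"linear", "rbf"}
    C : float
        Soft-margin parameter (default 1).
    tie_break : {"lexicographic"}
    standardize : bool
        If True, per-feature standardisation is fit on the training data
        (off by default: raw betas are used).
    """

    def __init__(self, kernel="linear", C=1.0, tie_break="lexicographic",
                 standardize=False):
        self.kernel = kernel
        self.C = C
        self.tie_break = tie_break
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise SearchlightError("X must be (n_samples, n_features)")
        self.classes_ = np.unique(y)  # sorted -> lexicographic tie order
        if len(self.classes_) < 2:
            raise SearchlightError("need at least 2 classes to train")
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        thin = [c for c, n in counts.items() if n < 2]
        if thin:
            raise SearchlightError(
                f"classes with fewer than 2 training samples: {thin}"
            )
        if self.tie_break != "lexicographic":
            raise SearchlightError(f"unknown tie_break {self.tie_break!r}")
        self.scaler_ = None
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        self.pair_models_ = {}
        for i in range(len(self.classes_)):
            for j in range(i + 1, len(self.classes_)):
                a, b = self.classes_[i], self.classes_[j]
                sel = (y == a) | (y == b)
                clf = SVC(kernel=self.kernel, C=self.C, gamma="scale")
                clf.fit(X[sel], y[sel])
                self.pair_models_[(a, b)] = clf
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        votes = self.vote_counts(X)
        # argmax returns the first (lexicographically smallest) maximiser
        return self.classes_[np.argmax(votes, axis=1)]

    def vote_counts(self, X):
        """(n_samples, n_classes) pairwise vote tallies."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=int)
        index = {c: k for k, c in enumerate(self.classes_)}
        for (a, b), clf in self.pair_models_.items():
            pred = clf.predict(X)
            for k, p in enumerate(pred):
                votes[k, index[p]] += 1
        return votes


def ovo_predict(train_features, train_labels, test_features, kernel="linear",
                C=1.0, tie_break="lexicographic"):
    """Fit an OvO voting SVM and predict test labels (functional wrapper)."""
    clf = OvOVotingSVC(kernel=kernel, C=C, tie_break=tie_break)
    clf.fit(train_features, train_labels)
    return clf.predict(test_features)


def sphere_offsets(radius_mm, voxel_size_mm=(2.0, 2.0, 2.0),
                   boundary="exclusive"):
    """Integer voxel offsets within a sphere of physical radius.

    ``boundary`` "exclusive" keeps offsets with distance < r (895 voxels at
    r = 12 mm, 2 mm isotropic), "inclusive" uses <= r (925 voxels).
    """
    if boundary not in ("inclusive", "exclusive"):
        raise SearchlightError("boundary must be inclusive or exclusive")
    vs = np.asarray(voxel_size_mm, dtype=float)
    nmax = np.floor(radius_mm / vs).astype(int)
    ax = [np.arange(-n, n + 1) for n in nmax]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    d2 = (ii * vs[0]) ** 2 + (jj * vs[1]) ** 2 + (kk * vs[2]) ** 2
    keep = d2 <= radius_mm**2 if boundary == "inclusive" else d2 < radius_mm**2
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


def sphere_members(mask, center, radius_voxels=6, boundary="exclusive"):
    """Voxel indices of the sphere around ``center``, clipped to the mask.

    ``radius_voxels`` is in voxel units (isotropic); use
    :func:`sphere_offsets` for mm-specified anisotropic spheres.
    """
    mask = np.asarray(mask, dtype=bool)
    center = tuple(int(c) for c in center)
    if not mask[center]:
        raise SearchlightError("sphere center lies outside the mask")
    offs = sphere_offsets(radius_voxels, (1.0, 1.0, 1.0), boundary)
    pts = np.asarray(center)[None, :] + offs
    ok = np.all((pts >= 0) & (pts < np.asarray(mask.shape)[None, :]), axis=1)
    pts = pts[ok]
    inside = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
    pts = pts[inside]
    return tuple(pts.T)


def _cv_folds(meta: pd.DataFrame, scheme: str):
    key = SCHEME_GROUP_KEY.get(scheme)
    if key is None:
        raise SearchlightError(f"unknown CV scheme {scheme!r} (loro|lowo)")
    groups = meta[key].to_numpy()
    for g in sorted(pd.unique(groups)):
        yield g, groups != g, groups == g


def cross_validated_accuracy(features, meta, scheme="loro", kernel="linear",
                             C=1.0, standardize=False):
    """Pooled cross-validated accuracy and confusion matrix.

    LORO folds by run (4 folds); LOWO folds by word (12 folds: train on 11
    words x 3 speakers x all runs, test on the held-out word). Predictions
    are pooled over folds before computing accuracy, and the confusion
    matrix accumulates pooled counts normalised to percentages summing 100.
    """
    X = np.asarray(features, dtype=float)
    labels = meta["speaker"].to_numpy()
    classes = np.array(sorted(pd.unique(labels)))
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: k for k, c in enumerate(classes)}
    n_folds = 0
    for g, train, test in _cv_folds(meta, scheme):
        n_folds += 1
        train_classes = set(labels[train])
        if train_classes != set(classes):
            raise FoldError(
                f"fold {g!r}: training set missing classes "
                f"{set(classes) - train_classes}"
            )
        clf = OvOVotingSVC(kernel=kernel, C=C, standardize=standardize)
        pred = clf.fit(X[train], labels[train]).predict(X[test])
        for t, p in zip(labels[test], pred):
            counts[index[t], index[p]] += 1
    total = counts.sum()
    accuracy = float(np.trace(counts)) / total
    cm = ConfusionMatrix3(
        cells=100.0 * counts / total, n_trials=int(total),
        labels=tuple(classes),
    )
    assert np.isclose(cm.accuracy, accuracy)  # consistency identity
    return accuracy, cm


class SearchlightDecoder:
    """Map cross-validated decoding accuracy over a brain mask.

    sklearn-style estimator: construct with the analysis parameters, call
    ``fit(beta_series, mask)``, read ``accuracy_map_`` (3D, NaN outside the
    mask), ``chance_`` and ``flagged_small_spheres_``.
    """

    def __init__(self, radius_mm=12.0, scheme="loro", kernel="linear",
                 C=1.0, boundary="exclusive", min_sphere_voxels=10,
                 standardize=False):
        self.radius_mm = radius_mm
        self.scheme = scheme
        self.kernel = kernel
        self.C = C
        self.boundary = boundary
        self.min_sphere_voxels = min_sphere_voxels
        self.standardize = standardize

    def get_params(self, deep=True):
        return {
            "radius_mm": self.radius_mm, "scheme": self.scheme,
            "kernel": self.kernel, "C": self.C, "boundary": self.boundary,
            "min_sphere_voxels": self.min_sphere_voxels,
            "standardize": self.standardize,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, beta_series: TrialBetaSeries, mask=None):
        betas = beta_series.betas
        grid = beta_series.grid_shape
        if mask is None:
            mask = np.ones(grid, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SearchlightError("mask is empty")
        offs = sphere_offsets(self.radius_mm, beta_series.voxel_size,
                              self.boundary)
        shape = np.asarray(grid)
        acc = np.full(grid, np.nan)
        flagged, failed = [], []
        flat = betas.reshape(betas.shape[0], -1)
        mask_flat = mask.ravel()
        strides = np.array([grid[1] * grid[2], grid[2], 1])
        centers = np.argwhere(mask)
        off_lin = offs @ strides
        for c in centers:
            pts = c[None, :] + offs
            ok = np.all((pts >= 0) & (pts < shape[None, :]), axis=1)
            lin = (c @ strides) + off_lin[ok]
            lin = lin[mask_flat[lin]]
            if len(lin) < self.min_sphere_voxels:
                flagged.append(tuple(c))
            try:
                a, _ = cross_validated_accuracy(
                    flat[:, lin], beta_series.meta, scheme=self.scheme,
                    kernel=self.kernel, C=self.C,
                    standardize=self.standardize,
                )
            except FoldError as e:
                failed.append((tuple(c), str(e)))
                continue
            acc[tuple(c)] = a
        if failed:
            warnings.warn(f"{len(failed)} voxels skipped: fold errors",
                          RuntimeWarning)
        self.accuracy_map_ = acc
        self.chance_ = 1.0 / len(pd.unique(beta_series.meta["speaker"]))
        self.mask_ = mask
        self.flagged_small_spheres_ = flagged
        self.failed_voxels_ = failed
        return self


def run_searchlight(beta_series, mask=None, radius_mm=12.0, scheme="loro",
                    kernel="linear", C=1.0, boundary="exclusive",
                    standardize=False):
    """Functional wrapper over :class:`SearchlightDecoder`; returns the
    3D accuracy map (NaN outside the mask)."""
    sl = SearchlightDecoder(radius_mm=radius_mm, scheme=scheme,
                            kernel=kernel, C=C, boundary=boundary,
                            standardize=standardize)
    sl.fit(beta_series, mask)
    return sl.accuracy_map_


def roi_accuracy(beta_series, roi_mask, scheme="loro", kernel="linear",
                 C=1.0, standardize=False):
    """Decoding accuracy on all ROI voxels jointly (one value per subject)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise SearchlightError("ROI mask is empty")
    X = beta_series.betas[:, roi_mask]
    return cross_validated_accuracy(X, beta_series.meta, scheme=scheme,
                                    kernel=kernel, C=C,
                                    standardize=standardize)


def scheme_comparison(acc_a, acc_b):
    """Paired t-test between per-subject accuracies of two CV schemes."""
    acc_a, acc_b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if acc_a.shape != acc_b.shape or acc_a.size < 2:
        raise SearchlightError("need paired vectors of length >= 2")
    d = acc_a - acc_b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        warnings.warn("zero-variance non-zero difference", RuntimeWarning)
    t, p = stats.ttest_rel(acc_a, acc_b)
    return float(t), float(p)


def one_sample_vs_chance(acc, chance=100.0 / 3.0, alternative="greater"):
    """One-sample t-test of per-subject accuracies against chance."""
    acc = np.asarray(acc, dtype=float)
    if acc.size < 2:
        raise SearchlightError("need at least 2 subjects")
    if np.allclose(acc.std(ddof=1), 0.0):
        return (0.0, 1.0) if np.allclose(acc.mean(), chance) else \
            (np.inf if acc.mean() > chance else -np.inf, 0.0)
    t, p = stats.ttest_1samp(acc, chance, alternative=alternative)
    return float(t), float(p)
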