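"""Permutation-based group inference on accuracy maps.

Chance level is subtracted from each subject's accuracy map, the maps are
smoothed (8 mm FWHM Gaussian, mask-renormalised), and group effects are
assessed nonparametrically: a one-sample sign-flip test (random ±1 per
subject per permutation) or a covariate regression (covariate permuted
across subjects), both with voxel-level family-wise error control via the
permutation distribution of the image-wide maximum statistic. The identity
permutation is always included, so corrected p-values are bounded below by
1/n_permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

CHANCE_LEVEL = 1.0 / 3.0


class GroupInferenceError(ValueError):
    pass


@dataclass
class GroupStatMap:
    """Voxelwise statistic map with max-statistic FWE-corrected p-values."""

    stat: np.ndarray  # 3D, NaN outside mask
    p_fwe: np.ndarray  # 3D, NaN outside mask
    mask: np.ndarray
    n_permutations: int
    seed: int | None = None
    alpha: float = 0.05
    max_null: np.ndarray = None  # permutation distribution of the max

    def __post_init__(self):
        inside = self.mask
        p = self.p_fwe[inside]
        if p.size and (np.nanmin(p) < 1.0 / self.n_permutations - 1e-12
                       or np.nanmax(p) > 1.0 + 1e-12):
            raise GroupInferenceError(
                "p_fwe must lie in [1/n_permutations, 1]"
            )

    def significant(self, alpha=None):
        alpha = self.alpha if alpha is None else alpha
        out = np.zeros_like(self.mask, dtype=bool)
        out[self.mask] = self.p_fwe[self.mask] <= alpha
        return out


def subtract_chance(values, chance=CHANCE_LEVEL):
    """Centre an accuracy map at chance (33% for 3 balanced classes)."""
    return np.asarray(values, dtype=float) - chance


def gaussian_smooth(volume, fwhm_mm=8.0, voxel_size_mm=(2.0, 2.0, 2.0),
                    mask=None):
    """Separable Gaussian smoothing with mask renormalisation.

    sigma = FWHM / (2 * sqrt(2 * ln 2)) per axis, converted to voxels.
    Smoothing is renormalised by the smoothed mask so a constant map stays
    constant up to machine precision at mask boundaries; voxels outside
    the mask stay NaN.
    """
    if fwhm_mm < 0:
        raise GroupInferenceError("fwhm must be >= 0")
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = [
        fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
        for v in voxel_size_mm
    ]
    if mask is None:
        mask = np.isfinite(vol)
    mask = np.asarray(mask, dtype=bool)
    filled = np.where(mask, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out = np.full_like(vol, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[mask] = num[mask] / den[mask]
    return out


def _stack_maps(subject_maps, mask):
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 4:
        raise GroupInferenceError("subject maps must stack to 4D")
    data = maps[:, mask]
    if not np.isfinite(data).all():
        raise GroupInferenceError("non-finite values inside the mask")
    return data  # (n_subjects, n_voxels)


def _one_sample_t(data):
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.where(mean[sd == 0] > 0, np.inf,
                          np.where(mean[sd == 0] < 0, -np.inf, 0.0))
    return t


class SignFlipTest:
    """One-sample sign-flip permutation test with max-statistic FWE.

    Under the null each subject's (chance-centred) map is symmetric about
    zero, so its sign is exchangeable: every permutation randomly negates
    whole subject maps and recomputes the voxelwise one-sample t. The
    corrected p at a voxel is the fraction of permutations (identity
    included) whose image-wide maximum t reaches that voxel's observed t.
    """

    def __init__(self, n_permutations=5000, seed=0, alternative="greater",
                 alpha=0.05):
        self.n_permutations = n_permutations
        self.seed = seed
        self.alternative = alternative
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"n_permutations": self.n_permutations, "seed": self.seed,
                "alternative": self.alternative, "alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, subject_maps, mask=None):
        maps = np.asarray(subject_maps, dtype=float)
        if maps.shape[0] < 2:
            raise GroupInferenceError("need at least 2 subjects")
        if self.n_permutations < 1:
            raise GroupInferenceError("n_permutations must be >= 1")
        if mask is None:
            mask = np.all(np.isfinite(maps), axis=0)
        mask = np.asarray(mask, dtype=bool)
        data = _stack_maps(maps, mask)
        n = data.shape[0]
        t_obs = _one_sample_t(data)
        if self.alternative == "less":
            t_obs = -t_obs
            data = -data

        rng = np.random.default_rng(self.seed)
        max_null = np.empty(self.n_permutations)
        max_null[0] = t_obs.max()  # identity permutation
        for p in range(1, self.n_permutations):
            flips = rng.choice([-1.0, 1.0], size=n)
            max_null[p] = _one_sample_t(flips[:, None] * data).max()
        p_fwe = (
            (max_null[None, :] >= t_obs[:, None] - 1e-12).sum(axis=1)
            / self.n_permutations
        )

        stat3 = np.full(mask.shape, np.nan)
        p3 = np.full(mask.shape, np.nan)
        stat3[mask] = t_obs if self.alternative != "less" else -t_obs
        p3[mask] = p_fwe
        self.result_ = GroupStatMap(
            stat=stat3, p_fwe=p3, mask=mask,
            n_permutations=self.n_permutations, seed=self.seed,
            alpha=self.alpha, max_null=max_null,
        )
        return self


def signflip_onesample(subject_maps, n_permutations=5000, seed=0, mask=None,
                       alternative="greater", alpha=0.05) -> GroupStatMap:
    """Functional wrapper over :class:`SignFlipTest`."""
    est = SignFlipTest(n_permutations=n_permutations, seed=seed,
                       alternative=alternative, alpha=alpha)
    est.fit(subject_maps, mask=mask)
    return est.result_


def _slope_t(data, x):
    """Voxelwise t of the slope in y = a + b*x (x: per-subject covariate)."""
    n = len(x)
    xc = x - x.mean()
    sxx = np.sum(xc**2)
    b = (xc @ data) / sxx
    a = data.mean(axis=0) - b * x.mean()
    resid = data - a[None, :] - np.outer(x, b)
    df = n - 2
    s2 = (resid**2).sum(axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(s2 / sxx)
    bad = ~np.isfinite(t)
    if bad.any():  # zero residual variance: perfectly fit voxels
        t[bad] = np.sign(b[bad]) * np.inf
        t[bad & (b == 0)] = 0.0
    return t


class PermutationRegression:
    """Single-covariate permutation regression with max-statistic FWE.

    The observed statistic is the t of the covariate slope at each voxel;
    the null is built by permuting the covariate vector across subjects
    (identity permutation included). Spearman rank correlation (and its
    R^2) is reported descriptively per voxel.
    """

    def __init__(self, n_permutations=5000, seed=0, alternative="greater",
                 alpha=0.05):
        self.n_permutations = n_permutations
        self.seed = seed
        self.alternative = alternative
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"n_permutations": self.n_permutations, "seed": self.seed,
                "alternative": self.alternative, "alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, subject_maps, covariate, mask=None):
        maps = np.asarray(subject_maps, dtype=float)
        x = np.asarray(covariate, dtype=float)
        if maps.shape[0] != len(x):
            raise GroupInferenceError("covariate length != number of maps")
        if len(x) < 3:
            raise GroupInferenceError("need at least 3 subjects")
        if np.allclose(x, x[0]):
            raise GroupInferenceError("degenerate (constant) covariate")
        if self.n_permutations < 1:
            raise GroupInferenceError("n_permutations must be >= 1")
        if mask is None:
            mask = np.all(np.isfinite(maps), axis=0)
        mask = np.asarray(mask, dtype=bool)
        data = _stack_maps(maps, mask)

        t_obs = _slope_t(data, x)
        if self.alternative == "less":
            t_obs = -t_obs
            x_eff = -x
        else:
            x_eff = x

        rng = np.random.default_rng(self.seed)
        max_null = np.empty(self.n_permutations)
        max_null[0] = t_obs.max()
        for p in range(1, self.n_permutations):
            xp = rng.permutation(x_eff)
            max_null[p] = _slope_t(data, xp).max()
        p_fwe = (
            (max_null[None, :] >= t_obs[:, None] - 1e-12).sum(axis=1)
            / self.n_permutations
        )

        # descriptive Spearman R^2 per voxel
        rx = stats.rankdata(x)
        rd = np.apply_along_axis(stats.rankdata, 0, data)
        rxc = rx - rx.mean()
        rdc = rd - rd.mean(axis=0)
        denom = np.sqrt((rxc**2).sum() * (rdc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rxc @ rdc) / denom

        stat3 = np.full(mask.shape, np.nan)
        p3 = np.full(mask.shape, np.nan)
        r2 = np.full(mask.shape, np.nan)
        stat3[mask] = t_obs if self.alternative != "less" else -t_obs
        p3[mask] = p_fwe
        r2[mask] = rho**2
        self.spearman_r2_ = r2
        self.result_ = GroupStatMap(
            stat=stat3, p_fwe=p3, mask=mask,
            n_permutations=self.n_permutations, seed=self.seed,
            alpha=self.alpha, max_null=max_null,
        )
        return self


def permutation_regression(subject_maps, covariate, n_permutations=5000,
                           seed=0, mask=None, alternative="greater",
                           alpha=0.05) -> GroupStatMap:
    """Functional wrapper over :class:`PermutationRegression`."""
    est = PermutationRegression(n_permutations=n_permutations, seed=seed,
                                alternative=alternative, alpha=alpha)
    est.fit(subject_maps, covariate, mask=mask)
    return est.result_


def apply_explicit_mask(mask, sound_mask):
    """Restrict an analysis mask to sound-responsive voxels.

    Applied before the max-statistic computation: restriction can only
    shrink the permutation maximum, so corrected p-values inside the
    intersection are never larger than in the unmasked analysis.
    """
    mask = np.asarray(mask, dtype=bool)
    sound_mask = np.asarray(sound_mask, dtype=bool)
    if mask.shape != sound_mask.shape:
        raise GroupInferenceError("mask grids do not match")
    inter = mask & sound_mask
    if not inter.any():
        raise GroupInferenceError("empty mask intersection")
    return inter


def cluster_peaks(stat, threshold, voxel_size_mm=(2.0, 2.0, 2.0),
                  min_cluster_mm3=0.0, min_peak_separation_mm=8.0,
                  affine=None) -> pd.DataFrame:
    """Cluster the suprathreshold statistic map and report local maxima.

    Clusters use 26-connectivity; within each cluster, peaks are selected
    greedily in descending statistic order subject to pairwise separation
    strictly greater than ``min_peak_separation_mm``. Returns a table with
    one row per peak: mm coordinates, statistic, cluster id and size.
    """
    stat = np.asarray(stat, dtype=float)
    supra = np.nan_to_num(stat, nan=-np.inf) > threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_clusters = ndimage.label(supra, structure=structure)
    vs = np.asarray(voxel_size_mm, dtype=float)
    voxel_vol = float(np.prod(vs))
    if affine is None:
        affine = np.diag(list(vs) + [1.0])
    rows = []
    for cid in range(1, n_clusters + 1):
        voxels = np.argwhere(labels == cid)
        size_vox = len(voxels)
        if size_vox * voxel_vol < min_cluster_mm3:
            continue
        vals = stat[tuple(voxels.T)]
        order = np.argsort(vals)[::-1]
        kept_mm = []
        for k in order:
            xyz = voxels[k]
            mm = (affine @ np.append(xyz, 1.0))[:3]
            if all(np.linalg.norm(mm - q) > min_peak_separation_mm
                   for q in kept_mm):
                kept_mm.append(mm)
                rows.append(
                    {
                        "x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
                        "stat": vals[k], "cluster_id": cid,
                        "cluster_size_vox": size_vox,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["x_mm", "y_mm", "z_mm", "stat", "cluster_id",
                       "cluster_size_vox"],
    )
    return df.sort_values("stat", ascending=False).reset_index(drop=True) \
        if len(df) else df
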