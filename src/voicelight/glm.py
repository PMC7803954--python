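"""Single-trial (beta-series) GLM for event-related BOLD runs.

The multivariate first-level model contains one HRF-convolved boxcar
regressor per trial (36 per run), one zero-duration stick regressor for the
button press, optional nuisance columns, a discrete-cosine high-pass basis
(cutoff 128 s) and a constant. All trials of a run are estimated jointly
(least-squares-all), and only the per-trial coefficients are returned as
the decoding feature store.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class GlmError(ValueError):
    pass


@dataclass
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    sampling_dt: float = 0.1

    def __post_init__(self):
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "peak_undershoot_ratio",
            "sampling_dt",
        ):
            if getattr(self, name) <= 0:
                raise GlmError(f"{name} must be positive")


def canonical_hrf(params: HrfParams | None = None, duration: float = 32.0):
    """Sample the canonical double-gamma HRF on [0, duration].

    h(t) = Gamma_pdf(t; peak) - Gamma_pdf(t; undershoot) / ratio, with
    gamma shape = delay / dispersion and scale = dispersion. h(0) = 0.
    Returns (t, kernel).
    """
    params = params or HrfParams()
    if duration <= 0:
        raise GlmError("duration must be positive")
    t = np.arange(0.0, duration + params.sampling_dt / 2, params.sampling_dt)
    peak = stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    return t, peak - under / params.peak_undershoot_ratio


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float = 128.0):
    """Orthonormal discrete-cosine basis for drift with period > cutoff.

    Column k (k = 1..K, K = floor(2 * N * TR / cutoff)) is
    sqrt(2/N) * cos(pi * (2n + 1) * k / (2N)); the constant term is
    excluded (the design carries its own intercept).
    """
    n = np.arange(n_volumes)
    k_max = int(np.floor(2.0 * n_volumes * tr / cutoff))
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    values: np.ndarray  # (n_volumes, n_regressors)
    names: list
    trial_columns: np.ndarray  # indices of single-trial regressors
    hp_cutoff: float

    def __post_init__(self):
        if len(self.names) != self.values.shape[1]:
            raise GlmError("names length must match regressor count")
        if len(set(self.names)) != len(self.names):
            raise GlmError("regressor names must be unique")
        if np.any(np.all(self.values == 0, axis=0)):
            raise GlmError("design contains an all-zero column")


def _convolved_regressor(onsets, durations, amplitudes, n_volumes, tr, kernel, dt):
    """HRF-convolve impulse/boxcar trains on a dt grid, sample at volume times."""
    n_fine = int(np.ceil(n_volumes * tr / dt)) + len(kernel)
    x = np.zeros(n_fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))  # 0-duration -> stick
        x[i0:i1] += amp
    conv = np.convolve(x, kernel)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[vol_idx]


def build_design_matrix(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    hrf: HrfParams | None = None,
    hp_cutoff: float = 128.0,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Build the single-run, single-trial design matrix.

    Columns: one HRF-convolved boxcar per trial (stimulus duration), one
    response-stick regressor (duration 0, at the response instant; trials
    with a missing response contribute nothing to it), any nuisance columns,
    the DCT high-pass basis, and a constant.
    """
    hrf = hrf or HrfParams()
    dt = hrf.sampling_dt
    _, kernel = canonical_hrf(hrf)
    run_len = n_volumes * tr

    events = events.sort_values("onset").reset_index(drop=True)
    if len(events) and events["onset"].iloc[-1] >= run_len:
        raise GlmError("event onset beyond the end of the run")
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.ndim == 1:
            nuisance = nuisance[:, None]
        if nuisance.shape[0] != n_volumes:
            raise GlmError("nuisance row count must equal n_volumes")

    cols, names = [], []
    for i, trial in events.iterrows():
        cols.append(
            _convolved_regressor(
                [trial["onset"]], [trial["duration"]], [1.0],
                n_volumes, tr, kernel, dt,
            )
        )
        names.append(f"trial_{i:03d}_{trial['speaker']}_{trial['word']}")
    trial_columns = np.arange(len(cols))

    if len(events):
        answered = events[~events["missing"].astype(bool)]
        resp_times = (answered["onset"] + answered["response_time"]).to_numpy()
        resp_times = resp_times[resp_times < run_len]
        if len(resp_times):
            cols.append(
                _convolved_regressor(
                    resp_times, np.zeros(len(resp_times)),
                    np.full(len(resp_times), 1.0 / dt),
                    n_volumes, tr, kernel, dt,
                )
            )
            names.append("response")

    if nuisance is not None and nuisance.shape[1]:
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(f"nuisance_{j:02d}")

    dct = dct_highpass_basis(n_volumes, tr, hp_cutoff)
    for j in range(dct.shape[1]):
        cols.append(dct[:, j])
        names.append(f"dct_{j + 1:03d}")

    cols.append(np.ones(n_volumes))
    names.append("constant")

    return DesignMatrix(
        values=np.column_stack(cols),
        names=names,
        trial_columns=trial_columns,
        hp_cutoff=hp_cutoff,
    )


@dataclass
class TrialBetaSeries:
    """Per-trial coefficient volumes with aligned trial metadata."""

    betas: np.ndarray  # (n_trials, nx, ny, nz)
    meta: pd.DataFrame  # columns speaker, word, run
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: tuple = (2.0, 2.0, 2.0)

    def __post_init__(self):
        if len(self.meta) != self.betas.shape[0]:
            raise GlmError("meta length must equal the number of beta volumes")

    @property
    def grid_shape(self):
        return self.betas.shape[1:]

    def features(self, voxel_index_tuple):
        """(n_trials, n_voxels) feature matrix at the given voxel indices."""
        return self.betas[(slice(None),) + voxel_index_tuple]

    def concat(self, other: "TrialBetaSeries") -> "TrialBetaSeries":
        if self.grid_shape != other.grid_shape:
            raise GlmError("grids do not match")
        return TrialBetaSeries(
            betas=np.concatenate([self.betas, other.betas], axis=0),
            meta=pd.concat([self.meta, other.meta], ignore_index=True),
            affine=self.affine,
            voxel_size=self.voxel_size,
        )


class TrialBetaGLM:
    """Estimator for single-trial betas from one run (sklearn-style).

    Parameters mirror the first-level model: HRF shape, high-pass cutoff
    and an optional AR(1) pre-whitening pass. ``fit`` consumes the 4D run
    and its event table; fitted attributes carry the design, the beta
    series and a rank report.
    """

    def __init__(self, hrf=None, hp_cutoff=128.0, ar1=False):
        self.hrf = hrf
        self.hp_cutoff = hp_cutoff
        self.ar1 = ar1

    def get_params(self, deep=True):
        return {"hrf": self.hrf, "hp_cutoff": self.hp_cutoff, "ar1": self.ar1}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, run, events, tr, mask=None, nuisance=None,
            affine=None, voxel_size=(2.0, 2.0, 2.0)):
        run = np.asarray(run, dtype=float)
        if run.ndim != 4:
            raise GlmError("run must be a 4D (x, y, z, t) array")
        n_volumes = run.shape[-1]
        design = build_design_matrix(
            events, n_volumes, tr, hrf=self.hrf,
            hp_cutoff=self.hp_cutoff, nuisance=nuisance,
        )
        X = design.values
        grid = run.shape[:3]
        if mask is None:
            mask = np.ones(grid, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        Y = run[mask].T  # (T, V)

        rank = np.linalg.matrix_rank(X)
        self.dropped_columns_ = []
        if rank < X.shape[1]:
            # QR with column pivoting to name the dependent columns
            from scipy.linalg import qr as _qr

            _, _, piv = _qr(X, mode="economic", pivoting=True)
            dependent = piv[rank:]
            self.dropped_columns_ = [design.names[j] for j in dependent]
            warnings.warn(
                f"rank-deficient design ({rank}/{X.shape[1]}); "
                f"dependent columns: {self.dropped_columns_}",
                RuntimeWarning,
            )

        beta = np.linalg.pinv(X) @ Y
        if self.ar1:
            resid = Y - X @ beta
            num = np.sum(resid[1:] * resid[:-1])
            den = np.sum(resid[:-1] ** 2)
            rho = 0.0 if den == 0 else float(np.clip(num / den, -0.99, 0.99))
            Wy = Y[1:] - rho * Y[:-1]
            Wx = X[1:] - rho * X[:-1]
            beta = np.linalg.pinv(Wx) @ Wy
            self.ar1_rho_ = rho

        trial_beta = beta[design.trial_columns]  # (n_trials, V)
        vols = np.zeros((len(design.trial_columns),) + grid)
        vols[:, mask] = trial_beta

        events = events.sort_values("onset").reset_index(drop=True)
        meta = events[["speaker", "word", "run"]].copy()
        self.design_ = design
        self.mask_ = mask
        self.beta_series_ = TrialBetaSeries(
            betas=vols,
            meta=meta,
            affine=np.eye(4) if affine is None else affine,
            voxel_size=voxel_size,
        )
        return self


def fit_betas(run, events, tr, mask=None, nuisance=None, hrf=None,
              hp_cutoff=128.0, ar1=False, **kwargs) -> TrialBetaSeries:
    """Functional wrapper over :class:`TrialBetaGLM`."""
    est = TrialBetaGLM(hrf=hrf, hp_cutoff=hp_cutoff, ar1=ar1)
    est.fit(run, events, tr, mask=mask, nuisance=nuisance, **kwargs)
    return est.beta_series_


def one_sample_contrast_tmap(volumes):
    """Voxelwise one-sample t over subjects: t = mean / (sd / sqrt(n)).

    Zero-variance voxels get signed infinity (nan when the mean is also 0)
    and are reported through the returned ``degenerate`` mask.
    Returns (tmap, df, degenerate_mask).
    """
    vols = np.asarray(volumes, dtype=float)
    n = vols.shape[0]
    if n < 2:
        raise GlmError("need at least 2 subjects")
    mean = vols.mean(axis=0)
    sd = vols.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate & (mean > 0)] = np.inf
    t[degenerate & (mean < 0)] = -np.inf
    t[degenerate & (mean == 0)] = np.nan
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance voxels in t-map",
            RuntimeWarning,
        )
    return t, n - 1, degenerate


def threshold_mask(tmap, df, p_uncorrected=0.001):
    """One-sided suprathreshold mask: voxels with P(T_df > t) < p."""
    if df < 1:
        raise GlmError("df must be >= 1")
    t_crit = stats.t.isf(p_uncorrected, df)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(tmap, nan=-np.inf) > t_crit
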