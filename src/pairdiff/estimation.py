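"""Pattern estimation: HRF convolution, design matrices, high-pass
filtering, (prewhitened) GLM fitting, localizer contrasts and voxel
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

if TYPE_CHECKING:  # pragma: no cover
    from .design import TrialSequence
    from .synth.bold import BoldTimeseries

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "PatternEstimates",
    "SelectivityMap",
    "RoiMask",
    "scene_events",
    "build_design_matrix",
    "highpass_filter",
    "fit_glm",
    "combine_runs_fixed_effects",
    "localizer_contrast",
    "select_voxels",
]

T_CAP = 1e6  # reported |t| for zero-residual fits


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF: positive gamma peaking at ~5 s minus
    a scaled undershoot gamma, normalized to unit peak amplitude."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    dt: float = 0.1  # sampling resolution for boxcar convolution
    length: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion", "undershoot_dispersion", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def _raw(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        pos = gamma_dist.pdf(t, self.peak_delay / self.peak_dispersion, scale=self.peak_dispersion)
        neg = gamma_dist.pdf(
            t, self.undershoot_delay / self.undershoot_dispersion, scale=self.undershoot_dispersion
        )
        out = pos - self.undershoot_ratio * neg
        return np.where(t < 0, 0.0, out)

    @property
    def _peak(self) -> float:
        grid = np.arange(0.0, self.length, self.dt)
        return float(self._raw(grid).max())

    def sample(self, t: np.ndarray) -> np.ndarray:
        """HRF values at times ``t`` (seconds), peak-normalized to 1."""
        return self._raw(t) / self._peak


@dataclass(frozen=True)
class DesignMatrix:
    """Timepoints x regressors matrix with named columns."""

    matrix: np.ndarray
    names: tuple[str, ...]
    tr: float
    run_index: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count must match names")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass(frozen=True)
class PatternEstimates:
    """Per-regressor beta / se / t maps over voxels.

    ``tmap`` equals ``beta / se`` elementwise where ``se > 0``; zero-se
    (noiseless) entries are capped at +-``T_CAP`` and flagged in
    ``tmap_capped``.  ``cov_unscaled`` is (p, p) (shared) or (V, p, p)
    (per voxel, prewhitened) such that ``var(beta_j) = cov[j, j] *
    sigma2``; kept so contrasts can be formed downstream.
    """

    names: tuple[str, ...]
    beta: np.ndarray  # (p, V)
    se: np.ndarray
    tmap: np.ndarray
    dof: float
    sigma2: np.ndarray = field(repr=False)  # (V,)
    cov_unscaled: np.ndarray = field(repr=False)
    tmap_capped: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def subset(self, names: Sequence[str]) -> "PatternEstimates":
        idx = [self.names.index(n) for n in names]
        cov = self.cov_unscaled
        cov_sub = cov[np.ix_(idx, idx)] if cov.ndim == 2 else cov[:, idx][:, :, idx]
        return PatternEstimates(
            names=tuple(names),
            beta=self.beta[idx],
            se=self.se[idx],
            tmap=self.tmap[idx],
            dof=self.dof,
            sigma2=self.sigma2,
            cov_unscaled=cov_sub,
            tmap_capped=self.tmap_capped[idx] if self.tmap_capped is not None else None,
        )


@dataclass(frozen=True)
class SelectivityMap:
    """Per-voxel contrast z-statistic (e.g. scenes > faces & objects)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.z).all():
            raise ValueError("selectivity map must be finite")


@dataclass(frozen=True)
class RoiMask:
    mask: np.ndarray
    label: str = "roi"
    tercile: int | None = None  # 1 = least selective .. 3 = most

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def scene_events(sequence: "TrialSequence", run: int) -> pd.DataFrame:
    """Tidy event table (onset, duration, name) for the scene trials of
    one run of a TrialSequence."""
    df = sequence.run(run)
    df = df[df["kind"] == "scene"]
    return pd.DataFrame(
        {"onset": df["onset"].to_numpy(), "duration": df["duration"].to_numpy(), "name": df["scene_id"].to_numpy()}
    )


def build_design_matrix(
    events: pd.DataFrame,
    hrf: HRFSpec,
    tr: float,
    n_timepoints: int,
    events_as: str = "impulse",
    add_intercept: bool = True,
    run_index: int = 0,
) -> DesignMatrix:
    """Convolve per-name event trains with the HRF sampled at TR.

    ``events`` columns: onset (s), name, and duration (s; used in
    ``boxcar`` mode).  Impulse mode evaluates the HRF directly at
    ``t - onset`` (exact); boxcar mode convolves a 0/1 block with the
    HRF on the fine ``hrf.dt`` grid and resamples at the TR grid.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if events_as not in ("impulse", "boxcar"):
        raise ValueError(f"events_as must be 'impulse' or 'boxcar', got {events_as!r}")
    scan_end = n_timepoints * tr
    if (events["onset"] < 0).any() or (events["onset"] >= scan_end).any():
        bad = events.loc[(events["onset"] < 0) | (events["onset"] >= scan_end), "onset"]
        raise ValueError(f"event onsets outside scan window [0, {scan_end}): {list(bad)}")

    t_grid = np.arange(n_timepoints) * tr
    names = list(dict.fromkeys(events["name"]))
    cols = np.zeros((n_timepoints, len(names)))
    if events_as == "impulse":
        for j, name in enumerate(names):
            for onset in events.loc[events["name"] == name, "onset"]:
                cols[:, j] += hrf.sample(t_grid - onset)
    else:
        # exact boxcar convolution: difference of the HRF's running
        # integral at the block's start and end
        fine_t = np.arange(0.0, hrf.length + hrf.dt, hrf.dt)
        fine_h = hrf.sample(fine_t)
        cum = np.concatenate([[0.0], np.cumsum((fine_h[1:] + fine_h[:-1]) / 2.0) * hrf.dt])

        def integral(x: np.ndarray) -> np.ndarray:
            return np.interp(np.clip(x, 0.0, hrf.length), fine_t, cum)

        for j, name in enumerate(names):
            sel = events["name"] == name
            for onset, dur in zip(events.loc[sel, "onset"], events.loc[sel, "duration"]):
                cols[:, j] += integral(t_grid - onset) - integral(t_grid - onset - dur)

    if (np.abs(cols).max(axis=0) == 0).any():
        zero = [names[j] for j in np.flatnonzero(np.abs(cols).max(axis=0) == 0)]
        raise ValueError(f"all-zero event regressors: {zero}")

    if add_intercept:
        cols = np.column_stack([cols, np.ones(n_timepoints)])
        names = names + ["intercept"]
    return DesignMatrix(matrix=cols, names=tuple(names), tr=tr, run_index=run_index)


def _gaussian_line_smoother(n: int, sigma_vols: float) -> np.ndarray:
    """Row-stochastic smoother: row t holds the weights that evaluate a
    Gaussian-weighted least-squares line fit at timepoint t."""
    t = np.arange(n, dtype=float)
    S = np.empty((n, n))
    for i in range(n):
        w = np.exp(-0.5 * ((t - t[i]) / sigma_vols) ** 2)
        sw = w.sum()
        tbar = (w * t).sum() / sw
        var = (w * (t - tbar) ** 2).sum()
        S[i] = w / sw + (t[i] - tbar) * w * (t - tbar) / var
    return S


def highpass_filter(timeseries, sigma: float, tr: float | None = None):
    """Remove a Gaussian-weighted local linear trend (scale ``sigma`` in
    seconds) from each voxel's time-series.

    Accepts a BoldTimeseries (returns the same type) or a (voxels,
    timepoints) array with an explicit ``tr``.  Constants and exact
    linear ramps map to (numerically) zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    from .synth.bold import BoldTimeseries  # local import to avoid cycle

    if isinstance(timeseries, BoldTimeseries):
        data, tr_ = timeseries.data, timeseries.tr
    else:
        if tr is None:
            raise ValueError("tr is required when passing a raw array")
        data, tr_ = np.asarray(timeseries, dtype=float), tr
    S = _gaussian_line_smoother(data.shape[1], sigma / tr_)
    filtered = data - data @ S.T
    if isinstance(timeseries, BoldTimeseries):
        return BoldTimeseries(data=filtered, tr=tr_, run_index=timeseries.run_index)
    return filtered


class RankDeficientDesignError(ValueError):
    pass


def _check_rank(design: DesignMatrix) -> None:
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR flags the dependent columns by small diagonal of R
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        collinear = [design.names[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
        raise RankDeficientDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}"
        )


def _capped_t(beta: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tiny = np.finfo(float).tiny
    zero_se = se <= math.sqrt(tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, np.sign(beta) * T_CAP, beta / np.where(zero_se, 1.0, se))
    capped = zero_se | (np.abs(t) >= T_CAP)
    t = np.clip(t, -T_CAP, T_CAP)
    return t, capped


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form OLS.  Returns beta (p, V), sigma2 (V,), cov_unscaled
    (p, p), residuals (n, V)."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    return beta, sigma2, XtX_inv, resid


def _lag1_autocorr(resid: np.ndarray) -> np.ndarray:
    """Per-voxel lag-1 autocorrelation of (n, V) residuals."""
    r = resid - resid.mean(axis=0)
    num = (r[1:] * r[:-1]).sum(axis=0)
    den = (r**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, -0.95, 0.95)


def fit_glm(
    timeseries,
    design,
    prewhiten: str = "ar1",
) -> PatternEstimates:
    """Fit a voxelwise GLM; lists of runs are combined with fixed
    effects (inverse-variance weighting of run-level betas).

    ``prewhiten='none'`` is ordinary least squares; ``'ar1'`` estimates
    a per-voxel AR(1) coefficient from the OLS residuals, transforms
    model and data exactly (first observation scaled by sqrt(1-phi^2)),
    and re-fits — a local-autocorrelation-correction approximation.
    """
    if isinstance(timeseries, (list, tuple)):
        if not isinstance(design, (list, tuple)) or len(design) != len(timeseries):
            raise ValueError("need one design per run")
        fits = [fit_glm(ts, d, prewhiten=prewhiten) for ts, d in zip(timeseries, design)]
        return combine_runs_fixed_effects(fits)
    if prewhiten not in ("none", "ar1"):
        raise ValueError(f"prewhiten must be 'none' or 'ar1', got {prewhiten!r}")

    from .synth.bold import BoldTimeseries

    data = timeseries.data if isinstance(timeseries, BoldTimeseries) else np.asarray(timeseries)
    X = design.matrix
    if data.shape[1] != X.shape[0]:
        raise ValueError(
            f"timepoints mismatch: data has {data.shape[1]}, design has {X.shape[0]}"
        )
    _check_rank(design)
    Y = data.T  # (n, V)
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")

    beta, sigma2, cov_unscaled, resid = _ols(X, Y)

    if prewhiten == "ar1":
        phi = _lag1_autocorr(resid)  # (V,)
        V = Y.shape[1]
        Xlag = np.vstack([np.zeros((1, p)), X[:-1]])
        Ylag = np.vstack([np.zeros((1, V)), Y[:-1]])
        Xs = X[None, :, :] - phi[:, None, None] * Xlag[None, :, :]  # (V, n, p)
        Ys = (Y - phi[None, :] * Ylag).T  # (V, n)
        scale = np.sqrt(1.0 - phi**2)
        Xs[:, 0, :] = scale[:, None] * X[0][None, :]
        Ys[:, 0] = scale * Y[0]
        XtX = np.einsum("vnp,vnq->vpq", Xs, Xs)
        XtY = np.einsum("vnp,vn->vp", Xs, Ys)
        cov_unscaled = np.linalg.inv(XtX)  # (V, p, p)
        beta = np.einsum("vpq,vq->vp", cov_unscaled, XtY).T  # (p, V)
        resid_w = Ys - np.einsum("vnp,pv->vn", Xs, beta)
        sigma2 = (resid_w**2).sum(axis=1) / dof
        se = np.sqrt(np.einsum("vpp->vp", cov_unscaled).T * sigma2[None, :])
    else:
        se = np.sqrt(np.diag(cov_unscaled)[:, None] * sigma2[None, :])

    tmap, capped = _capped_t(beta, se)
    return PatternEstimates(
        names=design.names,
        beta=beta,
        se=se,
        tmap=tmap,
        dof=float(dof),
        sigma2=sigma2,
        cov_unscaled=cov_unscaled,
        tmap_capped=capped,
    )


def combine_runs_fixed_effects(fits: Sequence[PatternEstimates]) -> PatternEstimates:
    """Inverse-variance weighted combination of run-level estimates."""
    names = fits[0].names
    for f in fits[1:]:
        if set(f.names) != set(names):
            raise ValueError("runs must share regressor names to combine")
    fits = [f if f.names == names else f.subset(names) for f in fits]
    betas = np.stack([f.beta for f in fits])  # (R, p, V)
    ses = np.stack([f.se for f in fits])
    zero = ses <= 0
    w = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, ses**2))
    sum_w = w.sum(axis=0)
    any_zero = zero.any(axis=0)  # infinite-precision runs dominate
    beta_zero = np.where(zero, betas, 0.0).sum(axis=0) / np.maximum(zero.sum(axis=0), 1)
    beta_w = (w * betas).sum(axis=0) / np.where(sum_w > 0, sum_w, 1.0)
    beta_fe = np.where(any_zero, beta_zero, beta_w)
    se_fe = np.where(any_zero, 0.0, 1.0 / np.sqrt(np.where(sum_w > 0, sum_w, 1.0)))
    dof = float(sum(f.dof for f in fits))
    tmap, capped = _capped_t(beta_fe, se_fe)
    sigma2 = np.mean([f.sigma2 for f in fits], axis=0)
    return PatternEstimates(
        names=names,
        beta=beta_fe,
        se=se_fe,
        tmap=tmap,
        dof=dof,
        sigma2=sigma2,
        cov_unscaled=fits[0].cov_unscaled,
        tmap_capped=capped,
    )


def localizer_contrast(
    estimates: PatternEstimates, weights: Mapping[str, float]
) -> SelectivityMap:
    """Per-voxel z-statistic for a zero-sum contrast over category
    regressors (e.g. scenes +1, faces -0.5, objects -0.5)."""
    total = sum(weights.values())
    if abs(total) > 1e-12:
        raise ValueError(f"contrast weights must sum to 0, got {total}")
    c = np.zeros(len(estimates.names))
    for name, w in weights.items():
        if name not in estimates.names:
            raise ValueError(f"unknown regressor {name!r}")
        c[estimates.names.index(name)] = w
    effect = c @ estimates.beta  # (V,)
    cov = estimates.cov_unscaled
    if cov.ndim == 2:
        var_unscaled = float(c @ cov @ c)
        var = var_unscaled * estimates.sigma2
    else:
        var = np.einsum("p,vpq,q->v", c, cov, c) * estimates.sigma2
    z, _ = _capped_t(effect, np.sqrt(var))
    return SelectivityMap(z=z)


def select_voxels(
    selectivity: SelectivityMap,
    mode: str = "threshold",
    z_min: float | None = None,
    label: str = "roi",
):
    """Select voxels by selectivity.

    ``threshold`` keeps voxels with z strictly greater than ``z_min``;
    ``tercile`` partitions by rank into three near-equal groups (extra
    voxels assigned to the lower, least-selective terciles; ties broken
    by voxel index).  Returns a RoiMask, or a list of three for terciles.
    """
    z = selectivity.z
    if mode == "threshold":
        if z_min is None:
            raise ValueError("z_min required for threshold mode")
        mask = z > z_min
        if not mask.any():
            raise ValueError(
                f"no voxels with z > {z_min}; a lower threshold is necessary "
                "to yield enough voxels to analyse"
            )
        return RoiMask(mask=mask, label=label)
    if mode == "tercile":
        n = z.size
        if n < 3:
            raise ValueError("tercile mode needs at least 3 voxels")
        order = np.argsort(z, kind="stable")  # least -> most selective
        base, rem = divmod(n, 3)
        sizes = [base + (1 if k < rem else 0) for k in range(3)]
        masks = []
        start = 0
        for k, size in enumerate(sizes):
            mask = np.zeros(n, dtype=bool)
            mask[order[start : start + size]] = True
            masks.append(RoiMask(mask=mask, label=f"{label}_tercile{k + 1}", tercile=k + 1))
            start += size
        return masks
    raise ValueError(f"unknown mode {mode!r}")
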