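"""Event-related per-voxel GLM with AR(1) prewhitening.

Preprocessing follows the standard event-related pipeline: the first five
volumes are discarded, images are smoothed with a small (0.5 mm FWHM)
Gaussian kernel and high-pass filtered with a discrete-cosine basis
(cutoff 1/128 s). Regressors are built by convolving the binarized
slow-wave vector with a hemodynamic response kernel. Serial correlation is
handled by a single pooled AR(1) coefficient estimated from the lag-1
autocorrelation of the OLS residuals, followed by Cochrane-Orcutt
prewhitening and a refit. F maps come from extra-sum-of-squares tests, t
maps from linear contrasts with family-wise error control by Bonferroni
over the in-mask voxels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats

from swbold.types import BoldSession, GlmResult, SlowWaveVector

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def dct_highpass_basis(n_volumes: int, tr_s: float, cutoff_s: float) -> np.ndarray | None:
    """Orthonormal discrete-cosine regressors with periods above ``cutoff_s``."""
    k_max = int(np.floor(2.0 * n_volumes * tr_s / cutoff_s))
    if k_max < 1:
        return None
    v = np.arange(n_volumes)
    K = np.stack(
        [np.cos(np.pi * k * (2 * v + 1) / (2 * n_volumes)) for k in range(1, k_max + 1)],
        axis=1,
    )
    return K / np.linalg.norm(K, axis=0)


def preprocess_bold(raw: BoldSession, fwhm_mm: float = 0.5,
                    highpass_cutoff_s: float = 128.0,
                    n_discard: int = 5) -> BoldSession:
    """Discard initial volumes, smooth spatially, high-pass per voxel.

    Smoothing uses a Gaussian kernel of ``fwhm_mm`` converted to voxel
    units through the header geometry (skipped with a warning when the
    kernel would be much smaller than a voxel). The high pass projects out
    discrete-cosine regressors with periods longer than
    ``highpass_cutoff_s``, keeping the voxel mean.
    """
    if raw.n_volumes < n_discard + 40:
        raise ValueError("session too short for discard + FIR window")
    data = raw.data[..., n_discard:].copy()

    sigmas = np.array([fwhm_mm * FWHM_TO_SIGMA / v for v in raw.voxel_size_mm])
    if fwhm_mm < min(raw.voxel_size_mm) / 4.0:
        warnings.warn("smoothing kernel much smaller than a voxel; skipped")
    else:
        T = data.shape[3]
        for v in range(T):
            data[..., v] = ndimage.gaussian_filter(data[..., v], sigmas)

    T = data.shape[3]
    K = dct_highpass_basis(T, raw.tr_s, highpass_cutoff_s)
    if K is not None:
        flat = data.reshape(-1, T).T                     # (T, n_vox)
        flat -= K @ (K.T @ flat)
        data = flat.T.reshape(data.shape)

    return BoldSession(
        data=data,
        tr_s=raw.tr_s,
        voxel_size_mm=raw.voxel_size_mm,
        brain_mask=raw.brain_mask,
        n_discarded=raw.n_discarded + n_discard,
        highpass_cutoff_s=highpass_cutoff_s if K is not None else None,
    )


def make_regressor(sw: SlowWaveVector, hrf: np.ndarray,
                   model: str = "boxcar",
                   onset_volumes: np.ndarray | None = None) -> np.ndarray:
    """Convolve the slow-wave vector with an HRF sampled at the TR.

    ``model="boxcar"`` convolves the full binarized event vector (onsets
    and durations); ``model="impulse"`` uses onset deltas only. Onsets
    default to starts of runs of ones; pass ``onset_volumes`` when long
    event durations make consecutive events' volumes touch. The regressor
    is truncated to the session length and mean-centered.
    """
    if sw.bins.sum() == 0:
        raise ValueError("slow-wave vector contains no events")
    if model == "boxcar":
        neural = sw.bins.astype(float)
    elif model == "impulse":
        neural = np.zeros(sw.n_volumes)
        onsets = sw.onset_volumes if onset_volumes is None else np.asarray(onset_volumes, dtype=int)
        np.add.at(neural, onsets, 1.0)
    else:
        raise ValueError(f"unknown regressor model {model!r}")
    reg = np.convolve(neural, np.asarray(hrf, dtype=float))[: sw.n_volumes]
    return reg - reg.mean()


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(f"collinear regressors: {names[i]!r} and {names[j]!r}")


def fit_glm(bold: BoldSession, regressors: np.ndarray,
            ar1: str | float = "auto",
            regressor_names: list[str] | None = None) -> GlmResult:
    """Per-voxel GLM in percent signal change with AR(1) prewhitening.

    The data are scaled to percent of each voxel's temporal mean, an
    intercept is prepended, and an initial OLS fit provides residuals from
    which a single pooled lag-1 autocorrelation ``rho`` is estimated
    (``ar1="auto"``; pass a float to fix it, or 0 to disable whitening).
    Data and design are then Cochrane-Orcutt transformed
    (``y_t - rho*y_{t-1}``, first row scaled by sqrt(1-rho^2)) and refitted.
    """
    X0 = np.atleast_2d(np.asarray(regressors, dtype=float))
    if X0.shape[0] != bold.n_volumes:
        X0 = X0.T
    if X0.shape[0] != bold.n_volumes:
        raise ValueError("regressor length does not match the session")
    if bold.highpass_cutoff_s is not None:
        # the data were high-pass filtered; the model must see the same filter
        K = dct_highpass_basis(bold.n_volumes, bold.tr_s, bold.highpass_cutoff_s)
        if K is not None:
            X0 = X0 - K @ (K.T @ X0)
    n_reg = X0.shape[1]
    names = regressor_names or [f"reg{i}" for i in range(n_reg)]
    _check_collinear(X0, names)

    Y = bold.masked_timeseries()                         # (T, V)
    mean = Y.mean(axis=0)
    mean = np.where(mean == 0, 1.0, mean)
    Y = 100.0 * (Y - mean) / mean

    X = np.column_stack([np.ones(bold.n_volumes), X0])
    names = ["intercept"] + list(names)

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta

    if ar1 == "auto":
        num = float(np.sum(resid[1:] * resid[:-1]))
        den = float(np.sum(resid * resid))
        # residuals at numerical-noise level carry no serial structure
        rho = num / den if den > 1e-18 * float(np.sum(Y * Y) + 1.0) else 0.0
        rho = float(np.clip(rho, -0.95, 0.95))
    else:
        rho = float(ar1)

    if rho != 0.0:
        Yw = Y[1:] - rho * Y[:-1]
        Xw = X[1:] - rho * X[:-1]
        scale = np.sqrt(1.0 - rho * rho)
        Yw = np.vstack([Y[:1] * scale, Yw])
        Xw = np.vstack([X[:1] * scale, Xw])
    else:
        Yw, Xw = Y, X

    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    residw = Yw - Xw @ beta
    df = Xw.shape[0] - np.linalg.matrix_rank(Xw)
    if bold.highpass_cutoff_s is not None:
        # the high pass already removed this many dimensions from the data
        K = dct_highpass_basis(bold.n_volumes, bold.tr_s, bold.highpass_cutoff_s)
        if K is not None:
            df -= K.shape[1]
    sigma2 = (residw ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)

    return GlmResult(
        betas=beta,
        sigma2=sigma2,
        df_resid=int(df),
        design=Xw,
        xtx_inv=xtx_inv,
        mask=bold.brain_mask,
        rho=rho,
        regressor_names=names,
        _yw=Yw,
    )


def f_test(glm: GlmResult, regressor_subset) -> tuple[np.ndarray, np.ndarray]:
    """Extra-sum-of-squares F test for a subset of (non-intercept) regressors.

    Compares the full model against the model with the subset removed;
    returns (f_map, p_map) volumes (NaN outside the mask). A voxel with
    zero full-model residual gets ``F = +inf`` and ``p = 0``.
    """
    subset = np.atleast_1d(np.asarray(regressor_subset, dtype=int))
    if subset.size == 0:
        raise ValueError("empty regressor subset")
    cols = subset + 1                                    # skip intercept
    if cols.max() >= glm.design.shape[1]:
        raise ValueError("regressor index out of range")
    if glm._yw is None:
        raise ValueError("GLM was fitted without retaining data; cannot F-test")

    X, Y = glm.design, glm._yw
    rss_full = glm.sigma2 * glm.df_resid
    keep = np.setdiff1d(np.arange(X.shape[1]), cols)
    Xr = X[:, keep]
    beta_r, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
    rss_red = ((Y - Xr @ beta_r) ** 2).sum(axis=0)

    q = cols.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / q / (rss_full / glm.df_resid)
    f = np.where(rss_full <= 1e-12 * np.maximum(rss_red, 1e-300), np.inf, f)
    f = np.maximum(f, 0.0)
    p = stats.f.sf(f, q, glm.df_resid)

    f_map = glm.map_from_vector(f, fill=np.nan)
    p_map = glm.map_from_vector(p, fill=np.nan)
    return f_map, p_map


def t_test_map(glm: GlmResult, contrast, alpha: float = 0.05,
               correction: str = "fwe") -> dict:
    """Contrast t map with optional family-wise error control.

    ``contrast`` addresses the non-intercept regressors. FWE control uses
    Bonferroni over the in-mask voxels. Returns a dict with the ``t_map``,
    ``p_map``, boolean ``supra`` volume, the adjusted ``threshold_p`` and
    degrees of freedom.
    """
    c_user = np.atleast_1d(np.asarray(contrast, dtype=float))
    if np.all(c_user == 0):
        raise ValueError("contrast of zeros")
    if c_user.size != glm.design.shape[1] - 1:
        raise ValueError("contrast length does not match the regressors")
    c = np.concatenate([[0.0], c_user])

    effect = c @ glm.betas
    var = glm.sigma2 * float(c @ glm.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(var)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = stats.t.sf(t, glm.df_resid)                      # one-sided (positive)

    n_vox = glm.n_voxels
    if correction == "fwe":
        p_thresh = alpha / n_vox
    elif correction == "none":
        p_thresh = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")

    return {
        "t_map": glm.map_from_vector(t, fill=np.nan),
        "p_map": glm.map_from_vector(p, fill=np.nan),
        "supra": glm.map_from_vector((p < p_thresh).astype(float)) > 0.5,
        "threshold_p": p_thresh,
        "alpha": alpha,
        "correction": correction,
        "df": glm.df_resid,
    }


def roi_stats(stat_map: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean of a statistic map inside an ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("empty ROI")
    vals = stat_map[roi_mask]
    return float(np.nanmean(vals))


def compare_rois(sample_a: np.ndarray, sample_b: np.ndarray,
                 alpha_normality: float = 0.05) -> dict:
    """Two-sample comparison with automatic test selection.

    Each sample is checked for normality with the Lilliefors test
    (Kolmogorov-Smirnov with estimated parameters); if both pass, a
    two-tailed t test compares the means, otherwise the Wilcoxon rank-sum
    test compares the medians.
    """
    from statsmodels.stats.diagnostic import lilliefors

    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 4 or b.size < 4:
        raise ValueError("need >=4 observations per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return {"test": "t", "p": 1.0, "stat": 0.0, "normal": (True, True)}
    p_norm = []
    for s in (a, b):
        if np.ptp(s) == 0:
            p_norm.append(0.0)
        else:
            p_norm.append(float(lilliefors(s, dist="norm")[1]))
    normal = tuple(p > alpha_normality for p in p_norm)
    if all(normal):
        stat, p = stats.ttest_ind(a, b)
        test = "t"
    else:
        stat, p = stats.ranksums(a, b)
        test = "ranksum"
    return {"test": test, "p": float(p), "stat": float(stat), "normal": normal}
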