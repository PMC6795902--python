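"""Multivariate CL-history (restitution + short-term memory) regression.

Fits ``APD_n = C + a1*CL_{n-1} + a2*CL_{n-2} + ... + a_k*CL_{n-k}`` by
ordinary least squares, per pixel or for a single series.  ``CL_{n-1}``
denotes the activation interval between beats n-1 and n, so the lag-1
regressor of beat n is the interval entering it.  Regressors are raw CLs
in ms (not centred); the intercept absorbs the mean APD.

Per-pixel fits are vectorized through batched normal equations; the
single-series entry point uses statsmodels OLS.  Map summaries include a
measurement-error-corrected spatial correlation between the a1 and a2
maps: per-pixel OLS sampling noise inflates the map variances and masks
the true spatial correlation, and the OLS coefficient covariance of each
pixel provides an unbiased estimate of that inflation, which is
subtracted before forming the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .containers import BeatTable

__all__ = [
    "MIN_BEATS",
    "FitResult",
    "CoefficientMaps",
    "MapSummary",
    "fit_memory_model",
    "fit_coefficient_maps",
    "r2_vs_lag",
    "map_statistics",
    "pooled_corrected_correlation",
    "pooled_corrected_map_sd",
]

log = logging.getLogger(__name__)

#: minimum number of usable beats for a regression fit
MIN_BEATS = 80


@dataclass
class FitResult:
    c_ms: float
    alpha: np.ndarray
    r_squared: float
    n_obs: int
    sigma2: float
    cov: np.ndarray  # (k+1, k+1) covariance of [C, a1..ak]

    @property
    def alpha_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)[1:])


@dataclass
class CoefficientMaps:
    """Per-pixel fitted coefficients with fit diagnostics."""

    c_ms: np.ndarray
    alpha: np.ndarray       # (k, H, W)
    r_squared: np.ndarray
    n_obs: np.ndarray
    include: np.ndarray     # pixels with a successful fit
    cov_alpha: np.ndarray   # (k, k, H, W) OLS covariance of the alphas
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.alpha.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.c_ms.shape  # type: ignore[return-value]

    def to_frame(self) -> pd.DataFrame:
        h, w = self.shape
        rr, cc = np.mgrid[0:h, 0:w]
        cols = {"row": rr.ravel(), "col": cc.ravel(),
                "c_ms": self.c_ms.ravel(),
                "r_squared": self.r_squared.ravel(),
                "n_obs": self.n_obs.ravel(),
                "include": self.include.ravel()}
        for j in range(self.k):
            cols[f"alpha_{j + 1}"] = self.alpha[j].ravel()
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class MapSummary:
    mean_alpha: np.ndarray
    sd_alpha: np.ndarray
    sd_alpha_corrected: np.ndarray  # map SD after removing OLS noise
    mean_c_ms: float
    corr_alpha1_alpha2: float
    corr_alpha1_alpha2_corrected: float
    mean_r_squared: float
    n_pixels: int
    region_means: dict[str, np.ndarray] = field(default_factory=dict)
    # raw spatial moments and mean OLS (co)variances of (a1, a2), kept so
    # replicate scans can be pooled before forming noise-corrected ratios
    moments: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "mean_alpha": self.mean_alpha.tolist(),
            "sd_alpha": self.sd_alpha.tolist(),
            "sd_alpha_corrected": self.sd_alpha_corrected.tolist(),
            "mean_c_ms": self.mean_c_ms,
            "corr_alpha1_alpha2": self.corr_alpha1_alpha2,
            "corr_alpha1_alpha2_corrected": self.corr_alpha1_alpha2_corrected,
            "mean_r_squared": self.mean_r_squared,
            "n_pixels": self.n_pixels,
            "region_means": {k: v.tolist() for k, v in self.region_means.items()},
        }
        return d


def _design_rows(apd: np.ndarray, cl_in: np.ndarray, k: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack response, regressors and row-validity for (n_beats, P) inputs.

    ``cl_in[n]`` is the activation interval entering beat n; the lag-j
    regressor of beat n is ``cl_in[n - j + 1]``.
    """
    n, P = apd.shape
    X = np.empty((n, k, P))
    for j in range(1, k + 1):
        X[:, j - 1, :] = np.roll(cl_in, j - 1, axis=0)
        X[:j - 1, j - 1, :] = np.nan  # rolled-in garbage rows
    ok = np.isfinite(apd) & np.all(np.isfinite(X), axis=1)
    return apd, X, ok


def fit_memory_model(apd: np.ndarray, cl_in: np.ndarray, k: int = 2,
                     min_beats: int = MIN_BEATS) -> FitResult:
    """OLS fit of one APD series on its k previous CLs.

    ``cl_in[n]`` must be the interval entering beat n (NaN where
    undefined).  Raises if fewer than ``min_beats`` usable beats remain
    after dropping rows with missing lags, or if the CL lags are
    collinear (e.g. constant pacing).
    """
    import statsmodels.api as sm

    apd = np.asarray(apd, dtype=float).ravel()
    cl_in = np.asarray(cl_in, dtype=float).ravel()
    if apd.shape != cl_in.shape:
        raise ValueError("apd and cl_in must have the same length")
    y2, X2, ok = _design_rows(apd[:, None], cl_in[:, None], k)
    rows = ok[:, 0]
    n_obs = int(rows.sum())
    if n_obs < min_beats:
        raise ValueError(
            f"need at least {min_beats} usable beats, got {n_obs}")
    X = np.column_stack([np.ones(n_obs), X2[rows, :, 0]])
    y = y2[rows, 0]
    if np.linalg.matrix_rank(X) < k + 1:
        raise np.linalg.LinAlgError(
            "CL lags are collinear (rank-deficient design); "
            "constant pacing cannot identify the coefficients")
    res = sm.OLS(y, X).fit()
    return FitResult(c_ms=float(res.params[0]),
                     alpha=np.asarray(res.params[1:]),
                     r_squared=float(res.rsquared),
                     n_obs=n_obs,
                     sigma2=float(res.mse_resid),
                     cov=np.asarray(res.cov_params()))


def _batched_ols(apd: np.ndarray, X: np.ndarray, ok: np.ndarray,
                 min_beats: int) -> dict[str, np.ndarray]:
    """Weighted (masked) normal-equation OLS for every pixel at once.

    apd: (n, P); X: (n, k, P) lag regressors; ok: (n, P) row validity.
    """
    n, k, P = X.shape
    Xf = np.concatenate([np.ones((n, 1, P)), np.where(np.isfinite(X), X, 0.0)],
                        axis=1)  # (n, k+1, P)
    w = ok.astype(float)
    y = np.where(ok, apd, 0.0)
    A = np.einsum("nip,np,njp->pij", Xf, w, Xf)
    b = np.einsum("nip,np,np->pi", Xf, w, y)
    count = ok.sum(axis=0)
    syy = np.einsum("np,np->p", y, y * w)
    sy = np.einsum("np,np->p", y, w)

    fit_ok = count >= min_beats
    # guard singular systems (e.g. constant pacing -> collinear lags)
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(A)
    fit_ok &= np.isfinite(cond) & (cond < 1e12)
    beta = np.zeros((P, k + 1))
    cov_scaled = np.zeros((P, k + 1, k + 1))
    if fit_ok.any():
        Ai = np.linalg.inv(A[fit_ok])
        beta[fit_ok] = np.einsum("pij,pj->pi", Ai, b[fit_ok])
        cov_scaled[fit_ok] = Ai
    sse = syy - np.einsum("pi,pi->p", beta, b)
    sst = syy - sy ** 2 / np.maximum(count, 1)
    dof = np.maximum(count - (k + 1), 1)
    sigma2 = np.maximum(sse, 0.0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
    cov = cov_scaled * sigma2[:, None, None]
    return {"beta": beta, "r2": r2, "n_obs": count, "ok": fit_ok,
            "sigma2": sigma2, "cov": cov}


def fit_coefficient_maps(beats: BeatTable, k: int = 2,
                         min_beats: int = MIN_BEATS,
                         cl_mode: str = "pixel",
                         ref_pixel: tuple[int, int] | None = None
                         ) -> CoefficientMaps:
    """Fit the CL-history model at every included pixel.

    ``cl_mode='pixel'`` (default) uses each pixel's own activation
    intervals as regressors; ``cl_mode='reference'`` uses the CL series of
    a single reference site for all pixels (the convention of showing CLs
    from one mapping site).  Pixels whose fits fail preconditions are
    masked, never raised.
    """
    h, w = beats.shape
    n = beats.n_beats
    apd = beats.apd_ms.reshape(n, -1)
    if cl_mode == "pixel":
        cl_in = beats.cl_prev_ms.reshape(n, -1)
    elif cl_mode == "reference":
        if ref_pixel is None:
            ref_pixel = (h // 2, w // 2)
        ref = beats.cl_prev_ms[:, ref_pixel[0], ref_pixel[1]]
        cl_in = np.repeat(ref[:, None], h * w, axis=1)
    else:
        raise ValueError("cl_mode must be 'pixel' or 'reference'")
    _, X, ok = _design_rows(apd, cl_in, k)
    ok &= beats.pixel_include.ravel()[None, :]
    res = _batched_ols(apd, X, ok, min_beats)
    include = res["ok"].reshape(h, w)
    if not include.any():
        log.warning("fit_coefficient_maps: no pixel produced a valid fit")
    beta = res["beta"]
    nanify = lambda a: np.where(include.ravel(), a, np.nan)  # noqa: E731
    c_map = nanify(beta[:, 0]).reshape(h, w)
    alpha = np.stack([nanify(beta[:, 1 + j]).reshape(h, w) for j in range(k)])
    cov_alpha = res["cov"][:, 1:, 1:].transpose(1, 2, 0).reshape(k, k, h, w)
    return CoefficientMaps(
        c_ms=c_map, alpha=alpha,
        r_squared=nanify(res["r2"]).reshape(h, w),
        n_obs=res["n_obs"].reshape(h, w),
        include=include, cov_alpha=cov_alpha,
        meta={"k": k, "cl_mode": cl_mode, "min_beats": min_beats,
              "source": beats.meta})


def r2_vs_lag(beats: BeatTable, k_max: int = 10,
              min_beats: int = MIN_BEATS) -> np.ndarray:
    """Mean per-pixel R-squared for lag depths k = 1..k_max.

    All depths are fitted on the common beat set (rows usable at
    ``k_max``), so the curve is non-decreasing by construction of nested
    OLS models.
    """
    n = beats.n_beats
    apd = beats.apd_ms.reshape(n, -1)
    cl_in = beats.cl_prev_ms.reshape(n, -1)
    _, X_full, ok = _design_rows(apd, cl_in, k_max)
    ok &= beats.pixel_include.ravel()[None, :]
    curve = np.full(k_max, np.nan)
    for k in range(1, k_max + 1):
        res = _batched_ols(apd, X_full[:, :k, :], ok, min_beats)
        r2 = res["r2"][res["ok"]]
        curve[k - 1] = float(np.nanmean(r2)) if r2.size else np.nan
    return curve


def map_statistics(maps: CoefficientMaps,
                   region_labels: np.ndarray | None = None,
                   region_names: tuple[str, ...] | None = None,
                   min_pixels: int = 10) -> MapSummary:
    """Spatial summaries of fitted coefficient maps.

    Means and SDs are over included pixels.  The raw spatial correlation
    between the a1 and a2 maps is attenuated by per-pixel OLS noise; the
    corrected value subtracts the mean OLS coefficient (co)variance from
    the observed map moments.  Undefined correlations (zero variance) are
    reported as NaN, never as 0.
    """
    inc = maps.include
    n_pix = int(inc.sum())
    if n_pix == 0:
        raise ValueError("all pixels are masked; no summary available")
    if n_pix < min_pixels:
        raise ValueError(f"need at least {min_pixels} included pixels")
    a = maps.alpha[:, inc]  # (k, n_pix)
    mean_alpha = a.mean(axis=1)
    sd_alpha = a.std(axis=1, ddof=1)
    noise_var = np.array([maps.cov_alpha[j, j][inc].mean()
                          for j in range(maps.k)])
    sd_corr = np.sqrt(np.maximum(sd_alpha ** 2 - noise_var, 0.0))
    corr = corr_corrected = np.nan
    moments: dict[str, float] = {}
    if maps.k >= 2:
        # variances at float-residue level count as zero (uniform maps)
        if sd_alpha[0] > 1e-9 and sd_alpha[1] > 1e-9:
            corr = float(np.corrcoef(a[0], a[1])[0, 1])
            moments = {
                "var1": float(a[0].var(ddof=1)),
                "var2": float(a[1].var(ddof=1)),
                "cov12": float(np.cov(a[0], a[1], ddof=1)[0, 1]),
                "noise_var1": float(maps.cov_alpha[0, 0][inc].mean()),
                "noise_var2": float(maps.cov_alpha[1, 1][inc].mean()),
                "noise_cov12": float(maps.cov_alpha[0, 1][inc].mean()),
            }
            v1 = moments["var1"] - moments["noise_var1"]
            v2 = moments["var2"] - moments["noise_var2"]
            c12 = moments["cov12"] - moments["noise_cov12"]
            if v1 > 0 and v2 > 0:
                corr_corrected = float(
                    np.clip(c12 / np.sqrt(v1 * v2), -1.0, 1.0))
    region_means: dict[str, np.ndarray] = {}
    if region_labels is not None:
        names = region_names or tuple(
            str(v) for v in np.unique(region_labels))
        for i, name in enumerate(names):
            m = inc & (region_labels == i)
            region_means[name] = maps.alpha[:, m].mean(axis=1) \
                if m.any() else np.full(maps.k, np.nan)
    return MapSummary(
        mean_alpha=mean_alpha, sd_alpha=sd_alpha, sd_alpha_corrected=sd_corr,
        mean_c_ms=float(maps.c_ms[inc].mean()),
        corr_alpha1_alpha2=corr,
        corr_alpha1_alpha2_corrected=corr_corrected,
        mean_r_squared=float(np.nanmean(maps.r_squared[inc])),
        n_pixels=n_pix, region_means=region_means, moments=moments)


def pooled_corrected_correlation(summaries: list[MapSummary]) -> float:
    """Noise-corrected corr(a1, a2) pooled over replicate scans.

    Per-scan corrected correlations are ratio estimates whose denominators
    are small differences of moments; averaging the moments over scans
    first and forming the ratio once removes most of the resulting
    small-sample (convexity) bias.
    """
    keys = ("var1", "var2", "cov12", "noise_var1", "noise_var2",
            "noise_cov12")
    ms = [s.moments for s in summaries if s.moments]
    if not ms:
        return float("nan")
    m = {k: float(np.mean([x[k] for x in ms])) for k in keys}
    v1 = m["var1"] - m["noise_var1"]
    v2 = m["var2"] - m["noise_var2"]
    c12 = m["cov12"] - m["noise_cov12"]
    if v1 <= 0 or v2 <= 0:
        return float("nan")
    return float(np.clip(c12 / np.sqrt(v1 * v2), -1.0, 1.0))


def pooled_corrected_map_sd(summaries: list[MapSummary], which: int = 0
                            ) -> float:
    """Noise-corrected spatial SD of a coefficient map pooled over scans."""
    key_v, key_n = (("var1", "noise_var1") if which == 0
                    else ("var2", "noise_var2"))
    ms = [s.moments for s in summaries if s.moments]
    if not ms:
        return float("nan")
    v = float(np.mean([x[key_v] for x in ms]))
    nv = float(np.mean([x[key_n] for x in ms]))
    return float(np.sqrt(max(v - nv, 0.0)))
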