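"""Spatial APD dispersion statistics and their CL-pattern dependence.

APD dispersion for one beat is the spatial standard deviation of the APD
map over included pixels (sigma_APD); the companion range statistic
delta_APD is the difference between the 99th and 1st percentiles of the
same map (linear-interpolation quantiles).  For near-normal maps
delta ~ 4 sigma.  Scan-level analyses locate the maximum-dispersion beat,
the cycle-length pattern preceding it, and the regression of sigma_APD on
the CL difference dCL = CL_{n-1} - CL_{n-2} (positive dCL = short-long).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BeatTable

__all__ = [
    "DispersionSeries",
    "dispersion_metrics",
    "dispersion_series",
    "correlate_dispersion_vs_dcl",
    "s1s2s3_analysis",
    "beat_to_beat_variation",
]

log = logging.getLogger(__name__)

MIN_PIXELS = 10
#: beats whose included-and-valid pixel count falls below this fraction of
#: the scan's included pixels are excluded from the series
MIN_PIXEL_FRACTION = 0.6


def dispersion_metrics(apd_map: np.ndarray,
                       min_pixels: int = MIN_PIXELS) -> tuple[float, float]:
    """(sigma_APD, delta_APD 99%-1%) for one beat's APD map.

    NaNs are ignored; with fewer than ``min_pixels`` finite values the
    beat is skipped (NaN, NaN) with a warning.
    """
    vals = np.asarray(apd_map, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < min_pixels:
        log.warning("dispersion_metrics: only %d pixels, beat skipped",
                    vals.size)
        return (np.nan, np.nan)
    sigma = float(vals.std(ddof=1))
    delta = float(np.quantile(vals, 0.99) - np.quantile(vals, 0.01))
    return sigma, delta


@dataclass
class DispersionSeries:
    """Per-beat dispersion metrics plus the max-dispersion-beat summary."""

    sigma_apd_ms: np.ndarray
    delta_apd_ms: np.ndarray
    n_pixels: np.ndarray
    cl_in_ms: np.ndarray        # stimulus interval entering each beat
    idx_max: int                # beat index of maximum sigma_APD
    preceding_cls_ms: np.ndarray  # (CL_{n-3}, CL_{n-2}, CL_{n-1}) at idx_max
    dcl_at_max_ms: float        # CL_{n-1} - CL_{n-2} at idx_max
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return self.sigma_apd_ms.size

    def to_frame(self) -> pd.DataFrame:
        dcl = np.full(self.n_beats, np.nan)
        dcl[1:] = self.cl_in_ms[1:] - self.cl_in_ms[:-1]
        return pd.DataFrame({
            "beat": np.arange(self.n_beats),
            "sigma_apd_ms": self.sigma_apd_ms,
            "delta_apd_ms": self.delta_apd_ms,
            "n_pixels": self.n_pixels,
            "cl_in_ms": self.cl_in_ms,
            "dcl_ms": dcl,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def dispersion_series(beats: BeatTable,
                      min_pixels: int = MIN_PIXELS,
                      min_pixel_fraction: float = MIN_PIXEL_FRACTION
                      ) -> DispersionSeries:
    """Per-beat dispersion and the CL pattern preceding the maximum.

    The maximum-dispersion beat is the argmax of sigma_APD over beats with
    at least three preceding beats (so the preceding CL triple is
    defined); the earliest beat wins ties.
    """
    n = beats.n_beats
    if n < 4:
        raise ValueError("need at least 4 beats for a dispersion series")
    n_included = int(beats.pixel_include.sum())
    floor = max(min_pixels, int(np.ceil(min_pixel_fraction * n_included)))
    sigma = np.full(n, np.nan)
    delta = np.full(n, np.nan)
    npx = np.zeros(n, dtype=int)
    for i in range(n):
        m = beats.apd_map(i)
        npx[i] = int(np.isfinite(m).sum())
        if npx[i] < floor:
            continue
        sigma[i], delta[i] = dispersion_metrics(m, min_pixels)
    cl_in = beats.cl_stim_ms
    cand = sigma.copy()
    cand[:3] = np.nan  # need CL_{n-3..n-1}
    if not np.isfinite(cand).any():
        raise ValueError("no beat has a defined dispersion and CL history")
    idx_max = int(np.nanargmax(cand))  # first index wins ties
    preceding = cl_in[idx_max - 2:idx_max + 1]  # CL_{n-3}, CL_{n-2}, CL_{n-1}
    dcl = float(cl_in[idx_max] - cl_in[idx_max - 1])
    return DispersionSeries(
        sigma_apd_ms=sigma, delta_apd_ms=delta, n_pixels=npx, cl_in_ms=cl_in,
        idx_max=idx_max, preceding_cls_ms=np.asarray(preceding),
        dcl_at_max_ms=dcl,
        meta={"n_included_pixels": n_included, "source": beats.meta})


def correlate_dispersion_vs_dcl(series: DispersionSeries,
                                min_beats: int = 10) -> tuple[float, float]:
    """OLS slope and Pearson r of sigma_APD on dCL = CL_{n-1} - CL_{n-2}."""
    df = series.to_frame()
    ok = np.isfinite(df["sigma_apd_ms"]) & np.isfinite(df["dcl_ms"])
    if ok.sum() < min_beats:
        raise ValueError(f"need >= {min_beats} beats with defined dCL")
    x = df.loc[ok, "dcl_ms"].to_numpy()
    y = df.loc[ok, "sigma_apd_ms"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("dCL has zero variance; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue)


def s1s2s3_analysis(beats: BeatTable | dict[float, BeatTable],
                    s2s3_ms: float | None = None,
                    min_pixels: int = MIN_PIXELS
                    ) -> tuple[pd.DataFrame, float, float]:
    """Dispersion of the S3 beat versus dCL = S2S3 - S1S2.

    Accepts either one BeatTable from a combined S1S2S3 protocol (whose
    metadata carries the S3 beat bookkeeping) or a mapping of S1S2 value
    to BeatTable where the S3 beat is the last beat of each table.
    Returns the per-point table, the OLS slope and Pearson r.
    """
    points: list[tuple[float, float]] = []
    if isinstance(beats, BeatTable):
        info = beats.meta.get("s3_info") or []
        if not info:
            raise ValueError("beat table has no S1S2S3 bookkeeping")
        for rec in info:
            if s2s3_ms is not None and rec["s2s3"] != s2s3_ms:
                continue
            sigma, _ = dispersion_metrics(beats.apd_map(int(rec["beat"])),
                                          min_pixels)
            if np.isfinite(sigma):
                points.append((rec["dcl"], sigma))
            else:
                log.warning("s1s2s3: S3 beat at S1S2=%s not captured, dropped",
                            rec["s1s2"])
    else:
        if s2s3_ms is None:
            raise ValueError("s2s3_ms is required with per-S1S2 tables")
        for s1s2, table in beats.items():
            sigma, _ = dispersion_metrics(table.apd_map(table.n_beats - 1),
                                          min_pixels)
            if np.isfinite(sigma):
                points.append((s2s3_ms - float(s1s2), sigma))
            else:
                log.warning("s1s2s3: S3 beat at S1S2=%s not captured, dropped",
                            s1s2)
    if len(points) < 3:
        raise ValueError("need S3 dispersion at >= 3 distinct S1S2 values")
    df = pd.DataFrame(points, columns=["dcl_ms", "sigma_apd_ms"])
    res = stats.linregress(df["dcl_ms"], df["sigma_apd_ms"])
    return df, float(res.slope), float(res.rvalue)


def beat_to_beat_variation(beats: BeatTable, min_beats: int = 10) -> float:
    """Temporal SD of APD per pixel, averaged over included pixels (ms)."""
    apd = beats.apd_ms.reshape(beats.n_beats, -1)
    inc = beats.pixel_include.ravel()
    apd = apd[:, inc]
    counts = np.isfinite(apd).sum(axis=0)
    use = counts >= min_beats
    if not use.any():
        raise ValueError(f"no pixel has >= {min_beats} valid beats")
    sds = np.nanstd(apd[:, use], axis=0, ddof=1)
    return float(np.nanmean(sds))
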