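"""Optical-mapping signal chain.

The measurement chain mirrors standard voltage-sensitive-dye practice:
each frame is smoothed with a normalized 3x3 Gaussian kernel, temporal
first/second derivatives are computed with a 13-point, 3rd-order local
polynomial (Savitzky-Golay) filter, activation is the time of maximum
dF/dt within each stimulus window, and repolarization is the time of
maximum d2F/dt2 between the upstroke blanking period and the next
activation.  Peak times are refined to sub-frame precision with a
least-squares parabola through the five samples around the discrete
argmax.  Pixels are excluded when their maximum dF/dt is below three
baseline standard deviations, and per-beat APD maps are cleaned with an
iterative two-sided Grubbs outlier test.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from scipy.stats import t as t_dist

from .containers import BeatTable, FluorescenceMovie, PixelMask

__all__ = [
    "SAVGOL_WINDOW",
    "SAVGOL_ORDER",
    "spatial_filter",
    "temporal_derivatives",
    "refine_peak",
    "detect_beats",
    "pixel_qc",
    "grubbs_critical",
    "grubbs_filter",
    "extract_beat_table",
]

log = logging.getLogger(__name__)

SAVGOL_WINDOW = 13
SAVGOL_ORDER = 3

#: normalized 3x3 binomial approximation of a Gaussian kernel
_KERNEL_3X3 = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0

#: default repolarization search window relative to activation, ms.  The
#: guard before the next activation must clear the next upstroke's own
#: positive d2F/dt2 lobe, widened by the 13-point derivative filter.
BLANKING_MS = 30.0
GUARD_MS = 15.0
MAX_APD_MS = 400.0


def spatial_filter(movie: FluorescenceMovie) -> FluorescenceMovie:
    """Convolve each frame with the normalized 3x3 Gaussian kernel.

    Borders are handled by reflection, so constant and linear intensity
    fields pass through unchanged in the interior.
    """
    if movie.shape[0] < 3 or movie.shape[1] < 3:
        raise ValueError("spatial filtering needs at least a 3x3 grid")
    out = ndimage.convolve(movie.frames, _KERNEL_3X3[None, :, :],
                           mode="reflect")
    return FluorescenceMovie(frames=out, stim_times_ms=movie.stim_times_ms,
                             frame_interval_ms=movie.frame_interval_ms,
                             pixel_pitch_um=movie.pixel_pitch_um,
                             metadata=dict(movie.metadata))


def temporal_derivatives(trace: np.ndarray, frame_interval_ms: float = 1.0,
                         axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """First and second time derivatives (per ms) of a fluorescence trace.

    Uses the 13-point, 3rd-order Savitzky-Golay differentiator; the input
    must have at least 13 samples along ``axis``.
    """
    trace = np.asarray(trace)
    if trace.shape[axis] < SAVGOL_WINDOW:
        raise ValueError(
            f"trace needs >= {SAVGOL_WINDOW} samples, got {trace.shape[axis]}")
    d1 = savgol_filter(trace, SAVGOL_WINDOW, SAVGOL_ORDER, deriv=1,
                       delta=frame_interval_ms, axis=axis)
    d2 = savgol_filter(trace, SAVGOL_WINDOW, SAVGOL_ORDER, deriv=2,
                       delta=frame_interval_ms, axis=axis)
    return d1, d2


def refine_peak(y: np.ndarray, idx: np.ndarray, half: int = 2) -> np.ndarray:
    """Sub-sample peak location by a least-squares parabola.

    ``y`` is (T, P); ``idx`` (P,) holds discrete argmax indices.  Fits a
    parabola through the ``2*half + 1`` samples centred on ``idx`` and
    returns fractional indices.  Indices too close to the array ends are
    returned unrefined.
    """
    y = np.asarray(y)
    idx = np.asarray(idx)
    T = y.shape[0]
    P = idx.shape[0]
    safe = (idx >= half) & (idx <= T - 1 - half)
    base = np.where(safe, idx, half)
    offs = np.arange(-half, half + 1)
    cols = np.arange(P)
    seg = y[(base[None, :] + offs[:, None]), cols[None, :]]  # (2h+1, P)
    # closed-form LS for y = c0 + c1*x + c2*x^2 on symmetric x = -h..h
    n = offs.size
    s2 = float((offs ** 2).sum())
    s4 = float((offs ** 4).sum())
    sy = seg.sum(axis=0)
    sxy = (offs[:, None] * seg).sum(axis=0)
    sx2y = ((offs ** 2)[:, None] * seg).sum(axis=0)
    c1 = sxy / s2
    denom = s4 - s2 ** 2 / n
    c2 = (sx2y - s2 * sy / n) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = -c1 / (2.0 * c2)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    shift = np.clip(shift, -half, half)
    return np.where(safe, base + shift, idx.astype(float))


def _activation_threshold(d1_flat: np.ndarray, baseline_sd: np.ndarray,
                          scan_max: np.ndarray) -> np.ndarray:
    """Per-pixel minimum upstroke slope for a window to count as captured.

    Combines an absolute floor (flat traces never fire), a noise bound
    (5 baseline SDs of dF/dt) and a relative bound (a quarter of the
    pixel's strongest upstroke), so windows of missed capture are not
    assigned activations at noise peaks.
    """
    return np.maximum.reduce([
        np.full_like(scan_max, 1e-12),
        5.0 * baseline_sd,
        0.25 * scan_max,
    ])


def _detect_arrays(d1: np.ndarray, d2: np.ndarray, stim_times: np.ndarray,
                   frame_interval_ms: float, baseline_sd: np.ndarray,
                   blanking_ms: float, guard_ms: float,
                   max_apd_ms: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core detector on flattened (T, P) derivative stacks.

    Returns activation times, repolarization times (ms, NaN when
    undetected) and a validity mask, each (n_beats, P).
    """
    T, P = d1.shape
    dt = frame_interval_ms
    stim_idx = np.clip((stim_times / dt).astype(int), 0, T - 1)
    n_beats = stim_idx.size
    median_cl = int(np.median(np.diff(stim_idx))) if n_beats > 1 else T
    bounds = np.append(stim_idx, min(T, stim_idx[-1] + median_cl))

    scan_max = d1.max(axis=0)
    thr = _activation_threshold(d1, baseline_sd, scan_max)

    act = np.full((n_beats, P), np.nan)
    valid = np.zeros((n_beats, P), dtype=bool)
    act_idx = np.zeros((n_beats, P), dtype=int)
    for n in range(n_beats):
        a, b = bounds[n], bounds[n + 1]
        if b - a < 3:
            continue
        seg = d1[a:b]
        idx = np.argmax(seg, axis=0)  # first index wins ties
        amax = seg[idx, np.arange(P)]
        ok = amax > thr
        lo = max(0, a - 3)
        frac = refine_peak(d1[lo:min(T, b + 3)], idx + (a - lo))
        act[n] = (frac + lo) * dt
        act_idx[n] = idx + a
        valid[n] = ok
    act[~valid] = np.nan

    # repolarization windows end at the next activation (or stimulus-based
    # fallback when the next beat is not captured at this pixel)
    delay = np.where(valid, act - stim_times[:, None], np.nan)
    med_delay = np.nanmedian(delay, axis=0)
    med_delay = np.where(np.isfinite(med_delay), med_delay, 0.0)

    rep = np.full((n_beats, P), np.nan)
    rep_ok = np.zeros((n_beats, P), dtype=bool)
    for n in range(n_beats):
        if not valid[n].any():
            continue
        start_t = act[n] + blanking_ms
        if n + 1 < n_beats:
            nxt = np.where(valid[n + 1], act[n + 1],
                           stim_times[n + 1] + med_delay)
            end_t = nxt - guard_ms
        else:
            end_t = np.minimum(act[n] + max_apd_ms, (T - 3) * dt)
        end_t = np.minimum(end_t, act[n] + max_apd_ms)
        start = np.ceil(np.where(valid[n], start_t, np.inf) / dt)
        end = np.floor(np.where(valid[n], end_t, -np.inf) / dt)
        ok = valid[n] & (end - start >= 5)
        if not ok.any():
            continue
        lo = int(np.nanmin(np.where(ok, start, np.inf)))
        hi = int(np.nanmax(np.where(ok, end, -np.inf))) + 1
        lo = max(lo, 0)
        hi = min(hi, T)
        seg = d2[lo:hi]
        tt = np.arange(lo, hi)[:, None]
        mask = (tt >= start[None, :]) & (tt <= end[None, :]) & ok[None, :]
        seg = np.where(mask, seg, -np.inf)
        idx = np.argmax(seg, axis=0)
        frac = refine_peak(d2[lo:hi], idx)
        rep[n] = (frac + lo) * dt
        rep_ok[n] = ok & mask[idx, np.arange(P)]
    valid &= rep_ok
    rep[~valid] = np.nan
    act2 = act.copy()
    act2[~valid] = np.nan
    return act2, rep, valid


def detect_beats(trace: np.ndarray, stim_times: np.ndarray,
                 frame_interval_ms: float = 1.0,
                 baseline_sd: float | None = None,
                 blanking_ms: float = BLANKING_MS,
                 guard_ms: float = GUARD_MS,
                 max_apd_ms: float = MAX_APD_MS) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-beat (activation, repolarization, valid) for a single trace.

    ``stim_times`` define the beat windows.  Returns arrays of length
    ``len(stim_times)``; undetected beats are NaN with ``valid=False``.
    """
    trace = np.asarray(trace, dtype=float)
    d1, d2 = temporal_derivatives(trace, frame_interval_ms)
    if baseline_sd is None:
        n0 = int(stim_times[0] / frame_interval_ms)
        baseline_sd = float(np.std(d1[:n0])) if n0 >= 10 else 0.0
    act, rep, valid = _detect_arrays(
        d1[:, None], d2[:, None], np.asarray(stim_times, float),
        frame_interval_ms, np.asarray([baseline_sd]),
        blanking_ms, guard_ms, max_apd_ms)
    return act[:, 0], rep[:, 0], valid[:, 0]


def pixel_qc(movie: FluorescenceMovie, d1: np.ndarray | None = None,
             min_baseline_ms: float = 100.0,
             exclude_edge: bool = True) -> PixelMask:
    """Scan-level pixel quality control.

    Excludes pixels whose maximum dF/dt over the scan (per frame) is below
    three standard deviations of the baseline fluorescence (baseline = the
    pre-first-stimulus segment), and optionally the one-pixel image border
    where the spatial filter is unreliable.  A pure-noise pixel's maximum
    derivative stays well below this bound because the differentiator
    attenuates white noise.
    """
    dt = movie.frame_interval_ms
    n0 = int(movie.stim_times_ms[0] / dt)
    if n0 * dt < min_baseline_ms:
        raise ValueError(
            f"need >= {min_baseline_ms} ms of pre-stimulus baseline, "
            f"got {n0 * dt} ms")
    h, w = movie.shape
    if d1 is None:
        d1, _ = temporal_derivatives(
            movie.frames.reshape(movie.n_frames, -1), dt)
    sd_b = movie.frames.reshape(movie.n_frames, -1)[:n0].std(axis=0) \
        .reshape(h, w) / dt
    peak = d1.max(axis=0).reshape(h, w)
    low_snr = peak < 3.0 * sd_b
    edge = np.zeros((h, w), dtype=bool)
    if exclude_edge:
        edge[0, :] = edge[-1, :] = True
        edge[:, 0] = edge[:, -1] = True
    include = ~(low_snr | edge)
    return PixelMask(include=include,
                     reasons={"low_snr": low_snr, "edge": edge})


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size ``n``."""
    tq = t_dist.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tq ** 2 / (n - 2 + tq ** 2))


def grubbs_filter(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs outlier test.

    Returns a boolean mask over ``values`` that is True for outliers.
    NaNs are ignored (never flagged).  With fewer than 3 finite values no
    test is performed.
    """
    values = np.asarray(values, dtype=float).ravel()
    out = np.zeros(values.size, dtype=bool)
    active = np.isfinite(values)
    if active.sum() < 3:
        log.warning("grubbs_filter: fewer than 3 values, no test performed")
        return out
    while active.sum() >= 3:
        x = values[active]
        mean = x.mean()
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - mean)
        i_rel = int(np.argmax(dev))
        g = dev[i_rel] / sd
        if g <= grubbs_critical(x.size, alpha):
            break
        idx = np.flatnonzero(active)[i_rel]
        out[idx] = True
        active[idx] = False
    return out


def extract_beat_table(movie: FluorescenceMovie,
                       stim_times: np.ndarray | None = None,
                       *,
                       apply_spatial_filter: bool = True,
                       apply_grubbs: bool = True,
                       grubbs_alpha: float = 0.05,
                       blanking_ms: float = BLANKING_MS,
                       guard_ms: float = GUARD_MS,
                       max_apd_ms: float = MAX_APD_MS,
                       exclude_edge: bool = True) -> BeatTable:
    """Run the full Methods chain on a movie and return the BeatTable.

    Chain: 3x3 spatial Gaussian -> Savitzky-Golay derivatives ->
    activation/repolarization detection per stimulus window -> pixel QC
    (low-SNR and border exclusion) -> per-beat Grubbs cleaning of the APD
    maps.  Invalid detections are NaN with ``valid=False``; excluded
    pixels are recorded in ``pixel_include``.
    """
    if stim_times is None:
        stim_times = movie.stim_times_ms
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size < 2:
        raise ValueError("need at least two stimuli")
    proc = spatial_filter(movie) if apply_spatial_filter else movie
    T = proc.n_frames
    h, w = proc.shape
    flat = proc.frames.reshape(T, h * w)
    d1, d2 = temporal_derivatives(flat, proc.frame_interval_ms)
    mask = pixel_qc(proc, d1=d1, exclude_edge=exclude_edge)
    n0 = int(stim_times[0] / proc.frame_interval_ms)
    sd_b = d1[:n0].std(axis=0)
    act, rep, valid = _detect_arrays(
        d1, d2, stim_times, proc.frame_interval_ms, sd_b,
        blanking_ms, guard_ms, max_apd_ms)
    n_beats = stim_times.size
    act = act.reshape(n_beats, h, w)
    rep = rep.reshape(n_beats, h, w)
    valid = valid.reshape(n_beats, h, w)

    n_grubbs = 0
    if apply_grubbs:
        apd = rep - act
        for n in range(n_beats):
            sel = valid[n] & mask.include
            vals = np.where(sel, apd[n], np.nan)
            out = grubbs_filter(vals.ravel(), grubbs_alpha).reshape(h, w)
            valid[n] &= ~out
            n_grubbs += int(out.sum())
        act = np.where(valid, act, np.nan)
        rep = np.where(valid, rep, np.nan)

    enough = valid.sum(axis=0) >= 2
    include = mask.include & enough
    meta = {
        "n_grubbs_removed": n_grubbs,
        "n_low_snr": int(mask.reasons["low_snr"].sum()),
        "n_edge": int(mask.reasons["edge"].sum()),
        "source": proc.metadata,
    }
    return BeatTable(activation_ms=act, repol_ms=rep, valid=valid,
                     stim_times_ms=stim_times,
                     pixel_pitch_um=proc.pixel_pitch_um,
                     pixel_include=include, meta=meta)
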