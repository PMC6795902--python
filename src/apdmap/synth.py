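"""Synthetic optical-mapping data generator.

Generates ground-truth tissue parameter maps (restitution slope a1,
short-term memory a2, intercept C), simulates per-pixel APD series that
obey the two-lag CL-history model under a pacing protocol, and renders
fluorescence movies whose action-potential templates are built so that the
standard derivative detectors recover the ground truth by construction:
the maximum of dF/dt of the sigmoidal upstroke falls at the activation
time and the maximum of d2F/dt2 of the sigmoidal downstroke falls at the
repolarization time (including the small constant shift introduced by the
Savitzky-Golay differentiator, which is calibrated out).

The APD-map heterogeneity is partially decoupled from the coefficient
heterogeneity: the intercept map partially compensates the coefficient
maps at the reference CL (the centre of the random-pacing window), so a
tissue can combine strong restitution heterogeneity with a moderate APD
dispersion at constant pacing, as mapped hearts do.
"""

from __future__ import annotations

import functools
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .containers import BeatTable, FluorescenceMovie, TissueParameterMap
from .presets import GenotypePreset
from .processing import refine_peak, temporal_derivatives
from .protocols import PacingProtocol

__all__ = [
    "WaveformParams",
    "build_parameter_maps",
    "simulate_apd_series",
    "render_movie",
    "write_movie",
    "read_movie",
]

log = logging.getLogger(__name__)

#: argmax of -d2/dx2 of the logistic function (at s = (3 + sqrt 3)/6)
XSTAR = 1.3169578969248166

#: standardized fluctuation fields are clipped at this many SDs to keep
#: extreme pixels physiological (and capture feasible)
CLIP_Z = 2.75

DEFAULT_CONDUCTION_CM_S = 50.0
SIDECAR_REQUIRED = ("frame_interval_ms", "pixel_pitch_um", "stim_times_ms")


@dataclass(frozen=True)
class WaveformParams:
    """Shape of the synthetic action-potential fluorescence template."""

    tau_up_ms: float = 1.5
    tau_down_ms: float = 3.0

    def as_dict(self) -> dict:
        return asdict(self)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _standardize(f: np.ndarray) -> np.ndarray:
    sd = f.std()
    if sd == 0:
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  length: float) -> np.ndarray:
    """Zero-mean, unit-SD spatially correlated Gaussian field."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=length, mode="reflect")
    return _standardize(f)


def _orthogonalize(z: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Standardize ``z`` after removing its sample projection on ``ref``."""
    z = z - z.mean()
    r = _standardize(ref)
    z = z - (z * r).mean() * r
    return _standardize(z)


def build_parameter_maps(preset: GenotypePreset,
                         grid: tuple[int, int] = (100, 100),
                         seed: int = 0,
                         conduction_velocity_cm_s: float = DEFAULT_CONDUCTION_CM_S,
                         pixel_pitch_um: float = 200.0) -> TissueParameterMap:
    """Generate ground-truth coefficient maps for a genotype preset.

    The restitution-slope map a1 combines an organised gradient (base to
    apex, or an endo/epi regional contrast for transmural presets) with a
    smooth random field; its sample mean and spatial SD match the preset
    exactly.  The memory map a2 is built from the standardized a1
    fluctuation plus an orthogonalized independent field, so the sample
    spatial correlation corr(a1, a2) equals the preset target exactly.
    The intercept map partially compensates both at the reference CL.
    """
    h, w = grid
    if h < 8 or w < 8:
        raise ValueError("grid must be at least 8 x 8")
    if abs(preset.corr_alpha1_alpha2) >= 1:
        raise ValueError("|corr target| must be < 1")
    rng = np.random.default_rng(seed)
    length = max(2.0, min(h, w) / 6.0)

    if preset.transmural:
        n_endo = int(round(preset.endo_fraction * w))
        labels = np.ones((h, w), dtype=int)
        labels[:, :n_endo] = 0
        names = ("endo", "epi")
        a1_endo, a1_epi = preset.region_alpha1  # type: ignore[misc]
        base_map = np.where(labels == 0, a1_endo, a1_epi)
        noise = _smooth_field(rng, (h, w), length)
        f = np.empty((h, w))
        for r in (0, 1):
            m = labels == r
            z = _standardize(noise[m])
            z = _standardize(np.clip(z, -CLIP_Z, CLIP_Z))
            f[m] = z
        alpha1 = base_map + preset.sd_alpha1_map * f
        origin = (h // 2, w - 1)  # paced from the epicardial side
    else:
        labels = np.zeros((h, w), dtype=int)
        labels[h // 2:, :] = 1
        names = ("base", "apex")
        grad = _standardize(np.repeat(
            np.linspace(1.0, -1.0, h)[:, None], w, axis=1))
        noise = _orthogonalize(_smooth_field(rng, (h, w), length), grad)
        gf = preset.gradient_fraction
        z = np.sqrt(gf) * grad + np.sqrt(1.0 - gf) * noise
        z = _standardize(np.clip(_standardize(z), -CLIP_Z, CLIP_Z))
        alpha1 = preset.mean_alpha1 + preset.sd_alpha1_map * z
        origin = (0, w // 2)  # stimulated at the base

    z1 = _standardize(alpha1)
    z2 = _orthogonalize(_smooth_field(rng, (h, w), length), z1)
    rho = preset.corr_alpha1_alpha2
    alpha2 = preset.mean_alpha2 + preset.sd_alpha2_map * (
        rho * z1 + np.sqrt(1.0 - rho ** 2) * z2)

    cl_ref = preset.erp_ms + preset.cl_range_ms / 2.0
    # residual APD-map pattern, orthogonal to both coefficient maps so
    # beat-level gain fluctuations on it do not contaminate their recovery
    eta = _orthogonalize(_orthogonalize(
        _smooth_field(rng, (h, w), length), z1), z2)
    c_ms = (preset.mean_c_ms
            - preset.compensation * cl_ref * ((alpha1 - alpha1.mean())
                                              + (alpha2 - alpha2.mean()))
            + preset.sd_c_ms * eta)

    amplitude = rng.uniform(0.7, 1.3, size=(h, w))
    return TissueParameterMap(
        c_ms=c_ms,
        alpha=np.stack([alpha1, alpha2]),
        amplitude=amplitude,
        region_labels=labels,
        region_names=names,
        origin_px=origin,
        conduction_velocity_cm_s=conduction_velocity_cm_s,
        pixel_pitch_um=pixel_pitch_um,
        apd_pattern_ms=preset.sd_c_ms * eta,
        meta={"preset": preset.name, "seed": seed, "cl_ref_ms": cl_ref,
              "compensation": preset.compensation},
    )


def simulate_apd_series(maps: TissueParameterMap,
                        protocol: PacingProtocol,
                        noise_sd: float = 0.0,
                        di_min: float = 20.0,
                        seed: int = 0,
                        *,
                        dispersion_gain_sd: float = 0.0,
                        spatial_noise_sd: float = 0.0,
                        t0_ms: float = 200.0) -> BeatTable:
    """Simulate per-pixel APDs for every beat of a pacing protocol.

    For beat n at pixel p, ``APD_n = C(p) + sum_j alpha_j(p) * CL_{n-j}
    + eps`` where the CLs are the realized stimulus intervals.  ``eps``
    combines white Gaussian noise of SD ``noise_sd``; an optional
    beat-level random gain (SD ``dispersion_gain_sd``) on the tissue's
    CL-independent APD pattern, emulating beat-to-beat fluctuations of
    repolarization dispersion that are not driven by cycle lengths; and an
    optional per-beat smooth spatial field (``spatial_noise_sd``).

    Activation time = stimulus time + planar conduction delay (+``t0_ms``,
    the pre-stimulus baseline).  A beat whose incoming diastolic interval
    at a pixel is below ``di_min`` is flagged not-captured; the first k
    beats (undefined CL lags) are flagged invalid.
    """
    k = maps.k
    if protocol.n_beats < k + 1:
        raise ValueError(f"protocol must have at least {k + 1} beats")
    h, w = maps.shape
    n = protocol.n_beats
    rng = np.random.default_rng(seed)
    cls = protocol.cls_ms  # cls[i] enters beat i+1
    delay = maps.conduction_delay_ms()
    stim_abs = t0_ms + protocol.stim_times_ms
    length = max(2.0, min(h, w) / 6.0)

    # CL lags per beat, padded with the first CL for the warmup beats
    cl_lag = np.empty((k, n))
    for j in range(1, k + 1):
        idx = np.arange(n) - j  # index into cls for CL_{n-j}
        cl_lag[j - 1] = cls[np.clip(idx, 0, cls.size - 1)]

    alpha = maps.alpha.reshape(k, -1)
    c = maps.c_ms.ravel()
    det = c[None, :] + cl_lag.T @ alpha  # (n, H*W)
    eps = rng.normal(0.0, noise_sd, size=det.shape) if noise_sd > 0 else 0.0
    apd = det + eps
    if dispersion_gain_sd > 0:
        gain = rng.normal(0.0, dispersion_gain_sd, size=n)
        apd = apd + gain[:, None] * maps.apd_pattern_ms.ravel()[None, :]
    if spatial_noise_sd > 0:
        fields = np.stack([
            _smooth_field(rng, (h, w), length).ravel() for _ in range(n)])
        apd = apd + spatial_noise_sd * fields

    act = stim_abs[:, None] + delay.ravel()[None, :]
    rep = np.full_like(act, np.nan)
    valid = np.ones(act.shape, dtype=bool)
    last_rep = np.full(h * w, -np.inf)
    n_blocked = 0
    for i in range(n):
        di = act[i] - last_rep
        blocked = di < di_min
        captured = ~blocked
        rep[i, captured] = act[i, captured] + apd[i, captured]
        rep[i, blocked] = np.nan
        valid[i] = captured
        last_rep[captured] = rep[i, captured]
        n_blocked += int(blocked.sum())
    valid[:k] = False  # undefined CL lags
    if n_blocked:
        frac = n_blocked / valid.size
        if frac > 0.005:
            log.warning("simulate_apd_series: %.2f%% of beats not captured",
                        100 * frac)

    meta = {"preset": maps.meta.get("preset"), "seed": seed, "k": k,
            "noise_sd": noise_sd, "dispersion_gain_sd": dispersion_gain_sd,
            "spatial_noise_sd": spatial_noise_sd,
            "di_min": di_min, "n_blocked": n_blocked,
            "protocol_kind": protocol.kind, "t0_ms": t0_ms,
            "protocol_params": protocol.params, "s3_info": protocol.s3_info}
    return BeatTable(activation_ms=act.reshape(n, h, w),
                     repol_ms=rep.reshape(n, h, w),
                     valid=valid.reshape(n, h, w),
                     stim_times_ms=stim_abs,
                     pixel_pitch_um=maps.pixel_pitch_um,
                     meta=meta)


@functools.lru_cache(maxsize=8)
def _repol_detector_offset(tau_down: float, dt: float = 1.0) -> float:
    """Constant shift of the detected repolarization peak.

    The Savitzky-Golay second-derivative of the sigmoid downstroke peaks
    slightly after the analytic d2F/dt2 maximum.  Measured once per
    waveform shape on noise-free templates and subtracted during
    rendering so the detector is unbiased by construction.
    """
    t = np.arange(0, 600.0, dt)
    errs = []
    for phase in np.linspace(0.0, 0.9, 7):
        t_act = 100.0 + phase
        t_rep = t_act + 180.0
        c = t_rep - XSTAR * tau_down
        f = _sigmoid((t - t_act) / 1.5) - _sigmoid((t - c) / tau_down)
        _, d2 = temporal_derivatives(f, dt)
        lo = int((t_act + 30) / dt)
        hi = int((t_rep + 60) / dt)
        idx = int(np.argmax(d2[lo:hi]))
        frac = refine_peak(d2[lo:hi, None], np.asarray([idx]))[0]
        errs.append((lo + frac) * dt - t_rep)
    return float(np.mean(errs))


def render_movie(beats: BeatTable,
                 maps: TissueParameterMap,
                 waveform: WaveformParams | None = None,
                 snr: float = 25.0,
                 seed: int = 0,
                 post_ms: float = 100.0,
                 frame_interval_ms: float = 1.0) -> FluorescenceMovie:
    """Render a fluorescence movie from a ground-truth beat table.

    Each pixel's trace is a sum of action-potential templates: a sigmoidal
    upstroke whose maximum slope falls at the activation time and a
    sigmoidal downstroke placed so the detected d2F/dt2 maximum falls at
    the repolarization time.  Additive white Gaussian noise has baseline
    SD = upstroke amplitude / snr, with a camera read-noise floor of a
    tenth of the median amplitude so low-amplitude pixels stay noisy
    (``snr=np.inf`` disables noise).
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    wf = waveform or WaveformParams()
    h, w = beats.shape
    P = h * w
    dt = frame_interval_ms
    act = beats.activation_ms.reshape(beats.n_beats, P)
    rep = beats.repol_ms.reshape(beats.n_beats, P)
    fin = np.isfinite(act) & np.isfinite(rep)
    if not fin.any():
        raise ValueError("beat table has no renderable beats")
    T = int(np.ceil((rep[fin].max() + post_ms) / dt))
    amp = maps.amplitude.ravel().astype(np.float32)

    offset = _repol_detector_offset(wf.tau_down_ms, dt)
    c_dn = rep - XSTAR * wf.tau_down_ms - offset

    # truncate templates that would overlap the next upstroke
    if beats.n_beats > 1:
        nxt = act[1:]
        limit = nxt - 2.0 * wf.tau_down_ms
        bad = fin[:-1] & np.isfinite(nxt) & (c_dn[:-1] > limit)
        if bad.any():
            log.warning("render_movie: truncating %d overlapping templates",
                        int(bad.sum()))
            c_dn[:-1][bad] = limit[bad]

    frames = np.zeros((T, P), dtype=np.float32)
    span_up = 10.0 * wf.tau_up_ms
    span_dn = 10.0 * wf.tau_down_ms
    for i in range(beats.n_beats):
        m = fin[i]
        if not m.any():
            continue
        lo = max(0, int(np.floor((np.nanmin(act[i, m]) - span_up) / dt)))
        hi = min(T, int(np.ceil((np.nanmax(c_dn[i, m]) + span_dn) / dt)) + 1)
        tt = (np.arange(lo, hi) * dt)[:, None].astype(np.float32)
        a = np.where(m, act[i], np.inf).astype(np.float32)
        cdn = np.where(m, c_dn[i], np.inf).astype(np.float32)
        tpl = _sigmoid((tt - a) / wf.tau_up_ms) \
            - _sigmoid((tt - cdn) / wf.tau_down_ms)
        frames[lo:hi] += amp[None, :] * tpl.astype(np.float32)

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        floor = np.float32(0.1 * np.median(amp))
        sigma = np.maximum(amp, floor) / np.float32(snr)
        frames += sigma[None, :] * noise

    metadata = {"seed": seed, "snr": None if np.isinf(snr) else float(snr),
                "waveform": wf.as_dict(),
                "preset": beats.meta.get("preset"),
                "protocol_kind": beats.meta.get("protocol_kind"),
                "protocol_params": beats.meta.get("protocol_params"),
                "s3_info": beats.meta.get("s3_info"),
                "t0_ms": beats.meta.get("t0_ms")}
    return FluorescenceMovie(frames=frames.reshape(T, h, w),
                             stim_times_ms=beats.stim_times_ms,
                             frame_interval_ms=dt,
                             pixel_pitch_um=beats.pixel_pitch_um,
                             metadata=metadata)


def write_movie(movie: FluorescenceMovie, path, quantize_16bit: bool = False) -> None:
    """Write a movie as a multi-page TIFF with a JSON metadata sidecar.

    Float32 mode round-trips losslessly; 16-bit mode quantizes intensities
    linearly (max absolute error = half a quantization step) and stores
    the scale/offset in the sidecar.
    """
    path = Path(path)
    frames = movie.frames
    quant = None
    if quantize_16bit:
        lo = float(frames.min())
        hi = float(frames.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        data = np.round((frames - lo) / scale).astype(np.uint16)
        quant = {"offset": lo, "scale": scale}
    else:
        data = frames.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "frame_interval_ms": movie.frame_interval_ms,
        "pixel_pitch_um": movie.pixel_pitch_um,
        "stim_times_ms": movie.stim_times_ms.tolist(),
        "quantization": quant,
        "metadata": _jsonable(movie.metadata),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_movie(path) -> FluorescenceMovie:
    """Read a TIFF + JSON-sidecar movie written by :func:`write_movie`."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing metadata sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in SIDECAR_REQUIRED:
        if key not in sidecar or sidecar[key] is None:
            raise ValueError(f"movie sidecar missing field {key!r}")
    frames = tifffile.imread(path)
    quant = sidecar.get("quantization")
    if quant is not None:
        frames = frames.astype(np.float32) * np.float32(quant["scale"]) \
            + np.float32(quant["offset"])
    return FluorescenceMovie(frames=frames,
                             stim_times_ms=np.asarray(sidecar["stim_times_ms"]),
                             frame_interval_ms=sidecar["frame_interval_ms"],
                             pixel_pitch_um=sidecar["pixel_pitch_um"],
                             metadata=sidecar.get("metadata") or {})
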