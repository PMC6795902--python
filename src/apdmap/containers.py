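"""Core in-memory containers for optical-mapping APD analysis.

Times are in milliseconds on a single movie time base (t = 0 is the first
frame).  Grids are (row, col), 0-based; pixel pitch is in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TissueParameterMap",
    "FluorescenceMovie",
    "BeatTable",
    "PixelMask",
]


@dataclass
class TissueParameterMap:
    """Ground-truth per-pixel electrophysiological parameters.

    ``c_ms`` is the regression intercept map; ``alpha`` stacks the lag
    coefficient maps (k, H, W): ``alpha[0]`` is the restitution-slope map
    (dependence of APD on the previous CL), ``alpha[1]`` the short-term
    memory map (dependence on the second-previous CL).  ``amplitude`` is
    the optical upstroke amplitude (arbitrary units).  ``region_labels``
    is an integer map with names in ``region_names`` (e.g. base/apex or
    endo/epi).  Conduction is a planar wave from ``origin_px`` at
    ``conduction_velocity_cm_s``.
    """

    c_ms: np.ndarray
    alpha: np.ndarray
    amplitude: np.ndarray
    region_labels: np.ndarray
    region_names: tuple[str, ...]
    origin_px: tuple[int, int]
    conduction_velocity_cm_s: float
    pixel_pitch_um: float = 200.0
    apd_pattern_ms: np.ndarray | None = None  # CL-independent APD-map
                                              # component (beat-gain mode)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c_ms = np.asarray(self.c_ms, dtype=float)
        self.alpha = np.atleast_3d(np.asarray(self.alpha, dtype=float))
        if self.alpha.shape[1:] != self.c_ms.shape:
            raise ValueError("alpha maps and C map must share the grid")
        for name, arr in (("c_ms", self.c_ms), ("alpha", self.alpha)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.apd_pattern_ms is None:
            self.apd_pattern_ms = np.zeros_like(self.c_ms)

    @property
    def shape(self) -> tuple[int, int]:
        return self.c_ms.shape  # type: ignore[return-value]

    @property
    def k(self) -> int:
        """Number of CL lags in the generative model."""
        return self.alpha.shape[0]

    def conduction_delay_ms(self) -> np.ndarray:
        """Activation delay of each pixel for a planar wave from the origin."""
        h, w = self.shape
        rr, cc = np.mgrid[0:h, 0:w]
        dist_cm = np.hypot(rr - self.origin_px[0], cc - self.origin_px[1]) \
            * self.pixel_pitch_um * 1e-4
        return dist_cm / self.conduction_velocity_cm_s * 1e3

    def region_mask(self, name: str) -> np.ndarray:
        return self.region_labels == self.region_names.index(name)


@dataclass
class FluorescenceMovie:
    """A T x H x W fluorescence stack with acquisition metadata."""

    frames: np.ndarray
    stim_times_ms: np.ndarray
    frame_interval_ms: float = 1.0
    pixel_pitch_um: float = 200.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W stack")
        self.stim_times_ms = np.asarray(self.stim_times_ms, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms


@dataclass
class PixelMask:
    """Scan-level pixel inclusion mask with reason codes."""

    include: np.ndarray
    reasons: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)

    @property
    def n_included(self) -> int:
        return int(self.include.sum())

    def to_frame(self) -> pd.DataFrame:
        h, w = self.include.shape
        rr, cc = np.mgrid[0:h, 0:w]
        cols = {"row": rr.ravel(), "col": cc.ravel(),
                "include": self.include.ravel()}
        for name, m in self.reasons.items():
            cols[name] = np.asarray(m, dtype=bool).ravel()
        return pd.DataFrame(cols)


@dataclass
class BeatTable:
    """Per-pixel, per-beat activation/repolarization/APD records.

    Arrays are (n_beats, H, W); invalid entries are NaN with
    ``valid = False``.  ``stim_times_ms`` are the stimulus times on the
    same time base as the activation times; ``cl_stim_ms[n]`` is the
    stimulus interval entering beat n (NaN for the first beat).
    """

    activation_ms: np.ndarray
    repol_ms: np.ndarray
    valid: np.ndarray
    stim_times_ms: np.ndarray
    pixel_pitch_um: float = 200.0
    pixel_include: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activation_ms = np.asarray(self.activation_ms, dtype=float)
        self.repol_ms = np.asarray(self.repol_ms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.stim_times_ms = np.asarray(self.stim_times_ms, dtype=float)
        if self.activation_ms.shape != self.repol_ms.shape:
            raise ValueError("activation and repolarization shapes differ")
        if self.valid.shape != self.activation_ms.shape:
            raise ValueError("valid mask shape differs from time arrays")
        if self.pixel_include is None:
            self.pixel_include = np.ones(self.activation_ms.shape[1:], bool)
        bad = self.valid & ~(self.repol_ms > self.activation_ms)
        if bad.any():
            raise ValueError("valid beats must have repol > activation")

    @property
    def n_beats(self) -> int:
        return self.activation_ms.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.activation_ms.shape[1:]  # type: ignore[return-value]

    @property
    def apd_ms(self) -> np.ndarray:
        """APD = repolarization - activation, NaN where invalid."""
        apd = self.repol_ms - self.activation_ms
        apd[~self.valid] = np.nan
        return apd

    @property
    def cl_stim_ms(self) -> np.ndarray:
        cl = np.full(self.n_beats, np.nan)
        cl[1:] = np.diff(self.stim_times_ms)
        return cl

    @property
    def cl_prev_ms(self) -> np.ndarray:
        """Per-pixel CL_{n-1}: difference of consecutive activation times.

        Defined only where beat n and beat n-1 are both valid at the pixel.
        """
        cl = np.full_like(self.activation_ms, np.nan)
        cl[1:] = self.activation_ms[1:] - self.activation_ms[:-1]
        ok = np.zeros_like(self.valid)
        ok[1:] = self.valid[1:] & self.valid[:-1]
        cl[~ok] = np.nan
        return cl

    @property
    def di_prev_ms(self) -> np.ndarray:
        """Per-pixel diastolic interval: CL_{n-1} - APD_{n-1}."""
        di = np.full_like(self.activation_ms, np.nan)
        di[1:] = self.activation_ms[1:] - self.repol_ms[:-1]
        ok = np.zeros_like(self.valid)
        ok[1:] = self.valid[1:] & self.valid[:-1]
        di[~ok] = np.nan
        return di

    def apd_map(self, beat: int) -> np.ndarray:
        """APD map for one beat, NaN outside included/valid pixels."""
        m = self.apd_ms[beat].copy()
        m[~self.pixel_include] = np.nan
        return m

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (beat, pixel)."""
        n, h, w = self.activation_ms.shape
        bb, rr, cc = np.mgrid[0:n, 0:h, 0:w]
        cl = self.cl_prev_ms
        di = self.di_prev_ms
        return pd.DataFrame({
            "beat": bb.ravel(), "row": rr.ravel(), "col": cc.ravel(),
            "activation_time_ms": self.activation_ms.ravel(),
            "repol_time_ms": self.repol_ms.ravel(),
            "apd_ms": self.apd_ms.ravel(),
            "cl_prev_ms": cl.ravel(),
            "di_prev_ms": di.ravel(),
            "valid": self.valid.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("activation_ms", data=self.activation_ms)
            f.create_dataset("repol_ms", data=self.repol_ms)
            f.create_dataset("valid", data=self.valid)
            f.create_dataset("stim_times_ms", data=self.stim_times_ms)
            f.create_dataset("pixel_include", data=self.pixel_include)
            f.attrs["pixel_pitch_um"] = self.pixel_pitch_um

    @classmethod
    def from_hdf5(cls, path) -> "BeatTable":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                activation_ms=f["activation_ms"][()],
                repol_ms=f["repol_ms"][()],
                valid=f["valid"][()].astype(bool),
                stim_times_ms=f["stim_times_ms"][()],
                pixel_include=f["pixel_include"][()].astype(bool),
                pixel_pitch_um=float(f.attrs["pixel_pitch_um"]),
            )
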