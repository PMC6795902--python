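"""Pacing protocols as explicit stimulus-time sequences.

Four protocols are used to probe cycle-length (CL) dependence of action
potential duration (APD): a classical S1S2 extrastimulus protocol, ramp
(decremental) pacing, random-interval pacing with CLs drawn uniformly from
a window above the effective refractory period (ERP), and an S1S2S3
protocol in which the final coupling interval (S2S3) is held fixed while
the penultimate one (S1S2) is varied.

All times are in milliseconds; the first stimulus is at t = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "PacingProtocol",
    "make_s1s2",
    "make_ramp",
    "make_random",
    "make_random_duration",
    "make_s1s2s3",
]


@dataclass(frozen=True)
class PacingProtocol:
    """A stimulus-time sequence for one optical-mapping scan.

    Attributes
    ----------
    kind : str
        One of ``{"s1s2", "ramp", "random", "s1s2s3"}``.
    stim_times_ms : np.ndarray
        Strictly increasing stimulus times, first stimulus at 0 ms.
    params : dict
        The parameters the protocol was built from (for provenance).
    s3_info : list of dict
        For ``s1s2s3`` only: one record per S3 beat with the beat index,
        the S1S2 used, the fixed S2S3 and the CL difference
        ``dcl = s2s3 - s1s2`` (positive for a short-long pattern).
    """

    kind: str
    stim_times_ms: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)
    s3_info: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        st = np.asarray(self.stim_times_ms, dtype=float)
        if st.ndim != 1 or st.size < 2:
            raise ValueError("a protocol needs at least two stimuli")
        if not np.all(np.diff(st) > 0):
            raise ValueError("stimulus times must be strictly increasing")
        object.__setattr__(self, "stim_times_ms", st)

    @property
    def cls_ms(self) -> np.ndarray:
        """Cycle lengths: first differences of the stimulus times."""
        return np.diff(self.stim_times_ms)

    @property
    def n_beats(self) -> int:
        return int(self.stim_times_ms.size)

    @property
    def duration_ms(self) -> float:
        return float(self.stim_times_ms[-1])

    def to_json(self) -> str:
        doc = {
            "kind": self.kind,
            "params": self.params,
            "stim_times_ms": self.stim_times_ms.tolist(),
            "s3_info": self.s3_info,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PacingProtocol":
        doc = json.loads(text)
        for key in ("kind", "stim_times_ms"):
            if key not in doc:
                raise ValueError(f"protocol document missing field {key!r}")
        return cls(
            kind=doc["kind"],
            stim_times_ms=np.asarray(doc["stim_times_ms"], dtype=float),
            params=doc.get("params", {}),
            s3_info=doc.get("s3_info", []),
        )


def _from_cls(kind: str, cls_ms: np.ndarray, params: dict,
              s3_info: list | None = None) -> PacingProtocol:
    stim = np.concatenate([[0.0], np.cumsum(np.asarray(cls_ms, dtype=float))])
    return PacingProtocol(kind=kind, stim_times_ms=stim, params=params,
                          s3_info=s3_info or [])


def make_s1s2(s1_cl: float, n_s1: int, s2_start: float, step: float,
              erp: float) -> PacingProtocol:
    """S1S2 extrastimulus protocol.

    Trains of ``n_s1`` beats at ``s1_cl`` each followed by a single S2;
    the S1S2 coupling interval starts at ``s2_start`` and is shortened by
    ``step`` down to ``erp`` (inclusive), where pacing is assumed to miss
    capture.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if s2_start > s1_cl:
        raise ValueError("s2_start must not exceed s1_cl")
    if erp > s2_start:
        raise ValueError("erp must not exceed s2_start")
    if n_s1 < 1:
        raise ValueError("need at least one S1 beat per train")
    s2_values = np.arange(s2_start, erp - step / 2, -step)
    cls: list[float] = []
    for s2 in s2_values:
        cls.extend([s1_cl] * n_s1)  # intervals entering each S1 beat
        cls.append(float(s2))
    params = dict(s1_cl=s1_cl, n_s1=n_s1, s2_start=s2_start, step=step,
                  erp=erp, s2_values=[float(v) for v in s2_values])
    return _from_cls("s1s2", np.asarray(cls), params)


def make_ramp(start_cl: float, step: float, min_cl: float,
              beats_per_step: int) -> PacingProtocol:
    """Decremental (ramp) pacing: blocks of constant CL, shortened stepwise."""
    if min_cl <= 0:
        raise ValueError("min_cl must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if start_cl < min_cl:
        raise ValueError("start_cl must be >= min_cl")
    if beats_per_step < 1:
        raise ValueError("beats_per_step must be >= 1")
    levels = np.arange(start_cl, min_cl - step / 2, -step)
    cls = np.repeat(levels, beats_per_step)
    params = dict(start_cl=start_cl, step=step, min_cl=min_cl,
                  beats_per_step=beats_per_step)
    return _from_cls("ramp", cls, params)


def make_random(erp: float, range_ms: float, n_beats: int,
                seed: int) -> PacingProtocol:
    """Random-interval pacing: CLs i.i.d. uniform on [erp, erp + range_ms].

    ``n_beats`` counts stimuli; the protocol has ``n_beats - 1`` cycle
    lengths, so at least two beats are required.
    """
    if range_ms < 0:
        raise ValueError("range_ms must be >= 0")
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2")
    rng = np.random.default_rng(seed)
    cls = rng.uniform(erp, erp + range_ms, size=n_beats - 1)
    params = dict(erp=erp, range_ms=range_ms, n_beats=n_beats, seed=seed)
    return _from_cls("random", cls, params)


def make_random_duration(erp: float, range_ms: float, duration_ms: float,
                         seed: int) -> PacingProtocol:
    """Random-interval pacing generated until the scan duration is reached.

    Beats are appended until the cumulative stimulus time is at least
    ``duration_ms`` (a 20-s scan by default in the pipeline).
    """
    if range_ms < 0:
        raise ValueError("range_ms must be >= 0")
    if duration_ms <= erp:
        raise ValueError("duration_ms must exceed one cycle")
    rng = np.random.default_rng(seed)
    cls: list[float] = []
    t = 0.0
    while t < duration_ms:
        cl = float(rng.uniform(erp, erp + range_ms))
        cls.append(cl)
        t += cl
    params = dict(erp=erp, range_ms=range_ms, duration_ms=duration_ms,
                  seed=seed)
    return _from_cls("random", np.asarray(cls), params)


def make_s1s2s3(s1_cl: float, n_s1: int, s1s2_values, s2s3: float) -> PacingProtocol:
    """S1S2S3 protocol: fixed S2S3, variable S1S2.

    For each S1S2 value a train of ``n_s1`` S1 beats is followed by one S2
    (after ``s1s2`` ms) and one S3 (after ``s2s3`` ms).  The CL difference
    seen by the S3 beat is ``dcl = s2s3 - s1s2``: shortening S1S2 below
    S2S3 imposes a short-long pattern on the S3 beat.
    """
    s1s2_values = [float(v) for v in np.atleast_1d(s1s2_values)]
    if len(s1s2_values) == 0:
        raise ValueError("s1s2_values must not be empty")
    if n_s1 < 1:
        raise ValueError("need at least one S1 beat per train")
    cls: list[float] = []
    s3_info: list[dict[str, float]] = []
    beat = 0  # index of the beat each appended CL leads *into*
    for s1s2 in s1s2_values:
        cls.extend([s1_cl] * n_s1)
        beat += n_s1
        cls.append(s1s2)
        beat += 1
        cls.append(s2s3)
        beat += 1
        s3_info.append(dict(beat=beat, s1s2=s1s2, s2s3=float(s2s3),
                            dcl=float(s2s3) - s1s2))
    params = dict(s1_cl=s1_cl, n_s1=n_s1, s1s2_values=s1s2_values,
                  s2s3=float(s2s3))
    return _from_cls("s1s2s3", np.asarray(cls), params, s3_info)
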