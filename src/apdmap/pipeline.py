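"""End-to-end pipeline: generate -> render -> process -> analyze -> fit.

``run_scan`` performs one complete synthetic scan for a genotype preset:
build ground-truth parameter maps, simulate the per-beat APD series under
random pacing, render the fluorescence movie at a given SNR, run the
optical-processing chain, fit the per-pixel CL-history regression and the
dispersion analyses.  ``run_replicates`` repeats it over seeds and
aggregates the parameter-recovery summaries; ``genotype_report`` assembles
the cross-genotype summary table with the routine comparison statistics
(paired/two-sample t-tests, one-way ANOVA), which are reporting plumbing,
not part of the scientific model.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BeatTable, FluorescenceMovie, TissueParameterMap
from .dispersion import (DispersionSeries, beat_to_beat_variation,
                         correlate_dispersion_vs_dcl, dispersion_series)
from .presets import get_preset
from .processing import extract_beat_table
from .protocols import make_random
from .regression import (CoefficientMaps, MapSummary, fit_coefficient_maps,
                         map_statistics)
from .synth import build_parameter_maps, render_movie, simulate_apd_series

__all__ = [
    "RunConfig",
    "ScanResult",
    "run_scan",
    "run_replicates",
    "genotype_report",
    "run_pipeline",
]

log = logging.getLogger(__name__)

DEFAULT_SNR = 25.0


@dataclass
class RunConfig:
    """Reproducible description of a pipeline run."""

    preset: str = "lqt2"
    grid: tuple[int, int] = (50, 50)
    n_beats: int = 100
    snr: float = DEFAULT_SNR
    seeds: tuple[int, ...] = (1, 2, 3)
    k: int = 2
    out_dir: str = "runs/out"
    save_movie: bool = False
    quantize_16bit: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        cfg = cls(**doc)
        cfg.grid = tuple(cfg.grid)  # type: ignore[assignment]
        cfg.seeds = tuple(cfg.seeds)  # type: ignore[assignment]
        return cfg


@dataclass
class ScanResult:
    """Everything produced by one synthetic scan."""

    preset: str
    seed: int
    maps: TissueParameterMap
    truth: BeatTable
    movie: FluorescenceMovie | None
    measured: BeatTable
    coeff: CoefficientMaps
    summary: MapSummary
    series: DispersionSeries
    timings_s: dict[str, float] = field(default_factory=dict)


def _sub_seeds(seed: int, n: int = 4) -> list[int]:
    """Independent child seeds derived deterministically from one seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep < 2**31


def run_scan(preset_name: str, grid: tuple[int, int] = (50, 50),
             seed: int = 1, n_beats: int = 100, snr: float = DEFAULT_SNR,
             k: int = 2, keep_movie: bool = False) -> ScanResult:
    """One complete random-pacing scan through the full pipeline."""
    preset = get_preset(preset_name)
    s_map, s_prot, s_sim, s_mov = _sub_seeds(seed)
    times: dict[str, float] = {}

    t0 = time.perf_counter()
    maps = build_parameter_maps(preset, grid=grid, seed=s_map)
    protocol = make_random(preset.erp_ms, preset.cl_range_ms,
                           n_beats=n_beats, seed=s_prot)
    truth = simulate_apd_series(
        maps, protocol, noise_sd=preset.noise_sd_ms, seed=s_sim,
        dispersion_gain_sd=preset.dispersion_gain_sd,
        spatial_noise_sd=preset.spatial_noise_sd_ms)
    times["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    movie = render_movie(truth, maps, snr=snr, seed=s_mov)
    times["render"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    measured = extract_beat_table(movie)
    times["process"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    coeff = fit_coefficient_maps(measured, k=k)
    summary = map_statistics(coeff, region_labels=maps.region_labels,
                             region_names=maps.region_names)
    series = dispersion_series(measured)
    times["analyze"] = time.perf_counter() - t0

    log.info("scan %s seed=%d: %s", preset_name, seed,
             {k_: round(v, 2) for k_, v in times.items()})
    return ScanResult(preset=preset_name, seed=seed, maps=maps, truth=truth,
                      movie=movie if keep_movie else None,
                      measured=measured, coeff=coeff, summary=summary,
                      series=series, timings_s=times)


def run_replicates(preset_name: str, seeds=(1, 2, 3),
                   grid: tuple[int, int] = (50, 50), n_beats: int = 100,
                   snr: float = DEFAULT_SNR, k: int = 2,
                   keep_movie: bool = False
                   ) -> tuple[list[ScanResult], pd.DataFrame]:
    """Replicate scans over seeds plus a per-scan summary table."""
    results = [run_scan(preset_name, grid=grid, seed=s, n_beats=n_beats,
                        snr=snr, k=k, keep_movie=keep_movie) for s in seeds]
    rows = []
    for r in results:
        slope, rval = correlate_dispersion_vs_dcl(r.series)
        row = {
            "preset": r.preset,
            "seed": r.seed,
            "alpha1_mean": r.summary.mean_alpha[0],
            "alpha2_mean": r.summary.mean_alpha[1] if r.coeff.k > 1 else np.nan,
            "alpha1_map_sd": r.summary.sd_alpha[0],
            "corr_a1_a2": r.summary.corr_alpha1_alpha2,
            "corr_a1_a2_corrected": r.summary.corr_alpha1_alpha2_corrected,
            "mean_r_squared": r.summary.mean_r_squared,
            "beat_to_beat_sd_ms": beat_to_beat_variation(r.measured),
            "dcl_at_max_ms": r.series.dcl_at_max_ms,
            "cl_nm1_at_max": r.series.preceding_cls_ms[2],
            "cl_nm2_at_max": r.series.preceding_cls_ms[1],
            "sigma_vs_dcl_slope": slope,
            "sigma_vs_dcl_r": rval,
            "n_pixels": r.summary.n_pixels,
        }
        for name, means in r.summary.region_means.items():
            row[f"alpha1_{name}"] = means[0]
        rows.append(row)
    return results, pd.DataFrame(rows)


def genotype_report(tables: dict[str, pd.DataFrame]) -> dict:
    """Cross-genotype summary analogous to a per-genotype statistics table.

    ``tables`` maps preset name -> per-scan summary (from
    ``run_replicates``).  Emits per-preset mean +/- SD for the recovery
    metrics, a paired t-test of CL_{n-1} vs CL_{n-2} at the
    maximum-dispersion beat within each preset, pairwise two-sample
    t-tests and a one-way ANOVA across presets on the fitted
    coefficients.
    """
    metrics = ["alpha1_mean", "alpha2_mean", "alpha1_map_sd",
               "corr_a1_a2_corrected", "beat_to_beat_sd_ms",
               "dcl_at_max_ms", "sigma_vs_dcl_slope", "mean_r_squared"]
    summary_rows = []
    for name, df in tables.items():
        row: dict = {"preset": name, "n_scans": len(df)}
        for mcol in metrics:
            row[f"{mcol}_mean"] = float(df[mcol].mean())
            row[f"{mcol}_sd"] = float(df[mcol].std(ddof=1)) \
                if len(df) > 1 else np.nan
        t_p = stats.ttest_rel(df["cl_nm1_at_max"], df["cl_nm2_at_max"]) \
            if len(df) > 1 else None
        row["paired_t_clnm1_vs_clnm2_p"] = float(t_p.pvalue) if t_p else np.nan
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    pairwise = []
    names = list(tables)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for mcol in ("alpha1_mean", "alpha2_mean", "sigma_vs_dcl_slope"):
                res = stats.ttest_ind(tables[a][mcol], tables[b][mcol])
                pairwise.append({"metric": mcol, "a": a, "b": b,
                                 "t": float(res.statistic),
                                 "p": float(res.pvalue)})
    anova = {}
    if len(names) >= 3:
        for mcol in ("alpha1_mean", "alpha2_mean"):
            res = stats.f_oneway(*[tables[nm][mcol] for nm in names])
            anova[mcol] = {"F": float(res.statistic), "p": float(res.pvalue)}
    return {"summary": summary, "pairwise": pd.DataFrame(pairwise),
            "anova": anova}


def run_pipeline(config: RunConfig) -> Path:
    """Run replicate scans for one preset and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    try:
        results, table = run_replicates(
            config.preset, seeds=config.seeds, grid=config.grid,
            n_beats=config.n_beats, snr=config.snr, k=config.k,
            keep_movie=config.save_movie)
    except Exception as exc:  # stage-named failure, partial outputs kept
        raise RuntimeError(f"pipeline stage failed for preset "
                           f"{config.preset!r}: {exc}") from exc
    table.to_csv(out / "scan_summary.csv", index=False)
    manifest = {"preset": config.preset, "seeds": list(config.seeds),
                "files": ["config.json", "scan_summary.csv"]}
    from .viz import save_apd_map_panel, save_coefficient_maps

    for r in results:
        tag = f"{config.preset}_seed{r.seed}"
        r.coeff.to_csv(out / f"coeff_{tag}.csv")
        r.series.to_csv(out / f"dispersion_{tag}.csv")
        r.measured.to_hdf5(out / f"beats_{tag}.h5")
        save_coefficient_maps(r.coeff, out / f"coeff_{tag}.png")
        save_apd_map_panel(r.measured, r.series, out / f"apd_maps_{tag}.png")
        manifest["files"] += [f"coeff_{tag}.csv", f"dispersion_{tag}.csv",
                              f"beats_{tag}.h5", f"coeff_{tag}.png",
                              f"apd_maps_{tag}.png"]
        if config.save_movie and r.movie is not None:
            from .synth import write_movie
            write_movie(r.movie, out / f"movie_{tag}.tif",
                        quantize_16bit=config.quantize_16bit)
            manifest["files"].append(f"movie_{tag}.tif")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
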