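"""Plotting helpers: per-beat APD map panels, coefficient-map heatmaps
and the iterated-map staircase diagram."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .containers import BeatTable
from .dispersion import DispersionSeries
from .mechanism import SiteModel, iterate
from .regression import CoefficientMaps

__all__ = ["save_apd_map_panel", "save_coefficient_maps", "save_staircase"]


def save_apd_map_panel(beats: BeatTable, series: DispersionSeries, path,
                       max_panels: int = 10) -> Path:
    """Row of consecutive per-beat APD maps; the max-dispersion beat is
    outlined in red and annotated with sigma_APD and delta_APD."""
    idx = series.idx_max
    first = max(3, idx - max_panels + 2)
    beats_shown = list(range(first, min(first + max_panels, beats.n_beats)))
    finite = [series.sigma_apd_ms[b] for b in beats_shown
              if np.isfinite(series.sigma_apd_ms[b])]
    maps = [beats.apd_map(b) for b in beats_shown]
    vmin = np.nanpercentile(np.stack(maps), 1)
    vmax = np.nanpercentile(np.stack(maps), 99)
    fig, axes = plt.subplots(1, len(beats_shown),
                             figsize=(1.6 * len(beats_shown), 2.2))
    for ax, b, m in zip(np.atleast_1d(axes), beats_shown, maps):
        im = ax.imshow(m, vmin=vmin, vmax=vmax, cmap="turbo")
        ax.set_xticks([]), ax.set_yticks([])
        ttl = f"beat {b}\nσ={series.sigma_apd_ms[b]:.1f}"
        ax.set_title(ttl, fontsize=7)
        if b == idx:
            for s in ax.spines.values():
                s.set_edgecolor("red"), s.set_linewidth(2)
    fig.colorbar(im, ax=axes, shrink=0.8, label="APD (ms)")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_coefficient_maps(coeff: CoefficientMaps, path) -> Path:
    """Heatmaps of the fitted a1 and a2 maps with a shared layout."""
    k = coeff.k
    fig, axes = plt.subplots(1, k, figsize=(4 * k, 3.2))
    for j, ax in enumerate(np.atleast_1d(axes)):
        m = coeff.alpha[j]
        im = ax.imshow(m, cmap="viridis")
        ax.set_title(f"alpha_{j + 1}")
        ax.set_xticks([]), ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.8)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_staircase(sites: list[SiteModel], cls, out_dir,
                   mode: str = "di") -> list[Path]:
    """Step-by-step restitution staircase frames (PNG sequence).

    Each frame adds one beat: restitution lines per site, the pacing
    constraint APD = CL - DI for the current CL, and the trajectory of
    (DI, APD) points so far.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cls = np.asarray(cls, dtype=float)
    res = iterate(sites, cls, mode=mode)
    apd = res["apd"]
    colors = plt.cm.tab10(np.linspace(0, 1, len(sites)))
    di_grid = np.linspace(0, max(cls), 100)
    paths = []
    for n in range(1, apd.shape[1]):
        if not res["captured"][n]:
            break
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for s, col in zip(sites, colors):
            ax.plot(di_grid, s.a_ms + s.s * di_grid + s.m * np.median(cls),
                    color=col, label=s.label)
        cl = cls[n - 1]
        ax.plot(di_grid, cl - di_grid, "b--", lw=1,
                label=f"APD = CL − DI (CL={cl:.0f})")
        for i_s, col in enumerate(colors):
            di_pts = cls[:n] - apd[i_s, :n]
            ax.plot(di_pts, apd[i_s, 1:n + 1], "o-", ms=3, lw=0.7, color=col)
        lo, hi = np.nanmin(apd) - 10, np.nanmax(apd) + 10
        ax.set_xlim(0, max(cls) * 0.6), ax.set_ylim(lo, hi)
        ax.set_xlabel("DI (ms)"), ax.set_ylabel("APD (ms)")
        ax.set_title(f"beat {n}, dispersion "
                     f"{res['dispersion'][n]:.1f} ms", fontsize=9)
        ax.legend(fontsize=6)
        p = out_dir / f"staircase_{n:03d}.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
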