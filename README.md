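# apdmap

Cycle-length-history-dependent analysis of action potential duration
(APD) dispersion for cardiac optical mapping, with a synthetic-data
generator that makes the entire pipeline testable end to end.

## The problem

In long-QT syndrome type 2 (LQT2), polymorphic ventricular tachycardia
is classically preceded by a short-long RR-interval pattern.  One
candidate mechanism is that such pacing histories transiently enlarge the
spatial dispersion of repolarization.  Quantifying this requires more
than a classical restitution curve: the APD of beat *n* depends on
several preceding cycle lengths (CLs), a property called short-term
cardiac memory.  This package implements the full analysis chain used to
study that question in voltage-sensitive-dye optical-mapping experiments:

- **Pacing protocols** — S1S2 extrastimulus, decremental ramp,
  random-interval pacing (CLs uniform on [ERP, ERP+50] ms), and the
  S1S2S3 protocol with fixed S2S3 and variable S1S2.
- **Signal processing** — 3×3 spatial Gaussian smoothing, 13-point
  3rd-order Savitzky–Golay derivatives, activation at (dF/dt)max,
  repolarization at (d²F/dt²)max, low-SNR pixel exclusion and iterative
  Grubbs outlier cleaning of per-beat APD maps.
- **Dispersion statistics** — per-beat spatial SD of APD (σ_APD) and the
  99%−1% percentile range (≈ 4 σ_APD), the CL pattern preceding the
  maximum-dispersion beat, and the regression of σ_APD on
  ΔCL = CL_{n−1} − CL_{n−2} (positive ΔCL = short-long).
- **Memory regression** — the per-pixel multivariate model

      APD_n = C + α₁·CL_{n−1} + α₂·CL_{n−2} + … + α_k·CL_{n−k}

  fitted by OLS (α₁ = restitution slope, α₂ = short-term memory), with
  coefficient maps, R²-vs-lag curves, and noise-corrected map summaries
  (spatial SD, corr(α₁, α₂)).
- **Mechanism model** — a two-site iterated restitution+memory map
  demonstrating that dispersion(short-long) − dispersion(long-short)
  = (L−S)(Δα₁ − Δα₂), so short-long pacing enhances dispersion exactly
  when restitution heterogeneity (Δα₁ > 0) is anticorrelated with memory
  (Δα₂ < 0).
- **Synthetic data** — genotype presets (littermate control, LQT1, LQT2,
  and an LQT2 transmural wedge) whose per-pixel coefficient maps carry
  the published population values as ground truth, rendered into noisy
  fluorescence movies (100×100 px, 1 kHz, TIFF + JSON sidecar) that the
  detectors can be validated against.

## Worked example

```python
from apdmap import run_scan

scan = run_scan("lqt2", grid=(50, 50), seed=1, n_beats=100)
s = scan.summary
print(f"fitted alpha1 = {s.mean_alpha[0]:.3f}  (truth mean 0.320)")
print(f"fitted alpha2 = {s.mean_alpha[1]:.3f}  (truth mean -0.053)")
print(f"slope-map SD  = {s.sd_alpha_corrected[0]:.3f}  (truth 0.064)")
print(f"max-dispersion beat {scan.series.idx_max}, "
      f"dCL before it = {scan.series.dcl_at_max_ms:+.1f} ms")
```

prints

```
fitted alpha1 = 0.319  (truth mean 0.320)
fitted alpha2 = -0.052  (truth mean -0.053)
slope-map SD  = 0.061  (truth 0.064)
max-dispersion beat 23, dCL before it = +42.0 ms
```

i.e. one complete synthetic LQT2 scan — movie rendering, detection,
per-pixel regression — recovers the restitution slope and memory
coefficient of the generator, and the beat with the largest spatial APD
dispersion follows a short-long (positive ΔCL) cycle pattern, the
signature this genotype shows before arrhythmia onset.

The same pipeline is available from the shell:

```sh
apdmap generate --preset lqt2 --grid 50x50 --seed 1 --out runs/scan.tif
apdmap process  --movie runs/scan.tif --out runs/beats.h5
apdmap fit      --beats runs/beats.h5 --out runs/coeff.csv
apdmap analyze  --beats runs/beats.h5 --out runs/dispersion.csv
apdmap mechanism --out-dir runs/mech --genotype lqt2
```

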