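# Methods

## The model

The package analyses how the spatial dispersion of cardiac action
potential duration (APD) depends on the recent pacing history, and
provides a synthetic optical-mapping generator that makes the whole chain
testable end to end.

The core statistical model is a linear CL-history ("restitution +
short-term memory") regression fitted per pixel:

    APD_n = C + a1*CL_{n-1} + a2*CL_{n-2} + ... + ak*CL_{n-k}

where `CL_{n-1}` is the activation interval entering beat n.  `a1` is the
(random-pacing) APD restitution slope; `a2` quantifies short-term cardiac
memory — the influence of the second-previous cycle.  The model is fitted
by ordinary least squares on raw (uncentred) CLs in ms, so `C` absorbs
the mean APD; a minimum of 80 usable beats is enforced.  Within a 50-ms
random-pacing window above the effective refractory period (ERP) the
restitution relation is well approximated as linear, which is the regime
the protocols are designed for.

Two spatial summaries carry the scientific claims: per-beat APD
dispersion `sigma_APD` (spatial SD over included pixels; the companion
99%−1% percentile range is ≈ 4 sigma for near-normal maps), and the
fitted coefficient maps with their means, spatial SDs and the spatial
Pearson correlation corr(a1, a2).

## Mechanism model

A two-site iterated map shows why a short-long CL pattern amplifies
dispersion only when restitution heterogeneity is anticorrelated with
memory.  Each site follows `APD = a + s*DI (+ m*CL_{n-2})` with the
pacing constraint `APD = CL − DI`; the constant-pacing fixed point is
`(a + (s+m)CL)/(1+s)` and is stable for s < 1.  In the purely linear
CL-driven mode the signed two-site spread obeys exactly

    spread(short-long) − spread(long-short) = (L−S)(Δs − Δm)
    spread(long-long) − spread(short-long) = Δm (L−S)

so with Δs > 0 and Δm < 0 (steep-restitution site has the stronger,
APD-shortening memory) a short second-previous cycle removes the memory
dampening |Δm·CL_{n-2}| and short-long maximises dispersion.  The
DI-driven mode reproduces the same ordering when the steep site also has
the longer APD, which is how the representative base/apex and endo/epi
sites are parameterised.

## Synthetic data generator

The generator defines the study conditions; every downstream stage is
validated against its ground truth.

**Coefficient maps.**  `a1` combines an organised base→apex gradient
(endo/epi regional contrast for the transmural wedge) with a smooth
Gaussian random field (correlation length ≈ grid/6); the sample mean and
spatial SD match the preset exactly by construction.  `a2` is built from
the standardized `a1` fluctuation plus an orthogonalized independent
field so the sample spatial correlation equals the preset target exactly.
Fluctuation fields are clipped at 2.75 SD to keep extreme pixels
physiological and capture feasible.

**Intercept compensation.**  The intercept map partially cancels the
coefficient maps at the reference CL (`C = C0 −
comp·cl_ref·(a1' + a2') + residual`), so strong restitution heterogeneity
coexists with moderate APD-map dispersion at constant pacing, as in
mapped hearts.  `comp = 0.6` for LMC/LQT2/wedge; `comp = 1.0` for LQT1,
whose restitution curves are parallel across sites (APD-map pattern
decoupled from the slope map).  This single parameter is what separates
LQT1's near-zero sigma-vs-dCL slope from LMC's positive one even though
their map SDs are nearly equal.

**Noise model.**  Three components: (i) white per-(beat,pixel) APD noise
(1.1–4 ms by genotype, set so the k=2 fit's R² lands near the reported
0.79–0.85 band); (ii) a beat-level random gain on the CL-independent APD
pattern, emulating beat-to-beat fluctuations of repolarization dispersion
that are not CL-driven — its amplitude is calibrated to the published
sigma-vs-dCL correlation coefficients (r ≈ 0.23 LMC / 0.10 LQT1 /
0.5–0.6 LQT2), and its spatial pattern is constructed exactly orthogonal
to both coefficient maps so coefficient recovery is uncontaminated;
(iii) optical shot noise added at rendering (baseline SD = amplitude/SNR
with a read-noise floor of a tenth of the median amplitude).  Without
component (ii) the maximum-dispersion beat is a deterministic function of
the CL draw and every genotype would show a significant short-long
preference, which the control data do not.

The beat-to-beat APD SD under this model reproduces the genotype ordering
(LQT2 > LMC > LQT1) but not the published magnitudes; the published
beat-to-beat SDs are not simultaneously consistent with the published R²
values under a two-lag model with independent noise, and the R² band was
given priority.

**Waveform and rendering.**  Each pixel's trace is a sum of templates: a
sigmoidal upstroke (tau 1.5 ms) whose maximum slope is the activation
time and a sigmoidal downstroke (tau 3 ms) positioned so the maximum of
the Savitzky-Golay-filtered second derivative falls exactly at the
repolarization time — the small constant peak shift introduced by the
13-point differentiator is measured on noise-free templates once per
waveform shape and subtracted, so the detector is unbiased by
construction and the APD level is defined operationally by the detector
itself.  Activation = stimulus time + planar conduction delay (default
50 cm/s from the stimulation site, ≈ 0.4 ms/pixel at 200 µm pitch).
Beats whose incoming diastolic interval falls below 20 ms are flagged
not-captured and render no template.  Movies are 1000 frames/s,
100×100 px by default (50×50 in the standard recovery experiments),
written as multi-page TIFF (float32 lossless, or 16-bit quantized) with
a JSON sidecar.

**Genotype presets.**  Population means are the published values
(a1 = 0.23/0.17/0.32 and a2 = −0.068/0.007/−0.053 for LMC/LQT1/LQT2;
slope-map SD 0.030/0.029/0.064; corr(a1,a2) = −0.41/−0.07/−0.27; wedge
a1 = 0.502, a2 = −0.213, corr −0.847, endo 0.578 vs epi 0.375 with the
endocardial region sized so the region means are consistent with the
overall mean).  ERPs are set so the mean random CL matches the
constant-pacing CL reported closest to each genotype's random scans
(200/215/245/240 ms).  The a2 map SDs are not published; they are chosen
so the anticorrelated component dominates (sd(a2) < |rho|·sd(a1)), which
the short-long mechanism requires — otherwise the orthogonal a2
variation makes long-long histories maximise dispersion.  A provenance
table (`apdmap.presets.PRESET_PROVENANCE`) marks which numbers are
published and which are modelling choices.

## Measurement chain

3×3 normalized Gaussian spatial filter (reflect borders) → 13-point,
3rd-order Savitzky-Golay first/second temporal derivatives → activation
= argmax dF/dt within each stimulus window → repolarization = argmax
d²F/dt² in (activation + 30 ms, next activation − 15 ms); the 15-ms
guard clears the next upstroke's own positive d² lobe after filter
widening.  Peaks are refined to sub-frame precision with a five-point
least-squares parabola (ties at the discrete argmax resolve to the
earliest index).  Pixel QC excludes pixels whose maximum dF/dt (per
frame) is under 3 baseline-fluorescence SDs, plus the one-pixel border;
per-beat APD maps are cleaned by an iterative two-sided Grubbs test at
alpha = 0.05.  Per-pixel CLs come from consecutive valid activations
(a single-reference-site mode is available); a beat enters the
regression only if it and its k predecessors are valid at that pixel,
which also drops the doubled intervals around a missed beat.

## Estimation details

- Per-pixel fits are batched weighted normal equations (solved with a
  conditioning guard; constant pacing is rejected as rank-deficient);
  the single-series front end uses statsmodels OLS.  Both agree with
  brute-force normal-equation oracles to 1e-8 in the tests.
- Per-pixel OLS noise inflates the spatial variance of fitted maps and
  attenuates corr(a1, a2).  The per-pixel OLS coefficient covariance is
  an unbiased estimate of that inflation, so the package also reports
  noise-corrected map SDs and correlation.  Because the corrected values
  are ratios of small moment differences, replicate scans are pooled at
  the moment level before forming the ratio (`pooled_corrected_*`);
  per-scan corrected correlations of weakly heterogeneous maps are
  convexity-biased and should not be averaged directly.
- The 3×3 spatial filter blends neighbouring waveforms; on heterogeneous
  maps the recovered coefficient at a pixel is, to first order, the
  amplitude-weighted kernel average of its neighbourhood, and a
  second-order term (the detected peak of a sigmoid mixture shifts with
  the variance of the component times, which grows with CL on steep
  maps) adds a small positive restitution-slope bias: about +0.0005
  (0.17%) on the steepest preset at a 32×32 grid, +0.0002 at 50×50, and
  zero with the filter bypassed.  This is negligible against every
  population comparison but is bounded explicitly in the recovery tests.
- Quantiles use linear interpolation between order statistics; the
  max-dispersion beat is the earliest argmax with at least three
  preceding beats; beats with under 60% of included pixels are dropped
  from dispersion series.

## What the generator does not emulate

Motion artifact and photobleaching (motion is pharmacologically
suppressed in the emulated preparations), ionic-current dynamics (EADs,
alternans beyond the linear regime, conduction block other than the
DI floor), wavefront curvature, inter-heart variability (preset means
are population means; the per-heart ± terms are not resampled by
default), and nonstationary drift.  Passing recovery tests therefore
demonstrates the correctness of the measurement and regression chain
under the stated model, not robustness to every artifact of real
recordings.

## Problem sizes

Standard recovery experiments use 50×50-pixel scans of 100 random-pacing
beats at SNR 25, with 4 replicate seeds per genotype (20 for the LQT2
map-correlation estimate, which pools the corrected moments); the test
suite uses 32×32–40×40 grids with the same beat counts.  These sizes
put the Monte-Carlo error of every reported quantity well inside its
acceptance band while keeping a full run in minutes on one core.
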