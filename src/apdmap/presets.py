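"""Genotype presets for the synthetic tissue generator.

Each preset fixes the population-mean regression coefficients of the
two-lag CL-history model ``APD_n = C + a1*CL_{n-1} + a2*CL_{n-2}`` together
with the spatial heterogeneity of the coefficient maps, the target spatial
correlation between the restitution-slope (a1) and short-term-memory (a2)
maps, the random-pacing window, and the noise level.  LMC is the littermate
control; LQT1 and LQT2 are transgenic long-QT genotypes (loss of IKs and
IKr respectively); ``lqt2_transmural`` emulates a left-ventricular wedge
mapped across the wall with distinct endocardial and epicardial regions.

``PRESET_PROVENANCE`` records where each published number comes from;
quantities with no published value (waveform shape, conduction velocity,
noise split) are this package's own modelling choices, documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["GenotypePreset", "PRESETS", "PRESET_PROVENANCE", "get_preset"]


@dataclass(frozen=True)
class GenotypePreset:
    name: str
    mean_alpha1: float
    sd_alpha1_map: float
    mean_alpha2: float
    sd_alpha2_map: float
    corr_alpha1_alpha2: float
    mean_c_ms: float
    sd_c_ms: float              # residual APD-map heterogeneity at the
                                # reference CL, on top of coefficient maps
    noise_sd_ms: float          # white per-(beat,pixel) APD noise
    erp_ms: float               # refractory period = random-CL lower bound
    compensation: float = 0.6   # fraction of coefficient-map heterogeneity
                                # cancelled by the intercept map at the
                                # reference CL; 1.0 = APD map decoupled
                                # from the slope map
    dispersion_gain_sd: float = 0.0   # per-beat random gain on the
                                      # CL-independent APD pattern:
                                      # beat-to-beat dispersion variability
                                      # not driven by cycle lengths
    spatial_noise_sd_ms: float = 0.0  # optional per-beat smooth spatial
                                      # APD fluctuation (off by default)
    cl_range_ms: float = 50.0   # width of the random-CL window
    gradient_fraction: float = 0.6  # variance share of the organised
                                    # base->apex gradient in the a1 map
    # transmural presets only: region-mean restitution slopes and the
    # fraction of the field occupied by the endocardial region
    region_alpha1: tuple[float, float] | None = None
    endo_fraction: float = 0.625
    transmural: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


PRESETS: dict[str, GenotypePreset] = {
    "lmc": GenotypePreset(
        name="lmc",
        mean_alpha1=0.23, sd_alpha1_map=0.030,
        mean_alpha2=-0.068, sd_alpha2_map=0.012,
        corr_alpha1_alpha2=-0.41,
        mean_c_ms=95.0, sd_c_ms=3.0,
        noise_sd_ms=1.8,
        erp_ms=200.0, gradient_fraction=0.5,
        dispersion_gain_sd=0.35,
    ),
    "lqt1": GenotypePreset(
        name="lqt1",
        mean_alpha1=0.17, sd_alpha1_map=0.029,
        mean_alpha2=0.007, sd_alpha2_map=0.008,
        corr_alpha1_alpha2=-0.07,
        mean_c_ms=110.0, sd_c_ms=3.0,
        noise_sd_ms=1.1,
        erp_ms=215.0, gradient_fraction=0.5,
        dispersion_gain_sd=0.25,
        compensation=1.0,  # APD-map pattern decoupled from the (nearly
                           # uniform) slope map: restitution curves are
                           # parallel across sites in this genotype
    ),
    "lqt2": GenotypePreset(
        name="lqt2",
        mean_alpha1=0.32, sd_alpha1_map=0.064,
        mean_alpha2=-0.053, sd_alpha2_map=0.015,
        corr_alpha1_alpha2=-0.27,
        mean_c_ms=90.0, sd_c_ms=3.0,
        noise_sd_ms=2.5,
        erp_ms=245.0, gradient_fraction=0.8,
        dispersion_gain_sd=0.40,
    ),
    "lqt2_transmural": GenotypePreset(
        name="lqt2_transmural",
        mean_alpha1=0.502, sd_alpha1_map=0.040,  # within-region SD; regional
        mean_alpha2=-0.213, sd_alpha2_map=0.080,  # contrast adds the rest
        corr_alpha1_alpha2=-0.847,
        mean_c_ms=75.0, sd_c_ms=3.0,
        noise_sd_ms=4.0,
        erp_ms=240.0,
        dispersion_gain_sd=0.30,
        region_alpha1=(0.578, 0.375), endo_fraction=0.625,
        transmural=True,
    ),
}

# Published sources of the preset numbers (population means over hearts).
PRESET_PROVENANCE: dict[str, str] = {
    "lmc.mean_alpha1": "coefficient a1 under random stimulation, 0.23 +/- 0.06 (n=6)",
    "lmc.mean_alpha2": "coefficient a2 under random stimulation, -0.068 +/- 0.045 (n=6)",
    "lmc.sd_alpha1_map": "SD of restitution-slope map, 0.030 +/- 0.014 (n=4)",
    "lmc.corr_alpha1_alpha2": "a1-a2 spatial correlation, largest in control (-0.41)",
    "lqt1.mean_alpha1": "coefficient a1 under random stimulation, 0.17 +/- 0.02 (n=6)",
    "lqt1.mean_alpha2": "coefficient a2 under random stimulation, 0.007 +/- 0.051 (n=6)",
    "lqt1.sd_alpha1_map": "SD of restitution-slope map, 0.029 +/- 0.008 (n=4)",
    "lqt1.corr_alpha1_alpha2": "a1-a2 spatial correlation, -0.07 +/- 0.15 (n=6)",
    "lqt2.mean_alpha1": "coefficient a1 under random stimulation, 0.32 +/- 0.06 (n=6)",
    "lqt2.mean_alpha2": "coefficient a2 under random stimulation, -0.053 +/- 0.021 (n=6)",
    "lqt2.sd_alpha1_map": "SD of restitution-slope map, 0.064 +/- 0.025 (n=4)",
    "lqt2.corr_alpha1_alpha2": "a1-a2 spatial correlation, -0.27 +/- 0.10 (n=6)",
    "lqt2_transmural.mean_alpha1": "wedge coefficient a1, 0.502 +/- 0.130",
    "lqt2_transmural.mean_alpha2": "wedge coefficient a2, -0.213 +/- 0.100",
    "lqt2_transmural.corr_alpha1_alpha2": "wedge a1-a2 spatial correlation, -0.847 +/- 0.067",
    "lqt2_transmural.region_alpha1": "endocardium 0.578 vs epicardium 0.375",
    "*.cl_range_ms": "random CLs span a 50-ms window above the refractory period",
    "*.erp_ms": "set so the mean random CL matches the constant-pacing CL "
                "reported closest to each genotype's random scans",
    "*.mean_c_ms / noise / gradient_fraction / sd maps without a source":
                "modelling choices of this package (see docs/methods.md)",
}


def get_preset(name: str) -> GenotypePreset:
    key = name.lower()
    if key not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[key]
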