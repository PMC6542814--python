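"""Seeded synthetic inputs emulating the field and laboratory measurements.

The real spectra behind the model (underwater light fields at 2–30 m,
gammarid eye/body optics, the spark's relative radiance, brown-algae
substrate) live in an external archive; this module generates statistically
faithful stand-ins so the whole pipeline is runnable and testable offline.
The generator pins the summary statistics the measurements established —
spark relative radiance peaking at 472 nm at 2.15× a diffuse white standard
with a 400–700 nm band mean of 1.34 (range 0.63–2.09), coaxial:non-coaxial
eye-reflectance ratios {2.68, 4.09, 9.87}, eye radius 0.0625 mm, spark
radius 0.09–0.25 mm — and fills in the unpublished shapes with smooth,
seeded curves. Everything is deterministic given the seed.

Free parameters that the source measurements do *not* pin (shading
fractions, body reflectance/transmittance levels, substrate shape) are
package defaults calibrated once to reproduce the qualitative detection-map
pattern; see docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .radiometry import (
    GammaridOptics,
    LightFieldScenario,
    Shading,
    SparkModel,
    ViewerOptics,
)
from .spectra import (
    CANONICAL_GRID,
    Spectrum,
    SpectrumUnit,
    band_mean,
    write_spectrum_csv,
)
from .vision import ViewerVisualSystem, default_ocular_media

__all__ = [
    "SynthConfig",
    "generate_light_field",
    "generate_gammarid",
    "generate_spark",
    "generate_substrate",
    "scale_spark",
    "build_scenario",
    "write_fixtures",
]

# distinct per-component salts so one seed yields independent streams
_SALT_LIGHT, _SALT_GAMMARID, _SALT_SPARK, _SALT_SUBSTRATE = 11, 23, 37, 53


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator settings. Defaults are the packaged study conditions."""

    seed: int = 0
    depth_m: float = 10.0
    surface_spectrum_shape: str = "daylight_like"  # or "flat"
    #: diffuse attenuation at 400 nm, m^-1 (coastal-water-like)
    attenuation_blue: float = 0.05
    #: extra attenuation at 700 nm, m^-1; K rises monotonically to the red
    attenuation_red: float = 0.55
    #: band-mean sidewelling/downwelling ratio in open (unshaded) water
    sidewelling_fraction: float = 0.20
    #: band-mean shaded-sidewelling/downwelling ratios per shading category
    shading_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"weak": 0.10, "average": 0.05, "strong": 0.025}
    )
    spark_peak_nm: float = 472.0
    spark_peak_rel: float = 2.15
    spark_band_mean: float = 1.34
    spark_radius_mm: float = 0.16
    eye_ratio: float = 4.09
    eye_noncoaxial_level: float = 0.02
    eye_radius_mm: float = 0.0625
    body_reflectance_level: float = 0.003
    body_transmittance_level: float = 0.8
    #: relative amplitude of the seeded smooth wiggle on generated spectra
    wiggle_amplitude: float = 0.08

    def __post_init__(self) -> None:
        sf = dict(self.shading_fractions)
        missing = {"weak", "average", "strong"} - sf.keys()
        if missing:
            raise ValueError(f"shading_fractions missing categories: {sorted(missing)}")
        if not sf["strong"] < sf["average"] < sf["weak"] < self.sidewelling_fraction:
            raise ValueError(
                "shading fractions must be ordered strong < average < weak < none"
            )
        if not 0 < sf["strong"]:
            raise ValueError("shading fractions must be positive")
        if self.surface_spectrum_shape not in ("flat", "daylight_like"):
            raise ValueError(
                f"unknown surface_spectrum_shape {self.surface_spectrum_shape!r}"
            )
        if self.eye_ratio <= 1:
            raise ValueError(f"eye_ratio must exceed 1, got {self.eye_ratio}")
        if not 0 <= self.body_transmittance_level <= 1:
            raise ValueError("body_transmittance_level must lie in [0, 1]")

    def sigma_fraction(self, shading: Shading) -> float:
        if shading is Shading.NONE:
            return self.sidewelling_fraction
        return dict(self.shading_fractions)[shading.value]


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, salt])


def _smooth_shape(rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth positive curve with unit band mean: 1 + a few random low-order
    sinusoids, floored and renormalised."""
    u = (CANONICAL_GRID - 400.0) / 300.0
    shape = np.ones_like(u)
    for k in (1, 2, 3):
        amp = amplitude / k * rng.uniform(0.3, 1.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        shape = shape + amp * np.sin(2.0 * np.pi * k * u + phase)
    shape = np.maximum(shape, 0.2)
    spec = Spectrum(CANONICAL_GRID, shape, SpectrumUnit.RELATIVE)
    return shape / band_mean(spec, 400.0, 700.0)


def _surface_spectrum(cfg: SynthConfig) -> np.ndarray:
    if cfg.surface_spectrum_shape == "flat":
        return np.ones_like(CANONICAL_GRID)
    # broad, gently peaked daylight-like curve
    return 0.9 + 0.4 * np.exp(-(((CANONICAL_GRID - 560.0) / 150.0) ** 2))


def attenuation_coefficients(cfg: SynthConfig) -> np.ndarray:
    """Diffuse attenuation K(λ), m⁻¹: monotone increasing toward the red,
    emulating coastal water that strips long wavelengths with depth."""
    u = (CANONICAL_GRID - 400.0) / 300.0
    return cfg.attenuation_blue + cfg.attenuation_red * u**3


def generate_light_field(
    cfg: SynthConfig,
    depth_m: float | None = None,
    shading: Shading = Shading.AVERAGE,
) -> LightFieldScenario:
    """Downwelling + sidewelling white-standard radiance proxies at depth.

    L_dw(λ, z) = L_surface(λ)·exp(−K(λ)·z); the sidewelling field is the
    configured (flat) fraction σ of the downwelling field, and a shading
    category replaces σ with its shaded fraction.
    """
    z = cfg.depth_m if depth_m is None else depth_m
    if z < 0:
        raise ValueError(f"depth must be >= 0 m, got {z}")
    L_dw = Spectrum(
        CANONICAL_GRID,
        _surface_spectrum(cfg) * np.exp(-attenuation_coefficients(cfg) * z),
        SpectrumUnit.ENERGY_RADIANCE,
    )
    sigma_none = np.full_like(CANONICAL_GRID, cfg.sidewelling_fraction)
    L_sw = L_dw.with_values(L_dw.values * sigma_none)
    sigma = np.full_like(CANONICAL_GRID, cfg.sigma_fraction(shading))
    return LightFieldScenario(
        depth_m=z,
        L_dw=L_dw,
        L_sw_unshaded=L_sw,
        shading=shading,
        sigma=Spectrum(CANONICAL_GRID, sigma, SpectrumUnit.FRACTION),
    )


def generate_gammarid(cfg: SynthConfig, ratio: float | None = None) -> GammaridOptics:
    """Prey optics with the exact configured coaxial:non-coaxial band ratio.

    The non-coaxial eye reflectance is a smooth seeded curve with the
    configured band mean; the coaxial curve is that shape scaled by the
    ratio, so the band-mean ratio is exact by construction. The body is a
    very dark diffuse reflector with high transmittance (translucent).
    """
    ratio = cfg.eye_ratio if ratio is None else float(ratio)
    if ratio <= 1:
        raise ValueError(f"coaxial:non-coaxial ratio must exceed 1, got {ratio}")
    rng = _rng(cfg, _SALT_GAMMARID)
    nc_shape = _smooth_shape(rng, cfg.wiggle_amplitude)
    body_shape = _smooth_shape(rng, cfg.wiggle_amplitude)
    R_nc = Spectrum(
        CANONICAL_GRID, cfg.eye_noncoaxial_level * nc_shape, SpectrumUnit.RELATIVE
    )
    R_cx = R_nc * ratio
    R_body = Spectrum(
        CANONICAL_GRID, cfg.body_reflectance_level * body_shape, SpectrumUnit.RELATIVE
    )
    # mild tilt on transmittance, clipped into [0, 1]
    tilt = 1.0 + 0.05 * (CANONICAL_GRID - 550.0) / 150.0
    T_body = Spectrum(
        CANONICAL_GRID,
        np.clip(cfg.body_transmittance_level * tilt, 0.0, 1.0),
        SpectrumUnit.FRACTION,
    )
    return GammaridOptics(
        R_cx=R_cx,
        R_nc=R_nc,
        ratio=ratio,
        R_body=R_body,
        T_body=T_body,
        eye_radius_mm=cfg.eye_radius_mm,
    )


def generate_spark(
    cfg: SynthConfig,
    radius_mm: float | None = None,
    target_band_mean: float | None = None,
) -> SparkModel:
    """Blue ocular spark: a Gaussian bump on a pedestal.

    The pedestal p and bump height h are solved so the grid maximum sits at
    the configured peak wavelength with the configured peak value, and the
    400–700 nm band mean equals ``target_band_mean`` exactly (band_mean is
    linear in the values, so the solution is closed-form).
    """
    m = cfg.spark_band_mean if target_band_mean is None else float(target_band_mean)
    peak = cfg.spark_peak_rel
    if not 0.0 < m < peak:
        raise ValueError(
            f"spark band mean must lie in (0, peak={peak:g}), got {m:g}"
        )
    rng = _rng(cfg, _SALT_SPARK)
    width = 45.0 * (1.0 + 0.1 * (rng.random() - 0.5))
    bump = np.exp(-(((CANONICAL_GRID - cfg.spark_peak_nm) / width) ** 2) / 2.0)
    g = band_mean(
        Spectrum(CANONICAL_GRID, bump, SpectrumUnit.RELATIVE), 400.0, 700.0
    )
    h = (peak - m) / (1.0 - g)
    p = peak - h
    if p < 0:
        raise ValueError(
            f"spark shape infeasible: band mean {m:g} too far below peak "
            f"{peak:g} for bump width {width:.1f} nm"
        )
    rho = Spectrum(CANONICAL_GRID, p + h * bump, SpectrumUnit.RELATIVE)
    return SparkModel(radius_mm=radius_mm or cfg.spark_radius_mm, rho=rho)


def scale_spark(spark: SparkModel, target_band_mean: float) -> SparkModel:
    """Rescale a spark's radiance spectrum to a new band mean, preserving
    its shape (a dimmer/brighter spark of identical colour)."""
    if target_band_mean <= 0:
        raise ValueError("target band mean must be > 0")
    factor = target_band_mean / spark.band_mean_radiance
    return SparkModel(spark.radius_mm, spark.rho * factor)


def generate_substrate(cfg: SynthConfig) -> Spectrum:
    """Brown-algae-like foraging substrate: low reflectance through the
    blue-green, rising past ~565 nm toward the red."""
    rng = _rng(cfg, _SALT_SUBSTRATE)
    base = 0.04 + 0.22 / (1.0 + np.exp(-(CANONICAL_GRID - 565.0) / 25.0))
    wiggle = _smooth_shape(rng, cfg.wiggle_amplitude / 2.0)
    return Spectrum(CANONICAL_GRID, base * wiggle, SpectrumUnit.RELATIVE)


def build_scenario(
    cfg: SynthConfig,
    ratio: float | None = None,
    shading: Shading = Shading.AVERAGE,
    spark_radius_mm: float | None = None,
    spark_band_mean: float | None = None,
    overrides: Mapping[str, Spectrum] | None = None,
):
    """Assemble a complete end-to-end scenario from the generator.

    ``overrides`` may replace individual generated spectra (keys:
    ``downwelling``, ``spark``, ``eye_coaxial``, ``eye_noncoaxial``,
    ``body_reflectance``, ``body_transmittance``, ``substrate``,
    ``ocular_media``) with measured CSV inputs resampled on the canonical
    grid.
    """
    from .detection import Scenario  # deferred: detection sits above synth

    overrides = dict(overrides or {})
    lf = generate_light_field(cfg, shading=shading)
    gam = generate_gammarid(cfg, ratio=ratio)
    spark = generate_spark(cfg, radius_mm=spark_radius_mm)
    if spark_band_mean is not None:
        spark = scale_spark(spark, spark_band_mean)
    substrate = generate_substrate(cfg)
    t_om = default_ocular_media()

    if "downwelling" in overrides:
        L_dw = overrides["downwelling"]
        lf = dataclasses.replace(
            lf, L_dw=L_dw, L_sw_unshaded=L_dw * cfg.sidewelling_fraction
        )
    if "spark" in overrides:
        spark = SparkModel(spark.radius_mm, overrides["spark"])
    gam_fields = {}
    if "eye_noncoaxial" in overrides:
        gam_fields["R_nc"] = overrides["eye_noncoaxial"]
    if "eye_coaxial" in overrides:
        gam_fields["R_cx"] = overrides["eye_coaxial"]
    if "body_reflectance" in overrides:
        gam_fields["R_body"] = overrides["body_reflectance"]
    if "body_transmittance" in overrides:
        gam_fields["T_body"] = overrides["body_transmittance"]
    if gam_fields:
        if "R_cx" in gam_fields or "R_nc" in gam_fields:
            R_cx = gam_fields.get("R_cx", gam.R_cx)
            R_nc = gam_fields.get("R_nc", gam.R_nc)
            gam_fields["ratio"] = band_mean(R_cx, 400, 700) / band_mean(R_nc, 400, 700)
        gam = dataclasses.replace(gam, **gam_fields)
    if "substrate" in overrides:
        substrate = overrides["substrate"]
    if "ocular_media" in overrides:
        t_om = overrides["ocular_media"]

    return Scenario(
        light_field=lf,
        spark=spark,
        gammarid=gam,
        substrate=substrate,
        viewer=ViewerOptics(),
        visual_system=dataclasses.replace(ViewerVisualSystem(), T_om=t_om),
    )


def write_fixtures(cfg: SynthConfig, out_dir) -> Path:
    """Write the full synthetic fixture set as spectrum CSVs plus a manifest
    recording the seed and config. Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lf = generate_light_field(cfg, shading=Shading.NONE)
    gam = generate_gammarid(cfg)
    spark = generate_spark(cfg)
    substrate = generate_substrate(cfg)
    files = {
        "downwelling.csv": lf.L_dw,
        "sidewelling_unshaded.csv": lf.L_sw_unshaded,
        "spark_relative_radiance.csv": spark.rho,
        "eye_coaxial_reflectance.csv": gam.R_cx,
        "eye_noncoaxial_reflectance.csv": gam.R_nc,
        "body_reflectance.csv": gam.R_body,
        "body_transmittance.csv": gam.T_body,
        "substrate_reflectance.csv": substrate,
        "ocular_media_transmission.csv": default_ocular_media(),
    }
    for name, spec in files.items():
        write_spectrum_csv(spec, out / name)
    manifest = {
        "seed": cfg.seed,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "files": sorted(files),
        "note": "synthetic stand-ins for archived field/lab spectra",
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
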