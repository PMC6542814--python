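"""Round-trip radiometry of the ocular-spark / prey-eye interaction.

The scene: a viewer fish in open downwelling light faces a small prey
(gammarid) eye at distance d on the same horizontal axis. The prey sits in
a (possibly shaded) sidewelling light field. Two radiance components reach
the viewer from the prey eye:

* **ambient** — sidewelling light reflected by the eye's inter-ommatidial
  reflectors at their weak non-coaxial reflectance, independent of d;
* **spark increment** — light from the viewer's own ocular spark (a bright
  iris spot of relative radiance ρ adjacent to the pupil) that travels to
  the prey eye, is reflected at the strong coaxial reflectance, and returns.

All reflectances and the spark radiance are *relative* quantities measured
against a diffuse white standard, which absorbs the Lambertian geometry of
the illumination: a surface of relative reflectance R under a light field
whose white-standard radiance is L has radiance R·L. The one place an
explicit 1/π appears is the conversion of the spark's irradiance at the
prey eye, L_spark·Ω_spark(d), into the white-standard-equivalent radiance
scale on which the coaxial reflectance is defined (a Lambertian white
standard under irradiance E has radiance E/π).

The same machinery applied to the translucent prey *body* (diffuse
reflectance plus transmitted substrate light, no coaxial boost) serves as a
negative control: the spark should light up eyes, not bodies.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .geometry import DiscGeometry, solid_angle_point
from .spectra import Spectrum, SpectrumUnit, band_mean

__all__ = [
    "Shading",
    "LightFieldScenario",
    "SparkModel",
    "GammaridOptics",
    "ViewerOptics",
    "eye_radiance_ambient",
    "spark_increment",
    "flux_at_pupil",
    "body_radiance",
]


class Shading(enum.Enum):
    """Shading category of the prey's sidewelling light field."""

    NONE = "none"
    WEAK = "weak"
    AVERAGE = "average"
    STRONG = "strong"


@dataclasses.dataclass(frozen=True)
class LightFieldScenario:
    """Ambient light at a given depth with a shading category.

    ``sigma`` is the effective sidewelling-to-downwelling ratio for the
    chosen category (a fraction spectrum in (0, 1]); for ``Shading.NONE``
    it is the measured unshaded ratio L_sw/L_dw itself.
    """

    depth_m: float
    L_dw: Spectrum
    L_sw_unshaded: Spectrum
    shading: Shading
    sigma: Spectrum

    def __post_init__(self) -> None:
        if self.sigma.unit is not SpectrumUnit.FRACTION:
            raise ValueError("sigma must be a fraction spectrum")
        if np.any(self.sigma.values <= 0):
            raise ValueError("sigma must be strictly positive")


@dataclasses.dataclass(frozen=True)
class SparkModel:
    """The emitter: ocular-spark disc radius and relative radiance ρ(λ)."""

    radius_mm: float
    rho: Spectrum

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"spark radius must be > 0, got {self.radius_mm}")

    @property
    def band_mean_radiance(self) -> float:
        return band_mean(self.rho, 400.0, 700.0)


@dataclasses.dataclass(frozen=True)
class GammaridOptics:
    """Prey optics: eye reflectances (coaxial ≫ non-coaxial), body optics.

    ``ratio`` is the band-level coaxial:non-coaxial factor (the field data
    span 2.68–9.87 with mean 4.09).
    """

    R_cx: Spectrum
    R_nc: Spectrum
    ratio: float
    R_body: Spectrum
    T_body: Spectrum
    eye_radius_mm: float = 0.0625

    def __post_init__(self) -> None:
        if self.eye_radius_mm <= 0:
            raise ValueError("eye_radius_mm must be > 0")
        if self.ratio <= 1:
            raise ValueError(f"coaxial:non-coaxial ratio must exceed 1, got {self.ratio}")
        if self.T_body.unit is not SpectrumUnit.FRACTION:
            raise ValueError("T_body must be a fraction spectrum")
        if np.any(self.R_cx.values < self.R_nc.values - 1e-12):
            raise ValueError("coaxial reflectance must dominate non-coaxial")


@dataclasses.dataclass(frozen=True)
class ViewerOptics:
    """The receiver aperture: viewer pupil (default triplefin, 0.78 mm radius)."""

    pupil_radius_mm: float = 0.78

    def __post_init__(self) -> None:
        if self.pupil_radius_mm <= 0:
            raise ValueError("pupil_radius_mm must be > 0")

    @property
    def pupil_area_mm2(self) -> float:
        return float(np.pi * self.pupil_radius_mm**2)


def eye_radiance_ambient(lf: LightFieldScenario, g: GammaridOptics) -> Spectrum:
    """Prey-eye radiance without the spark: L₀(λ) = R_nc(λ)·σ(λ)·L_dw(λ).

    The eye reflects its (shaded) sidewelling light field at the weak
    non-coaxial reflectance; independent of viewing distance.
    """
    return g.R_nc * lf.sigma * lf.L_dw


def spark_increment(
    lf: LightFieldScenario,
    spark: SparkModel,
    g: GammaridOptics,
    d_mm: float,
    solid_angle=solid_angle_point,
) -> Spectrum:
    """Radiance added to the prey eye by the spark at distance ``d_mm``.

    ΔL(λ, d) = R_cx(λ) · ρ(λ)·L_dw(λ)·Ω_spark(d) / π: the spark (radiance
    ρ·L_dw) subtends Ω_spark(d) at the prey eye, delivering irradiance
    ρ·L_dw·Ω_spark; dividing by π expresses that irradiance on the
    white-standard radiance scale on which the coaxial reflectance R_cx is
    defined. ``solid_angle`` may be swapped for a Monte-Carlo or
    extended-receiver variant.
    """
    if d_mm <= 0:
        raise ValueError(f"distance must be > 0 mm, got {d_mm}")
    omega = solid_angle(DiscGeometry(spark.radius_mm, d_mm))
    return g.R_cx * spark.rho * lf.L_dw * (omega / np.pi)


def flux_at_pupil(
    L_target: Spectrum,
    target_radius_mm: float,
    d_mm: float,
    v: ViewerOptics,
    solid_angle=solid_angle_point,
) -> Spectrum:
    """Per-nm flux entering the viewer's pupil from a small disc target.

    Φ(λ) = L(λ)·Ω_target(d)·A_pupil. Areas are in mm², so the absolute
    scale is arbitrary-but-consistent; contrasts downstream are invariant
    to it, and only the energy-vs-photon family of ``L_target`` matters.
    """
    if d_mm <= 0:
        raise ValueError(f"distance must be > 0 mm, got {d_mm}")
    omega = solid_angle(DiscGeometry(target_radius_mm, d_mm))
    return L_target * (omega * v.pupil_area_mm2)


def body_radiance(
    lf: LightFieldScenario,
    g: GammaridOptics,
    substrate_R: Spectrum,
    spark: SparkModel | None = None,
    d_mm: float | None = None,
    with_spark: bool = False,
) -> Spectrum:
    """Radiance of the translucent prey body (negative control).

    Diffusely reflected sidewelling light plus substrate light transmitted
    through the body:
    L_body = R_body·σ·L_dw + T_body·R_substrate·σ·L_dw,
    optionally plus the spark increment with R_body standing in the coaxial
    role (the body has no directional reflector, so its diffuse reflectance
    is all the spark can recruit).
    """
    ambient = g.R_body * lf.sigma * lf.L_dw + g.T_body * substrate_R * lf.sigma * lf.L_dw
    if not with_spark:
        return ambient
    if spark is None or d_mm is None:
        raise ValueError("with_spark=True requires spark and d_mm")
    if d_mm <= 0:
        raise ValueError(f"distance must be > 0 mm, got {d_mm}")
    omega = solid_angle_point(DiscGeometry(spark.radius_mm, d_mm))
    inc = g.R_body * spark.rho * lf.L_dw * (omega / np.pi)
    return ambient + inc
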