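"""Viewer-side transduction: photoreceptors, quantum catches, contrasts.

The viewer (a triplefin) is modelled with a single cone (peak 468 nm) and a
double cone (members peaking at 517 and 530 nm, pooled as the achromatic
channel), a 1:4 single:double density, ocular-media transmission, and two
contrast measures between the prey-eye flux with and without the spark:

* the receptor-noise-limited (RNL) chromatic distance in just-noticeable
  differences (JND), threshold 1.0, with log receptor signals and a Weber
  fraction ω = 0.05 anchored on the abundant double-cone class;
* the Michelson achromatic contrast (Q₁−Q₂)/(Q₁+Q₂) on the pooled
  double-cone catch, against an optimistic (0.008) or conservative (0.024)
  detection threshold.

Spectral sensitivities follow the Govardovskii et al. (2000) vertebrate A1
visual-pigment template (α plus β band), peak-normalised.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .spectra import CANONICAL_GRID, Spectrum, SpectrumUnit

__all__ = [
    "cone_template",
    "ConeClass",
    "QuantumCatches",
    "ViewerVisualSystem",
    "default_ocular_media",
    "quantum_catch",
    "chromatic_jnd",
    "michelson",
]


def cone_template(lambda_max_nm: float, grid: np.ndarray = CANONICAL_GRID) -> Spectrum:
    """Govardovskii A1 pigment template, peak-normalised on ``grid``.

    α band: S_α = 1/(e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D) with
    x = λmax/λ, A=69.7, B=28, C=−14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940).
    β band: A_β·exp(−((λ−λm_β)/b_β)²) with A_β=0.26,
    λm_β = 189 + 0.315·λmax, b_β = −40.5 + 0.195·λmax.
    """
    if not 400.0 <= lambda_max_nm <= 650.0:
        raise ValueError(
            f"lambda_max {lambda_max_nm} nm outside supported range [400, 650]"
        )
    grid = np.asarray(grid, dtype=float)
    x = lambda_max_nm / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lm_beta = 189.0 + 0.315 * lambda_max_nm
    b_beta = -40.5 + 0.195 * lambda_max_nm
    beta = 0.26 * np.exp(-(((grid - lm_beta) / b_beta) ** 2))
    s = alpha + beta
    return Spectrum(grid, s / s.max(), SpectrumUnit.RELATIVE)


@dataclasses.dataclass(frozen=True)
class ConeClass:
    """A photoreceptor class: peak wavelength and its sensitivity spectrum."""

    lambda_max_nm: float
    sensitivity: Spectrum

    @classmethod
    def from_template(cls, lambda_max_nm: float, grid: np.ndarray = CANONICAL_GRID):
        return cls(lambda_max_nm, cone_template(lambda_max_nm, grid))


@dataclasses.dataclass(frozen=True)
class QuantumCatches:
    """Catches of the two channels: single cone and pooled double cone."""

    q_single: float
    q_double: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.q_single) and np.isfinite(self.q_double)):
            raise ValueError("quantum catches must be finite")
        if self.q_single < 0 or self.q_double < 0:
            raise ValueError("quantum catches must be non-negative")


def default_ocular_media(grid: np.ndarray = CANONICAL_GRID) -> Spectrum:
    """Synthetic ocular-media transmission: logistic rise centred at 410 nm
    (scale 8 nm) to a plateau of 1 — a generic short-wave cut-on standing in
    for a species-specific curve, replaceable by CSV input."""
    grid = np.asarray(grid, dtype=float)
    t = 1.0 / (1.0 + np.exp(-(grid - 410.0) / 8.0))
    return Spectrum(grid, t, SpectrumUnit.FRACTION)


def _default_single() -> ConeClass:
    return ConeClass.from_template(468.0)


def _default_double() -> tuple[ConeClass, ConeClass]:
    return (ConeClass.from_template(517.0), ConeClass.from_template(530.0))


@dataclasses.dataclass(frozen=True)
class ViewerVisualSystem:
    """Receptor set, noise parameters and detection thresholds of the viewer."""

    single: ConeClass = dataclasses.field(default_factory=_default_single)
    double_members: tuple[ConeClass, ConeClass] = dataclasses.field(
        default_factory=_default_double
    )
    T_om: Spectrum = dataclasses.field(default_factory=default_ocular_media)
    density_single: float = 1.0
    density_double: float = 4.0
    weber: float = 0.05
    jnd_threshold: float = 1.0
    michelson_optimistic: float = 0.008
    michelson_conservative: float = 0.024

    def __post_init__(self) -> None:
        if self.weber <= 0:
            raise ValueError("weber fraction must be > 0")
        if self.density_single <= 0 or self.density_double <= 0:
            raise ValueError("receptor densities must be > 0")
        if not self.michelson_optimistic < self.michelson_conservative:
            raise ValueError("optimistic threshold must be below conservative")

    @property
    def noise_double(self) -> float:
        """Channel noise of the abundant double-cone class: e_d = ω."""
        return self.weber

    @property
    def noise_single(self) -> float:
        """Noise of the sparser single-cone class, scaled by relative density:
        e_s = ω·√(η_double/η_single)."""
        return self.weber * float(np.sqrt(self.density_double / self.density_single))


def quantum_catch(flux: Spectrum, vs: ViewerVisualSystem) -> QuantumCatches:
    """Integrate photon flux against ocular media and cone sensitivities.

    q_i = ∫ Φ(λ)·T_om(λ)·S_i(λ) dλ (trapezoid); the double-cone catch sums
    both members. The flux must be in photon units — convert explicitly
    with :func:`photoloc.spectra.to_photon_units` first.
    """
    if flux.unit is SpectrumUnit.ENERGY_RADIANCE:
        raise ValueError(
            "quantum_catch requires photon-unit flux; apply to_photon_units first"
        )
    grid = flux.wavelengths_nm

    def _catch(cone: ConeClass) -> float:
        sens = cone.sensitivity
        if not flux.same_grid(sens) or not flux.same_grid(vs.T_om):
            raise ValueError("flux, sensitivities and T_om must share one grid")
        return float(np.trapezoid(flux.values * vs.T_om.values * sens.values, grid))

    q_single = _catch(vs.single)
    q_double = sum(_catch(m) for m in vs.double_members)
    return QuantumCatches(q_single, q_double)


def chromatic_jnd(c1: QuantumCatches, c2: QuantumCatches, vs: ViewerVisualSystem) -> float:
    """Dichromatic receptor-noise-limited distance in JND.

    Δf_i = ln(q_i(c1)/q_i(c2)) per channel;
    ΔS = |Δf_single − Δf_double| / √(e_single² + e_double²).
    Intensity-invariant: equal scaling of both stimuli gives 0.
    """
    if min(c1.q_single, c1.q_double, c2.q_single, c2.q_double) <= 0:
        raise ValueError("chromatic JND undefined for zero quantum catches")
    df_s = np.log(c1.q_single / c2.q_single)
    df_d = np.log(c1.q_double / c2.q_double)
    e_s, e_d = vs.noise_single, vs.noise_double
    return float(abs(df_s - df_d) / np.sqrt(e_s**2 + e_d**2))


def michelson(c1: QuantumCatches, c2: QuantumCatches) -> float:
    """Achromatic Michelson contrast on the pooled double-cone catch:
    (Q₁ − Q₂)/(Q₁ + Q₂) ∈ [−1, 1]."""
    total = c1.q_double + c2.q_double
    if total <= 0:
        raise ValueError("Michelson contrast undefined when both catches are zero")
    return float((c1.q_double - c2.q_double) / total)
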