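"""Wavelength-indexed spectra: the shared container for every radiometric
quantity in the pipeline.

All quantities — downwelling/sidewelling light, spark relative radiance,
prey-eye and body reflectances, ocular-media transmission, photoreceptor
sensitivities — are vectors over a common visible-light grid. The canonical
working grid is 400–700 nm at 1 nm steps (301 points); inputs on other grids
are resampled (linear interpolation) on load.

Unit semantics are tracked with a small enum rather than a full unit system:

* ``energy_radiance``  — W sr⁻¹ m⁻² nm⁻¹ (or an arbitrary proxy thereof; the
  contrast model is scale-invariant, only the *family* energy-vs-photon
  matters for quantum-catch integration),
* ``photon_radiance``  — photons s⁻¹ sr⁻¹ m⁻² nm⁻¹,
* ``relative``         — measured against a diffuse (Lambertian) white
  standard under identical illumination; may exceed 1,
* ``fraction``         — a transmittance or shading factor in [0, 1].
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "CANONICAL_GRID",
    "SpectrumUnit",
    "Spectrum",
    "resample",
    "to_photon_units",
    "band_mean",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

#: Planck constant, J s (SI exact value).
PLANCK_H = 6.62607015e-34
#: Speed of light in vacuum, m s⁻¹ (SI exact value).
SPEED_OF_LIGHT = 2.99792458e8

#: 400–700 nm at 1 nm: the working grid all pipeline inputs are resampled to.
CANONICAL_GRID = np.arange(400.0, 701.0)
CANONICAL_GRID.setflags(write=False)

_FRACTION_TOL = 1e-9


class SpectrumUnit(enum.Enum):
    """Unit family of a :class:`Spectrum`."""

    ENERGY_RADIANCE = "energy_radiance"
    PHOTON_RADIANCE = "photon_radiance"
    RELATIVE = "relative"
    FRACTION = "fraction"


_DIMENSIONLESS = {SpectrumUnit.RELATIVE, SpectrumUnit.FRACTION}


def _product_unit(a: SpectrumUnit, b: SpectrumUnit) -> SpectrumUnit:
    if a in _DIMENSIONLESS and b in _DIMENSIONLESS:
        # reflectance x transmittance etc. -> generic dimensionless
        return SpectrumUnit.RELATIVE
    if a in _DIMENSIONLESS:
        return b
    if b in _DIMENSIONLESS:
        return a
    raise ValueError(
        f"cannot multiply two physical-unit spectra ({a.value} x {b.value})"
    )


@dataclasses.dataclass(frozen=True, eq=False)
class Spectrum:
    """Immutable wavelength-indexed vector with declared unit semantics.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    values
        Non-negative, finite values, one per wavelength.
    unit
        Unit family; ``fraction`` additionally enforces values ≤ 1.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit: SpectrumUnit = SpectrumUnit.RELATIVE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float).copy()
        vals = np.asarray(self.values, dtype=float).copy()
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths must be finite")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        if np.any(vals < 0):
            raise ValueError("values must be non-negative")
        if self.unit is SpectrumUnit.FRACTION and np.any(vals > 1 + _FRACTION_TOL):
            raise ValueError("fraction spectra must not exceed 1")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    # -- convenience -----------------------------------------------------

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def grid(self) -> np.ndarray:
        return self.wavelengths_nm

    def with_values(self, values: np.ndarray, unit: SpectrumUnit | None = None) -> "Spectrum":
        """Same grid, new values (and optionally a new unit)."""
        return Spectrum(self.wavelengths_nm, values, unit or self.unit)

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths_nm.size == other.wavelengths_nm.size and bool(
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
        )

    def _require_same_grid(self, other: "Spectrum") -> None:
        if not self.same_grid(other):
            raise ValueError("spectra are on different wavelength grids")

    def __mul__(self, other):
        if isinstance(other, Spectrum):
            self._require_same_grid(other)
            return Spectrum(
                self.wavelengths_nm,
                self.values * other.values,
                _product_unit(self.unit, other.unit),
            )
        return Spectrum(self.wavelengths_nm, self.values * float(other), self.unit)

    __rmul__ = __mul__

    def __add__(self, other: "Spectrum") -> "Spectrum":
        self._require_same_grid(other)
        if self.unit is not other.unit:
            raise ValueError(
                f"cannot add spectra with units {self.unit.value} and {other.unit.value}"
            )
        return Spectrum(self.wavelengths_nm, self.values + other.values, self.unit)


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid`` (no extrapolation).

    Returns ``s`` itself when ``grid`` already equals its grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == s.wavelengths_nm.size and np.array_equal(grid, s.wavelengths_nm):
        return s
    lo, hi = s.wavelengths_nm[0], s.wavelengths_nm[-1]
    below = grid < lo
    above = grid > hi
    if below.any() or above.any():
        bad = grid[below][0] if below.any() else grid[above][0]
        raise ValueError(
            f"resampling would extrapolate: requested {bad:g} nm outside "
            f"[{lo:g}, {hi:g}] nm"
        )
    return Spectrum(grid, np.interp(grid, s.wavelengths_nm, s.values), s.unit)


def to_photon_units(s: Spectrum) -> Spectrum:
    """Convert an energy-radiance spectrum to photon radiance.

    A photon of wavelength λ carries energy hc/λ, so per-nm photon radiance
    is energy radiance × λ/(hc) with λ in metres.
    """
    if s.unit is not SpectrumUnit.ENERGY_RADIANCE:
        raise ValueError(
            f"to_photon_units expects energy_radiance input, got {s.unit.value}"
        )
    factor = (s.wavelengths_nm * 1e-9) / (PLANCK_H * SPEED_OF_LIGHT)
    return Spectrum(s.wavelengths_nm, s.values * factor, SpectrumUnit.PHOTON_RADIANCE)


def band_mean(s: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of ``s`` over [lo, hi] divided by (hi − lo).

    The band edges need not be grid points; values there are interpolated.
    """
    if lo >= hi:
        raise ValueError(f"band edges must satisfy lo < hi, got [{lo}, {hi}]")
    if lo < s.wavelengths_nm[0] or hi > s.wavelengths_nm[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] nm outside spectrum range "
            f"[{s.wavelengths_nm[0]:g}, {s.wavelengths_nm[-1]:g}] nm"
        )
    inner = s.wavelengths_nm[(s.wavelengths_nm > lo) & (s.wavelengths_nm < hi)]
    xs = np.concatenate(([lo], inner, [hi]))
    ys = np.interp(xs, s.wavelengths_nm, s.values)
    return float(np.trapezoid(ys, xs) / (hi - lo))


# -- CSV I/O -------------------------------------------------------------

_HEADER = "wavelength_nm,value"


def read_spectrum_csv(
    path,
    unit: SpectrumUnit = SpectrumUnit.RELATIVE,
    wavelength_range: tuple[float, float] | None = None,
) -> Spectrum:
    """Read a two-column spectrum CSV (header ``wavelength_nm,value``).

    Errors carry the offending 1-based line number. ``wavelength_range``
    optionally rejects wavelengths outside a policy window such as the
    400–700 nm working band.
    """
    path = Path(path)
    wavelengths: list[float] = []
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != _HEADER:
            raise ValueError(
                f"{path}: line 1: expected header '{_HEADER}', got '{header}'"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields")
            try:
                wl, val = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if wavelengths and wl <= wavelengths[-1]:
                raise ValueError(
                    f"{path}: line {lineno}: wavelengths not strictly "
                    f"increasing ({wl:g} after {wavelengths[-1]:g})"
                )
            if val < 0:
                raise ValueError(f"{path}: line {lineno}: negative value {val:g}")
            if wavelength_range is not None and not (
                wavelength_range[0] <= wl <= wavelength_range[1]
            ):
                raise ValueError(
                    f"{path}: line {lineno}: wavelength {wl:g} nm outside "
                    f"allowed range [{wavelength_range[0]:g}, "
                    f"{wavelength_range[1]:g}] nm"
                )
            wavelengths.append(wl)
            values.append(val)
    if len(wavelengths) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    return Spectrum(np.array(wavelengths), np.array(values), unit)


def write_spectrum_csv(s: Spectrum, path) -> None:
    """Write ``s`` as CSV; floats use shortest round-trip repr."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for wl, val in zip(s.wavelengths_nm, s.values):
            fh.write(f"{float(wl)!r},{float(val)!r}\n")
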