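"""Run configuration: YAML schema, validation, and scenario assembly.

A run config is a YAML mapping with the blocks

.. code-block:: yaml

    seed: 1                      # required integer
    synthetic: {...}             # SynthConfig fields (may be empty {})
    inputs:                      # optional measured-spectrum CSV overrides
      downwelling: path.csv
      spark: path.csv
      # eye_coaxial, eye_noncoaxial, body_reflectance, body_transmittance,
      # substrate, ocular_media
    sweep: {...}                 # sweep axes, see _build_sweep
    scenario:                    # the single-scenario block for `single`
      shading: average
      ratio: 4.09
      spark_radius_mm: 0.16
      spark_band_mean: 1.34

At least one of ``synthetic`` / ``inputs`` must be present (the generator
fills whatever measured inputs do not override). Validation errors name the
offending field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .detection import Scenario, SweepConfig
from .radiometry import Shading
from .spectra import CANONICAL_GRID, SpectrumUnit, read_spectrum_csv, resample
from .synth import SynthConfig, build_scenario

__all__ = ["RunConfig", "ConfigError", "load_config"]

_INPUT_KEYS = {
    "downwelling": SpectrumUnit.ENERGY_RADIANCE,
    "spark": SpectrumUnit.RELATIVE,
    "eye_coaxial": SpectrumUnit.RELATIVE,
    "eye_noncoaxial": SpectrumUnit.RELATIVE,
    "body_reflectance": SpectrumUnit.RELATIVE,
    "body_transmittance": SpectrumUnit.FRACTION,
    "substrate": SpectrumUnit.RELATIVE,
    "ocular_media": SpectrumUnit.FRACTION,
}


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


def _axis(raw: Any, field: str) -> tuple[float, ...]:
    """An axis is either an explicit list or {start, stop, num}."""
    if isinstance(raw, Mapping):
        missing = {"start", "stop", "num"} - raw.keys()
        if missing:
            raise ConfigError(f"sweep.{field}: missing keys {sorted(missing)}")
        return tuple(np.linspace(raw["start"], raw["stop"], int(raw["num"])))
    if isinstance(raw, (list, tuple)):
        if not raw:
            raise ConfigError(f"sweep.{field}: must not be empty")
        return tuple(float(v) for v in raw)
    raise ConfigError(f"sweep.{field}: expected list or start/stop/num mapping")


def _build_sweep(raw: Mapping[str, Any], seed: int) -> SweepConfig:
    kwargs: dict[str, Any] = {"seed": seed}
    if "spark_radii_mm" in raw:
        kwargs["spark_radii_mm"] = _axis(raw["spark_radii_mm"], "spark_radii_mm")
    if "spark_radiance_means" in raw:
        kwargs["spark_radiance_means"] = _axis(
            raw["spark_radiance_means"], "spark_radiance_means"
        )
    if "ratios" in raw:
        if not raw["ratios"]:
            raise ConfigError("sweep.ratios: must not be empty")
        kwargs["ratio_categories"] = tuple(float(r) for r in raw["ratios"])
    if "shading" in raw:
        if not raw["shading"]:
            raise ConfigError("sweep.shading: must not be empty")
        try:
            kwargs["shading_categories"] = tuple(Shading(s) for s in raw["shading"])
        except ValueError as exc:
            raise ConfigError(f"sweep.shading: {exc}") from None
    if "channels" in raw:
        kwargs["channels"] = tuple(raw["channels"])
    if "target" in raw:
        kwargs["target"] = raw["target"]
    if "distance_min_mm" in raw or "distance_max_mm" in raw:
        lo = int(raw.get("distance_min_mm", 5))
        hi = int(raw.get("distance_max_mm", 45))
        if not 5 <= lo < hi <= 45:
            raise ConfigError(
                "sweep.distance_min_mm/max_mm: need 5 <= min < max <= 45"
            )
        kwargs["distance_grid_mm"] = tuple(range(lo, hi + 1))
    try:
        return SweepConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"sweep: {exc}") from None


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    seed: int
    synthetic: SynthConfig
    sweep: SweepConfig
    input_paths: Mapping[str, Path]
    scenario_ratio: float
    scenario_shading: Shading
    scenario_spark_radius_mm: float
    scenario_spark_band_mean: float
    raw: Mapping[str, Any]

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def load_overrides(self):
        """Read and resample the measured-spectrum CSVs named in ``inputs``."""
        overrides = {}
        for key, path in self.input_paths.items():
            spec = read_spectrum_csv(path, unit=_INPUT_KEYS[key])
            overrides[key] = resample(spec, CANONICAL_GRID)
        return overrides

    def build_single_scenario(self) -> Scenario:
        return build_scenario(
            self.synthetic,
            ratio=self.scenario_ratio,
            shading=self.scenario_shading,
            spark_radius_mm=self.scenario_spark_radius_mm,
            spark_band_mean=self.scenario_spark_band_mean,
            overrides=self.load_overrides(),
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from None
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "seed" not in raw:
        raise ConfigError("seed: required field is missing")
    try:
        seed = int(raw["seed"])
    except (TypeError, ValueError):
        raise ConfigError(f"seed: expected an integer, got {raw['seed']!r}") from None

    if "synthetic" not in raw and "inputs" not in raw:
        raise ConfigError(
            "config must contain a 'synthetic' block, an 'inputs' block, or both"
        )

    synth_raw = raw.get("synthetic") or {}
    if not isinstance(synth_raw, Mapping):
        raise ConfigError("synthetic: expected a mapping")
    known = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(synth_raw) - known
    if unknown:
        raise ConfigError(f"synthetic: unknown fields {sorted(unknown)}")
    try:
        synth = SynthConfig(seed=seed, **{k: v for k, v in synth_raw.items() if k != "seed"})
    except ValueError as exc:
        raise ConfigError(f"synthetic: {exc}") from None

    inputs_raw = raw.get("inputs") or {}
    if not isinstance(inputs_raw, Mapping):
        raise ConfigError("inputs: expected a mapping of names to CSV paths")
    unknown = set(inputs_raw) - set(_INPUT_KEYS)
    if unknown:
        raise ConfigError(
            f"inputs: unknown spectrum names {sorted(unknown)}; "
            f"expected {sorted(_INPUT_KEYS)}"
        )
    input_paths = {}
    for key, p in inputs_raw.items():
        p = Path(p)
        if not p.is_absolute():
            p = path.parent / p
        input_paths[key] = p

    sweep_raw = raw.get("sweep") or {}
    if not isinstance(sweep_raw, Mapping):
        raise ConfigError("sweep: expected a mapping")
    sweep = _build_sweep(sweep_raw, seed)

    sc_raw = raw.get("scenario") or {}
    if not isinstance(sc_raw, Mapping):
        raise ConfigError("scenario: expected a mapping")
    try:
        shading = Shading(sc_raw.get("shading", "average"))
    except ValueError:
        raise ConfigError(
            f"scenario.shading: unknown category {sc_raw.get('shading')!r}"
        ) from None

    return RunConfig(
        seed=seed,
        synthetic=synth,
        sweep=sweep,
        input_paths=input_paths,
        scenario_ratio=float(sc_raw.get("ratio", synth.eye_ratio)),
        scenario_shading=shading,
        scenario_spark_radius_mm=float(
            sc_raw.get("spark_radius_mm", synth.spark_radius_mm)
        ),
        scenario_spark_band_mean=float(
            sc_raw.get("spark_band_mean", synth.spark_band_mean)
        ),
        raw=dict(raw),
    )
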