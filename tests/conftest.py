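import dataclasses

import numpy as np
import pytest

from photoloc import (
    CANONICAL_GRID,
    GammaridOptics,
    LightFieldScenario,
    Scenario,
    Shading,
    SparkModel,
    Spectrum,
    SpectrumUnit,
    SynthConfig,
    ViewerOptics,
    ViewerVisualSystem,
)


def flat(value: float, unit: SpectrumUnit = SpectrumUnit.RELATIVE) -> Spectrum:
    return Spectrum(CANONICAL_GRID, np.full(CANONICAL_GRID.size, value), unit)


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def flat_light_field() -> LightFieldScenario:
    """Flat unit downwelling light with a flat 0.2 sidewelling fraction."""
    L_dw = flat(1.0, SpectrumUnit.ENERGY_RADIANCE)
    sigma = flat(0.2, SpectrumUnit.FRACTION)
    return LightFieldScenario(
        depth_m=10.0,
        L_dw=L_dw,
        L_sw_unshaded=flat(0.2, SpectrumUnit.ENERGY_RADIANCE),
        shading=Shading.NONE,
        sigma=sigma,
    )


@pytest.fixture(scope="session")
def flat_gammarid() -> GammaridOptics:
    return GammaridOptics(
        R_cx=flat(0.3),
        R_nc=flat(0.05),
        ratio=6.0,
        R_body=flat(0.05),
        T_body=flat(0.6, SpectrumUnit.FRACTION),
    )


@pytest.fixture(scope="session")
def flat_scenario(flat_light_field, flat_gammarid) -> Scenario:
    """Fully flat-spectrum scenario: every contrast reduces to closed form."""
    vs = dataclasses.replace(
        ViewerVisualSystem(), T_om=flat(1.0, SpectrumUnit.FRACTION)
    )
    return Scenario(
        light_field=flat_light_field,
        spark=SparkModel(radius_mm=0.16, rho=flat(1.34)),
        gammarid=flat_gammarid,
        substrate=flat(0.1),
        viewer=ViewerOptics(),
        visual_system=vs,
    )
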