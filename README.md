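# photoloc

Radiometric and visual modelling of **diurnal active photolocation**: can a
small benthic fish detect camouflaged micro-prey by the light its own
"blue ocular spark" throws back from the prey's eyes?

The triplefin *Tripterygion delaisi* focuses downwelling light into a
bright, controllable spot on its iris next to the pupil. Gammarid prey
carry strongly *directional* reflectors between the ommatidia of their
compound eyes: they return several-fold more light coaxially than at 45°.
Because the spark sits beside the pupil, the fish views its own reflection
near-coaxially — the geometry in which the prey eye lights up the most.
`photoloc` implements the full physical chain and asks at what distance the
induced radiance change is detectable by the fish's own visual system.

The round-trip model, per wavelength λ and viewing distance d:

```
ambient      L0(λ)    = R_nc(λ) · σ(λ) · L_dw(λ)
increment    ΔL(λ,d)  = R_cx(λ) · ρ(λ) · L_dw(λ) · Ω_spark(d) / π
pupil flux   Φ(λ,d)   = L(λ) · Ω_eye(d) · A_pupil
```

with `Ω(d) = 2π(1 − d/√(d² + r²))` the on-axis disc solid angle, `ρ` the
spark's relative radiance, `R_cx`/`R_nc` the prey eye's coaxial and
non-coaxial relative reflectance, and `σ` the (possibly shaded)
sidewelling-to-downwelling ratio at the prey. The returned increment
carries *two* solid angles and falls off as d⁻⁴: doubling the distance
costs a 16-fold flux drop, which confines active photolocation to mm–cm
range. Photon-unit fluxes are turned into cone quantum catches
(Govardovskii A1 templates, single cone 468 nm, double cone 517+530 nm)
and compared spark-on vs spark-off with the Michelson achromatic contrast
(thresholds 0.008 optimistic / 0.024 conservative) and the
receptor-noise-limited chromatic distance (ω = 0.05, 1:4 densities,
threshold 1 JND). The maximum discernable distance is extracted on a
5–45 mm grid, and a 4-factor sweep (spark radius 0.09–0.25 mm, spark
radiance 0.63–2.09× a white standard, reflectance ratio 2.68/4.09/9.87,
four shading levels) maps where the mechanism helps. The translucent prey
*body* run through the same machinery serves as a negative control.

Measured input spectra are archived externally; a seeded generator
(`photoloc.synth`) emulates them with the published summary statistics
pinned exactly (spark band mean 1.34, peak 2.15 at 472 nm, eye radius
0.0625 mm, pupil radius 0.78 mm, …), so everything here runs offline. Any
generated spectrum can be replaced by a measured CSV. See
`docs/methods.md` for model details and the calibration of the free
parameters.

## Worked example

```python
from photoloc import (Shading, SynthConfig, build_scenario,
                      contrast_curve, max_detection_distance)

sc = build_scenario(SynthConfig(seed=1), ratio=4.09, shading=Shading.AVERAGE)
curve = contrast_curve(sc, "achromatic")       # Michelson vs 5..45 mm
print(max_detection_distance(curve, 0.008))    # optimistic threshold
```

Running `python examples/03_contrast_vs_distance.py` prints:

```
distance  Michelson   JND
     5 mm    0.06532  0.1684
    10 mm    0.01718  0.0467
    15 mm    0.00771  0.0212
    25 mm    0.00279  0.0077
    45 mm    0.00086  0.0024
...
  achromatic, optimistic (0.008) : 14 mm
  achromatic, conservative (0.024): 8 mm
  chromatic (1 JND)               : not detectable on the grid
```

At average conditions the spark raises the prey eye's radiance enough for
the achromatic channel out to 14 mm (optimistic threshold) — beyond the
species' typical strike distance — while the colour shift stays below
1 JND: the mechanism works through brightness, not hue. The other scripts
in `examples/` demonstrate the light-field/spark generators, the three
solid-angle routes, and the full sweep with the body control (which never
crosses threshold: the spark lights up eyes, not bodies).

A thin CLI wraps the same library:

```sh
photoloc sweep --config examples/sweep_config.yaml --out out/
photoloc single --config examples/sweep_config.yaml --distance 10
photoloc generate-fixtures --seed 1 --out fixtures/
photoloc validate-inputs --config examples/sweep_config.yaml
```

Outputs embed the seed and a config hash; identical config + seed
reproduce the CSVs byte for byte.

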