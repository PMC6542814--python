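# Methods

## The model

`photoloc` models **diurnal active photolocation**: a small benthic fish
(the triplefin *Tripterygion delaisi*) focuses downwelling light into a
bright spot on its iris — a "blue ocular spark" — immediately adjacent to
its pupil, and may detect camouflaged prey by the extra light this spark
throws back from the strongly *directional* reflectors between the
ommatidia of a gammarid's compound eye. Because the spark sits next to the
pupil, the viewing geometry is near-coaxial, exactly the direction in which
those reflectors return the most light.

Both eyes are placed on one horizontal axis at normal incidence. Two
radiance components leave the prey eye toward the viewer:

* **ambient** (spark off): the prey's sidewelling light field reflected at
  the weak non-coaxial relative reflectance,
  `L0(λ) = R_nc(λ) · σ(λ) · L_dw(λ)`,
  where `σ` is the sidewelling-to-downwelling ratio of the prey's
  (possibly shaded) position and `L_dw` the white-standard downwelling
  radiance proxy. Independent of distance.
* **spark increment** (spark on): the spark of relative radiance `ρ(λ)`
  and disc radius `r_s` subtends `Ω_s(d) = 2π(1 − d/√(d² + r_s²))` at the
  prey eye, delivering irradiance `ρ·L_dw·Ω_s(d)`; expressed on the
  white-standard radiance scale (a Lambertian white standard under
  irradiance E has radiance E/π) and reflected at the coaxial relative
  reflectance:
  `ΔL(λ, d) = R_cx(λ) · ρ(λ) · L_dw(λ) · Ω_s(d) / π`.

All reflectances and the spark radiance are *relative* quantities (sample
radiance ÷ diffuse-white-standard radiance under the same illumination),
which absorbs the Lambertian 1/π of the ambient illumination; the single
explicit 1/π above is the only place the conversion surfaces. The
directionality of the reflectors is carried entirely by the band-level
coaxial:non-coaxial ratio categories (2.68 minimum, 4.09 mean, 9.87
maximum observed); the reflection itself is treated as diffuse into the
viewing direction. Water attenuation over cm path lengths, self-screening
and veiling light are not modelled.

The per-nm flux entering the viewer's pupil from a disc target of radius
`r_t` is `Φ(λ) = L(λ) · Ω_t(d) · A_pupil`. The spark increment therefore
arrives attenuated by the *product* of two solid angles — `Ω_s(d)·Ω_t(d)`
— and falls off as d⁻⁴ in the far field: doubling the distance cuts the
returned flux 16-fold. This is the signature constraint of any active
sensing system and the reason the mechanism only works at mm–cm range.

## Viewer transduction and contrast

Photon-unit fluxes (energy × λ/hc) are integrated against the ocular-media
transmission and Govardovskii A1 α+β pigment templates for a single cone
(λmax 468 nm) and a double cone (members 517 and 530 nm, catches summed as
the achromatic channel):

    q_i = ∫ Φ(λ) · T_om(λ) · S_i(λ) dλ        (trapezoid, 400–700 nm, 1 nm)

Contrast between spark-on and spark-off:

* **achromatic**: Michelson contrast `(Q₁−Q₂)/(Q₁+Q₂)` on the pooled
  double-cone catch, with an optimistic threshold 0.008 (behaviourally
  measured in the species) and a conservative 0.024;
* **chromatic**: dichromatic receptor-noise-limited distance with log
  receptor signals `Δf_i = ln(q_i,on/q_i,off)` and
  `ΔS = |Δf_single − Δf_double| / √(e_s² + e_d²)` in JND, threshold 1.
  The Weber fraction ω = 0.05 anchors the abundant double-cone class
  (`e_d = ω`) and the sparser single cone gets
  `e_s = ω·√(η_d/η_s)` = 0.1 with the 1:4 single:double density. Log
  signals and this noise-scaling convention are the standard RNL
  parameterisation; the sources for this model do not pin either choice,
  so both are explicit here and configurable via `ViewerVisualSystem`.

Both contrasts are ratios of catches, so the target solid angle, pupil
area and the absolute radiance scale cancel: detection distances depend
only on spectral shapes and the geometry of the spark leg. An absolute
(photon-noise) sensitivity floor is not modelled.

The **maximum discernable distance** is the largest distance on the
5–45 mm grid (nearest focus to the point-source resolution limit of the
viewer) whose contrast meets the threshold. Contrast decreases
monotonically in distance (the increment shrinks, the baseline is
constant), so this equals the first qualifying value scanning from the far
end; a non-monotone curve — impossible for this model, possible for user
supplied curves — triggers a warning and the same far-end scan. "No
crossing anywhere" (NONE/NaN) is encoded distinctly from a crossing at the
5 mm grid minimum.

## Geometry: why the closed form is the default

Solid angles of discs from *extended* receivers have no elementary closed
form; the package provides a seeded Monte-Carlo estimator and a
deterministic Gauss–Legendre quadrature for the receiver-averaged value,
cross-validated against each other and against the exact point-receiver
formula. At the geometries modelled (disc radii ≤ 0.78 mm, distances
≥ 5 mm) the receiver-extent correction is below 0.5% — far below the 1 mm
resolution of the distance grid — so the pipeline defaults to the exact
point formula, which also makes every sweep deterministic without a
sampling budget. Monte-Carlo defaults: 10⁶ samples, standard error
reported, seed a required argument.

## Synthetic study conditions

The measured spectra are archived externally; `photoloc.synth` generates
seeded stand-ins that pin every printed summary statistic and label
everything else a package default:

| parameter | default | status |
|---|---|---|
| spark band-mean relative radiance | 1.34 (swept 0.63–2.09) | measured |
| spark peak | 2.15 at 472 nm | measured |
| spark radius | 0.16 mm (swept 0.09–0.25) | measured |
| coaxial:non-coaxial ratio | 4.09 (categories 2.68/9.87) | measured |
| prey eye radius | 0.0625 mm | measured |
| pupil radius | 0.78 mm | measured (treated as radius; the source phrasing is ambiguous between radius and size) |
| depth of the light profile | 10 m | fixed condition |
| attenuation K(λ) | 0.05 + 0.55·((λ−400)/300)³ m⁻¹ | package default (coastal-like, blue-green window) |
| unshaded σ (band mean) | 0.20 | package default |
| shaded σ: weak/average/strong | 0.10 / 0.05 / 0.025 | package default, calibrated (below) |
| eye non-coaxial reflectance level | 0.02 | package default (detection distances are independent of it; only the ratio matters) |
| body reflectance / transmittance | 0.003 / 0.8 | package default, calibrated (below) |
| substrate | 0.04→0.26 logistic rise past 565 nm | package default (brown-algae-like) |
| ocular media | logistic cut-on at 410 nm, scale 8 nm | package default stand-in |

The spark spectrum is a Gaussian bump (width ≈ 45 nm, slightly seed
jittered) on a pedestal, with pedestal and height solved in closed form so
the grid peak and the band mean are pinned *exactly*; sweeping spark
radiance rescales the whole spectrum (a dimmer spark of the same colour).
The coaxial eye reflectance is the non-coaxial shape times the ratio, so
the band-mean ratio is exact by construction.

**Calibration of the free parameters.** The shading fractions and body
optics are unpublished degrees of freedom, fixed once — analytically, from
the flat-spectrum closed form `M ≈ x/(2+x)` with
`x = R·ρ·(Ω_s/π)/(L0-level·σ)` — so that the packaged conditions
reproduce the qualitative detection-map pattern the model is known to
produce: the most favourable cell (ratio 9.87, brightest/largest spark,
strong shade) saturates the 45 mm grid at the optimistic threshold, the
unshaded column stays mostly short-range or undetectable, and the
translucent body control never crosses threshold beyond 5 mm anywhere in
the sweep (which requires a body reflectance well below the transmitted
substrate radiance; 0.003 with T·R_substrate ≈ 0.06 gives the control a
~1.5× margin below threshold in its worst cell). Steeper shading
fractions (e.g. σ_strong = 0.01) inflate eye *and* body contrasts alike
and push the body control past 5 mm, which is why the gentler ladder above
is the default. These choices shape only the synthetic fixtures, never the
model equations.

**What passing tests show.** The synthetic fixtures exercise every code
path with realistic magnitudes and pinned summary statistics, so green
tests demonstrate the correctness of the radiometric chain, the contrast
model and the sweep logic — not field-accurate detection distances. Real
spectra (jagged reflectance curves, depth- and substrate-dependent σ(λ)
with spectral structure, a measured ocular-media curve) can be substituted
per input via CSV without touching the pipeline; absolute distances will
shift with them, the qualitative structure will not.

## Numerical choices

* Canonical grid 400–700 nm at 1 nm (301 points); linear interpolation for
  resampling (monotone, no overshoot on reflectance data); trapezoidal
  integration throughout. Band edges interpolate when off-grid.
* Physical constants h, c at their SI-exact values.
* Chromatic model is dichromatic (single vs pooled double); treating the
  double-cone members as separate channels would make it trichromatic and
  is deliberately not the default, since the density statement assigns the
  double cone one class. Double-cone pooling uses the *sum* of member
  catches; Michelson is invariant to sum-vs-mean.
* Sweep axes: continuous factors discretised to 9×9 by default
  (configurable); ratio and shading are categorical.
* Degenerate inputs are rejected early with named-field errors (empty
  sweep axes, inverted bands, non-increasing wavelengths, zero catches in
  the log-ratio JND, fraction spectra above 1).

## Problem sizes

The default full sweep (9×9×3×4 cells × 41 distances × 3 channels) runs in
about a second; the packaged test suite uses 3×3×3×4 and 5×5×3×4 sweeps
and 10⁶-sample Monte-Carlo checks, all chosen as comfortable desk-scale
sizes for the precision the assertions need.

## Known limitations

* The contrast chain is scale-invariant, so absolute photon-noise limits
  and temporal contrast sensitivity (the on/off flicker of a real spark)
  are outside the model.
* Only coaxial geometry: no tilted eyes, no occlusion, no spark
  illumination of the substrate behind the prey.
* The synthetic σ ladder and body optics are calibrated defaults, not
  measurements; conclusions about *absolute* detection distances require
  the archived field spectra supplied as CSV overrides.
* The spatial-resolution bound enters only through the 45 mm grid cap.
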