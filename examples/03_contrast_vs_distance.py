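"""Contrast between a spark-lit and unlit prey eye across viewing distance.

Assembles one average scenario (ratio 4.09, average shading, mean spark),
prints the achromatic (Michelson) and chromatic (RNL JND) contrast at a
few distances, and extracts the maximum discernable distance per channel.
"""

from photoloc import (
    Shading,
    SynthConfig,
    ViewerVisualSystem,
    build_scenario,
    contrast_curve,
    max_detection_distance,
    DISTANCE_GRID_MM,
)

sc = build_scenario(SynthConfig(seed=1), ratio=4.09, shading=Shading.AVERAGE)
vs = ViewerVisualSystem()

achrom = contrast_curve(sc, "achromatic")
chrom = contrast_curve(sc, "chromatic")

print("distance  Michelson   JND")
for d in (5, 10, 15, 25, 45):
    i = list(DISTANCE_GRID_MM).index(d)
    print(f"  {d:>4} mm  {achrom[i]:9.5f}  {chrom[i]:6.4f}")
print("(both contrasts shrink as the returned spark light falls off as d^-4)")

print("\nmaximum discernable distance:")
for label, curve, thr in (
    ("achromatic, optimistic (0.008) ", achrom, vs.michelson_optimistic),
    ("achromatic, conservative (0.024)", achrom, vs.michelson_conservative),
    ("chromatic (1 JND)               ", chrom, vs.jnd_threshold),
):
    d = max_detection_distance(curve, thr)
    print(f"  {label}: {'not detectable on the grid' if d is None else f'{d} mm'}")
print("(the spark works through the achromatic channel; the colour shift it")
print(" induces is too small for the chromatic channel on these conditions)")
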