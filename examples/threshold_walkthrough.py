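"""Step through the segmentation stages on one synthetic scene.

Shows the intermediate quantities the pipeline derives on the way to a
grade: the grayscale conversion, the auto-contrast stretch, the automatic
(isodata/intermeans) thresholds for the rib-eye and for the marbling
within it, and the particle analysis that filters out sub-0.5 cm^2 specks.
"""

import ribeyegrade as rg
from ribeyegrade.segmentation import histogram256, intermeans_fixed_points

ci, truth = rg.generate_sample(rg.SyntheticSpec(seed=7, target_marbling_fraction=0.30))

gray = rg.to_grayscale(ci.image)
stretched = rg.auto_contrast(gray)
print(f"gray range before/after auto-contrast: "
      f"[{gray.pixels.min()}, {gray.pixels.max()}] -> "
      f"[{stretched.pixels.min()}, {stretched.pixels.max()}]")

fixed = intermeans_fixed_points(stretched)
print(f"intermeans fixed points of the full histogram: {fixed}")
print("  (smallest = background/rib-eye split; a higher one splits muscle/fat)")

ribeye = rg.segment_ribeye(ci)
marbling = rg.segment_marbling(ci, ribeye)
inside = stretched.pixels[ribeye.pixels]
t_fat = rg.isodata_threshold(histogram256(inside))
print(f"within-ribeye isodata threshold for marbling: {t_fat}")

particles = rg.particle_analysis(marbling, ci.calibration, min_size_cm2=0.5)
total = sum(p.area_cm2 for p in particles)
print(f"marbling particles >= 0.5 cm^2: {len(particles)}, "
      f"total {total:.2f} cm^2 of {rg.px2_to_cm2(ribeye.area_px, ci.calibration):.2f} cm^2 rib-eye")
print(f"marbling percentage: {100 * total / rg.px2_to_cm2(ribeye.area_px, ci.calibration):.1f}% "
      f"(truth {truth.marbling_pct:.1f}%)")
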