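"""Retinotopic quadrant analysis of a fish retina.

Teleost retinas carry a ventrotemporal (VT) density peak. This example
partitions a simulated young-killifish whole-mount into the four quadrants
around the optic nerve head and recovers the configured VT/DN contrast from
the detected centroids.
"""

import rgcquant as rq

full = rq.make_preset("killifish", "6w")
preset = rq.make_preset("killifish", "6w", retinal_area=full.retinal_area * 0.15)
retina = rq.generate_retina(preset, dpi=0, pixel_size=1.0, seed=9)
meas = rq.analyze_image(retina.image, preset=preset)

part = rq.quadrant_partition(retina.onh_center, retina.dorsal_axis_angle, nasal_side="right")
qs = rq.quadrant_stats(meas.centroids, meas.mask, part)

print(qs.round(1).to_string())
print()
ratio = qs.loc["VT", "density"] / qs.loc["DN", "density"]
print(f"VT/DN density ratio: {ratio:.2f} (preset gradient contrast {preset.gradient_contrast})")
print(f"counts sum to total detections: {qs['count'].sum()} == {meas.count}")
print(f"areas sum to retinal area: {qs['area_mm2'].sum():.4f} == {meas.area_mm2:.4f} mm^2")
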