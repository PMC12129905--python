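"""Accept the counting engine the way trained counters are accepted.

Per-frame counts from the detector are regressed against ground truth over
36 fixed-size (177 x 177 um) frames pooled from an uninjured and an injured
whole-mount, sampled equally from the central, mid and peripheral retina.
The detector passes if its slope is near 1, its R^2 is high, and its R^2 is
not materially below the agreement between two emulated human counters.
"""

import rgcquant as rq

full = rq.make_preset("zebrafish", "21w")
preset = rq.make_preset("zebrafish", "21w", retinal_area=full.retinal_area * 0.2)

report = rq.run_acceptance_protocol(preset, seed=5)
model, inter, match = report["model"], report["inter_counter"], report["match"]

print(f"injured time-point pooled : {report['injured_dpi']:.0f} dpi")
print(f"model vs truth            : slope {model.slope:.3f}, R^2 {model.r_squared:.3f}")
print(f"counter A vs counter B    : slope {inter.slope:.3f}, R^2 {inter.r_squared:.3f}")
print(f"point-level (uninjured)   : precision {match.precision:.3f}, recall {match.recall:.3f}")
print(f"ACCEPTED: {report['accepted']}"
      "  (slope in [0.9, 1.1], R^2 >= 0.9, within 0.05 of inter-counter R^2)")
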