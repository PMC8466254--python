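"""Measure the six accuracy metrics between a planned and a placed implant.

A 10-mm fixture planned straight down at the origin is 'placed' 0.3 mm
buccally, 0.4 mm deeper and tilted 2 degrees.  The printed record shows how
the displacement splits into global/lateral/depth parts and the tilt angle.
"""

import numpy as np

from guidedev import Implant, measure_deviations, safety_flags

planned = Implant(platform=[0, 0, 0], apex=[0, 0, -10], id="site1")

tilt = np.radians(2.0)
axis = np.array([np.sin(tilt), 0.0, -np.cos(tilt)])  # 2 deg toward buccal
platform = np.array([0.3, 0.0, -0.4])                # 0.3 lateral, 0.4 deep
placed = Implant(platform=platform, apex=platform + 10 * axis, id="site1")

rec = measure_deviations(planned, placed)
print(f"global platform : {rec.global_platform_mm:.3f} mm")
print(f"lateral platform: {rec.lateral_platform_mm:.3f} mm")
print(f"global apex     : {rec.global_apex_mm:.3f} mm")
print(f"lateral apex    : {rec.lateral_apex_mm:.3f} mm")
print(f"depth (signed)  : {rec.depth_mm:+.3f} mm (positive = deeper)")
print(f"angular         : {rec.angular_deg:.3f} deg")
print("safety flags    :", {k: v for k, v in safety_flags(rec).items() if v})
# The platform numbers satisfy global^2 = lateral^2 + depth^2 (0.5 = 3-4-5);
# the apex deviation is larger because the 2-degree tilt adds ~0.35 mm of
# lateral displacement over the 10-mm implant length.
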