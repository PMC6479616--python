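"""Tangential distortion of a rotating-mirror scanner and its linear range.

The mirror sweeps the view across the object plane as y_d = r*tan(gamma);
away from the normal point the optical path lengthens and objects shrink by
h = 1/sin(2*theta).  The linear range is the gamma interval keeping the
relative elongation below a tolerance.
"""

import math

from mirrorscan import (
    angle_to_object_y, linear_range, linearized_object_y, path_elongation,
    width_scale,
)

r = 348.73  # mirror-to-plane distance, mm

print("gamma (deg)   y_d (mm)   linearized   path elong. (mm)   width scale")
for gamma_deg in (0, 5, 10, 15, 20, 22.5):
    gamma = math.radians(gamma_deg)
    theta = (math.pi / 2 - gamma) / 2
    print(f"{gamma_deg:10.1f} {angle_to_object_y(theta, r):10.2f} "
          f"{linearized_object_y(theta, r):12.2f} "
          f"{path_elongation(theta, r):14.2f} {width_scale(theta):14.4f}")

# widest gamma interval with at most 8% relative elongation
lr = linear_range(0.08)
print(f"\nlinear range for dr/r <= 8%: gamma in +/-{lr.gamma_half_width:.4f} rad "
      f"(+/-{math.degrees(lr.gamma_half_width):.2f} deg)")
print(f"at the pi/8 half-width the bound is "
      f"{100 * (1 / math.cos(math.pi / 8) - 1):.2f}%, i.e. it rounds to 8%")
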