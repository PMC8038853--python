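"""Recover the leaf coordinate system from an arbitrarily posed leaf.

A bent leaf is rotated by a random rigid pose; the pipeline then
re-derives the vein axis l (first principal component, oriented away
from the plant's emergence point) and the surface normal h (minimal
side-view projected area over a 1-degree sweep). Printed angles measure
how far the recovered axes are from the generator's ground truth.
"""

import numpy as np

import leafsurf as ls

spec = ls.SyntheticLeafSpec(
    density=2.0, bend_sag=30.0, roll_amplitude=0.0, noise_sigma=0.2,
    apply_pose=True, seed=7,
)
leaf = ls.generate_leaf(spec)
axes = ls.determine_axes(leaf.world)


def angle(u, v):
    return np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


print(f"winning sweep angle theta': {axes.theta_opt:.0f} deg")
print(f"vein axis error:    {angle(axes.l, leaf.axes.l):.2f} deg")
print(f"normal axis error:  {angle(axes.h, leaf.axes.h):.2f} deg")
print("Errors within a few degrees mean the leaf frame is recovered")
print("reliably regardless of how the leaf was oriented in the scanner.")
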