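"""Build a synthetic SPECT/CT knee phantom and derive its anatomic frames.

The phantom is generated in an arbitrary scanner pose; the femoral frame
reconstructed from its landmarks undoes that pose, and the realignment
angle quantifies how far the patient lay from the anatomic orientation.
"""

import numpy as np

import orthospect as osp

spec = osp.PhantomSpec(
    hotspots=(osp.Hotspot((0.0, 18.0, 10.0), (12.0, 10.0, 12.0), 4.0),),
    pose_rotation=osp.rotation_about((0, 0, 1), 12.0),
    pose_translation=np.array([25.0, -10.0, 40.0]),
    noise="poisson",
    seed=1,
)
ph = osp.make_phantom(spec)
print(f"CT grid {ph['ct'].shape} at {ph['ct'].spacing} mm")
print(f"SPECT grid {ph['spect'].shape} at {ph['spect'].spacing} mm")

lm = ph["truth"].landmarks
fem = osp.femoral_frame(lm)
tib = osp.tibial_frame(fem, fem.origin, lm.talus_centre)
realign = osp.frame_rotation(osp.AnatomicFrame.identity(), fem)

print(f"knee centre (world mm): {np.round(fem.origin, 1)}")
print(f"femoral PROX axis:      {np.round(fem.prox, 3)}")
print(f"realignment vs scanner: total {realign['total_deg']:.1f} deg, "
      f"axial {realign['about_PROX_deg']:.1f} deg")
# The axial angle recovers the 12-degree pose injected above: measurements
# taken in this frame are independent of how the patient lay in the scanner.
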