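"""Generate a synthetic distal-femur phantom and extract its slice-wise
2D morphometric distributions.

The phantom is a cortical tube that flares distally, with a plate
lattice in the medullary cavity whose density peaks at a virtual growth
plate and decays proximally.  Every slice is segmented into cortex /
trabecular ROI automatically, then all 2D parameters are measured per
slice and expressed over percent bone length.
"""

import numpy as np

from osteoslice import (PhantomSpec, build_frame, compute_slice_metrics,
                        make_phantom, segment_stack)

spec = PhantomSpec(length_slices=120, image_size=110,
                   outer_radius_px=44.0, inner_radius_px=36.0,
                   lattice_period_px=12, lattice_thickness_px=6,
                   density_decay=0.006, growth_plate_z=90,
                   voxel_size_mm=0.05, seed=0)
stack, meta, truth = make_phantom(spec)
frame = build_frame(stack, meta)
masks = segment_stack(stack)
metrics = compute_slice_metrics(masks, stack.voxel_size_mm, frame=frame)

print(f"phantom: {stack.n_slices} slices, "
      f"{frame.percent_array().min():.1f}-100.0% bone length, "
      f"growth plate at {frame.percent_of_slice(meta.growth_plate_slice):.1f}%")

sel = metrics.iloc[::24][["percent_length", "ba_ta", "ct_th_2d", "ct_ar_2d", "j_2d"]]
print(sel.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

gp = meta.growth_plate_slice
print(f"\nBA/TA: epiphysis {metrics.ba_ta[gp + 20]:.3f} | "
      f"metaphyseal peak {metrics.ba_ta[gp - 5]:.3f} | "
      f"40 slices proximal {metrics.ba_ta[gp - 40]:.3f} | "
      f"80 slices proximal {metrics.ba_ta[gp - 80]:.3f}")
print("The trabecular area fraction peaks just proximal of the growth "
      "plate and decays monotonically into the shaft — the slice-wise "
      "view keeps that spatial structure instead of averaging it away.")
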