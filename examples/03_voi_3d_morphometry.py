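"""Targeted 3D morphometry on a percent-bone-length VOI.

After the slice-wise survey localizes where structure changes, a VOI is
cut on the percent axis and conventional 3D parameters are measured:
BV/TV, direct (maximal-inscribed-sphere) Tb.Th/Tb.Sp, Tb.N, pattern
factor, connectivity density, BS/BV and the un-plate index (uPi ≈ 1 for
plates, ≈ 2 for rods).
"""

from osteoslice import (PhantomSpec, VOISpec, build_frame, extract_voi,
                        make_phantom, segment_stack, trabecular_3d)

spec = PhantomSpec(length_slices=80, image_size=110,
                   outer_radius_px=44.0, inner_radius_px=36.0,
                   trabecular_pattern="rods",
                   lattice_period_px=12, lattice_thickness_px=6,
                   density_decay=0.0, epiphysis_ba_ta=None,
                   growth_plate_z=20, voxel_size_mm=0.05, seed=0)
stack, meta, _ = make_phantom(spec)
frame = build_frame(stack, meta)
masks = segment_stack(stack)

pct = frame.percent_array()
voi = VOISpec("epiphyseal", float(pct[30]), float(pct[70]), "trabecular")
bone, roi = extract_voi(masks, frame, voi)
m = trabecular_3d(bone, roi, stack.voxel_size_mm)

print(f"VOI {voi.name}: {bone.shape[0]} slices, "
      f"{voi.lo_percent:.1f}-{voi.hi_percent:.1f}% bone length")
print(f"  BV/TV   = {m.bv_tv:.3f}")
print(f"  Tb.Th   = {m.tb_th:.3f} mm (direct);  Tb.Sp = {m.tb_sp:.3f} mm")
print(f"  Tb.N    = {m.tb_n:.2f} 1/mm;  BS/BV = {m.bs_bv:.2f} 1/mm")
print(f"  uPi     = {m.upi:.2f}  (rod lattice: expect ~2)")
print(f"  Conn.D  = {m.conn_d:.1f} 1/mm^3;  Tb.Pf = {m.tb_pf:.2f} 1/mm")
print("\nThe rod lattice is read as a rod-dominated structure (uPi near 2); "
      "connected lattices give high connectivity density, and BV/TV matches "
      "the lattice density the generator imposed.")
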