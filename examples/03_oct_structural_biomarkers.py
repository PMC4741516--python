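"""Structural biomarkers from a segmented OCT b-scan pair.

A synthetic horizontal/vertical scan pair is generated with the
ellipsoid zone (EZ) visible over +/- 1.75 mm, flat outer-retina layers,
a foveal pit, and a shared cubic curvature; the biomarkers below are the
layer-thickness summaries, band widths, and fovea location, before and
after curvature flattening.
"""

from hovmap import TruthSurface, flatten, structural_biomarkers
from hovmap.synthetic import LayerSpec, simulate_bscan_pair

layers = LayerSpec()  # ONL+ 90, ELM->EZ 25, OS+ 35 um; 60 um pit
scan_h, scan_v = simulate_bscan_pair(
    TruthSurface(), ez_halfwidth_mm=1.75, layers=layers, axial_noise_sd=1.0,
    seed=7,
)

b = structural_biomarkers(scan_h)
print("horizontal scan:")
print(f"  fovea          : {b['fovea_mm']:+.3f} mm (truth 0.000)")
print(f"  W_EZ           : {b['W_EZ']:.3f} mm (truth 3.500), "
      f"truncated={b['ez_truncated']}")
print(f"  T_ONL (FOV/AVG): {b['T_ONL_FOV']:.1f} / {b['T_ONL_AVG']:.1f} um")
print(f"  T_OS  (FOV/AVG): {b['T_OS_FOV']:.1f} / {b['T_OS_AVG']:.1f} um")
print(f"  T_REC (FOV/AVG): {b['T_REC_FOV']:.1f} / {b['T_REC_AVG']:.1f} um")

flat = structural_biomarkers(flatten(scan_h))
print("\nafter cubic pRPE flattening:")
print(f"  T_REC_AVG unchanged: {flat['T_REC_AVG'] == b['T_REC_AVG']}")
print(f"  W_EZ {b['W_EZ']:.4f} -> {flat['W_EZ']:.4f} mm "
      f"({100 * abs(flat['W_EZ'] - b['W_EZ']) / b['W_EZ']:.3f}% change)")
print("\nThickness summaries are exactly invariant under flattening (the"
      "\nshift cancels within each column); band widths move only by the"
      "\nremoved axial offset between their endpoints.")
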