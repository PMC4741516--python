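"""Build a hill-of-vision surface from duplicate exams and read off the
classical global indices and solid-angle volumes.

A synthetic eye with a preserved central island (half sensitivity at 12
degrees eccentricity) is examined twice with 1 dB threshold noise; the
exams are merged by reliability weighting and interpolated with an exact
thin-plate spline at the 0.36 degree protocol spacing.
"""

import numpy as np

from hovmap import (
    NormalFieldModel,
    TruthSurface,
    combine_exams,
    defect_hov,
    global_indices,
    hov_volume,
    interpolate_hov,
    make_test_grid,
    simulate_exams,
)

truth = TruthSurface(family="logistic_edge", s_max=30, r0=12, w=2)
grid = make_test_grid()  # 164 points spanning 140 x 130 degrees
exam1, exam2 = simulate_exams(truth, grid, noise_sd=1.0, rf_pair=(5, 10), seed=42)

exam = combine_exams(exam1, exam2)
surface = interpolate_hov(exam, spacing=0.36)

normal_model = NormalFieldModel()
normal = normal_model.surface(exam.age, like=surface)
defect = defect_hov(normal, surface)

ms, md, lv = global_indices(
    exam, normal_model.at(grid.points[:, 0], grid.points[:, 1], exam.age)
)
print(f"MS  = {ms:6.2f} dB     (mean sensitivity over the 164 test points)")
print(f"MD  = {md:6.2f} dB     (mean defect, positive = loss vs age-normal)")
print(f"LV  = {lv:6.2f} dB^2   (loss variance: how uneven the loss is)")

sv, sv30 = hov_volume(surface), hov_volume(surface, 30.0)
dv, dv30 = hov_volume(defect), hov_volume(defect, 30.0)
print(f"S_V   = {sv:6.2f} dB.sr  (total hill-of-vision volume)")
print(f"S_V30 = {sv30:6.2f} dB.sr  (central 30-degree volume)")
print(f"D_V   = {dv:6.2f} dB.sr  (defect volume; N_V - S_V = "
      f"{hov_volume(normal) - sv:6.2f})")
print(f"D_V30 = {dv30:6.2f} dB.sr")
print("\nWith a preserved island of radius ~12 deg, nearly all sensitivity"
      "\nvolume lies centrally: S_V ~= S_V30, while the defect volume is"
      "\ndominated by the lost periphery.")
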