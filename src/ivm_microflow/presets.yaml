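# Shipped study-condition presets, one per tissue x cell-line group.
#
# tissue: FW = femur window (bone), DSC = dorsal skinfold chamber (muscle).
# n_implanted: chambers implanted per group (15 FW / 20 DSC).
# engraft_prob: engraftment probability matching the reported take rates
#   (14/15, 14/15, 10/15 in bone; 14/20, 14/20, 9/20 in muscle).
# day7_area_mm2: absolute day-7 tumor area; muscle tumors start 2-fold
#   larger than bone, and Pc3 starts at half the burden of the other lines.
# rel_area_by_day: relative area anchors, day 7 defined as 100%.  Muscle
#   day-14 values are log-linear interpolations of the day-7/21 anchors.
# censor_day: last observable day before tumor-induced femur fracture
#   mandates sacrifice (bone LnCap after day 14, bone Pc3 after day 21).
# noise_sigma: log-scale SD of multiplicative area measurement noise.

growth_presets:
  "FW:LnCap":
    tissue: FW
    cell_line: LnCap
    n_implanted: 15
    engraft_prob: 0.93333333
    day7_area_mm2: 1.0
    rel_area_by_day: {7: 100.0, 14: 382.0}
    censor_day: 14
    noise_sigma: 0.15
  "FW:Du145":
    tissue: FW
    cell_line: Du145
    n_implanted: 15
    engraft_prob: 0.93333333
    day7_area_mm2: 1.0
    rel_area_by_day: {7: 100.0, 14: 250.0, 21: 340.0}
    censor_day: null
    noise_sigma: 0.15
  "FW:Pc3":
    tissue: FW
    cell_line: Pc3
    n_implanted: 15
    engraft_prob: 0.66666667
    day7_area_mm2: 0.5
    rel_area_by_day: {7: 100.0, 14: 274.0, 21: 730.0}
    censor_day: 21
    noise_sigma: 0.15
  "DSC:LnCap":
    tissue: DSC
    cell_line: LnCap
    n_implanted: 20
    engraft_prob: 0.70
    day7_area_mm2: 2.0
    rel_area_by_day: {7: 100.0, 14: 143.2, 21: 205.0}
    censor_day: null
    noise_sigma: 0.15
  "DSC:Du145":
    tissue: DSC
    cell_line: Du145
    n_implanted: 20
    engraft_prob: 0.70
    day7_area_mm2: 2.0
    rel_area_by_day: {7: 100.0, 14: 150.0, 21: 225.0}
    censor_day: null
    noise_sigma: 0.15
  "DSC:Pc3":
    tissue: DSC
    cell_line: Pc3
    n_implanted: 20
    engraft_prob: 0.45
    day7_area_mm2: 1.0
    rel_area_by_day: {7: 100.0, 14: 144.9, 21: 210.0}
    censor_day: null
    noise_sigma: 0.15

# Qualitative per-tissue vessel-field regimes for the synthetic FITC channel:
# striated muscle is denser with narrower, slower capillaries; bone fields
# are sparser with wider, faster sinusoidal vessels.  Values are synthetic
# defaults (the per-group bar magnitudes are not published numerically).
vessel_field_presets:
  FW:
    field_size_um: [160.0, 160.0]
    pixel_size_um: 0.5
    n_segments: 3
    diameter_range_um: [12.0, 24.0]
    velocity_range_um_s: [400.0, 900.0]
    perfused_fraction: 0.9
    frame_rate_hz: 30.0
    duration_s: 10.0
  DSC:
    field_size_um: [160.0, 160.0]
    pixel_size_um: 0.5
    n_segments: 5
    diameter_range_um: [6.0, 14.0]
    velocity_range_um_s: [200.0, 500.0]
    perfused_fraction: 0.9
    frame_rate_hz: 30.0
    duration_s: 10.0

# Representative true permeability regimes (cm/s) for synthetic traces:
# bone vasculature is substantially leakier than striated muscle.
permeability_presets:
  FW: {P_true_cm_s: 3.0e-7, I0: 1000.0, Ib: 100.0, vs_ratio_um: 4.5}
  DSC: {P_true_cm_s: 1.2e-7, I0: 1000.0, Ib: 100.0, vs_ratio_um: 2.5}
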