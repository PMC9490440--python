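# Default pipeline configuration.
#
# Detection limits are conservative placeholders (oxide wt%): replace them
# with the per-run instrument limits when processing real microprobe data.
# Ratio band centers are literature-standard defaults and deliberately live
# here, not in code, so they can be reconciled against any lab's protocol.

paths:
  input_dir: results/study
  output_dir: results

seed: 0

anchors: [450, 800, 900, 1200, 1300, 1800, 2200]

ratios:
  - name: IRSF
    numerator: [{center: 565}, {center: 605}]
    denominator: [{center: 587.5, tolerance: 12.5, mode: valley}]
  - name: C/P
    numerator: [{center: 1415}]
    denominator: [{center: 1035}]
  - name: BPI
    numerator: [{center: 1415}]
    denominator: [{center: 605}]
  - name: API
    numerator: [{center: 1540}]
    denominator: [{center: 605}]
    applicability: burnt-only
  - name: C/C
    numerator: [{center: 1415}]
    denominator: [{center: 1540}]
    applicability: burnt-only
  - name: CN/P
    numerator: [{center: 2010}]
    denominator: [{center: 1035}]
  - name: CO/CO3
    numerator: [{center: 1740}]
    denominator: [{center: 1415}]
  - name: N/P
    numerator: [{center: 1660}]
    denominator: [{center: 1035}]
    applicability: unburnt-only
  - name: APR
    numerator: [{center: 1640}]
    denominator: [{center: 1035}]
    applicability: unburnt-only
  - name: PHT
    numerator: [{center: 625}]
    denominator: [{center: 610}]

markers:
  btcp_center: 1123
  shoulder_center: 547
  extra_band: [1080, 1100]
  oh_cl_center: 3494   # literature apatite OH-Cl position; configurable
  prominence_floor: 0.005

detection_limits:
  P2O5: 0.05
  CaO: 0.05
  Al2O3: 0.01
  Na2O: 0.01
  SiO2: 0.01
  K2O: 0.01
  Cl: 0.01
  MgO: 0.01
  SrO: 0.01
  FeO: 0.01
  MnO: 0.01

stats:
  sidedness: two-sided
  mct_method: holm
  regression_unit: sample
  alpha: 0.05

decisions:
  k_threshold: 0.07
  k_band: 0.01
  fresh_floor: 0.20
  k_scale: elemental
  cn_p_floor: 0.02
  irsf_cut: 3.8

simulate:
  points_per_zone: 5
  absorbance_noise_sd: 0.005
  low_total_fraction: 0.02
  oc_uptake: 0.02
  extra_peak_absent_34d: false
  include_btcp: false
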