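# Default model constants: regulatory thresholds, toxicity values, exposure
# parameters and classification schemes for the six heavy metal(loid)s
# assessed in wetland overlying water (Hg, As, Cu, Zn, Pb, Cd).
#
# Units: concentrations and thresholds ug/L; reference doses (rfd_*)
# ug/kg/d; slope factors (sf_*) (ug/kg/d)^-1; dermal permeability kp cm/h.
# A null toxicity value means the metal is not assessable for that endpoint.
#
# Every value here may be overridden by a user config file with the same
# structure; overrides are validated against the same type invariants.

metals:
  Hg: {class2_threshold: 0.05, detection_limit: 0.04, kp: 1.0e-3,
       rfd_ing: 0.3, rfd_derm: 0.024, sf_ing: null, sf_derm: null}
  As: {class2_threshold: 50.0, detection_limit: 0.30, kp: 1.0e-3,
       rfd_ing: 0.3, rfd_derm: 0.123, sf_ing: 1.5e-3, sf_derm: 3.66e-3}
  Cu: {class2_threshold: 1000.0, detection_limit: 0.08, kp: 1.0e-3,
       rfd_ing: 40.0, rfd_derm: 12.0, sf_ing: null, sf_derm: null}
  Zn: {class2_threshold: 1000.0, detection_limit: 0.67, kp: 6.0e-4,
       rfd_ing: 300.0, rfd_derm: 60.0, sf_ing: null, sf_derm: null}
  Pb: {class2_threshold: 10.0, detection_limit: 0.09, kp: 1.0e-4,
       rfd_ing: 1.4, rfd_derm: 0.42, sf_ing: null, sf_derm: null}
  Cd: {class2_threshold: 5.0, detection_limit: 0.05, kp: 1.0e-3,
       rfd_ing: 0.5, rfd_derm: 0.005, sf_ing: 6.1e-3, sf_derm: 3.8e-4}

# Exposure parameters per population. IR L/day, EF days/year, ED years,
# BW kg, AT days, SA cm^2, T_event h/event, EV events/day.
# NOTE: the BW standard deviation of 0.15 kg is kept exactly as published
# for this study even though it is implausibly small for a population;
# override it here if a realistic body-weight spread is wanted.
exposure_profiles:
  children:
    ir: {family: normal, params: {mean: 1.25, sd: 0.3}, lower_trunc: 0.0125}
    ef: {family: triangular, params: {min: 180.0, mode: 350.0, max: 360.0},
         upper_trunc: 366.0}
    ed: 2.5
    bw: {family: normal, params: {mean: 20.0, sd: 0.15}, lower_trunc: 0.2}
    at_noncancer: 912.5
    at_cancer: 25550.0
    sa: 7422.0
    t_event: 0.58
    ev: 1.0
  adults:
    ir: {family: normal, params: {mean: 1.95, sd: 0.3}, lower_trunc: 0.0195}
    ef: {family: triangular, params: {min: 180.0, mode: 350.0, max: 360.0},
         upper_trunc: 366.0}
    ed: 26.0
    bw: {family: normal, params: {mean: 70.0, sd: 0.15}, lower_trunc: 0.7}
    at_noncancer: 9490.0
    at_cancer: 25550.0
    sa: 18182.0
    t_event: 1.0
    ev: 1.0

# Classification schemes. Each bin is (upper bound, label, whether the
# upper bound itself belongs to the bin). Bins are ordered from least to
# most severe; the last bin is unbounded above.
classification_schemes:
  Pi:
    - {upper: 0.7, label: no contamination, inclusive: true}
    - {upper: 1.0, label: slight contamination, inclusive: true}
    - {upper: 2.0, label: light contamination, inclusive: true}
    - {upper: 3.0, label: moderate contamination, inclusive: true}
    - {upper: .inf, label: high contamination, inclusive: false}
  NPI:
    - {upper: 0.7, label: no contamination, inclusive: true}
    - {upper: 1.0, label: slight contamination, inclusive: true}
    - {upper: 2.0, label: light contamination, inclusive: true}
    - {upper: 3.0, label: moderate contamination, inclusive: true}
    - {upper: .inf, label: high contamination, inclusive: false}
  HQ:
    - {upper: 1.0, label: no significant non-carcinogenic risk, inclusive: true}
    - {upper: .inf, label: potential non-carcinogenic risk, inclusive: false}
  CR:
    - {upper: 1.0e-6, label: very low risk, inclusive: false}
    - {upper: 1.0e-4, label: low risk, inclusive: false}
    - {upper: 1.0e-3, label: moderate risk, inclusive: false}
    - {upper: 0.1, label: high risk, inclusive: false}
    - {upper: .inf, label: extremely high risk, inclusive: false}
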