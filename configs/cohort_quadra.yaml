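# Synthetic spec for the long-axial-FOV (Quadra) cohort: 553 patients at a
# fixed 150 MBq prescription (observed median 149.5 MBq). Matches
# petctdose.synthetic.default_quadra_spec().
cohort_name: Quadra
strata:
  - {label: "<50",   n: 39,  target_median_weight: 46.0,  weight_spread: 4.0}
  - {label: "50–59", n: 99,  target_median_weight: 56.0,  weight_spread: 3.0}
  - {label: "60–69", n: 122, target_median_weight: 64.8,  weight_spread: 3.0}
  - {label: "70–79", n: 126, target_median_weight: 74.0,  weight_spread: 3.0}
  - {label: "80–89", n: 84,  target_median_weight: 84.0,  weight_spread: 3.0}
  - {label: "90–99", n: 43,  target_median_weight: 93.0,  weight_spread: 3.0}
  - {label: ">100",  n: 40,  target_median_weight: 111.5, weight_spread: 8.0}
activity_protocol:
  name: fixed
  standard_mbq: 150.0
  jitter_median: 0.9966666666666667   # 149.5 / 150
  jitter_sigma: 0.03
dlp_model: {intercept: 4.685, slope: 0.01864, noise_sd: 0.18}
height_model: {mean_bmi: 26.0, bmi_sd: 4.0, min_bmi: 15.0, max_bmi: 45.0}
height_missing_rate: 0.7576853526220615   # 419/553 -> 134 heights recorded
gender_ratio_male: 0.5768535262206148     # 319/553
seed: 20241
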