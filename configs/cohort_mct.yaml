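# Synthetic spec for the conventional-scanner (mCT) cohort: 484 patients,
# 250 MBq standard / 300 MBq above 90 kg, jitter calibrated to the observed
# 303 MBq cohort median. Matches petctdose.synthetic.default_mct_spec().
cohort_name: mCT
strata:
  - {label: "<50",   n: 16,  target_median_weight: 45.9,  weight_spread: 4.0}
  - {label: "50–59", n: 75,  target_median_weight: 56.0,  weight_spread: 3.0}
  - {label: "60–69", n: 110, target_median_weight: 65.0,  weight_spread: 3.0}
  - {label: "70–79", n: 107, target_median_weight: 74.0,  weight_spread: 3.0}
  - {label: "80–89", n: 78,  target_median_weight: 83.5,  weight_spread: 3.0}
  - {label: "90–99", n: 63,  target_median_weight: 93.0,  weight_spread: 3.0}
  - {label: ">100",  n: 35,  target_median_weight: 108.0, weight_spread: 8.0}
activity_protocol:
  name: weight_tiered
  standard_mbq: 250.0
  heavy_mbq: 300.0
  heavy_threshold_kg: 90.0
  jitter_median: 1.17
  jitter_sigma: 0.20
dlp_model: {intercept: 4.798, slope: 0.01649, noise_sd: 0.18}
height_model: {mean_bmi: 26.0, bmi_sd: 4.0, min_bmi: 15.0, max_bmi: 45.0}
height_missing_rate: 0.20041322314049587  # 97/484 -> 387 heights recorded
gender_ratio_male: 0.5640495867768595     # 273/484
seed: 20101
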