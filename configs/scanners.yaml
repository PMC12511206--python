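# CT scanner acquisition settings for the two PET/CT systems (the
# conventional-scanner CT is listed with its two most common scan ranges,
# which depend on the number of PET bed positions).
# scan_range_cm uses the signed anatomical convention: vertex at +94 cm,
# caudal positions negative.
# normalized_ctdiw (mGy per 100 mAs) is a scanner constant not published in
# the source audit; the values here are back-inferred from the all-patient
# median (mAs, CTDIvol) pair of each scanner and are placeholders to be
# replaced with measured constants where available.
scanners:
  quadra_de:
    scanner_name: Siemens Definition Edge (Quadra)
    tube_voltage_kvp: 120.0
    slice_collimation_mm: 0.6
    active_channels: 128
    pitch: 0.8
    scan_range_cm: [-14.0, 94.0]
    rotation_time_s: 0.28
    normalized_ctdiw: 6.39
  mct_as_100:
    scanner_name: Siemens Definition AS (mCT, 100 cm range)
    tube_voltage_kvp: 120.0
    slice_collimation_mm: 1.2
    active_channels: 16
    pitch: 0.8
    scan_range_cm: [-6.0, 94.0]
    rotation_time_s: 0.33
    normalized_ctdiw: 7.78
  mct_as_110:
    scanner_name: Siemens Definition AS (mCT, 110 cm range)
    tube_voltage_kvp: 120.0
    slice_collimation_mm: 1.2
    active_channels: 16
    pitch: 0.8
    scan_range_cm: [-16.0, 94.0]
    rotation_time_s: 0.33
    normalized_ctdiw: 7.78
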