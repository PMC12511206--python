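# ICRP FDG dose coefficients and DLP conversion used by the audit.
# Assignment bands: >65 kg -> 70 kg adult; [45, 65] kg -> 57 kg adult;
# <45 kg -> 33 kg child. Entries must be ordered by decreasing lower bound
# and the last entry must reach down to 0 kg.
dlp_conversion: 0.018   # mSv per mGy·cm, whole-body CT
models:
  - name: 70 kg adult
    model_weight: 70.0
    coefficient: 0.019   # mSv/MBq
    lower_bound: 65.0
    lower_inclusive: false
  - name: 57 kg adult
    model_weight: 57.0
    coefficient: 0.024
    lower_bound: 45.0
    lower_inclusive: true
  - name: 33 kg child
    model_weight: 33.0
    coefficient: 0.036
    lower_bound: 0.0
    lower_inclusive: false
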