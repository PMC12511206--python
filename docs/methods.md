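# Methods

## The audit model

The pipeline estimates, per patient, the effective dose of a whole-body
[¹⁸F]FDG PET/CT examination and compares two scanner-era cohorts.

**PET component.** The phantom-based dose is

    ED_PET = A · Γ(W)

where `A` is the injected activity (MBq) and `Γ(W)` the ICRP FDG dose
coefficient of the reference phantom matched to the patient weight `W`:
0.019 mSv/MBq (70 kg adult) for `W > 65` kg, 0.024 mSv/MBq (57 kg adult)
for `45 ≤ W ≤ 65` kg, and 0.036 mSv/MBq (33 kg child) for `W < 45` kg.
The "45–65 kg" band is read as the closed interval, so both edges belong to
the 57 kg phantom; the assignment is a partition of all positive weights.
The 0.019 mSv/MBq adult coefficient is used deliberately; the 0.017 value
argued for in recent literature has not appeared in an ICRP publication.

Two first-order corrections for the phantom/patient mismatch are carried in
parallel:

* weight scaling: `ED_PET-WS = ED_PET · M / W`, with `M` the phantom mass;
* blood-volume scaling: `ED_PET-BV = ED_PET · IBV / 70`, with the indexed
  blood volume `IBV = 70 / sqrt(BMI / 22)` ml/kg. At the reference BMI of
  22 kg/m² this is the identity; it is strictly decreasing in BMI, which is
  the intended behaviour for large patients in whom much of the activity is
  held in tissue with low specific blood volume. BMI needs a height; a
  patient without a recorded height gets *no* blood-volume dose (absent,
  never zero or imputed) and is excluded from blood-volume medians, with
  exclusion counts reported in the audit metadata.

**CT component.** `ED_CT = DLP · k` with the whole-body conversion factor
`k = 0.018 mSv/(mGy·cm)` (configurable). Totals are `ED_CT + ED_PET`
per PET method.

**CT exposure bookkeeping.** For the phantom-software workflow the package
reproduces the input arithmetic only: total collimation = slice
collimation × simultaneously acquired channels; table feed = total
collimation × pitch; and the mAs recovered from the scanner-reported
CTDIvol via `mAs = 100 · CTDIvol · pitch / nCTDIw` (from CTDIvol =
CTDIw/pitch and CTDIw = nCTDIw·mAs/100). The normalized CTDIw (mGy per
100 mAs) is a per-scanner constant that the source records do not state;
the shipped configs carry values back-inferred from each scanner's
all-patient median (mAs, CTDIvol) pair and are documented placeholders —
every test of the mAs inversion is purely algebraic. The male/female
"potential error" of an all-male phantom assumption is defined as
`100 · (ED_female − ED_male) / ED_female`; the female-model denominator is
the convention that reproduces both published values (16.9% and 16.1%) and
is adopted and documented here. Phantom-based organ dosimetry itself
(Monte Carlo phantoms, automatic exposure control) is out of scope; the
published phantom outputs are treated as reference inputs.

## Cohort comparison

Patients are stratified into seven weight bands, `<50`, `50–59`, …,
`90–99`, `>100` kg, implemented as half-open bins `[lower, lower+10)` with
`>100 = [100, ∞)`; exactly 100 kg is assigned upward so the bins stay
contiguous. Per quantity (weight, activity, ED_CT, three PET doses, three
totals), per stratum and overall, the audit reports median and IQR
(quartiles by linear interpolation between order statistics — the common
default in scientific software, documented because IQRs differ slightly
across quantile conventions), the percentage difference of the comparison
cohort against the reference (conventional-era) cohort median, and a
two-sided Mann–Whitney U p-value. Medians are used to blunt outliers; the
significance flag is α = 0.05 with no multiple-testing correction, matching
the source analysis. The Mann–Whitney implementation uses the exact null
when the pooled size is ≤ 12 and the samples are tie-free (a threshold
chosen so exact tests stay fast and deterministic), and otherwise the
normal approximation with midranks, tie-corrected variance and continuity
correction; the test suite checks it exhaustively against a brute-force
enumeration oracle for every tie-free rank configuration with pooled size
≤ 10. The CT share of the total dose is computed per patient as
`100 · ED_CT / ED_TOTAL-WS` and summarized by stratum medians.

All statistics are computed at full precision; rounding (one decimal for
mSv and percentages) happens only in rendered tables, which mark p < 0.05
with `*` and leave absent blood-volume cells empty.

## Synthetic cohorts

The hospital records behind the audit are not public, so a seeded generator
emulates the two cohorts' statistical structure; its defaults *are* the
study conditions:

* **Weights.** Per-stratum counts and target medians follow the published
  weight table (484 and 553 patients). Within a stratum, weights are
  truncated normal centred on the target median and truncated to the
  stratum band — the published data constrain only counts and medians, so
  the simplest documented distribution is used. Spreads are 3 kg for the
  10-kg bands, 4 kg for `<50` and 8 kg for `>100`; the open-ended bands are
  truncated at 35 and 160 kg to avoid implausible tails.
* **Activity.** Conventional protocol: 250 MBq, rising to 300 MBq above
  90 kg; LAFOV protocol: fixed 150 MBq. Both are multiplied by lognormal
  jitter (multiplicative, positivity-preserving). The conventional cohort's
  observed median (303 MBq) sits above protocol — attributed to concurrent
  clinical trials requiring higher activities — so its jitter median is a
  calibration constant, 1.17 (log-sd 0.20), chosen in closed form so the
  mixture median lands near 303 MBq without modelling trial subgroups
  explicitly; the LAFOV jitter median is 149.5/150 (log-sd 0.03). These
  constants describe the generator, not the hospital data.
* **DLP.** `log DLP = a + b·W + ε`, `ε ~ N(0, 0.18)`; `(a, b)` per cohort
  are least-squares fits through the published per-stratum CT-dose medians
  converted back to DLP, so stratum median ED_CT tracks the published
  column (residuals of the fit are < 4%, sampling noise ~2%, comfortably
  inside the ±15% calibration band the generator targets).
* **Height/gender.** Height is present for exactly round(n·(1−rate))
  patients (387/484 and 134/553), back-computed from a truncated-normal BMI
  draw (mean 26, sd 4, truncated to [15, 45] kg/m² — a realistic adult
  oncology case mix); gender is sampled at the published cohort ratios and
  carried only for reporting, since no in-scope equation depends on it.

A single integer seed drives everything; identical spec + seed yields a
byte-identical table.

**What the generator does not emulate:** within-stratum weight shape beyond
the median, any activity–weight correlation inside a protocol tier,
scan-length/bed-position variation, repeat scans of the same patient, or
secular drift within an era. Passing the recovery checks therefore shows
the pipeline reproduces the study's headline statistics *under these
generating assumptions*, not that it would reproduce every stratum p-value
of the hospital data.

## Numerical choices and degenerate inputs

* Invalid scalars (non-positive weight, negative activity or DLP) raise
  typed errors; empty samples raise a distinct empty-input error; schema
  violations in a patient table are collected and reported together with
  row indices. Missing height is never an error, only an absence.
* Percent differences always use the conventional-era cohort as reference,
  the convention consistent with every reproducible published value.
* Written reports keep full precision so a report re-read from disk equals
  the computed values exactly.
* Audit runs log cohort sizes, height-exclusion counts and warn on strata
  with n < 5, where medians are unstable.

## Problem sizes

Tests and the acceptance script run the generator at the full study sizes
(484 + 553 patients) — the whole pipeline takes seconds. The exhaustive
Mann–Whitney oracle check enumerates all ~2 000 tie-free rank
configurations with pooled size ≤ 10 against a full-labelling brute force.

## Known limitations

* The cohort medians of the real audit cannot be reproduced exactly without
  the hospital records; synthetic recovery is checked within stated
  tolerance bands (activity reduction −50.7 ± 2 points; LAFOV CT share
  73 ± 6 points) rather than as exact targets.
* Organ-level dosimetry, tissue-weighting computation, image
  reconstruction and the dose-reduction techniques discussed around LAFOV
  systems (tin filtration, MLAA, deep-learning attenuation correction) are
  out of scope.
* The DLP→ED conversion uses a single whole-body factor; it is not valid
  for partial-coverage protocols (e.g. vertex-to-abdomen neurological
  scans).
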