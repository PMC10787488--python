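# Default configuration: cardiology department of a large Chinese tertiary
# hospital. 87 ward beds, two EP labs open 08:00-22:00 Monday-Friday, two
# electrophysiologists on duty each workday; eleven EP procedure types.
# Stays are in days, operative/clean-up times in minutes.
calendar:
  workdays: [Mon, Tue, Wed, Thu, Fri]
  lab_open: "08:00"
  lab_close: "22:00"
  arrival_time: "07:00"
  start_weekday: Sun
horizon:
  warmup_days: 10
  observation_days: 61
  replications: 1000
resources:
  beds: 87
  labs: 2
  physicians_on_duty: 2
arrivals:
  TEP: {mean: 2.446, sd: 2.358}
  CLEP: {mean: 3.875, sd: 2.684}
  NEP: {mean: 13.161, sd: 5.990}
weekday_allocations:
  Mon: [0.727, 0.273]
  Tue: [0.184, 0.816]
  Wed: [0.500, 0.500]
  Thu: [0.532, 0.468]
  Fri: [0.292, 0.708]
clep_los: {mean: 5.427, sd: 4.261}
nep_los: {mean: 3.758, sd: 2.718}
seed: 20220501
procedure_classes:
  - name: Paroxysmal AF ablation
    proportion: 0.184
    operative_time: {mean: 204.947, sd: 66.735, min: 65, max: 340}
    cleanup: {mean: 7.467, sd: 7.477, min: 2, max: 40}
    length_of_stay: {mean: 5.050, sd: 2.350, min: 3, max: 11}
    preop_stay: {mean: 2.000, sd: 2.151, min: 1, max: 8}
  - name: Persistent AF ablation
    proportion: 0.096
    operative_time: {mean: 208.688, sd: 51.927, min: 128, max: 321}
    cleanup: {mean: 5.800, sd: 2.833, min: 2, max: 11}
    length_of_stay: {mean: 3.375, sd: 1.061, min: 3, max: 6}
    preop_stay: {mean: 1.375, sd: 1.061, min: 1, max: 4}
  - name: PVC ablation
    proportion: 0.162
    operative_time: {mean: 107.206, sd: 40.630, min: 35, max: 202}
    cleanup: {mean: 6.963, sd: 4.485, min: 1, max: 25}
    length_of_stay: {mean: 2.810, sd: 1.209, min: 2, max: 7}
    preop_stay: {mean: 1.400, sd: 0.681, min: 0, max: 3}
  - name: SVT ablation
    proportion: 0.176
    operative_time: {mean: 99.067, sd: 30.770, min: 70, max: 209}
    cleanup: {mean: 5.130, sd: 2.117, min: 1, max: 10}
    length_of_stay: {mean: 2.478, sd: 0.730, min: 1, max: 4}
    preop_stay: {mean: 1.250, sd: 0.550, min: 0, max: 2}
  - name: AFlutter/PAC/AT ablation
    proportion: 0.059
    operative_time: {mean: 212.545, sd: 149.095, min: 70, max: 574}
    cleanup: {mean: 9.286, sd: 9.032, min: 1, max: 28}
    length_of_stay: {mean: 4.000, sd: 2.646, min: 2, max: 9}
    preop_stay: {mean: 1.333, sd: 0.816, min: 1, max: 3}
  - name: GP ablation
    proportion: 0.022
    operative_time: {mean: 99.000, sd: 52.849, min: 50, max: 155}
    cleanup: {mean: 6.500, sd: 2.121, min: 5, max: 8}
    length_of_stay: {mean: 2.500, sd: 0.707, min: 2, max: 3}
    preop_stay: {mean: 2.000, sd: 0.000, min: 2, max: 2}
  - name: PFO closure
    proportion: 0.022
    operative_time: {mean: 35.333, sd: 6.110, min: 30, max: 42}
    cleanup: {mean: 7.500, sd: 3.536, min: 5, max: 10}
    length_of_stay: {mean: 3.000, sd: 0.000, min: 3, max: 3}
    preop_stay: {mean: 1.000, sd: 0.000, min: 1, max: 1}
  - name: ICD implant
    proportion: 0.015
    operative_time: {mean: 99.250, sd: 41.979, min: 65, max: 160}
    cleanup: {mean: 6.667, sd: 2.887, min: 5, max: 10}
    length_of_stay: {mean: 5.000, sd: 0.000, min: 5, max: 5}
    preop_stay: {mean: 1.000, sd: 0.000, min: 1, max: 1}
  - name: Dual-chamber PM implant
    proportion: 0.059
    operative_time: {mean: 104.063, sd: 31.693, min: 49, max: 167}
    cleanup: {mean: 8.444, sd: 4.773, min: 2, max: 15}
    length_of_stay: {mean: 4.500, sd: 1.732, min: 3, max: 7}
    preop_stay: {mean: 2.000, sd: 1.414, min: 1, max: 3}
  - name: CRT PM implant
    proportion: 0.037
    operative_time: {mean: 190.200, sd: 67.087, min: 94, max: 267}
    cleanup: {mean: 5.600, sd: 3.362, min: 2, max: 10}
    length_of_stay: {mean: 6.600, sd: 3.715, min: 4, max: 12}
    preop_stay: {mean: 2.200, sd: 2.168, min: 1, max: 6}
  - name: Miscellaneous EP procedures
    proportion: 0.169
    operative_time: {mean: 86.741, sd: 54.488, min: 27, max: 305}
    cleanup: {mean: 6.600, sd: 4.619, min: 2, max: 25}
    length_of_stay: {mean: 2.917, sd: 1.165, min: 2, max: 5}
    preop_stay: {mean: 1.167, sd: 0.577, min: 1, max: 3}
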