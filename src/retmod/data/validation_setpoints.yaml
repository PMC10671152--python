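# Method conditions of the validation setpoints (gradient tables in
# time_min / organic_pct form, as printed in method descriptions).
# ternary_fraction: 0.0 = neat ACN, 0.5 = 50% MeOH in ACN, 1.0 = neat MeOH.
chiralcel_od:
  "1":
    temp_c: 15
    flow_ml_min: 0.7
    ternary_fraction: 0.0
    gradient: [[0, 26], [70, 86]]
  "2":
    temp_c: 20
    flow_ml_min: 0.7
    ternary_fraction: 0.0
    gradient: [[0, 26], [40, 86], [45, 86]]
  "3":
    temp_c: 30
    flow_ml_min: 0.7
    ternary_fraction: 0.0
    gradient: [[0, 34], [24, 53], [40, 95], [45, 95]]
  "4":
    temp_c: 20
    flow_ml_min: 0.7
    ternary_fraction: 1.0
    gradient: [[0, 50], [50, 100], [60, 100]]
chiral_cdph:
  "1":
    temp_c: 5
    flow_ml_min: 0.5
    ternary_fraction: 1.0
    gradient: [[0, 60], [50, 100], [55, 100]]
  "2":
    temp_c: 5
    flow_ml_min: 0.5
    ternary_fraction: 1.0
    gradient: [[0, 50], [30, 100], [42, 100]]
  "3":
    temp_c: 5
    flow_ml_min: 0.7
    ternary_fraction: 1.0
    gradient: [[0, 50], [30, 100], [40, 100]]
  "4":
    temp_c: 5
    flow_ml_min: 0.5
    ternary_fraction: 0.5
    gradient: [[0, 50], [40, 100]]
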