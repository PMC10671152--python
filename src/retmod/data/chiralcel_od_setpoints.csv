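column,setpoint,analyte,predicted_rt,experimental_rt
chiralcel_od,1,ezetimibe_diol,23.72,25.73
chiralcel_od,1,desfluoro_ezetimibe,32.20,34.86
chiralcel_od,1,ezetimibe,33.97,36.16
chiralcel_od,1,thp_compound,35.79,38.17
chiralcel_od,1,ezetimibe_ketone,41.79,44.59
chiralcel_od,1,tbdms_ketone,56.38,58.33
chiralcel_od,1,benzylated_ezetimibe,63.41,65.94
chiralcel_od,2,ezetimibe_diol,20.19,20.12
chiralcel_od,2,desfluoro_ezetimibe,25.72,25.48
chiralcel_od,2,ezetimibe,26.70,26.25
chiralcel_od,2,thp_compound,27.80,27.33
chiralcel_od,2,ezetimibe_ketone,31.80,31.40
chiralcel_od,2,tbdms_ketone,40.10,39.57
chiralcel_od,2,benzylated_ezetimibe,44.31,43.62
chiralcel_od,3,ezetimibe_diol,17.50,17.57
chiralcel_od,3,ezetimibe,25.70,27.81
chiralcel_od,3,thp_compound,27.55,30.06
chiralcel_od,3,ezetimibe_ketone,32.27,35.40
chiralcel_od,3,tbdms_ketone,39.38,41.58
chiralcel_od,3,benzylated_ezetimibe,42.26,43.60
chiralcel_od,4,ezetimibe_diol,27.29,25.00
chiralcel_od,4,ezetimibe,36.61,35.91
chiralcel_od,4,monofluoro_ezetimibe,38.28,37.26
chiralcel_od,4,ezetimibe_ketone,45.92,46.41
chiralcel_od,4,tbdms_ketone,50.29,52.44
chiralcel_od,4,benzylated_ezetimibe,52.23,55.50
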